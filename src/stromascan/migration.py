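"""Trajectory metrics and persistent-random-walk motility fitting.

Cell tracks are tables with columns ``track_id, frame, t_min, x_um, y_um``
(uniform sampling).  From these the module computes instantaneous speeds,
step headings, the time-and-ensemble-averaged mean squared displacement
(MSD), and fits the persistent random walk (Fürth) model

    MSD(t) = 2 n_d mu [ t - P (1 - exp(-t / P)) ],    n_d = 2,

by nonlinear least squares for the motility coefficient mu (um^2/min) and
the directional persistence time P (min).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

__all__ = [
    "MSDCurve",
    "PRWFit",
    "prw_msd",
    "instantaneous_speeds",
    "step_directions",
    "ensemble_msd",
    "fit_prw",
    "fit_per_track",
]

TRACK_COLUMNS = ("track_id", "frame", "t_min", "x_um", "y_um")
MIN_TRACK_FRAMES = 10  # tracks shorter than this are excluded from ensembles


@dataclass
class MSDCurve:
    """Ensemble mean squared displacement versus lag time."""

    lag_min: np.ndarray
    msd_um2: np.ndarray
    n_pairs: np.ndarray
    n_tracks: int


@dataclass
class PRWFit:
    """Fitted persistent-random-walk parameters with diagnostics.

    ``identifiable_P`` is False when the persistence time ran into its
    bound or its standard error exceeds the estimate (e.g. for purely
    ballistic or purely diffusive curves).
    """

    mu_um2_per_min: float
    P_min: float
    n_d: int
    rss: float
    converged: bool
    identifiable_P: bool
    stderr_mu: float
    stderr_P: float


def prw_msd(t, mu: float, P: float, n_d: int = 2):
    """Fürth-formula MSD of a persistent random walk."""
    t = np.asarray(t, dtype=float)
    return 2.0 * n_d * mu * (t - P * (1.0 - np.exp(-t / P)))


def _validate_track(track: pd.DataFrame) -> np.ndarray:
    t = np.asarray(track["t_min"], dtype=float)
    if t.size < 2:
        raise ValueError("a trajectory needs at least 2 samples")
    dt = np.diff(t)
    if np.any(dt <= 0):
        raise ValueError("time stamps must be strictly increasing")
    if np.ptp(dt) > 0.01 * dt.mean():
        raise ValueError("non-uniform sampling interval (gap detected)")
    return dt


def instantaneous_speeds(track: pd.DataFrame) -> np.ndarray:
    """Per-step speed (um/min): consecutive displacement over the interval."""
    dt = _validate_track(track)
    dx = np.diff(np.asarray(track["x_um"], dtype=float))
    dy = np.diff(np.asarray(track["y_um"], dtype=float))
    return np.hypot(dx, dy) / dt


def step_directions(track: pd.DataFrame, axial: bool = False) -> np.ndarray:
    """Per-step heading in degrees from +x toward +y (image y points down).

    Full-circle headings lie in [0, 360); with ``axial=True`` they are
    folded modulo 180 for comparison with fiber-orientation distributions.
    """
    _validate_track(track)
    dx = np.diff(np.asarray(track["x_um"], dtype=float))
    dy = np.diff(np.asarray(track["y_um"], dtype=float))
    ang = np.rad2deg(np.arctan2(dy, dx)) % 360.0
    return ang % 180.0 if axial else ang


def _track_msd(xy: np.ndarray, max_lag: int) -> tuple[np.ndarray, np.ndarray]:
    """Time-averaged MSD of one track over all overlapping pairs per lag."""
    n = xy.shape[0]
    msd = np.empty(max_lag)
    npairs = np.empty(max_lag, dtype=np.int64)
    for lag in range(1, max_lag + 1):
        d = xy[lag:] - xy[:-lag]
        msd[lag - 1] = np.mean(np.sum(d * d, axis=1))
        npairs[lag - 1] = n - lag
    return msd, npairs


def ensemble_msd(
    tracks: pd.DataFrame,
    max_lag_fraction: float = 1.0 / 3.0,
    min_frames: int = MIN_TRACK_FRAMES,
) -> MSDCurve:
    """Pair-count-weighted ensemble MSD from a trajectory table.

    Each track contributes its time-averaged MSD over all overlapping
    start/end pairs; tracks are combined weighted by pair counts.  Lags are
    restricted to at most ``max_lag_fraction`` of the track duration, where
    the time-averaged estimator is reliable.  Tracks shorter than
    ``min_frames`` samples are skipped.
    """
    if not 0 < max_lag_fraction <= 1:
        raise ValueError("max_lag_fraction must lie in (0, 1]")
    sums: dict[int, float] = {}
    counts: dict[int, int] = {}
    dts = []
    n_used = 0
    for _, track in tracks.groupby("track_id", sort=True):
        track = track.sort_values("frame")
        if len(track) < max(min_frames, 3):
            continue
        dt = _validate_track(track)
        dts.append(dt.mean())
        xy = np.column_stack(
            [np.asarray(track["x_um"], float), np.asarray(track["y_um"], float)]
        )
        max_lag = max(int(np.floor(max_lag_fraction * (len(track) - 1))), 1)
        msd, npairs = _track_msd(xy, max_lag)
        for lag in range(1, max_lag + 1):
            sums[lag] = sums.get(lag, 0.0) + msd[lag - 1] * npairs[lag - 1]
            counts[lag] = counts.get(lag, 0) + int(npairs[lag - 1])
        n_used += 1
    if n_used == 0:
        raise ValueError("no track long enough to compute an MSD curve")
    dt_mean = float(np.mean(dts))
    lags = np.array(sorted(sums))
    return MSDCurve(
        lag_min=lags * dt_mean,
        msd_um2=np.array([sums[k] / counts[k] for k in lags]),
        n_pairs=np.array([counts[k] for k in lags], dtype=np.int64),
        n_tracks=n_used,
    )


def fit_prw(
    curve: MSDCurve,
    n_d: int = 2,
    weight_by_pairs: bool = False,
) -> PRWFit:
    """Fit the Fürth formula to an MSD curve for (mu, P).

    Unweighted nonlinear least squares with positivity bounds; the initial
    motility is the slope of the last half of the curve divided by 2 n_d
    and the initial persistence time is the first lag.  An optional
    1/n_pairs weighting is available but off by default.  Non-convergence
    after bounded restarts yields a flagged result, not an exception.
    """
    t = np.asarray(curve.lag_min, dtype=float)
    y = np.asarray(curve.msd_um2, dtype=float)
    if t.size < 4:
        raise ValueError("at least 4 lags are required to fit (mu, P)")

    half = t.size // 2
    slope = max(
        np.polyfit(t[half:], y[half:], 1)[0] if t.size - half >= 2 else y[-1] / t[-1],
        1e-12,
    )
    mu0 = slope / (2.0 * n_d)
    P0 = t[0]
    # a persistence time beyond the observed lags is not identifiable
    p_upper = 10.0 * t[-1]
    bounds = ([1e-12, 1e-6], [np.inf, p_upper])
    sigma = np.sqrt(1.0 / curve.n_pairs) if weight_by_pairs else None

    best = None
    converged = False
    for p_start in (P0, 10.0 * P0, 0.1 * P0):
        try:
            popt, pcov = curve_fit(
                lambda tt, mu, P: prw_msd(tt, mu, P, n_d),
                t, y, p0=[mu0, p_start], bounds=bounds, sigma=sigma,
                maxfev=10000,
            )
        except RuntimeError:
            continue
        rss = float(np.sum((prw_msd(t, *popt, n_d) - y) ** 2))
        if best is None or rss < best[2]:
            best = (popt, pcov, rss)
        converged = True
        break  # first successful start wins; restarts only on failure
    if best is None:
        return PRWFit(
            mu_um2_per_min=mu0, P_min=P0, n_d=n_d, rss=float("inf"),
            converged=False, identifiable_P=False,
            stderr_mu=float("nan"), stderr_P=float("nan"),
        )
    (mu, P), pcov, rss = best
    with np.errstate(invalid="ignore"):
        err = np.sqrt(np.diag(pcov))
    stderr_mu, stderr_P = float(err[0]), float(err[1])
    at_bound = P >= 0.99 * p_upper or P <= bounds[0][1] * 1.01
    identifiable = converged and not at_bound and P <= t[-1] and not (
        np.isfinite(stderr_P) and stderr_P / P > 1.0
    )
    if not np.isfinite(stderr_P):
        identifiable = False
    return PRWFit(
        mu_um2_per_min=float(mu), P_min=float(P), n_d=n_d, rss=rss,
        converged=converged, identifiable_P=bool(identifiable),
        stderr_mu=stderr_mu, stderr_P=stderr_P,
    )


def fit_per_track(
    tracks: pd.DataFrame,
    max_lag_fraction: float = 1.0 / 3.0,
    n_d: int = 2,
) -> pd.DataFrame:
    """Fit the PRW model to each track's own MSD curve.

    Returns one row per usable track (``track_id, mu_um2_per_min, P_min,
    rss, converged, identifiable_P``).  Ensemble fitting via
    :func:`ensemble_msd` + :func:`fit_prw` is the default analysis; this
    per-cell mode quantifies cell-to-cell variability.
    """
    rows = []
    for tid, track in tracks.groupby("track_id", sort=True):
        if len(track) < MIN_TRACK_FRAMES:
            continue
        try:
            curve = ensemble_msd(track, max_lag_fraction)
            fit = fit_prw(curve, n_d=n_d)
        except ValueError:
            continue
        rows.append(
            {
                "track_id": tid,
                "mu_um2_per_min": fit.mu_um2_per_min,
                "P_min": fit.P_min,
                "rss": fit.rss,
                "converged": fit.converged,
                "identifiable_P": fit.identifiable_P,
            }
        )
    return pd.DataFrame(rows)
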