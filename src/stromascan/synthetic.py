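"""Seeded phantoms for the scaffold/migration pipeline.

Generators for (i) fibrous-matrix images emulating the four stromal
morphology classes seen in ovarian tissue (normal stroma, benign tumor,
high-risk, high-grade), (ii) persistent-random-walk cell trajectories with
known motility parameters, (iii) elliptical cell masks, and (iv) punctate
focal-adhesion-like spot images.  Every generator takes an integer seed and
returns ground truth alongside the rendered data, so each downstream stage
can be validated without any microscopy data.

Coordinate convention: pixel (row, col), origin at the image top-left,
x = col * pixel_size (rightward), y = row * pixel_size (downward).  Angles
are measured from the +x axis toward +y and, for axial quantities
(orientations), are reported modulo 180 degrees.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.signal import lfilter

__all__ = [
    "MorphologyParams",
    "PRWParams",
    "SpotFieldParams",
    "MORPHOLOGY_PRESETS",
    "morphology_preset",
    "generate_fiber_image",
    "generate_trajectories",
    "generate_cell_mask",
    "generate_spot_image",
]


@dataclass(frozen=True)
class MorphologyParams:
    """Parameters of one fibrous-matrix morphology class.

    Orientation dispersion is controlled by a von Mises concentration
    ``orientation_kappa`` on doubled angles (axial data); ``kappa = 0`` is
    isotropic.  Crimping (waviness) is a sinusoidal centerline perturbation
    with amplitude ``crimp_amplitude_um`` and wavelength
    ``crimp_wavelength_um``.
    """

    class_label: str
    image_size_px: tuple[int, int] = (400, 400)
    pixel_size_um: float = 0.5
    n_fibers: int = 60
    fiber_width_um: float = 1.5
    fiber_length_um: float = 80.0
    orientation_mean_deg: float = 0.0
    orientation_kappa: float = 0.0
    crimp_amplitude_um: float = 0.0
    crimp_wavelength_um: float = 20.0
    peak_intensity: float = 200.0
    background_level: float = 5.0
    noise_model: str = "poisson"  # "poisson", "gaussian", or "none"
    noise_sd: float = 2.0  # used only for gaussian noise

    def validate(self) -> None:
        if any(s <= 0 for s in self.image_size_px):
            raise ValueError("image_size_px entries must be positive")
        if self.pixel_size_um <= 0:
            raise ValueError("pixel_size_um must be positive")
        if self.n_fibers < 0:
            raise ValueError("n_fibers must be non-negative")
        if self.fiber_width_um <= 0 or self.fiber_length_um <= 0:
            raise ValueError("fiber width/length must be positive")
        if not 0 <= self.orientation_mean_deg < 180:
            raise ValueError("orientation_mean_deg must lie in [0, 180)")
        if self.orientation_kappa < 0 or self.crimp_amplitude_um < 0:
            raise ValueError("kappa and crimp amplitude must be non-negative")
        if self.crimp_amplitude_um > 0 and self.crimp_wavelength_um <= 0:
            raise ValueError("crimp_wavelength_um must be positive")
        if self.noise_model not in ("poisson", "gaussian", "none"):
            raise ValueError(f"unknown noise model {self.noise_model!r}")


# Class presets.  The normal stroma is a mesh of randomly oriented straight
# fibers; the benign class keeps the random mesh but with thicker, more
# fibrotic fibers; high-risk tissue has strongly aligned straight fibers;
# high-grade tumors show aligned fibers with a wavy (crimped) periodicity.
# Per-class widths and wavelengths are plausible values for ovarian stroma,
# not calibrated measurements.
MORPHOLOGY_PRESETS: dict[str, MorphologyParams] = {
    "normal": MorphologyParams(
        class_label="normal", orientation_kappa=0.0, fiber_width_um=1.5
    ),
    "benign": MorphologyParams(
        class_label="benign", orientation_kappa=0.0, fiber_width_um=3.0,
        n_fibers=40,
    ),
    "high_risk": MorphologyParams(
        class_label="high_risk", orientation_kappa=10.0,
        orientation_mean_deg=45.0, fiber_width_um=1.5,
    ),
    "high_grade": MorphologyParams(
        class_label="high_grade", orientation_kappa=10.0,
        orientation_mean_deg=45.0, fiber_width_um=1.5,
        crimp_amplitude_um=2.0, crimp_wavelength_um=25.0,
    ),
}


def morphology_preset(class_label: str, **overrides) -> MorphologyParams:
    """Return the preset for a morphology class, optionally overridden."""
    try:
        preset = MORPHOLOGY_PRESETS[class_label]
    except KeyError:
        raise ValueError(
            f"unknown morphology class {class_label!r}; "
            f"choose from {sorted(MORPHOLOGY_PRESETS)}"
        ) from None
    return replace(preset, **overrides) if overrides else preset


def _sample_axial_angles(
    rng: np.random.Generator, n: int, mean_deg: float, kappa: float
) -> np.ndarray:
    """Sample axial angles (deg in [0, 180)) from a von Mises on doubled angles."""
    if kappa == 0:
        return rng.uniform(0.0, 180.0, size=n)
    doubled = rng.vonmises(np.deg2rad(2.0 * mean_deg), kappa, size=n)
    return np.rad2deg(doubled) / 2.0 % 180.0


def generate_fiber_image(
    params: MorphologyParams, seed: int
) -> tuple["FiberImage", pd.DataFrame]:
    """Render a fibrous-matrix phantom and return it with its ground truth.

    Each fiber is a straight or sinusoidally crimped centerline with a
    Gaussian cross-section of FWHM ``fiber_width_um``; its orientation is a
    draw from a von Mises distribution on doubled angles.  The ground-truth
    table has columns ``fiber_id, point_index, x_um, y_um, local_angle_deg``
    (one row per rendered centerline point inside the image).

    Returns
    -------
    image : FiberImage
    truth : pandas.DataFrame
    """
    from .blueprint import FiberImage  # deferred to avoid import cycle

    params.validate()
    rng = np.random.default_rng(seed)
    n_rows, n_cols = params.image_size_px
    px = params.pixel_size_um
    height_um = n_rows * px
    width_um = n_cols * px

    acc = np.zeros((n_rows, n_cols), dtype=float)
    records: list[tuple[int, int, float, float, float]] = []

    angles = _sample_axial_angles(
        rng, params.n_fibers, params.orientation_mean_deg, params.orientation_kappa
    )
    # centerline sampling step: quarter pixel for a smooth rasterization
    ds = px / 4.0
    half = params.fiber_length_um / 2.0
    s = np.arange(-half, half + ds / 2, ds)
    amp = params.crimp_amplitude_um
    wav = params.crimp_wavelength_um

    for fid in range(params.n_fibers):
        theta = np.deg2rad(angles[fid])
        cx = rng.uniform(0.0, width_um)
        cy = rng.uniform(0.0, height_um)
        phase = rng.uniform(0.0, 2.0 * np.pi)
        ux, uy = np.cos(theta), np.sin(theta)
        nx, ny = -uy, ux
        if amp > 0:
            k = 2.0 * np.pi / wav
            off = amp * np.sin(k * s + phase)
            slope = amp * k * np.cos(k * s + phase)
        else:
            off = np.zeros_like(s)
            slope = np.zeros_like(s)
        x = cx + s * ux + off * nx
        y = cy + s * uy + off * ny
        local = (angles[fid] + np.rad2deg(np.arctan(slope))) % 180.0

        inside = (x >= 0) & (x < width_um) & (y >= 0) & (y < height_um)
        xi, yi, li = x[inside], y[inside], local[inside]
        for idx in range(xi.size):
            records.append((fid, idx, xi[idx], yi[idx], li[idx]))
        # bilinear deposition of unit mass per unit length
        col = xi / px
        row = yi / px
        r0 = np.floor(row).astype(int)
        c0 = np.floor(col).astype(int)
        fr = row - r0
        fc = col - c0
        for dr, dc, w in (
            (0, 0, (1 - fr) * (1 - fc)),
            (0, 1, (1 - fr) * fc),
            (1, 0, fr * (1 - fc)),
            (1, 1, fr * fc),
        ):
            rr = r0 + dr
            cc = c0 + dc
            ok = (rr >= 0) & (rr < n_rows) & (cc >= 0) & (cc < n_cols)
            np.add.at(acc, (rr[ok], cc[ok]), w[ok])

    sigma_px = params.fiber_width_um / (2.0 * np.sqrt(2.0 * np.log(2.0))) / px
    noiseless = ndimage.gaussian_filter(acc, sigma_px)
    if noiseless.max() > 0:
        noiseless = params.peak_intensity * noiseless / noiseless.max()
    noiseless = noiseless + params.background_level

    if params.noise_model == "poisson":
        pixels = rng.poisson(noiseless).astype(float)
    elif params.noise_model == "gaussian":
        pixels = noiseless + rng.normal(0.0, params.noise_sd, noiseless.shape)
        pixels = np.clip(pixels, 0.0, None)
    else:
        pixels = noiseless

    truth = pd.DataFrame(
        records,
        columns=["fiber_id", "point_index", "x_um", "y_um", "local_angle_deg"],
    )
    truth["fiber_angle_deg"] = (
        truth["fiber_id"].map(dict(enumerate(angles)))
        if len(truth)
        else pd.Series(dtype=float)
    )
    return FiberImage(pixels=pixels, pixel_size_um=px), truth


@dataclass(frozen=True)
class PRWParams:
    """Persistent-random-walk simulation parameters.

    The walk is the integral of an Ornstein-Uhlenbeck velocity process with
    per-component stationary variance ``mu/P`` and correlation time ``P``,
    whose ensemble mean squared displacement follows the Fürth formula
    MSD(t) = 2 n_d mu [t - P (1 - exp(-t/P))] with dimensionality n_d = 2.

    ``guidance_strength > 0`` adds a contact-guidance heading bias toward a
    local fiber axis; the Fürth formula then no longer holds.
    """

    mu_um2_per_min: float = 10.0
    P_min: float = 30.0
    dt_min: float = 30.0
    n_frames: int = 145  # 30-min sampling over 72 h
    n_cells: int = 20
    guidance_strength: float = 0.0
    guidance_axis_deg: float = 0.0
    n_substeps: int = 50
    n_d: int = 2

    def validate(self) -> None:
        if min(self.mu_um2_per_min, self.P_min, self.dt_min) <= 0:
            raise ValueError("mu, P and dt must be positive")
        if self.n_frames < 2:
            raise ValueError("n_frames must be at least 2")
        if self.n_cells < 1 or self.n_substeps < 1:
            raise ValueError("n_cells and n_substeps must be positive")
        if self.guidance_strength < 0:
            raise ValueError("guidance_strength must be non-negative")
        if self.n_d != 2:
            raise ValueError("only planar (n_d = 2) walks are supported")


def _rotate_toward_axis(
    vx: np.ndarray, vy: np.ndarray, axis_deg: np.ndarray, strength: float
) -> tuple[np.ndarray, np.ndarray]:
    """Rotate velocity headings toward the nearest sense of an axial direction.

    The rotation angle is ``strength`` times the signed axial difference
    between the heading and the fiber axis (capped at the difference itself).
    """
    heading = np.arctan2(vy, vx)
    axis = np.deg2rad(axis_deg)
    # signed difference to the nearest axis sense, in (-pi/2, pi/2]
    diff = (axis - heading + np.pi / 2) % np.pi - np.pi / 2
    rot = np.clip(strength, 0.0, 1.0) * diff
    c, s = np.cos(rot), np.sin(rot)
    return vx * c - vy * s, vx * s + vy * c


def generate_trajectories(
    params: PRWParams,
    seed: int,
    orientation_field=None,
) -> pd.DataFrame:
    """Simulate PRW cell trajectories sampled at ``dt_min`` intervals.

    Velocities follow the exact discrete Ornstein-Uhlenbeck update at
    substep delta = dt/n_substeps (decay exp(-delta/P), innovation variance
    (mu/P)(1 - exp(-2 delta/P)) per component, stationary initial draw);
    positions are trapezoidal integrals of the velocity.  With
    ``guidance_strength > 0`` the velocity is additionally rotated toward
    the local fiber axis of ``orientation_field`` once per frame.

    Returns a table with columns ``track_id, frame, t_min, x_um, y_um``.
    """
    params.validate()
    if params.guidance_strength > 0 and orientation_field is None:
        raise ValueError(
            "guidance_strength > 0 requires an orientation_field"
        )
    rng = np.random.default_rng(seed)
    n_cells = params.n_cells
    sigma2 = params.mu_um2_per_min / params.P_min  # per-component velocity variance
    delta = params.dt_min / params.n_substeps
    a = np.exp(-delta / params.P_min)
    innov_sd = np.sqrt(sigma2 * (1.0 - a * a))
    n_sub_total = (params.n_frames - 1) * params.n_substeps

    v0 = rng.normal(0.0, np.sqrt(sigma2), size=(n_cells, 2))
    x0 = np.zeros((n_cells, 2))

    if params.guidance_strength == 0:
        # AR(1) velocities via a linear filter, fully vectorized over cells
        eps = rng.normal(0.0, innov_sd, size=(n_sub_total, n_cells, 2))
        v = np.empty((n_sub_total + 1, n_cells, 2))
        v[0] = v0
        v[1:] = lfilter([1.0], [1.0, -a], eps, axis=0)
        decay = a ** np.arange(1, n_sub_total + 1)
        v[1:] += decay[:, None, None] * v0[None]
        # trapezoidal position integral, then subsample at frame boundaries
        pos = np.concatenate(
            [x0[None], x0[None] + np.cumsum((v[1:] + v[:-1]) / 2 * delta, axis=0)]
        )
        frames = pos[:: params.n_substeps]
    else:
        field_angle = orientation_field.angle_deg
        field_coh = getattr(
            orientation_field, "coherence", np.ones_like(field_angle)
        )
        px = getattr(orientation_field, "pixel_size_um", 1.0)
        n_rows, n_cols = field_angle.shape
        # start cells inside the field so guidance look-ups are meaningful
        x0 = np.column_stack(
            [
                rng.uniform(0, n_cols * px, size=n_cells),
                rng.uniform(0, n_rows * px, size=n_cells),
            ]
        )
        frames = np.empty((params.n_frames, n_cells, 2))
        frames[0] = x0
        v = v0.copy()
        pos = x0.copy()
        # per-substep rotation fraction compounding to guidance_strength
        # over one frame, so the bias acts continuously against the
        # velocity decorrelation instead of washing out within a frame
        g = min(params.guidance_strength, 0.999)
        r = 1.0 - (1.0 - g) ** (1.0 / params.n_substeps)
        for k in range(1, params.n_frames):
            # the scaffold is a periodically repeated tile: wrap look-ups
            rr = (pos[:, 1] / px).astype(int) % n_rows
            cc = (pos[:, 0] / px).astype(int) % n_cols
            axis = field_angle[rr, cc]
            # cells only sense an axis where the matrix is locally oriented
            strength = r * field_coh[rr, cc]
            for _ in range(params.n_substeps):
                v[:, 0], v[:, 1] = _rotate_toward_axis(
                    v[:, 0], v[:, 1], axis, strength
                )
                v_new = a * v + rng.normal(0.0, innov_sd, size=(n_cells, 2))
                pos = pos + delta * (v + v_new) / 2.0
                v = v_new
            frames[k] = pos

    t = np.arange(params.n_frames) * params.dt_min
    out = pd.DataFrame(
        {
            "track_id": np.repeat(np.arange(n_cells), params.n_frames),
            "frame": np.tile(np.arange(params.n_frames), n_cells),
            "t_min": np.tile(t, n_cells),
            "x_um": frames[:, :, 0].T.ravel(),
            "y_um": frames[:, :, 1].T.ravel(),
        }
    )
    return out


def generate_cell_mask(
    aspect_ratio: float,
    area_um2: float,
    angle_deg: float,
    pixel_size_um: float,
    seed: int = 0,
    image_size_px: Optional[tuple[int, int]] = None,
) -> np.ndarray:
    """Rasterize an elliptical cell mask of given area, elongation and angle.

    The ellipse semi-axes are chosen so that pi*a*b equals ``area_um2`` and
    a/b equals ``aspect_ratio``; the major axis is rotated to ``angle_deg``
    (axial, from +x toward +y).  The subpixel center position is jittered by
    the seed so repeated draws sample digitization noise.
    """
    if aspect_ratio < 1:
        raise ValueError("aspect_ratio must be >= 1")
    if area_um2 <= 0 or pixel_size_um <= 0:
        raise ValueError("area and pixel size must be positive")
    a_um = np.sqrt(area_um2 * aspect_ratio / np.pi)
    b_um = np.sqrt(area_um2 / (np.pi * aspect_ratio))
    if area_um2 / pixel_size_um**2 < 100:
        raise ValueError("mask would have fewer than 100 foreground pixels")

    a_px = a_um / pixel_size_um
    b_px = b_um / pixel_size_um
    margin = 3
    if image_size_px is None:
        n = int(np.ceil(2 * a_px)) + 2 * margin
        image_size_px = (n, n)
    n_rows, n_cols = image_size_px
    if 2 * a_px + 2 > min(n_rows, n_cols):
        raise ValueError("ellipse does not fit inside image_size_px")

    rng = np.random.default_rng(seed)
    cy = n_rows / 2.0 + rng.uniform(-0.5, 0.5)
    cx = n_cols / 2.0 + rng.uniform(-0.5, 0.5)
    theta = np.deg2rad(angle_deg)
    rows, cols = np.mgrid[0:n_rows, 0:n_cols]
    dx = (cols + 0.5) - cx
    dy = (rows + 0.5) - cy
    u = dx * np.cos(theta) + dy * np.sin(theta)
    w = -dx * np.sin(theta) + dy * np.cos(theta)
    return (u / a_px) ** 2 + (w / b_px) ** 2 <= 1.0


@dataclass(frozen=True)
class SpotFieldParams:
    """Parameters for a punctate (focal-adhesion-like) spot phantom."""

    n_spots: int = 50
    spot_sigma_um: float = 0.5
    spot_amplitude: float = 100.0
    cell_background: float = 10.0
    noise_sd: float = 10.0
    pixel_size_um: float = 0.25

    def validate(self, pixel_size_um: float) -> None:
        if self.n_spots < 0:
            raise ValueError("n_spots must be non-negative")
        if self.spot_sigma_um < pixel_size_um:
            raise ValueError("spot_sigma_um must be at least one pixel")
        if self.spot_amplitude <= 0:
            raise ValueError("spot_amplitude must be positive")
        if min(self.cell_background, self.noise_sd) < 0:
            raise ValueError("background and noise must be non-negative")


def generate_spot_image(
    params: SpotFieldParams, cell_mask: np.ndarray, seed: int
) -> tuple["FiberImage", pd.DataFrame]:
    """Render Gaussian spots at uniform in-mask positions over a cell background.

    Returns the image and a ground-truth table ``spot_id, x_um, y_um``.
    """
    from .blueprint import FiberImage

    px = params.pixel_size_um
    params.validate(px)
    rng = np.random.default_rng(seed)
    mask = np.asarray(cell_mask, dtype=bool)
    rows, cols = np.nonzero(mask)
    if params.n_spots > 0 and rows.size == 0:
        raise ValueError("cell_mask has no foreground pixels")

    img = np.zeros(mask.shape, dtype=float)
    img[mask] = params.cell_background
    centers = []
    if params.n_spots > 0:
        pick = rng.integers(0, rows.size, size=params.n_spots)
        jitter = rng.uniform(-0.5, 0.5, size=(params.n_spots, 2))
        cr = rows[pick] + 0.5 + jitter[:, 0]
        cc = cols[pick] + 0.5 + jitter[:, 1]
        sig = params.spot_sigma_um / px
        rr, ccg = np.mgrid[0 : mask.shape[0], 0 : mask.shape[1]]
        for i in range(params.n_spots):
            d2 = (rr + 0.5 - cr[i]) ** 2 + (ccg + 0.5 - cc[i]) ** 2
            img += params.spot_amplitude * np.exp(-d2 / (2 * sig**2))
            centers.append((i, cc[i] * px, cr[i] * px))
    img += rng.normal(0.0, params.noise_sd, img.shape)
    img = np.clip(img, 0.0, None)
    truth = pd.DataFrame(centers, columns=["spot_id", "x_um", "y_um"])
    return FiberImage(pixels=img, pixel_size_um=px), truth
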