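"""End-to-end orchestration: generate, discretize, simulate, analyze, report.

A :class:`RunConfig` (fully serializable; a run is reproducible from the
config plus its seed alone) drives, for each stromal morphology class, the
full chain: fiber phantom -> blueprint -> scan plan -> simulated
fabrication + fidelity -> simulated trajectories -> motility fit ->
orientation distribution -> cell-shape / focal-adhesion / CTCF phantom
metrics.  Numeric results are written to a machine-readable
``metrics.json`` (byte-identical across reruns at the same seed) and a
human-readable summary; versions, parameters and timings go to the log,
never into the metrics file.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import yaml

from .blueprint import (
    build_scan_plan,
    discretize_fibers,
    fidelity_score,
    simulate_fabrication,
)
from .io import (
    save_blueprint,
    save_distribution,
    save_image,
    save_scan_plan,
    save_trajectories,
)
from .migration import ensemble_msd, fit_prw, instantaneous_speeds
from .morphometry import ctcf, detect_focal_adhesions, shape_metrics
from .orientation import alignment_index, angular_distribution, orientation_field
from .stats import compare_groups
from .synthetic import (
    PRWParams,
    SpotFieldParams,
    generate_cell_mask,
    generate_fiber_image,
    generate_spot_image,
    generate_trajectories,
    morphology_preset,
)

__all__ = ["RunConfig", "run_pipeline", "DEFAULT_GUIDANCE"]

log = logging.getLogger("stromascan.pipeline")

# Contact-guidance emulation defaults: stronger heading bias on the more
# aligned morphologies, mirroring the observed motility ordering.
DEFAULT_GUIDANCE = {
    "normal": 0.0,
    "benign": 0.1,
    "high_risk": 0.3,
    "high_grade": 0.5,
}


@dataclass
class RunConfig:
    """Everything needed to reproduce a pipeline run."""

    seed: int = 0
    classes: tuple[str, ...] = ("normal", "benign", "high_risk", "high_grade")
    morphology_overrides: dict = field(default_factory=dict)  # per-class kwargs
    guidance: dict = field(default_factory=lambda: dict(DEFAULT_GUIDANCE))
    mu_um2_per_min: float = 10.0
    P_min: float = 30.0
    dt_min: float = 30.0
    n_frames: int = 145
    n_cells: int = 20
    n_bins: int = 36
    max_lag_fraction: float = 1.0 / 3.0
    psf_fwhm_um: float = 0.6
    snr: float = 20.0
    scales_um: tuple[float, ...] = (0.5, 1.0, 2.0)
    min_object_um2: float = 1.0
    orientation_sigma_um: float = 1.5
    cell_area_um2: float = 500.0
    cell_pixel_size_um: float = 0.25
    n_spots: int = 50

    def to_yaml(self, path) -> None:
        data = {
            k: (list(v) if isinstance(v, tuple) else v)
            for k, v in self.__dict__.items()
        }
        Path(path).write_text(yaml.safe_dump(data, sort_keys=True))

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        for key in ("classes", "scales_um"):
            if key in data:
                data[key] = tuple(data[key])
        return cls(**data)


def _class_seeds(seed: int, n: int) -> list[int]:
    """Independent per-class child seeds, all below 2**31."""
    ss = np.random.SeedSequence(seed)
    return [int(s) % (2**31) for s in ss.generate_state(max(n, 1))]


def _round_floats(obj, ndigits: int = 6):
    if isinstance(obj, float):
        return round(obj, ndigits)
    if isinstance(obj, dict):
        return {k: _round_floats(v, ndigits) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_round_floats(v, ndigits) for v in obj]
    return obj


def _analyze_class(
    class_label: str, cfg: RunConfig, seed: int, class_dir: Optional[Path]
) -> dict:
    t0 = time.perf_counter()
    params = morphology_preset(
        class_label, **cfg.morphology_overrides.get(class_label, {})
    )
    image, truth = generate_fiber_image(params, seed=seed)
    blueprint = discretize_fibers(image, cfg.scales_um, cfg.min_object_um2)
    plan = build_scan_plan(blueprint)
    fabricated = simulate_fabrication(
        blueprint, psf_fwhm_um=cfg.psf_fwhm_um, noise="poisson", snr=cfg.snr,
        seed=seed + 1,
    )
    fidelity = fidelity_score(blueprint, fabricated)

    field_ = orientation_field(image, sigma_um=cfg.orientation_sigma_um)
    dist = angular_distribution(
        field_, n_bins=cfg.n_bins, mask=blueprint.mask, weight="coherence"
    )
    align = alignment_index(dist)

    g = float(cfg.guidance.get(class_label, 0.0))
    prw = PRWParams(
        mu_um2_per_min=cfg.mu_um2_per_min, P_min=cfg.P_min, dt_min=cfg.dt_min,
        n_frames=cfg.n_frames, n_cells=cfg.n_cells, guidance_strength=g,
        guidance_axis_deg=params.orientation_mean_deg,
    )
    tracks = generate_trajectories(
        prw, seed=seed + 2, orientation_field=field_ if g > 0 else None
    )
    curve = ensemble_msd(tracks, cfg.max_lag_fraction)
    fit = fit_prw(curve)
    speeds = np.concatenate(
        [instantaneous_speeds(t) for _, t in tracks.groupby("track_id")]
    )

    # morphometry phantoms: one elliptical cell plus a spot field on it
    aspect = 1.0 + 3.0 * g  # guided cells elongate along the fibers
    mask = generate_cell_mask(
        aspect_ratio=aspect, area_um2=cfg.cell_area_um2,
        angle_deg=params.orientation_mean_deg,
        pixel_size_um=cfg.cell_pixel_size_um, seed=seed + 3,
    )
    shape = shape_metrics(mask, cfg.cell_pixel_size_um)
    spot_params = SpotFieldParams(
        n_spots=cfg.n_spots, pixel_size_um=cfg.cell_pixel_size_um
    )
    spot_img, spot_truth = generate_spot_image(spot_params, mask, seed=seed + 4)
    spots = detect_focal_adhesions(
        spot_img, mask, sigma_um=spot_params.spot_sigma_um
    )
    bg_mask = ~mask
    ctcf_res = ctcf(spot_img, mask, bg_mask)

    metrics = {
        "fidelity": {
            "spatial_overlap_pct": fidelity.spatial_overlap_pct,
            "intensity_corr": fidelity.intensity_corr,
            "fidelity_pct": fidelity.fidelity_pct,
        },
        "scan_plan": {
            "tiles": list(plan.tiles),
            "overall_extent_um": list(plan.overall_extent_um),
        },
        "orientation": {"alignment_index": align},
        "motility": {
            "mu_um2_per_min": fit.mu_um2_per_min,
            "P_min": fit.P_min,
            "converged": fit.converged,
            "identifiable_P": fit.identifiable_P,
            "mean_speed_um_per_min": float(speeds.mean()),
            "guidance_strength": g,
        },
        "morphometry": {
            "circularity": shape.circularity,
            "area_um2": shape.area_um2,
            "spot_count": spots.count,
            "spot_density_per_um2": spots.density_per_um2,
            "ctcf": ctcf_res.ctcf,
        },
        "n_ground_truth_fibers": int(truth["fiber_id"].nunique())
        if len(truth) else 0,
    }

    if class_dir is not None:
        class_dir.mkdir(parents=True, exist_ok=True)
        save_image(image, class_dir / "image.tif")
        truth.to_csv(class_dir / "fiber_truth.csv", index=False)
        save_blueprint(blueprint, class_dir / "blueprint.tif")
        save_scan_plan(
            plan, class_dir / "scan_plan.csv", class_dir / "scan_plan.json"
        )
        save_image(fabricated, class_dir / "fabricated.tif")
        save_trajectories(tracks, class_dir / "tracks.csv")
        save_distribution(dist, class_dir / "fiber_orientation.csv")
        spot_truth.to_csv(class_dir / "spot_truth.csv", index=False)
    log.info(
        "class=%s seed=%d fidelity=%.1f align=%.3f mu=%.2f elapsed=%.2fs",
        class_label, seed, fidelity.fidelity_pct, align, fit.mu_um2_per_min,
        time.perf_counter() - t0,
    )
    return metrics, speeds


def run_pipeline(config: RunConfig, out_dir=None) -> dict:
    """Run the full pipeline for every configured morphology class.

    Returns the metrics dictionary; when ``out_dir`` is given, also writes
    all artifacts plus ``metrics.json`` and ``summary.txt``.  The metrics
    depend only on the config (seed included), never on the output path.
    """
    out = Path(out_dir) if out_dir is not None else None
    seeds = _class_seeds(config.seed, len(config.classes))
    per_class = {}
    speed_groups = {}
    for label, seed in zip(config.classes, seeds):
        metrics, speeds = _analyze_class(
            label, config, seed, out / label if out else None
        )
        per_class[label] = metrics
        speed_groups[label] = speeds

    report = {"seed": config.seed, "classes": per_class}
    if len(speed_groups) >= 2:
        comparison = compare_groups(speed_groups, metric="instantaneous_speed")
        report["speed_comparison"] = {
            "anova_p": comparison.anova_p,
            "pairwise": [
                {
                    "groups": [p.group_a, p.group_b],
                    "p": p.t_p,
                    "significant": p.significant,
                }
                for p in comparison.pairwise
            ],
        }
    report = _round_floats(report)

    if out is not None:
        out.mkdir(parents=True, exist_ok=True)
        (out / "metrics.json").write_text(
            json.dumps(report, indent=2, sort_keys=True) + "\n"
        )
        config.to_yaml(out / "config.yaml")
        lines = [f"stromascan pipeline report (seed {config.seed})", ""]
        for label, m in per_class.items():
            lines.append(
                f"{label:>10s}: fidelity {m['fidelity']['fidelity_pct']:.1f}% | "
                f"alignment {m['orientation']['alignment_index']:.3f} | "
                f"mu {m['motility']['mu_um2_per_min']:.2f} um^2/min | "
                f"circularity {m['morphometry']['circularity']:.3f} | "
                f"spots {m['morphometry']['spot_count']}"
            )
        (out / "summary.txt").write_text("\n".join(lines) + "\n")
    return report
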