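"""Reading and writing pipeline artifacts.

Images travel as single-channel TIFF with a JSON sidecar recording the
pixel size (and, for blueprints, tile extent and nominal height);
trajectories, ground truth, distributions and scan plans are plain CSV.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .blueprint import Blueprint, FiberImage, ScanPlan
from .orientation import AngularDistribution

__all__ = [
    "save_image",
    "load_image",
    "save_blueprint",
    "load_blueprint",
    "save_scan_plan",
    "load_scan_plan",
    "save_trajectories",
    "load_trajectories",
    "save_distribution",
    "load_distribution",
]

TRAJECTORY_COLUMNS = ["track_id", "frame", "t_min", "x_um", "y_um"]


def _sidecar(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".json")


def save_image(image: FiberImage, path) -> None:
    path = Path(path)
    tifffile.imwrite(path, image.pixels.astype(np.float32))
    _sidecar(path).write_text(
        json.dumps({"pixel_size_um": image.pixel_size_um}, indent=2)
    )


def load_image(path) -> FiberImage:
    path = Path(path)
    pixels = tifffile.imread(path).astype(float)
    meta = json.loads(_sidecar(path).read_text())
    return FiberImage(pixels=pixels, pixel_size_um=meta["pixel_size_um"])


def save_blueprint(blueprint: Blueprint, path) -> None:
    """Write the graded map as 16-bit TIFF plus a JSON sidecar."""
    path = Path(path)
    scaled = np.round(blueprint.graded * 65535.0).astype(np.uint16)
    tifffile.imwrite(path, scaled)
    _sidecar(path).write_text(
        json.dumps(
            {
                "pixel_size_um": blueprint.pixel_size_um,
                "tile_um": list(blueprint.tile_um),
                "height_um": blueprint.height_um,
                "encoding": "uint16/65535",
            },
            indent=2,
        )
    )


def load_blueprint(path) -> Blueprint:
    path = Path(path)
    scaled = tifffile.imread(path)
    meta = json.loads(_sidecar(path).read_text())
    graded = scaled.astype(float) / 65535.0
    mask = graded > 0
    if mask.any():  # restore max-1 normalization lost to quantization
        graded = graded / graded.max()
    return Blueprint(
        mask=mask, graded=graded, pixel_size_um=meta["pixel_size_um"],
        tile_um=tuple(meta["tile_um"]), height_um=meta["height_um"],
    )


def save_scan_plan(plan: ScanPlan, csv_path, header_path) -> None:
    """Export as (row, col, open_fraction) CSV plus a JSON header.

    Open fractions are written with full precision (repr round-trip) so a
    reload compares bit-exactly.
    """
    rows, cols = np.nonzero(plan.open_fraction)
    df = pd.DataFrame(
        {
            "row": rows,
            "col": cols,
            "open_fraction": plan.open_fraction[rows, cols],
        }
    )
    df.to_csv(csv_path, index=False, float_format="%.17g")
    Path(header_path).write_text(
        json.dumps(
            {
                "dwell_us": plan.dwell_us,
                "tiles": list(plan.tiles),
                "tile_um": list(plan.tile_um),
                "overall_extent_um": list(plan.overall_extent_um),
                "shape": list(plan.open_fraction.shape),
            },
            indent=2,
        )
    )


def load_scan_plan(csv_path, header_path) -> ScanPlan:
    meta = json.loads(Path(header_path).read_text())
    # default pandas float parsing is fast but lossy; exact values required
    df = pd.read_csv(csv_path, float_precision="round_trip")
    open_fraction = np.zeros(tuple(meta["shape"]))
    open_fraction[df["row"].to_numpy(), df["col"].to_numpy()] = df[
        "open_fraction"
    ].to_numpy()
    return ScanPlan(
        open_fraction=open_fraction,
        dwell_us=meta["dwell_us"],
        tiles=tuple(meta["tiles"]),
        tile_um=tuple(meta["tile_um"]),
    )


def save_trajectories(tracks: pd.DataFrame, path) -> None:
    tracks[TRAJECTORY_COLUMNS].to_csv(path, index=False)


def load_trajectories(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = set(TRAJECTORY_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"trajectory table is missing columns {sorted(missing)}")
    return df


def save_distribution(dist: AngularDistribution, path) -> None:
    pd.DataFrame(
        {
            "bin_start_deg": dist.bin_edges_deg[:-1],
            "bin_end_deg": dist.bin_edges_deg[1:],
            "density": dist.density,
        }
    ).to_csv(path, index=False)


def load_distribution(path, n_effective: float = 1.0) -> AngularDistribution:
    df = pd.read_csv(path)
    edges = np.append(df["bin_start_deg"].to_numpy(), df["bin_end_deg"].iloc[-1])
    return AngularDistribution(
        bin_edges_deg=edges,
        density=df["density"].to_numpy(),
        n_effective=n_effective,
    )
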