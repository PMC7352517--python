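"""Axial orientation analysis and circular statistics.

Fiber and stress-fiber orientations are *axial* data: an orientation and
its 180-degree rotation are the same physical state, so every statistic
here doubles the angles, works on the circle, and halves the result.  The
module provides a structure-tensor local-orientation field (a stand-in for
curvelet-based fiber extraction), weighted angular histograms, an
alignment index (mean resultant length of doubled angles), Pearson
correlation between binned distributions, the two-sample Watson U-squared
test with a permutation p-value, and the circular mean direction.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
from skimage.feature import structure_tensor

from .blueprint import FiberImage

__all__ = [
    "OrientationField",
    "AngularDistribution",
    "WatsonU2Result",
    "orientation_field",
    "angular_distribution",
    "alignment_index",
    "pearson_between",
    "watson_u2",
    "mean_direction",
]


@dataclass
class OrientationField:
    """Per-pixel dominant axial orientation (deg in [0, 180)) and coherence.

    Coherence is (l1 - l2)/(l1 + l2) of the structure-tensor eigenvalues:
    1 for a perfectly oriented neighborhood, 0 for an isotropic one.
    ``degenerate`` flags a constant input image, whose angles are set to 0
    by convention and carry no information.
    """

    angle_deg: np.ndarray
    coherence: np.ndarray
    sigma_um: float
    pixel_size_um: float
    degenerate: bool = False


@dataclass
class AngularDistribution:
    """Normalized axial-orientation histogram on [0, 180)."""

    bin_edges_deg: np.ndarray
    density: np.ndarray
    n_effective: float

    def __post_init__(self) -> None:
        self.bin_edges_deg = np.asarray(self.bin_edges_deg, dtype=float)
        self.density = np.asarray(self.density, dtype=float)
        if self.density.size < 8:
            raise ValueError("at least 8 bins are required")
        if np.any(self.density < 0):
            raise ValueError("densities must be non-negative")
        if self.density.sum() > 0 and not np.isclose(self.density.sum(), 1.0):
            raise ValueError("densities must sum to 1")

    @property
    def bin_centers_deg(self) -> np.ndarray:
        return (self.bin_edges_deg[:-1] + self.bin_edges_deg[1:]) / 2.0


@dataclass
class WatsonU2Result:
    """Two-sample Watson U-squared statistic with a permutation p-value."""

    u2: float
    p_value: float
    n1: int
    n2: int
    n_permutations: int


def orientation_field(image: FiberImage, sigma_um: float) -> OrientationField:
    """Structure-tensor local orientation of a fibrous image.

    The fiber axis at each pixel is the eigenvector of the *smaller*
    structure-tensor eigenvalue (axis of least intensity variation),
    reported in degrees from the image +x (column) axis, modulo 180.
    """
    px = image.pixel_size_um
    if sigma_um < px:
        raise ValueError("sigma_um must be at least the pixel size")
    img = image.pixels
    if img.max() == img.min():
        zeros = np.zeros_like(img, dtype=float)
        return OrientationField(
            angle_deg=zeros, coherence=zeros.copy(), sigma_um=sigma_um,
            pixel_size_um=px, degenerate=True,
        )
    Arr, Arc, Acc = structure_tensor(
        img, sigma=sigma_um / px, mode="reflect", order="rc"
    )
    # x = columns, y = rows: Axx = <Ix^2> is the col-col entry
    Axx, Axy, Ayy = Acc, Arc, Arr
    # dominant gradient direction; the fiber axis is orthogonal to it
    grad_angle = 0.5 * np.arctan2(2.0 * Axy, Axx - Ayy)
    angle = (np.rad2deg(grad_angle) + 90.0) % 180.0
    trace = Axx + Ayy
    root = np.sqrt((Axx - Ayy) ** 2 + 4.0 * Axy**2)
    with np.errstate(invalid="ignore", divide="ignore"):
        coherence = np.where(trace > 0, root / trace, 0.0)
    return OrientationField(
        angle_deg=angle, coherence=np.clip(coherence, 0.0, 1.0),
        sigma_um=sigma_um, pixel_size_um=px,
    )


def angular_distribution(
    angles_or_field,
    n_bins: int = 36,
    mask: Optional[np.ndarray] = None,
    weight: str = "coherence",
    intensity: Optional[np.ndarray] = None,
) -> AngularDistribution:
    """Weighted axial-orientation histogram on [0, 180).

    Accepts either an :class:`OrientationField` (weighted per pixel by
    ``"coherence"``, ``"intensity"`` or ``"uniform"``) or a flat array of
    axial angles in degrees (implicitly uniform weights).
    """
    if n_bins < 8:
        raise ValueError("n_bins must be at least 8")
    if isinstance(angles_or_field, OrientationField):
        field = angles_or_field
        angles = field.angle_deg.ravel()
        if weight == "coherence":
            w = field.coherence.ravel()
        elif weight == "intensity":
            if intensity is None:
                raise ValueError("intensity weighting requires an intensity array")
            w = np.asarray(intensity, dtype=float).ravel()
        elif weight == "uniform":
            w = np.ones_like(angles)
        else:
            raise ValueError(f"unknown weight {weight!r}")
        if mask is not None:
            keep = np.asarray(mask, dtype=bool).ravel()
            angles, w = angles[keep], w[keep]
    else:
        angles = np.asarray(angles_or_field, dtype=float).ravel() % 180.0
        w = np.ones_like(angles)
        if mask is not None:
            keep = np.asarray(mask, dtype=bool).ravel()
            angles, w = angles[keep], w[keep]

    edges = np.linspace(0.0, 180.0, n_bins + 1)
    hist, _ = np.histogram(angles % 180.0, bins=edges, weights=w)
    total = hist.sum()
    density = hist / total if total > 0 else hist
    return AngularDistribution(
        bin_edges_deg=edges, density=density, n_effective=float(total)
    )


def alignment_index(dist: AngularDistribution) -> float:
    """Mean resultant length of the doubled bin-center angles, in [0, 1].

    0 for a uniform axial distribution, 1 for perfect alignment.
    """
    doubled = np.deg2rad(2.0 * dist.bin_centers_deg)
    r = np.abs(np.sum(dist.density * np.exp(1j * doubled)))
    return float(np.clip(r, 0.0, 1.0))


def pearson_between(
    dist_a: AngularDistribution, dist_b: AngularDistribution
) -> float:
    """Pearson correlation between two angular distributions' density vectors.

    The distributions must share identical bin edges; mismatched binning is
    an error rather than a silent rebin.
    """
    if not np.array_equal(dist_a.bin_edges_deg, dist_b.bin_edges_deg):
        raise ValueError("distributions must share identical bin edges")
    a, b = dist_a.density, dist_b.density
    if a.std() == 0 or b.std() == 0:
        raise ValueError("correlation undefined for a constant density vector")
    return float(np.corrcoef(a, b)[0, 1])


def _watson_u2_stat(sorted_labels: np.ndarray, n1: int, n2: int) -> float:
    """U-squared from group labels (1 = sample A) ordered by circular value."""
    n = n1 + n2
    cum1 = np.cumsum(sorted_labels) / n1
    cum2 = np.cumsum(1 - sorted_labels) / n2
    d = cum1 - cum2
    return float(n1 * n2 / n**2 * (np.sum(d * d) - np.sum(d) ** 2 / n))


def watson_u2(
    angles_a,
    angles_b,
    n_permutations: int = 999,
    seed: Optional[int] = None,
    axial: bool = True,
) -> WatsonU2Result:
    """Two-sample Watson U-squared test for a difference in circular law.

    Axial input angles (degrees mod 180) are doubled onto the circle; the
    statistic is computed from the ranked combined sample and the p-value
    by random permutation of the group labels, p = (1 + #{U* >= U}) /
    (n_permutations + 1).  The statistic is invariant under a common
    rotation of both samples.
    """
    a = np.asarray(angles_a, dtype=float).ravel()
    b = np.asarray(angles_b, dtype=float).ravel()
    n1, n2 = a.size, b.size
    if n1 < 8 or n2 < 8:
        raise ValueError("each sample needs at least 8 angles")
    if n_permutations < 1:
        raise ValueError("n_permutations must be positive")

    if axial:
        circ = np.concatenate([2.0 * a, 2.0 * b]) % 360.0
    else:
        circ = np.concatenate([a, b]) % 360.0
    labels = np.concatenate([np.ones(n1, dtype=np.int64), np.zeros(n2, dtype=np.int64)])
    order = np.argsort(circ, kind="stable")
    sorted_labels = labels[order]
    u2 = _watson_u2_stat(sorted_labels, n1, n2)

    rng = np.random.default_rng(seed)
    n = n1 + n2
    perm = np.broadcast_to(sorted_labels, (n_permutations, n)).copy()
    perm = rng.permuted(perm, axis=1)
    cum1 = np.cumsum(perm, axis=1) / n1
    cum2 = np.cumsum(1 - perm, axis=1) / n2
    d = cum1 - cum2
    u2_perm = n1 * n2 / n**2 * (np.sum(d * d, axis=1) - np.sum(d, axis=1) ** 2 / n)
    p = (1.0 + np.count_nonzero(u2_perm >= u2)) / (n_permutations + 1.0)
    return WatsonU2Result(
        u2=u2, p_value=float(p), n1=n1, n2=n2, n_permutations=n_permutations
    )


def mean_direction(angles, axial: bool = True) -> float:
    """Circular mean of axial angles, in degrees.

    Axial angles are doubled, averaged on the circle, and halved back to
    [0, 180); e.g. the mean of {10, 170} is 0, not 90.
    """
    a = np.asarray(angles, dtype=float).ravel()
    if a.size == 0:
        raise ValueError("mean direction of an empty sample is undefined")
    mult = 2.0 if axial else 1.0
    z = np.mean(np.exp(1j * np.deg2rad(mult * a)))
    if np.abs(z) < 1e-12:
        raise ValueError("mean direction undefined: zero resultant length")
    ang = np.rad2deg(np.angle(z)) / mult
    return float(ang % (180.0 if axial else 360.0))
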