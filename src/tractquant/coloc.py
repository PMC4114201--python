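"""Li intensity-correlation analysis (PDM / ICQ) and the colocalization
colour map, with nonparametric group comparison.

For two channels A and B sampled over the same pixels, the product of the
differences from the mean is

    PDM_i = (A_i - mean(A)) * (B_i - mean(B)).

If the two stains covary, most PDM values are positive; if they segregate,
most are negative.  The intensity correlation quotient condenses this:

    ICQ = (# PDM > 0) / (# PDM != 0) - 0.5,     ICQ in [-0.5, +0.5],

with 0 indicating random staining overlap, +0.5 perfect covariation and
-0.5 perfect segregation.  Pixels whose PDM is exactly zero are excluded
from the ratio (their count is reported so the alternative convention can be
recomputed).

The colocalization colour map normalises each PDM by the product of maximal
channel deviations, giving a per-pixel value in [-1, 1] whose positive part
marks covariation "hot spots".
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

from .image_model import ImageStack, ValidationError

__all__ = [
    "CellROI",
    "ICQResult",
    "GroupComparison",
    "extract_cell_pixels",
    "compute_pdm",
    "compute_icq",
    "li_sign_test",
    "nmdp_map",
    "compare_icq_groups",
]


@dataclass
class CellROI:
    """A 3D crop isolating one cell: half-open (z, y, x) ranges plus an
    optional per-voxel mask (e.g. a disc) within the crop."""

    z: tuple[int, int]
    y: tuple[int, int]
    x: tuple[int, int]
    mask: np.ndarray | None = None
    cell_id: str = ""
    group: str = ""

    def __post_init__(self) -> None:
        for name, (lo, hi) in zip("zyx", (self.z, self.y, self.x)):
            if hi <= lo:
                raise ValidationError(f"empty {name}-range [{lo}, {hi}) in cell crop")
        if self.mask is not None:
            self.mask = np.asarray(self.mask, dtype=bool)
            expected = (
                self.z[1] - self.z[0],
                self.y[1] - self.y[0],
                self.x[1] - self.x[0],
            )
            if self.mask.shape != expected:
                raise ValidationError(
                    f"cell mask shape {self.mask.shape} does not match crop {expected}"
                )

    def slices(self) -> tuple[slice, slice, slice]:
        return slice(*self.z), slice(*self.y), slice(*self.x)


@dataclass(frozen=True)
class ICQResult:
    icq: float
    n_pixels: int
    n_pdm_positive: int
    n_pdm_zero: int
    mean_a: float
    mean_b: float


@dataclass(frozen=True)
class GroupComparison:
    statistic: float
    p_value: float
    n1: int
    n2: int
    median1: float
    median2: float
    method: str


def extract_cell_pixels(
    stack: ImageStack,
    roi: CellROI,
    channel_a: str,
    channel_b: str,
) -> tuple[np.ndarray, np.ndarray]:
    """Paired per-voxel intensity vectors for one cell crop.

    Voxel order is identical between the two channels; masked-out voxels are
    dropped when the crop carries a mask.
    """
    for ch in (channel_a, channel_b):
        if ch not in stack.channels:
            raise ValidationError(f"channel {ch!r} not in stack {list(stack.channels)}")
    nz, ny, nx = stack.shape
    if not (0 <= roi.z[0] and roi.z[1] <= nz and 0 <= roi.y[0] and roi.y[1] <= ny
            and 0 <= roi.x[0] and roi.x[1] <= nx):
        raise ValidationError(
            f"cell crop z{roi.z} y{roi.y} x{roi.x} lies outside stack shape {(nz, ny, nx)}"
        )
    sl = roi.slices()
    a = stack.channels[channel_a][sl].astype(float)
    b = stack.channels[channel_b][sl].astype(float)
    if roi.mask is not None:
        return a[roi.mask], b[roi.mask]
    return a.ravel(), b.ravel()


def compute_pdm(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Per-pixel products of the differences from the channel means."""
    a = np.asarray(a, dtype=float).ravel()
    b = np.asarray(b, dtype=float).ravel()
    if a.size != b.size or a.size == 0:
        raise ValidationError(f"need equal non-empty vectors, got {a.size} and {b.size}")
    return (a - a.mean()) * (b - b.mean())


def compute_icq(a: np.ndarray, b: np.ndarray) -> ICQResult:
    """Intensity correlation quotient of two equal-length pixel vectors."""
    a = np.asarray(a, dtype=float).ravel()
    b = np.asarray(b, dtype=float).ravel()
    if a.size != b.size or a.size < 2:
        raise ValidationError(f"need equal vectors of length >= 2, got {a.size} and {b.size}")
    pdm = compute_pdm(a, b)
    n_zero = int((pdm == 0).sum())
    n_pos = int((pdm > 0).sum())
    denom = pdm.size - n_zero
    if denom == 0:
        const = "A" if np.all(a == a[0]) else "B"
        raise ValidationError(
            f"ICQ undefined: all PDM values are zero (channel {const} is constant)"
        )
    return ICQResult(
        icq=n_pos / denom - 0.5,
        n_pixels=pdm.size,
        n_pdm_positive=n_pos,
        n_pdm_zero=n_zero,
        mean_a=float(a.mean()),
        mean_b=float(b.mean()),
    )


def li_sign_test(a: np.ndarray, b: np.ndarray) -> float:
    """Per-cell sign-test p-value for the ICQ (two-sided binomial).

    Under no covariation, each nonzero PDM is positive with probability 1/2;
    this tests the observed positive count against Binomial(n, 0.5).  It is
    reported per cell for completeness; group-level inference in the headline
    pipeline is the Mann-Whitney comparison of per-cell ICQ values.
    """
    res = compute_icq(a, b)
    n = res.n_pixels - res.n_pdm_zero
    return float(stats.binomtest(res.n_pdm_positive, n, 0.5).pvalue)


def nmdp_map(
    section_a: np.ndarray, section_b: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Colocalization colour map: normalised mean deviation product per pixel.

    Each pixel's PDM is normalised by ``(max(A) - mean(A)) * (max(B) - mean(B))``
    and clipped to [-1, 1]; the returned hot-spot layer is ``value > 0``.
    """
    a = np.asarray(section_a, dtype=float)
    b = np.asarray(section_b, dtype=float)
    if a.shape != b.shape:
        raise ValidationError(f"channel shapes differ: {a.shape} vs {b.shape}")
    da = a - a.mean()
    db = b - b.mean()
    norm = da.max() * db.max()
    if norm == 0:
        const = "A" if da.max() == 0 else "B"
        raise ValidationError(f"colour map undefined: channel {const} is constant")
    values = np.clip(da * db / norm, -1.0, 1.0)
    return values, values > 0


def compare_icq_groups(
    icq_group1: Sequence[float], icq_group2: Sequence[float]
) -> GroupComparison:
    """Two-sided Mann-Whitney rank-sum comparison of per-cell ICQ values.

    Uses the exact null distribution when both groups have n <= 20 and the
    pooled values contain no ties; otherwise the tie-corrected normal
    approximation with continuity correction.
    """
    g1 = np.asarray(icq_group1, dtype=float)
    g2 = np.asarray(icq_group2, dtype=float)
    if g1.size < 2 or g2.size < 2:
        raise ValidationError("each group needs at least 2 ICQ values")
    pooled = np.concatenate([g1, g2])
    no_ties = np.unique(pooled).size == pooled.size
    method = "exact" if (g1.size <= 20 and g2.size <= 20 and no_ties) else "asymptotic"
    res = stats.mannwhitneyu(
        g1, g2, alternative="two-sided", method=method, use_continuity=True
    )
    return GroupComparison(
        statistic=float(res.statistic),
        p_value=float(res.pvalue),
        n1=int(g1.size),
        n2=int(g2.size),
        median1=float(np.median(g1)),
        median2=float(np.median(g2)),
        method=method,
    )
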