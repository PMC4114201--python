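"""Synthetic data with known ground truth for every pipeline stage.

Three generators emulate the statistical structure the analyses assume:

* :func:`generate_injection_series` — serial sections with a nucleus-shaped
  polygon ROI, a bright tracer blob occupying an exactly controlled fraction
  of the ROI, optional spillover lobes just outside it, and Gaussian
  background noise (a "TRITC"-like tracer channel plus a Nissl-like
  delineation channel);
* :func:`generate_coloc_cells` — a two-channel field of non-overlapping
  circular somata whose per-cell channel correlation is set exactly through
  a Gaussian copula;
* :func:`generate_ipsc_experiment` — per-cell IPSC amplitude triplets
  (total / after strychnine / after both blockers) with a settable GABAergic
  fraction per group.

Every generator is a pure function of its parameters plus a seed and returns
a ground-truth manifest alongside the data, so noiseless generation followed
by the matching quantification stage recovers truth exactly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy.ndimage import gaussian_filter

from .coloc import CellROI
from .ephys import IPSCRecord
from .image_model import (
    BinaryMask,
    ImageSection,
    ImageStack,
    PolygonROI,
    ValidationError,
    rasterize,
)

__all__ = [
    "InjectionTruth",
    "ColocTruth",
    "IPSCTruth",
    "bell_profile",
    "generate_injection_series",
    "generate_coloc_cells",
    "generate_ipsc_experiment",
]


def bell_profile(
    n_sections: int, mean_fraction: float, amplitude: float = 0.5
) -> np.ndarray:
    """A bell-shaped per-section injected-fraction profile with a set mean.

    Injections are brightest near their epicentre and fade towards the
    antero-posterior poles; a raised-cosine shape (relative peak-to-mean
    swing ``amplitude``) rescaled to the requested mean captures that.  The
    default amplitude keeps peak sections below ~1.5x the mean, where the
    pooled mean + 2*SD threshold remains reliably below a sub-saturating
    tracer core; see the methods note on this sensitivity of the rule.
    """
    if not 0.0 <= amplitude <= 1.0:
        raise ValidationError("amplitude must lie in [0, 1]")
    x = (np.arange(n_sections) + 0.5) / n_sections
    shape = 1.0 - amplitude * np.cos(2 * math.pi * x)
    shape = shape / shape.mean()
    profile = mean_fraction * shape
    if profile.max() > 1.0:
        raise ValidationError(
            f"mean fraction {mean_fraction} needs a peak of {profile.max():.2f} > 1"
        )
    return profile


def _discretize(x: np.ndarray) -> np.ndarray:
    """Round half-up to integers, then clip to the 8-bit range."""
    return np.clip(np.floor(x + 0.5), 0, 255).astype(np.uint8)


# ---------------------------------------------------------------------------
# Injection series
# ---------------------------------------------------------------------------


@dataclass
class InjectionTruth:
    """Ground truth for a generated injection series.

    ``volume_fraction`` is the thickness-weighted mean of the per-section
    injected fractions (uniform thickness here, so the plain mean).
    """

    section_fractions: list[float]
    section_spillover_px: list[int]
    volume_fraction: float
    params: dict = field(default_factory=dict)


def _nucleus_polygon(
    rng: np.random.Generator,
    center: tuple[float, float],
    radii: tuple[float, float],
    n_vertices: int = 64,
    irregularity: float = 0.08,
) -> PolygonROI:
    """A smooth, irregular, star-shaped closed outline (nucleus-like)."""
    theta = np.linspace(0, 2 * math.pi, n_vertices, endpoint=False)
    perturb = np.zeros_like(theta)
    for m in range(2, 6):
        a, b = rng.normal(0, irregularity / m, size=2)
        perturb += a * np.cos(m * theta) + b * np.sin(m * theta)
    scale = np.clip(1.0 + perturb, 0.5, 1.5)
    cx, cy = center
    rx, ry = radii
    xs = cx + rx * scale * np.cos(theta)
    ys = cy + ry * scale * np.sin(theta)
    return PolygonROI(vertices=np.column_stack([xs, ys]), label="MNTB")


def _blob_pixels(
    rng: np.random.Generator,
    mask: BinaryMask,
    n_target: int,
    smooth_sigma: float = 6.0,
) -> np.ndarray:
    """Select exactly ``n_target`` mask pixels forming an irregular blob.

    A radial bowl centred near the ROI centroid plus a smoothed random field
    is thresholded at the quantile that yields the requested count, giving
    exact area control with biologically plausible ragged edges.
    """
    ys, xs = np.nonzero(mask.grid)
    if n_target == 0:
        return np.zeros(mask.shape, dtype=bool)
    cy, cx = ys.mean(), xs.mean()
    r_scale = max(ys.std(), xs.std(), 1.0)
    noise = gaussian_filter(rng.standard_normal(mask.shape), smooth_sigma)
    noise = noise / (noise.std() + 1e-12)
    dist2 = ((ys - cy) ** 2 + (xs - cx) ** 2) / r_scale**2
    score = -dist2 + 0.8 * noise[ys, xs]
    top = np.argpartition(score, -n_target)[-n_target:]
    blob = np.zeros(mask.shape, dtype=bool)
    blob[ys[top], xs[top]] = True
    return blob


def generate_injection_series(
    n_sections: int,
    injected_fraction_profile: Sequence[float],
    roi_shape_params: Mapping | None = None,
    core_intensity: float = 200.0,
    background_mean: float = 20.0,
    background_sd: float = 5.0,
    spillover_px_profile: Sequence[int] | None = None,
    image_shape: tuple[int, int] = (256, 256),
    pixel_size_um: float = 0.742,
    thickness_um: float = 80.0,
    separability_sigmas: float = 4.0,
    seed: int | None = None,
) -> tuple[list[tuple[ImageSection, PolygonROI]], InjectionTruth]:
    """Generate a serial-section stack with a tracer blob of known extent.

    Parameters
    ----------
    injected_fraction_profile
        Per-section fraction of the ROI area occupied by tracer, each in
        [0, 1].  The realised fraction differs from the request only by pixel
        rounding and is recorded in the truth manifest.
    spillover_px_profile
        Optional per-section count of bright pixels placed just outside the
        ROI boundary (spillover lobes).
    background_sd
        SD of the additive Gaussian noise applied to the whole image; set to
        0 for noiseless closed-loop checks.
    """
    profile = np.asarray(injected_fraction_profile, dtype=float)
    if profile.size != n_sections:
        raise ValidationError(
            f"profile length {profile.size} != n_sections {n_sections}"
        )
    if np.any(profile < 0) or np.any(profile > 1):
        raise ValidationError(
            "injected fractions must lie in [0, 1]; the maximum attainable "
            "fraction of the ROI is 1.0"
        )
    if not core_intensity > background_mean + separability_sigmas * background_sd:
        raise ValidationError(
            f"core intensity {core_intensity} is not separable from background "
            f"{background_mean} +/- {background_sd} "
            f"(needs > mean + {separability_sigmas}*SD)"
        )
    spill_profile = (
        np.zeros(n_sections, dtype=int)
        if spillover_px_profile is None
        else np.asarray(spillover_px_profile, dtype=int)
    )
    if spill_profile.size != n_sections:
        raise ValidationError("spillover profile length mismatch")

    params = dict(roi_shape_params or {})
    rows, cols = image_shape
    center = params.get("center", (cols / 2, rows / 2))
    base_radii = params.get("radii", (0.22 * cols, 0.16 * rows))
    irregularity = params.get("irregularity", 0.08)
    ap_amplitude = params.get("ap_amplitude", 0.05)

    rng = np.random.default_rng(seed)
    sections: list[tuple[ImageSection, PolygonROI]] = []
    true_fracs: list[float] = []
    true_spill: list[int] = []

    for i in range(n_sections):
        # nucleus is slightly larger mid-stack, mimicking its AP profile
        ap_scale = 1.0 + ap_amplitude * math.sin(math.pi * (i + 0.5) / n_sections)
        roi = _nucleus_polygon(
            rng, center, (base_radii[0] * ap_scale, base_radii[1] * ap_scale),
            irregularity=irregularity,
        )
        mask = rasterize(roi, image_shape)
        area = mask.area_px
        n_target = int(round(profile[i] * area))
        blob = _blob_pixels(rng, mask, n_target)

        tracer = np.full(image_shape, background_mean, dtype=float)
        tracer[blob] = core_intensity

        k_spill = int(spill_profile[i])
        if k_spill > 0:
            outside = ~mask.grid
            oy, ox = np.nonzero(outside)
            if k_spill > oy.size:
                raise ValidationError("spillover count exceeds available outside pixels")
            anchor = roi.vertices[rng.integers(len(roi.vertices))]
            d2 = (ox - anchor[0]) ** 2 + (oy - anchor[1]) ** 2
            near = np.argpartition(d2, k_spill - 1)[:k_spill]
            tracer[oy[near], ox[near]] = core_intensity

        if background_sd > 0:
            tracer = tracer + rng.normal(0, background_sd, image_shape)
        nissl = np.full(image_shape, 10.0)
        nissl[mask.grid] = 80.0
        if background_sd > 0:
            nissl = nissl + rng.normal(0, background_sd, image_shape)

        section = ImageSection(
            channels={"TRITC": _discretize(tracer), "Nissl": _discretize(nissl)},
            pixel_size_um=pixel_size_um,
            thickness_um=thickness_um,
            section_index=i,
        )
        sections.append((section, roi))
        true_fracs.append(n_target / area if area else 0.0)
        true_spill.append(k_spill)

    truth = InjectionTruth(
        section_fractions=true_fracs,
        section_spillover_px=true_spill,
        volume_fraction=float(np.mean(true_fracs)),
        params={
            "core_intensity": core_intensity,
            "background_mean": background_mean,
            "background_sd": background_sd,
            "image_shape": tuple(image_shape),
            "pixel_size_um": pixel_size_um,
            "thickness_um": thickness_um,
            "seed": seed,
        },
    )
    return sections, truth


# ---------------------------------------------------------------------------
# Colocalization cells
# ---------------------------------------------------------------------------


@dataclass
class ColocTruth:
    """Per-cell generating correlation and placement for a coloc field."""

    rho: list[float]
    group: list[str]
    cell_bounds: list[tuple[tuple[int, int], tuple[int, int], tuple[int, int]]]
    params: dict = field(default_factory=dict)


def _disc(radius: int) -> np.ndarray:
    d = 2 * radius + 1
    yy, xx = np.mgrid[:d, :d] - radius
    return (yy**2 + xx**2) <= radius**2


def generate_coloc_cells(
    n_cells: int,
    rho: float | Sequence[float],
    cell_radius_px: int = 8,
    field_shape: tuple[int, int] = (256, 256),
    background_mean: float = 20.0,
    background_sd: float = 5.0,
    marginal_mean: float = 128.0,
    marginal_sd: float = 30.0,
    group: str = "",
    channel_names: tuple[str, str] = ("GFP", "GAD67"),
    seed: int | None = None,
    max_tries: int = 5000,
) -> tuple[ImageStack, list[CellROI], ColocTruth]:
    """Two-channel field of circular somata with controlled co-labeling.

    Within each cell mask the two channel intensities are drawn from a
    bivariate Gaussian (a Gaussian copula over a Gaussian marginal with the
    requested Pearson correlation), then rounded half-up and clipped to
    0-255.  Outside cells both channels carry independent background noise.
    """
    if n_cells < 1:
        raise ValidationError("need at least one cell")
    rhos = np.broadcast_to(np.asarray(rho, dtype=float), (n_cells,)).copy()
    if np.any(rhos < -1) or np.any(rhos > 1):
        raise ValidationError("rho must lie in [-1, 1]")
    rows, cols = field_shape
    r = int(cell_radius_px)
    if 2 * r + 2 >= min(rows, cols):
        raise ValidationError("cells do not fit the field")

    rng = np.random.default_rng(seed)

    # Non-overlapping placement by bounded rejection sampling.
    centers: list[tuple[int, int]] = []
    tries = 0
    min_d2 = (2 * r + 2) ** 2
    while len(centers) < n_cells and tries < max_tries:
        tries += 1
        cy = int(rng.integers(r + 1, rows - r - 1))
        cx = int(rng.integers(r + 1, cols - r - 1))
        if all((cy - y) ** 2 + (cx - x) ** 2 >= min_d2 for y, x in centers):
            centers.append((cy, cx))
    if len(centers) < n_cells:
        raise ValidationError(
            f"could only place {len(centers)} of {n_cells} cells of radius {r} "
            f"in a {rows}x{cols} field; reduce n_cells or cell size"
        )

    chan_a = background_mean + rng.normal(0, background_sd, (1, rows, cols))
    chan_b = background_mean + rng.normal(0, background_sd, (1, rows, cols))
    disc = _disc(r)
    n_px = int(disc.sum())
    cell_rois: list[CellROI] = []
    bounds_list = []
    for idx, ((cy, cx), rho_i) in enumerate(zip(centers, rhos)):
        z1 = rng.standard_normal(n_px)
        z2 = rng.standard_normal(n_px)
        zb = rho_i * z1 + math.sqrt(max(0.0, 1.0 - rho_i**2)) * z2
        a_vals = marginal_mean + marginal_sd * z1
        b_vals = marginal_mean + marginal_sd * zb
        ys, xs = np.nonzero(disc)
        chan_a[0, cy - r + ys, cx - r + xs] = a_vals
        chan_b[0, cy - r + ys, cx - r + xs] = b_vals
        bounds = ((0, 1), (cy - r, cy + r + 1), (cx - r, cx + r + 1))
        cell_rois.append(
            CellROI(
                z=bounds[0], y=bounds[1], x=bounds[2],
                mask=disc[None],
                cell_id=f"{group}_cell{idx:03d}" if group else f"cell{idx:03d}",
                group=group,
            )
        )
        bounds_list.append(bounds)

    stack = ImageStack(
        channels={
            channel_names[0]: _discretize(chan_a),
            channel_names[1]: _discretize(chan_b),
        }
    )
    truth = ColocTruth(
        rho=[float(x) for x in rhos],
        group=[group] * n_cells,
        cell_bounds=bounds_list,
        params={
            "cell_radius_px": r,
            "marginal_mean": marginal_mean,
            "marginal_sd": marginal_sd,
            "background_mean": background_mean,
            "background_sd": background_sd,
            "seed": seed,
        },
    )
    return stack, cell_rois, truth


# ---------------------------------------------------------------------------
# IPSC experiment
# ---------------------------------------------------------------------------


@dataclass
class IPSCTruth:
    """Generating parameters for a synthetic IPSC pharmacology experiment."""

    gaba_fraction: dict[str, float]
    total_amp_mean_pA: float
    noise_cv: float
    leak_pA: float
    n_per_group: dict[str, int]
    params: dict = field(default_factory=dict)


def generate_ipsc_experiment(
    n_cells_per_group: Mapping[str, int],
    group_fractions: Mapping[str, float],
    total_amp_mean_pA: float = 100.0,
    noise_cv: float = 0.05,
    leak_pA: float = 0.0,
    seed: int | None = None,
    max_resample: int = 100,
) -> tuple[list[IPSCRecord], IPSCTruth]:
    """Per-cell amplitude triplets with a settable GABAergic fraction.

    Total amplitudes are Gaussian around ``total_amp_mean_pA`` with
    coefficient of variation ``noise_cv`` (resampled if non-positive, bounded
    retries); the strychnine residual is ``leak + f*(total - leak)`` with
    multiplicative noise of the same CV; the complete-block amplitude is the
    leak.  ``noise_cv = 0`` yields exact arithmetic.
    """
    if set(n_cells_per_group) != set(group_fractions):
        raise ValidationError("group keys of sizes and fractions must match")
    for g, f in group_fractions.items():
        if not 0.0 <= f <= 1.0:
            raise ValidationError(f"group {g!r}: fraction {f} outside [0, 1]")
    if noise_cv < 0:
        raise ValidationError("noise_cv must be >= 0")
    if leak_pA < 0 or total_amp_mean_pA <= leak_pA:
        raise ValidationError("need 0 <= leak < total amplitude mean")

    rng = np.random.default_rng(seed)

    def _positive_normal(mean: float, sd: float) -> float:
        if sd == 0:
            return mean
        for _ in range(max_resample):
            x = rng.normal(mean, sd)
            if x > 0:
                return float(x)
        raise ValidationError(
            f"could not sample a positive amplitude around {mean} +/- {sd}"
        )

    records: list[IPSCRecord] = []
    for g, n in n_cells_per_group.items():
        f = group_fractions[g]
        for i in range(n):
            total = _positive_normal(total_amp_mean_pA, noise_cv * total_amp_mean_pA)
            evoked = total - leak_pA
            for _ in range(max_resample):
                mult = 1.0 if noise_cv == 0 else rng.normal(1.0, noise_cv)
                residual = leak_pA + f * evoked * mult
                if leak_pA <= residual <= total:
                    break
            else:
                raise ValidationError("could not sample a valid residual amplitude")
            records.append(
                IPSCRecord(
                    cell_id=f"{g}_cell{i:03d}",
                    group=g,
                    amp_total_pA=total,
                    amp_after_strychnine_pA=residual,
                    amp_after_both_pA=leak_pA,
                )
            )
    truth = IPSCTruth(
        gaba_fraction=dict(group_fractions),
        total_amp_mean_pA=total_amp_mean_pA,
        noise_cv=noise_cv,
        leak_pA=leak_pA,
        n_per_group=dict(n_cells_per_group),
        params={"seed": seed},
    )
    return records, truth
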