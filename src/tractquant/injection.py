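"""Semi-automated tracer injection-site quantification.

The procedure, per analysed section:

1. the experimenter's nucleus outline (a :class:`~tractquant.image_model.PolygonROI`,
   traced on the Nissl channel) is rasterized to a mask;
2. three square background sample boxes, each covering 1% of the image's
   pixels, capture the background signal distribution in the tracer channel;
3. a threshold is computed from the pooled ROI + background pixels as
   ``mean + 2*SD``, with an upper-bound rule ``255 - 2*SD`` when pixel
   variability pushes the primary rule past the 8-bit ceiling;
4. pixels strictly above threshold inside the nucleus mask count as labeled;
5. a dynamically expanding box, initialised 25% larger in area than the ROI
   and centred on it, grows one pixel per tripped side per iteration until
   fewer than 10% of each side's pixels are suprathreshold; suprathreshold
   pixels outside the nucleus but inside the final box quantify spillover.

Per-brain, labeled areas are converted to volumes (area x section thickness)
and expressed as a percentage of nucleus volume, with a coverage rule that at
least 70% of the nucleus's antero-posterior extent must have been analysed.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .image_model import (
    BinaryMask,
    BoxROI,
    ImageSection,
    PolygonROI,
    ValidationError,
    rasterize,
)

logger = logging.getLogger(__name__)

__all__ = [
    "ThresholdSpec",
    "SectionQuant",
    "InjectionSummary",
    "SpilloverResult",
    "place_background_boxes",
    "compute_threshold",
    "count_labeled",
    "expand_spillover_box",
    "quantify_section",
    "summarize_injection",
]

MAX_INTENSITY = 255.0


@dataclass(frozen=True)
class ThresholdSpec:
    """Pooled background statistics and the resulting labeling threshold.

    ``capped`` is true iff ``mean + 2*sd`` exceeded 255, in which case the
    upper-bound rule ``threshold = 255 - 2*sd`` applies.  The threshold is
    kept real-valued; labeling uses a strict ``>`` comparison, so rounding
    would only discard information.
    """

    mean: float
    sd: float
    threshold: float
    capped: bool


@dataclass
class SpilloverResult:
    box: BoxROI
    spillover_px: int
    hit_border: bool = False
    n_iterations: int = 0


@dataclass
class SectionQuant:
    """Full per-section audit record of the quantification."""

    section_index: int
    roi_area_px: int
    threshold_spec: ThresholdSpec
    labeled_px_in_roi: int
    spillover_px: int
    final_box: BoxROI
    background_boxes: list[BoxROI] = field(default_factory=list)
    hit_border: bool = False

    @property
    def labeled_fraction(self) -> float:
        return self.labeled_px_in_roi / self.roi_area_px if self.roi_area_px else math.nan


@dataclass
class InjectionSummary:
    """Whole-nucleus injection summary across serial sections."""

    volume_fraction_pct: float
    epicenter_section_index: int
    epicenter_area_pct: float
    ap_coverage_fraction: float
    coverage_ok: bool
    total_spillover_volume_um3: float
    injected_volume_um3: float
    roi_volume_um3: float
    n_sections: int


# ---------------------------------------------------------------------------


def _box_side(total_pixels: int, box_fraction: float) -> int:
    return int(round(math.sqrt(box_fraction * total_pixels)))


def place_background_boxes(
    section: ImageSection,
    roi_mask: BinaryMask,
    positions: Sequence[tuple[int, int]] | None = None,
    box_fraction: float = 0.01,
) -> list[BoxROI]:
    """Place three square background sample boxes of 1% of image area each.

    When ``positions`` (a list of ``(x, y)`` top-left anchors) is omitted,
    boxes are placed deterministically at image corners, skipping any corner
    whose box would intersect the ROI.  Experimenter-supplied positions are
    honoured even if they overlap the ROI (logged as a warning).
    """
    rows, cols = section.shape
    if roi_mask.shape != (rows, cols):
        raise ValidationError("ROI mask shape differs from image shape")
    side = _box_side(rows * cols, box_fraction)
    if side < 1 or side > rows or side > cols:
        raise ValidationError(
            f"cannot fit background boxes of side {side} in a {rows}x{cols} image; "
            "use a smaller box fraction"
        )

    if positions is not None:
        if len(positions) != 3:
            raise ValidationError(f"need exactly 3 box anchors, got {len(positions)}")
        boxes = []
        for x, y in positions:
            box = BoxROI(left=x, right=x + side, top=y, bottom=y + side).clipped((rows, cols))
            rs, cs = box.slices()
            if roi_mask.grid[rs, cs].any():
                logger.warning(
                    "background box at (%d, %d) overlaps the ROI (experimenter override)", x, y
                )
            boxes.append(box)
        return boxes

    corners = [
        (0, 0),
        (cols - side, 0),
        (0, rows - side),
        (cols - side, rows - side),
    ]
    boxes: list[BoxROI] = []
    for x, y in corners:
        box = BoxROI(left=x, right=x + side, top=y, bottom=y + side)
        rs, cs = box.slices()
        if roi_mask.grid[rs, cs].any():
            continue
        if any(box.overlaps(b) for b in boxes):
            continue
        boxes.append(box)
        if len(boxes) == 3:
            return boxes
    raise ValidationError(
        "could not place three ROI-disjoint background boxes at the image corners; "
        "use a smaller box fraction or provide explicit positions"
    )


def compute_threshold(pixels: np.ndarray) -> ThresholdSpec:
    """Threshold = pooled mean + 2*SD, capped at 255 - 2*SD.

    ``pixels`` is the pooled set of tracer-channel intensities from the
    nucleus ROI and the three background sample boxes.  The SD is the sample
    standard deviation (n-1 denominator).  A constant pixel set has SD 0 and
    threshold equal to the mean.  The result is clamped to [0, 255].
    """
    px = np.asarray(pixels, dtype=float).ravel()
    if px.size < 2:
        raise ValidationError("need at least 2 pooled pixels for a threshold")
    if px.min() < 0 or px.max() > MAX_INTENSITY:
        raise ValidationError("pooled intensities must lie in [0, 255]")
    mean = float(px.mean())
    sd = float(px.std(ddof=1))
    threshold = mean + 2.0 * sd
    capped = threshold > MAX_INTENSITY
    if capped:
        threshold = MAX_INTENSITY - 2.0 * sd
    threshold = min(max(threshold, 0.0), MAX_INTENSITY)
    return ThresholdSpec(mean=mean, sd=sd, threshold=threshold, capped=capped)


def count_labeled(channel: np.ndarray, mask: BinaryMask, threshold: float) -> int:
    """Count pixels strictly above ``threshold`` inside the mask."""
    channel = np.asarray(channel)
    if channel.shape != mask.shape:
        raise ValidationError(
            f"channel shape {channel.shape} does not match mask {mask.shape}"
        )
    return int((channel[mask.grid] > threshold).sum())


def initial_spillover_box(
    roi_mask: BinaryMask,
    shape: tuple[int, int],
    init_area_scale: float = 1.25,
) -> tuple[BoxROI, bool]:
    """Initial spillover search box: ``init_area_scale`` x ROI area, centred
    on the ROI mask centroid, with the aspect ratio of the ROI bounding box,
    rounded outward to integer bounds.  Returns (box, clipped_flag)."""
    if roi_mask.area_px == 0:
        raise ValidationError("ROI mask is empty")
    ys, xs = np.nonzero(roi_mask.grid)
    cy = (ys.mean() + 0.5)
    cx = (xs.mean() + 0.5)
    bbox_w = xs.max() - xs.min() + 1
    bbox_h = ys.max() - ys.min() + 1
    aspect = bbox_w / bbox_h
    area = init_area_scale * roi_mask.area_px
    w = math.sqrt(area * aspect)
    h = math.sqrt(area / aspect)
    box = BoxROI(
        left=int(math.floor(cx - w / 2)),
        right=int(math.ceil(cx + w / 2)),
        top=int(math.floor(cy - h / 2)),
        bottom=int(math.ceil(cy + h / 2)),
    )
    clipped_box = box.clipped(shape)
    clipped = clipped_box != box
    if clipped:
        warnings.warn("initial spillover box exceeded image bounds; clipped", stacklevel=2)
    return clipped_box, clipped


def _side_fractions(above: np.ndarray, box: BoxROI) -> dict[str, float]:
    """Suprathreshold fraction of each 1-pixel-wide side strip.

    Corner pixels belong to both adjacent sides.  ``above`` is the boolean
    suprathreshold image.
    """
    rs, cs = box.slices()
    return {
        "left": float(above[rs, box.left].mean()),
        "right": float(above[rs, box.right - 1].mean()),
        "top": float(above[box.top, cs].mean()),
        "bottom": float(above[box.bottom - 1, cs].mean()),
    }


def expand_spillover_box(
    channel: np.ndarray,
    roi_mask: BinaryMask,
    threshold: float,
    init_area_scale: float = 1.25,
    side_fraction: float = 0.10,
) -> SpilloverResult:
    """Grow the spillover search box until every side is quiet.

    Each iteration checks the four 1-pixel-wide side strips of the box; any
    side on which the fraction of suprathreshold pixels is >= ``side_fraction``
    moves outward by one pixel.  A side stops at the image border (logged).
    The spillover count is the number of suprathreshold pixels inside the
    final box but outside the nucleus mask.
    """
    channel = np.asarray(channel)
    rows, cols = channel.shape
    if roi_mask.shape != (rows, cols):
        raise ValidationError("ROI mask shape differs from image shape")
    above = channel > threshold

    box, _ = initial_spillover_box(roi_mask, (rows, cols), init_area_scale)
    hit_border = False
    n_iter = 0
    while True:
        fracs = _side_fractions(above, box)
        moved = False
        left, right, top, bottom = box.left, box.right, box.top, box.bottom
        if fracs["left"] >= side_fraction:
            if left > 0:
                left -= 1
                moved = True
            else:
                hit_border = True
        if fracs["right"] >= side_fraction:
            if right < cols:
                right += 1
                moved = True
            else:
                hit_border = True
        if fracs["top"] >= side_fraction:
            if top > 0:
                top -= 1
                moved = True
            else:
                hit_border = True
        if fracs["bottom"] >= side_fraction:
            if bottom < rows:
                bottom += 1
                moved = True
            else:
                hit_border = True
        if not moved:
            break
        box = BoxROI(left=left, right=right, top=top, bottom=bottom)
        n_iter += 1

    if hit_border:
        logger.warning("spillover box stopped at the image border; estimate may be truncated")
    rs, cs = box.slices()
    spill = int((above[rs, cs] & ~roi_mask.grid[rs, cs]).sum())
    return SpilloverResult(box=box, spillover_px=spill, hit_border=hit_border, n_iterations=n_iter)


def quantify_section(
    section: ImageSection,
    roi: PolygonROI,
    tracer_channel: str = "TRITC",
    background_positions: Sequence[tuple[int, int]] | None = None,
    pooling: str = "roi+background",
    init_area_scale: float = 1.25,
    side_fraction: float = 0.10,
) -> SectionQuant:
    """Run the full per-section quantification.

    ``pooling`` selects the pixel set for the threshold statistics:
    ``"roi+background"`` (the default, pooling nucleus-ROI pixels with the
    three background boxes) or ``"background"`` (boxes only, a documented
    deviation for sensitivity analysis).
    """
    if tracer_channel not in section.channels:
        raise ValidationError(
            f"tracer channel {tracer_channel!r} not in section channels "
            f"{list(section.channels)}"
        )
    channel = section.channels[tracer_channel]
    mask = rasterize(roi, section.shape)
    boxes = place_background_boxes(section, mask, positions=background_positions)

    box_pixels = np.concatenate([channel[b.slices()].ravel() for b in boxes])
    if pooling == "roi+background":
        pooled = np.concatenate([channel[mask.grid].ravel(), box_pixels])
    elif pooling == "background":
        pooled = box_pixels
    else:
        raise ValidationError(f"unknown pooling mode {pooling!r}")

    spec = compute_threshold(pooled)
    labeled = count_labeled(channel, mask, spec.threshold)
    spill = expand_spillover_box(
        channel, mask, spec.threshold, init_area_scale=init_area_scale,
        side_fraction=side_fraction,
    )
    return SectionQuant(
        section_index=section.section_index,
        roi_area_px=mask.area_px,
        threshold_spec=spec,
        labeled_px_in_roi=labeled,
        spillover_px=spill.spillover_px,
        final_box=spill.box,
        background_boxes=boxes,
        hit_border=spill.hit_border,
    )


def summarize_injection(
    sections: Sequence[SectionQuant],
    thickness_um: float | Sequence[float],
    pixel_size_um: float,
    total_ap_extent_sections: int,
    coverage_threshold: float = 0.70,
) -> InjectionSummary:
    """Aggregate per-section quantifications into whole-nucleus volumes.

    Labeled and ROI pixel counts become areas (``px * pixel_size_um**2``) and
    then volumes (``area * thickness_um``); the injected volume percentage is
    ``100 * injected_volume / roi_volume``.  The epicentre is the section with
    the highest labeled *fraction* of its ROI.  ``ap_coverage_fraction`` is
    the number of analysed sections over the nucleus's full antero-posterior
    extent in sections; at least ``coverage_threshold`` (70%) must be covered
    for the summary to count as adequately sampled.
    """
    if not sections:
        raise ValidationError("need at least one quantified section")
    if not pixel_size_um > 0:
        raise ValidationError("pixel_size_um must be positive")
    n = len(sections)
    thickness = np.broadcast_to(np.asarray(thickness_um, dtype=float), (n,))
    if np.any(thickness <= 0):
        raise ValidationError("thickness_um must be positive")

    kept: list[tuple[SectionQuant, float]] = []
    for q, t in zip(sections, thickness):
        if q.roi_area_px == 0:
            warnings.warn(
                f"section {q.section_index} has empty ROI; excluded from summary",
                stacklevel=2,
            )
            continue
        kept.append((q, float(t)))
    if not kept:
        raise ValidationError("all sections had empty ROIs")

    px_area = pixel_size_um**2
    injected_vol = sum(q.labeled_px_in_roi * px_area * t for q, t in kept)
    roi_vol = sum(q.roi_area_px * px_area * t for q, t in kept)
    spill_vol = sum(q.spillover_px * px_area * t for q, t in kept)

    epi_q = max((q for q, _ in kept), key=lambda q: q.labeled_fraction)
    n_analyzed = len(kept)
    if total_ap_extent_sections < n_analyzed:
        raise ValidationError(
            "total antero-posterior extent is smaller than the number of analysed sections"
        )
    ap_cov = n_analyzed / total_ap_extent_sections
    return InjectionSummary(
        volume_fraction_pct=100.0 * injected_vol / roi_vol,
        epicenter_section_index=epi_q.section_index,
        epicenter_area_pct=100.0 * epi_q.labeled_fraction,
        ap_coverage_fraction=ap_cov,
        coverage_ok=ap_cov >= coverage_threshold,
        total_spillover_volume_um3=spill_vol,
        injected_volume_um3=injected_vol,
        roi_volume_um3=roi_vol,
        n_sections=n_analyzed,
    )
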