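# Methods

## Coordinate and intensity conventions

All pixel coordinates are 0-based, x rightward (columns), y downward
(rows); the centre of pixel (x, y) is the continuous point
(x + 0.5, y + 0.5). ROI JSON files state this convention in a `convention`
field. A pixel belongs to a polygon ROI iff its centre lies strictly inside
the polygon (even-odd rule, delegated to shapely); the test suite checks
this against a brute-force ray-casting oracle on random simple polygons.

Images are processed at 8-bit working depth. Higher acquisition depths
(12/16 bit) are reduced by floor division by 2^(depth−8) — a pure bit
shift, not min–max rescaling — so thresholds expressed in 8-bit units are
independent of acquisition depth up to quantisation, and the conversion is
monotone and parameter-free.

## Injection-site quantification

Per section, the threshold statistics pool the tracer-channel pixels of the
traced nucleus ROI **and** three square background boxes (each of side
round(√(0.01·N)) for an N-pixel image, i.e. 1% of image area; side 205 for
a 2048×2048 frame). That pooling follows the procedure's literal
description; a `pooling="background"` switch restricts the statistics to
the boxes alone for sensitivity analysis. Automatic box placement uses the
image corners, skipping any corner whose box would touch the ROI — a
deterministic stand-in for the experimenter's choice of signal-free
regions; explicit positions are honoured even if they overlap the ROI
(logged). The threshold is `mean + 2·SD` (sample SD, n−1), replaced by
`255 − 2·SD` when the primary rule exceeds 255, and kept real-valued:
labeling uses a strict `>` comparison, so rounding the threshold would only
discard information.

The spillover search box starts at 1.25× the ROI area, centred on the ROI
mask centroid, with the aspect ratio of the ROI bounding box and bounds
rounded outward — the least-surprising reading of "centred on the ROI",
since the original procedure does not define the box shape. Each iteration
evaluates all four 1-pixel-wide side strips on the current box (corner
pixels belong to both adjacent sides) and moves every side with a
suprathreshold fraction ≥ 0.10 outward by one pixel; a side stops at the
image border with a logged flag. Expansion triggering is inclusive
(≥ 0.10), termination strict (< 0.10). Equivalence with an independent
loop-level simulation of this rule is asserted on 50 random images.

Volume summaries multiply pixel counts by pixel area (default 0.742 µm,
the acquisition's pixel pitch) and section thickness (default 80 µm).
The injected-volume percentage is 100·Σ(labeled·t)/Σ(ROI·t); the epicentre
is the section with the maximal labeled *fraction* (robust to ROI-area
variation along the axis, in contrast to the maximal absolute count);
antero-posterior coverage of at least 70% of the nucleus's extent marks a
summary as adequately sampled. Spillover is reported separately and never
enters the injected-volume percentage, since whether it should is not
determinate from the procedure's description.

### Known sensitivities of the threshold rule

Because ROI pixels enter the pooled statistics, the threshold rises with
the injected fraction. For a tracer core at intensity c over background b,
`mean + 2·SD` crosses c once the bright fraction p of the pooled set
exceeds the root of p + 2√(p(1−p)) = 1, i.e. p = 0.2, *independently of
c − b*. Beyond that, a sub-saturating core (e.g. 200) goes uncounted while
the cap (255 − 2·SD) only rescues near-saturated signal. In the original
acquisition this regime is avoided by exposure choice (the epicentre is
near-saturated); the synthetic defaults avoid it by keeping per-section
fractions below ~0.25 at core 200. Relatedly, the expanding box can
undercount spillover lobes whose suprathreshold crossing of a side stays
below the 10% rule: the box never reaches the lobe's far tail. Closed-loop
tests therefore assert exact recovery of the injected fraction (noiseless)
and bounded-from-above, typically-complete recovery of spillover.

## Synthetic data

`generate_injection_series` draws, per section, a star-shaped nucleus
outline (low-order harmonic perturbation of an ellipse, default radii
0.22/0.16 of the frame, irregularity 0.08) whose size swells ~5% mid-stack
to mimic the nucleus's antero-posterior profile. The injected blob is the
top-k scoring pixels inside the ROI under a radial bowl plus a smoothed
Gaussian field — exact area control (k = round(fraction·area)) with ragged,
plausible edges. Spillover lobes are the k nearest outside pixels to a
random boundary vertex. Intensities: background mean 20, additive Gaussian
noise SD 5, core 200 — the separation (>4 SD by a guard) a usable tracer
image needs; these are free parameters of the generator, not estimates of
any particular dataset. The per-section fraction profile is the caller's;
`bell_profile` provides a raised-cosine with a set mean (default relative
amplitude 0.5, keeping peak sections below the p = 0.2 regime above at the
default core). The truth manifest records realised per-section fractions
and their thickness-weighted mean; with the mild ROI-size modulation the
estimator's area-weighted ratio differs from that mean only in the second
order (well under the 2-point tolerance used in closed-loop checks).

`generate_coloc_cells` packs non-overlapping discs (default radius 8 px)
by bounded rejection sampling, then fills each with a bivariate Gaussian —
Gaussian copula over a Gaussian marginal (mean 128, SD 30), correlation ρ —
rounded half-up and clipped to 0–255. Half-up rounding after an exact
reflection makes ρ = ±1 yield ICQ = ±0.5 exactly (the SD is small enough
that clipping is negligible, which that exactness needs); at intermediate ρ
the expected ICQ is asin(ρ)/π ≈ 0.167 at ρ = 0.5. Outside cells both
channels carry independent background noise, so rectangular crops without
masks dilute the correlation — per-cell disc masks are attached to every
generated `CellROI`.

`generate_ipsc_experiment` draws per-cell totals ~ N(100 pA, CV·100 pA)
(resampled if non-positive), residual = leak + f·(total − leak)·(1 + ε),
ε ~ N(0, CV), complete block = leak (default 0). CV 0 gives exact
arithmetic; sampled records always satisfy leak ≤ residual ≤ total.

Every generator takes one seed and owns one `numpy.random.Generator`; no
global state.

## Colocalization conventions

Pixels with PDM exactly 0 are excluded from the ICQ ratio (their count is
reported, so the count-as-non-positive convention can be recomputed); this
keeps the ±0.5 extremes attainable and the statistic symmetric in the
channels. No background pre-thresholding is applied inside cell crops by
default. The colour map normalises PDM by (A_max − Ā)(B_max − B̄) and clips
to [−1, 1]; its sign pattern equals the PDM sign pattern pixel for pixel.
The 3D crop (not a single plane) is the default analysis unit; single-plane
analysis is the z-range (z, z+1). Group comparison uses the exact
Mann-Whitney distribution when both n ≤ 20 with no ties, otherwise the
tie-corrected normal approximation with continuity correction; a per-cell
binomial sign test on the positive-PDM count is available but is not part
of the headline pipeline, which reports only the group-level comparison.

## IPSC decomposition conventions

The complete-block amplitude is used as the leak baseline for both the
numerator and the denominator, so per-cell fractions sum to 1 exactly and
are invariant to rescaling all three amplitudes. Records violating
0 ≤ leak ≤ residual ≤ total are flagged and excluded from group summaries
with a log entry, never silently dropped. Welch's t-test is the default
(small unequal groups, unequal variances plausible); Student's is
available. Degenerate zero-variance comparisons report the p-value floored
at the smallest positive float rather than 0.

## Problem sizes

Synthetic frames default to 256×256 (320×320 for the 120-cell
colocalization fields); these sizes leave every statistical property of the
pipelines intact — thresholds, ICQ distributions and fraction recovery
depend on fractions and SDs, not on frame size — while keeping the full
suite and the acceptance script fast. The acquisition-scale defaults
(2048×2048, 0.742 µm, 80 µm) remain the CLI defaults and are exercised in
the background-box sizing test.

## Limitations

- No registration, denoising, or automatic segmentation: outlines and cell
  crops are inputs, assumed pre-aligned by section index.
- The generators model neither the point-spread function, photobleaching,
  nor z-optics; passing closed-loop tests shows the *computations* are
  correct under the stated statistical structure, not that the thresholding
  rule is robust to optical artefacts absent from the model.
- The injection pipeline quantifies the *apparent* (fluorescently visible)
  injection site only; no attempt is made to infer the effective uptake
  region.
- One traced outline per analysed section is required; no interpolation
  between sections is performed.
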