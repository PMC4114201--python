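# tractquant

Quantification pipelines for fluorescent neural tract-tracing studies of the
auditory brainstem, built for work on inhibitory projections to the medial
nucleus of the trapezoid body (MNTB). The package implements three analyses
that in the original workflow lived in ad-hoc lab scripts, and pairs each
with a synthetic-data generator carrying exact ground truth, so every stage
can be validated end to end without microscope or patch-clamp data.

## What it computes

**1. Injection-site quantification** (`tractquant.injection`).
Given serial epifluorescent sections (a TRITC-like tracer channel plus a
Nissl delineation channel) and an experimenter-traced nucleus outline per
section, the pipeline:

- samples the background in three square boxes, each 1% of the image pixels;
- pools ROI + background pixels and sets the labeling threshold

  `T = mean + 2·SD`, capped at `T = 255 − 2·SD` when the primary rule
  exceeds the 8-bit ceiling (sample SD, n−1 denominator);

- counts pixels strictly above `T` inside the nucleus outline as labeled;
- estimates tracer **spillover** outside the nucleus with a dynamically
  expanding box: initialised 25% larger in area than the ROI and centred on
  it, each 1-pixel-wide side expands outward while ≥ 10% of its pixels are
  suprathreshold;
- converts per-section areas to volumes (pixel area × section thickness) and
  reports the injected volume as a percentage of nucleus volume, the
  epicentre section, and whether ≥ 70% of the nucleus's antero-posterior
  extent was analysed.

**2. ICQ colocalization** (`tractquant.coloc`).
Li's intensity-correlation analysis per cell: the product of the differences
from the mean, PDM_i = (A_i − Ā)(B_i − B̄), condensed into the intensity
correlation quotient ICQ = (#PDM>0)/(#PDM≠0) − 0.5 ∈ [−0.5, +0.5], the
normalised-PDM colocalization colour map for hot-spot rendering, and a
two-sided Mann-Whitney rank-sum comparison of per-cell ICQ values between
groups (exact null distribution for small tie-free samples).

**3. IPSC pharmacological decomposition** (`tractquant.ephys`).
From per-cell peak amplitudes recorded drug-free, after strychnine, and
after strychnine + gabazine, the GABAergic fraction of the leak-subtracted
total is `(R − L)/(T − L)`; glycinergic is its complement. Groups are
compared with Welch's t-test (Student's optional).

`tractquant.synthetic` generates inputs for all three with known truth;
`tractquant.image_model` supplies TIFF/ROI I/O (a documented JSON polygon
dialect plus an ImageJ `.roi` importer) and polygon rasterization.

## Worked example

`examples/` holds one narrative script per pipeline. For instance
`python examples/injection_quantification.py` builds a 10-section synthetic
brain whose tracer truly fills 14.00% of the nucleus volume and prints:

```
section 4: ROI 7992 px, threshold 183.4, labeled 1650 px (20.6% of ROI), spillover 155 px
...
injected volume: 14.14% of the nucleus (ground truth 14.00%)
epicenter: section 5 (20.6% of its ROI area labeled)
AP coverage: 100% (meets the 70% rule)
```

The per-section lines show the pooled threshold and the labeled pixel count
inside the traced outline; the summary converts these to the whole-nucleus
injected-volume percentage, which lands within 0.2 points of truth here.
`examples/colocalization_icq.py` separates cell groups generated at channel
correlation 0.5 vs 0.0 (mean ICQ +0.166 vs −0.000, Mann-Whitney
p ≈ 3.5e-21), and `examples/ipsc_fractions.py` recovers GABA fractions of
23.9% (young) vs 5.9% (adult) from a 24%/6% generating truth.

A thin CLI mirrors the pipelines for shell use:
`tractquant quantify`, `tractquant coloc`, `tractquant ipsc-fractions`, and
`tractquant synth-injection` (see `--help` on each).

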