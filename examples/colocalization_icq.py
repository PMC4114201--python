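"""Per-cell intensity-correlation (ICQ) analysis of two-channel somata.

Generates two fields of 60 circular cells each: a "young" group in which the
green (glycinergic marker) and red (GABAergic marker) channels covary with
Pearson correlation 0.5 inside each cell, and an "adult" group with no
covariation.  Computes the ICQ per cell and compares the groups with the
two-sided Mann-Whitney rank-sum test.
"""

import numpy as np

from tractquant import (
    compare_icq_groups,
    compute_icq,
    extract_cell_pixels,
    generate_coloc_cells,
)

icqs = {}
for rho, tag, seed in ((0.5, "young", 1), (0.0, "adult", 2)):
    stack, cells, _ = generate_coloc_cells(
        n_cells=60, rho=rho, field_shape=(320, 320), group=tag, seed=seed
    )
    icqs[tag] = [
        compute_icq(*extract_cell_pixels(stack, cell, "GFP", "GAD67")).icq
        for cell in cells
    ]
    print(
        f"{tag}: generating correlation {rho}, mean ICQ "
        f"{np.mean(icqs[tag]):+.3f} +/- {np.std(icqs[tag], ddof=1):.3f} "
        f"over {len(cells)} cells"
    )

cmp = compare_icq_groups(icqs["young"], icqs["adult"])
print(f"Mann-Whitney U = {cmp.statistic:.0f}, two-sided p = {cmp.p_value:.3g}")

# ICQ lies in [-0.5, +0.5]: 0 means random channel overlap, +0.5 perfect
# covariation.  A bivariate-normal cell at correlation rho has expected ICQ
# asin(rho)/pi (about 0.167 at rho = 0.5), so the two groups separate far
# below the p < 0.001 level at these sample sizes.
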