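"""Pharmacological decomposition of evoked inhibitory currents.

Mixed inhibitory postsynaptic currents (IPSCs) at auditory brainstem synapses
carry a glycinergic and a GABAergic component.  Recording the peak evoked
amplitude under three conditions isolates them:

* ``amp_total_pA``            — drug-free mixed IPSC;
* ``amp_after_strychnine_pA`` — residual (GABAergic) current after blocking
  glycine receptors with strychnine;
* ``amp_after_both_pA``       — leak remaining after additionally blocking
  GABA_A receptors with gabazine (SR-95531).

With leak L, total T0 and strychnine residual R, the per-cell fractions are

    gaba_fraction    = (R - L) / (T0 - L)
    glycine_fraction = 1 - gaba_fraction

so the two always sum to one.  Group comparison between age groups uses a
two-sample two-tailed t-test on the GABA fraction (Welch by default).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .image_model import ValidationError

logger = logging.getLogger(__name__)

__all__ = [
    "IPSCRecord",
    "FractionSummary",
    "decompose",
    "summarize_groups",
    "read_ipsc_csv",
]

IPSC_CSV_COLUMNS = [
    "cell_id",
    "group",
    "amp_total_pA",
    "amp_after_strychnine_pA",
    "amp_after_both_pA",
]


@dataclass
class IPSCRecord:
    """Peak evoked IPSC magnitudes (pA) for one cell under each condition."""

    cell_id: str
    group: str
    amp_total_pA: float
    amp_after_strychnine_pA: float
    amp_after_both_pA: float = 0.0
    amp_washout_pA: float | None = None

    def validate(self) -> list[str]:
        """Return invariant violations (empty list = valid).

        Violating records are flagged, not silently dropped; downstream
        aggregation excludes them with a log entry.
        """
        problems = []
        if min(self.amp_total_pA, self.amp_after_strychnine_pA, self.amp_after_both_pA) < 0:
            problems.append("negative amplitude magnitude")
        if self.amp_after_both_pA > self.amp_after_strychnine_pA:
            problems.append("leak exceeds strychnine residual")
        if self.amp_after_strychnine_pA > self.amp_total_pA:
            problems.append("strychnine residual exceeds total")
        return problems


@dataclass
class FractionSummary:
    per_cell: pd.DataFrame
    group_means: dict[str, float]
    group_sds: dict[str, float]
    group_ns: dict[str, int]
    t_statistic: float
    p_value: float
    test: str
    n_excluded: int


def decompose(record: IPSCRecord) -> tuple[float, float]:
    """Split one cell's inhibitory current into (gaba, glycine) fractions.

    The complete-block amplitude is subtracted as leak from both the
    numerator and the denominator.
    """
    problems = record.validate()
    if problems:
        raise ValidationError(f"record {record.cell_id!r} invalid: {'; '.join(problems)}")
    total = record.amp_total_pA - record.amp_after_both_pA
    if total <= 0:
        raise ValidationError(
            f"record {record.cell_id!r}: no evoked current after leak subtraction "
            f"(T = {total:g} pA)"
        )
    gaba = (record.amp_after_strychnine_pA - record.amp_after_both_pA) / total
    return gaba, 1.0 - gaba


def summarize_groups(
    records: Sequence[IPSCRecord],
    test: str = "welch",
) -> FractionSummary:
    """Per-cell fractions, group mean +/- SD, and a between-group t-test.

    ``test`` is ``"welch"`` (default; unequal variances) or ``"student"``.
    Exactly two groups are compared.  The p-value is floored at the smallest
    positive float so that degenerate zero-variance groups report a bounded,
    nonzero value.
    """
    if test not in ("welch", "student"):
        raise ValidationError(f"unknown test {test!r}; use 'welch' or 'student'")
    rows = []
    n_excluded = 0
    for rec in records:
        problems = rec.validate()
        if problems:
            logger.warning("excluding cell %r: %s", rec.cell_id, "; ".join(problems))
            n_excluded += 1
            continue
        gaba, gly = decompose(rec)
        rows.append(
            {"cell_id": rec.cell_id, "group": rec.group,
             "gaba_fraction": gaba, "glycine_fraction": gly}
        )
    per_cell = pd.DataFrame(rows, columns=["cell_id", "group", "gaba_fraction", "glycine_fraction"])
    groups = list(dict.fromkeys(per_cell["group"]))
    if len(groups) != 2:
        raise ValidationError(f"need exactly 2 groups, got {groups}")
    by_group = {g: per_cell.loc[per_cell["group"] == g, "gaba_fraction"].to_numpy() for g in groups}
    for g, vals in by_group.items():
        if vals.size < 2:
            raise ValidationError(f"group {g!r} has fewer than 2 valid records")
    res = stats.ttest_ind(
        by_group[groups[0]], by_group[groups[1]], equal_var=(test == "student")
    )
    tiny = float(np.nextafter(0.0, 1.0))
    return FractionSummary(
        per_cell=per_cell,
        group_means={g: float(v.mean()) for g, v in by_group.items()},
        group_sds={g: float(v.std(ddof=1)) for g, v in by_group.items()},
        group_ns={g: int(v.size) for g, v in by_group.items()},
        t_statistic=float(res.statistic),
        p_value=max(float(res.pvalue), tiny),
        test=test,
        n_excluded=n_excluded,
    )


def read_ipsc_csv(path: str | Path) -> list[IPSCRecord]:
    """Load per-cell IPSC amplitudes from CSV.

    Required columns: cell_id, group, amp_total_pA, amp_after_strychnine_pA,
    amp_after_both_pA; optional amp_washout_pA.
    """
    df = pd.read_csv(path)
    missing = [c for c in IPSC_CSV_COLUMNS if c not in df.columns]
    if missing:
        raise ValidationError(f"IPSC CSV missing columns: {missing}")
    records = []
    for _, row in df.iterrows():
        records.append(
            IPSCRecord(
                cell_id=str(row["cell_id"]),
                group=str(row["group"]),
                amp_total_pA=float(row["amp_total_pA"]),
                amp_after_strychnine_pA=float(row["amp_after_strychnine_pA"]),
                amp_after_both_pA=float(row["amp_after_both_pA"]),
                amp_washout_pA=float(row["amp_washout_pA"]) if "amp_washout_pA" in df.columns and pd.notna(row.get("amp_washout_pA")) else None,
            )
        )
    return records
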