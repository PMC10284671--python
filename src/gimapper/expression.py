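"""Differential GOI expression gate between control and mutant subgroups.

Before a screen, the user must pick one mutant subgroup; the pick should be
supported by evidence that GOI function is actually reduced in those lines.
This module compares GOI mRNA (and, when a protein matrix is supplied,
protein) expression of each mutant subgroup against the control group with
Welch's unequal-variance t-test and reports one row per (subgroup,
modality) with the test statistic, Welch–Satterthwaite degrees of freedom,
two-sided p-value and a direction call.  The tool reports — the *user*
selects the subgroup downstream (an explicit argument, never auto-picked).

The test is two-sided with the direction reported separately: a mutant
group qualifies for the classical "significant reduction" gate exactly when
``direction == "reduced"``.  No multiple-testing correction is applied here
— at most six tests are run (three subgroups × two modalities) for a single
query gene.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd
from scipy import stats

from .cohort import MUTANT_GROUPS, GroupAssignment
from .depmap_io import GeneMatrix, MatrixRole

__all__ = ["WelchResult", "welch_t", "expression_gate"]

REDUCED = "reduced"
INCREASED = "increased"
UNCHANGED = "unchanged"


@dataclass(frozen=True)
class WelchResult:
    t_stat: float
    df: float
    p_value: float
    flag: str = "ok"  # ok | insufficient_n | degenerate

    @property
    def ok(self) -> bool:
        return self.flag == "ok"


def welch_t(a, b) -> WelchResult:
    """Welch's two-sample t-test, two-sided.

    t = (mean_a − mean_b) / sqrt(s²_a/n_a + s²_b/n_b), with
    Welch–Satterthwaite degrees of freedom.  Missing values are dropped.
    Degenerate inputs do not raise: fewer than two observations on either
    side yields ``insufficient_n``; zero variance on both sides with equal
    means yields ``degenerate`` (0/0).  Identical samples with nonzero
    variance give t = 0, p = 1.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    a = a[~np.isnan(a)]
    b = b[~np.isnan(b)]
    if len(a) < 2 or len(b) < 2:
        return WelchResult(np.nan, np.nan, np.nan, "insufficient_n")
    if np.var(a, ddof=1) == 0 and np.var(b, ddof=1) == 0:
        return WelchResult(np.nan, np.nan, np.nan, "degenerate")
    res = stats.ttest_ind(a, b, equal_var=False)
    return WelchResult(float(res.statistic), float(res.df), float(res.pvalue))


def expression_gate(
    goi: str,
    assignment: GroupAssignment,
    expr: GeneMatrix,
    prot: Optional[GeneMatrix] = None,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Test the GOI's expression in each mutant subgroup against control.

    Returns one row per (mutant subgroup × available modality) with columns
    ``group, modality, n_control, n_mutant, mean_control, mean_mutant,
    t_stat, df, p_value, direction, flag``.  Empty subgroups produce a row
    with ``n_mutant = 0`` and missing statistics rather than being dropped,
    so the report always shows all three subgroups.
    """
    modalities = [("mrna", expr)]
    if prot is not None:
        modalities.append(("protein", prot))

    rows = []
    for modality, matrix in modalities:
        profile = matrix.profile(goi)  # raises GeneNotFoundError if absent
        control_vals = profile.reindex(sorted(assignment.control)).dropna()
        for group in MUTANT_GROUPS:
            mutant_lines = sorted(assignment.group_of(group))
            mutant_vals = profile.reindex(mutant_lines).dropna()
            res = welch_t(control_vals.to_numpy(), mutant_vals.to_numpy())
            # welch_t orders (a, b); report mutant-vs-control means directly
            direction = UNCHANGED
            if res.ok and res.p_value < alpha:
                direction = (
                    REDUCED
                    if mutant_vals.mean() < control_vals.mean()
                    else INCREASED
                )
            rows.append(
                {
                    "group": group,
                    "modality": modality,
                    "n_control": int(len(control_vals)),
                    "n_mutant": int(len(mutant_vals)),
                    "mean_control": float(control_vals.mean())
                    if len(control_vals)
                    else np.nan,
                    "mean_mutant": float(mutant_vals.mean())
                    if len(mutant_vals)
                    else np.nan,
                    "t_stat": -res.t_stat if res.ok else np.nan,
                    "df": res.df,
                    "p_value": res.p_value,
                    "direction": direction if res.ok else "",
                    "flag": res.flag,
                }
            )
    return pd.DataFrame(rows)
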