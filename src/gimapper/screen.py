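"""Differential lethality-probability screen (the GI screen proper).

For every gene in the dependency-probability matrix (or a user-supplied
subset for a small-scale screen), the lethality probabilities of the chosen
mutant subgroup are compared to those of the control group with a two-sided
Mann–Whitney U test.  Genes whose knockout is *more* lethal in the mutant
lines (Δmedian > 0) are candidate lethal (synthetic-lethal) interactions of
the GOI; genes *less* lethal in mutant lines (Δmedian < 0) are candidate
alleviating interactions.  Because both directions are biologically
meaningful, the test is two-sided and the direction is carried by the
median difference.

Each gene gets a signed interaction score

    score = −log10(p) × sign(median_mutant − median_control)

which is monotone in evidence and ranks candidates from most to least
likely lethal (positive extreme) through alleviating (negative extreme).
P-values are Benjamini–Hochberg adjusted across exactly the genes tested in
the run, and a gene is *called* lethal/alleviating when its adjusted p
clears the FDR threshold with the matching sign.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .cohort import CONTROL, GroupAssignment, check_group_sizes
from .depmap_io import GeneMatrix
from .errors import NoDataError

logger = logging.getLogger(__name__)

__all__ = [
    "MWUResult",
    "mann_whitney_u",
    "interaction_score",
    "bh_adjust",
    "run_screen",
]

#: Largest n_a·n_b for which the exact U distribution is used (ties permitting).
EXACT_MAX_PRODUCT = 400

CALL_LETHAL = "lethal"
CALL_ALLEVIATING = "alleviating"
CALL_NONE = "none"


@dataclass(frozen=True)
class MWUResult:
    u_stat: float
    p_value: float
    method: str  # exact | asymptotic | degenerate | insufficient_n

    @property
    def ok(self) -> bool:
        return self.method in ("exact", "asymptotic")


def mann_whitney_u(a, b) -> MWUResult:
    """Two-sided Mann–Whitney U test of sample ``a`` against ``b``.

    Ties are handled with midranks.  The exact null distribution is used
    for small samples (n_a·n_b ≤ 400) without ties; otherwise the normal
    approximation with tie and continuity corrections.  The method actually
    used is recorded in the result.  The reported U is the statistic of the
    first sample.  Degenerate inputs (all values tied, or an empty sample)
    yield a flagged result with missing p instead of raising.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    a = a[~np.isnan(a)]
    b = b[~np.isnan(b)]
    if len(a) == 0 or len(b) == 0:
        return MWUResult(np.nan, np.nan, "insufficient_n")
    combined = np.concatenate([a, b])
    if np.all(combined == combined[0]):
        return MWUResult(np.nan, np.nan, "degenerate")
    has_ties = len(np.unique(combined)) < len(combined)
    if not has_ties and len(a) * len(b) <= EXACT_MAX_PRODUCT:
        method = "exact"
    else:
        method = "asymptotic"
    res = stats.mannwhitneyu(
        a,
        b,
        alternative="two-sided",
        method="exact" if method == "exact" else "asymptotic",
        use_continuity=True,
    )
    return MWUResult(float(res.statistic), float(min(res.pvalue, 1.0)), method)


def interaction_score(p_value: float, delta_median: float) -> float:
    """Signed evidence score: −log10(p) carrying the sign of Δmedian.

    Positive ⇒ lethal direction, negative ⇒ alleviating, zero when the
    medians are equal.  p = 0 (possible only through underflow of the
    normal approximation) is clamped to the smallest positive float and the
    clamping is logged.
    """
    if np.isnan(p_value) or np.isnan(delta_median):
        return np.nan
    if delta_median == 0:
        return 0.0
    if p_value <= 0.0:
        logger.warning("p-value underflow clamped to %g", np.nextafter(0.0, 1.0))
        p_value = np.nextafter(0.0, 1.0)
    return float(-np.log10(p_value) * np.sign(delta_median))


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini–Hochberg step-up adjustment with missing-value passthrough.

    Missing entries are excluded from the number of tests m and returned as
    missing, in input order.  Output is elementwise ≥ input and ≤ 1, and
    monotone in the ranked p-values.
    """
    from statsmodels.stats.multitest import multipletests

    p = np.asarray(p_values, dtype=float)
    out = np.full(p.shape, np.nan)
    mask = ~np.isnan(p)
    if mask.sum() > 0:
        out[mask] = multipletests(p[mask], method="fdr_bh")[1]
    return out


def run_screen(
    goi: str,
    assignment: GroupAssignment,
    chosen_group: str,
    prob: GeneMatrix,
    gene_subset: Optional[Sequence[str]] = None,
    fdr_threshold: float = 0.05,
) -> pd.DataFrame:
    """Screen all (or a subset of) genes for differential lethality.

    Parameters
    ----------
    chosen_group
        The mutant subgroup the user selected after the expression gate
        (``HomDel``, ``T-HetDel`` or ``HetDel``).  Must be present and
        non-empty in ``assignment``.
    gene_subset
        Optional gene list for a small-scale screen; genes absent from the
        matrix are reported in the log and skipped.  BH adjustment runs
        across exactly the genes tested in this run.

    Returns
    -------
    DataFrame with one row per screened gene, sorted by interaction score
    descending (lethal candidates first, alleviating last); columns:
    ``gene, n_control, n_mutant, median_control, median_mutant,
    delta_median, u_stat, p_value, p_adj, interaction_score, call, method,
    is_goi``.  The GOI's own row is retained and flagged.
    """
    try:
        mutant_lines = sorted(assignment.group_of(chosen_group))
    except KeyError:
        raise ValueError(
            f"unknown group {chosen_group!r}; expected one of "
            "HomDel, T-HetDel, HetDel"
        ) from None
    if chosen_group == CONTROL:
        raise ValueError("chosen group must be a mutant subgroup, not the control")
    check_group_sizes(assignment, [CONTROL, chosen_group])

    control_lines = sorted(assignment.control)
    cols = set(prob.values.columns)
    mutant_lines = [l for l in mutant_lines if l in cols]
    control_lines = [l for l in control_lines if l in cols]
    if not mutant_lines or not control_lines:
        raise NoDataError(
            "no overlap between cohort line IDs and lethality-probability columns"
        )

    if gene_subset is not None:
        wanted = list(dict.fromkeys(gene_subset))
        known = [g for g in wanted if g in prob.values.index]
        unknown = sorted(set(wanted) - set(known))
        if unknown:
            logger.warning(
                "%d subset gene(s) absent from matrix, skipped: %s%s",
                len(unknown),
                ", ".join(unknown[:10]),
                "…" if len(unknown) > 10 else "",
            )
        genes = known
    else:
        genes = list(prob.values.index)
    if not genes:
        raise NoDataError("no genes to screen")

    mut = prob.values.loc[genes, mutant_lines].to_numpy()
    ctl = prob.values.loc[genes, control_lines].to_numpy()

    rows = []
    for i, gene in enumerate(genes):
        a = mut[i]
        b = ctl[i]
        a = a[~np.isnan(a)]
        b = b[~np.isnan(b)]
        if len(a) < 2 or len(b) < 2:
            rows.append(
                (gene, len(b), len(a), np.nan, np.nan, np.nan, np.nan, np.nan,
                 "insufficient_n")
            )
            continue
        med_a = float(np.median(a))
        med_b = float(np.median(b))
        res = mann_whitney_u(a, b)
        rows.append(
            (
                gene,
                len(b),
                len(a),
                med_b,
                med_a,
                med_a - med_b,
                res.u_stat,
                res.p_value,
                res.method,
            )
        )

    out = pd.DataFrame(
        rows,
        columns=[
            "gene", "n_control", "n_mutant", "median_control", "median_mutant",
            "delta_median", "u_stat", "p_value", "method",
        ],
    )
    out["p_adj"] = bh_adjust(out["p_value"])
    out["interaction_score"] = [
        interaction_score(p, d) for p, d in zip(out["p_value"], out["delta_median"])
    ]
    significant = out["p_adj"] < fdr_threshold
    out["call"] = CALL_NONE
    out.loc[significant & (out["delta_median"] > 0), "call"] = CALL_LETHAL
    out.loc[significant & (out["delta_median"] < 0), "call"] = CALL_ALLEVIATING
    out["is_goi"] = out["gene"] == goi

    # gene symbol as tie-break keeps the order canonical whatever the input order
    out = out.sort_values(
        ["interaction_score", "gene"], ascending=[False, True], na_position="last"
    ).reset_index(drop=True)
    return out[
        [
            "gene", "n_control", "n_mutant", "median_control", "median_mutant",
            "delta_median", "u_stat", "p_value", "p_adj", "interaction_score",
            "call", "method", "is_goi",
        ]
    ]
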