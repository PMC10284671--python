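"""Control / mutant cohort assignment for a gene of interest (GOI).

Every cell line in a panel is placed in exactly one of five buckets:

* ``control`` — wild type for the GOI (no loss-of-function variant, no
  damaging missense) with neutral copy number,
* ``HomDel`` — homozygous loss: a homozygous LoF variant, or any LoF variant
  on a deeply deleted locus, or deep deletion alone,
* ``T-HetDel`` — trans-heterozygous loss, approximated as two or more
  *distinct* heterozygous LoF variants (variant phase is not available in
  gene-level DepMap calls),
* ``HetDel`` — exactly one heterozygous LoF variant without deep deletion,
* ``excluded`` — everything else, with a single reason code per line
  (e.g. only damaging missense, LoF of unknown zygosity off the neutral/deep
  copy-number bands, missing copy number, removed by the selector).

Loss of function means a truncating consequence (nonsense, frameshift,
splice site, start lost) or a non-missense variant flagged damaging.
Damaging missense bars a line from the control group but is not counted as
LoF — the functional impact is too uncertain to call the line mutant, so it
is excluded (conservative in both directions).

Copy number is on the relative-copies scale with diploid = 2: neutral is
[1.5, 2.5] and deep deletion < 0.25 by default; all thresholds are
configurable via :class:`CohortParams`.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Callable, Iterable, Mapping

import pandas as pd

from .depmap_io import Consequence, GeneMatrix, MutationRecord, Zygosity, records_from_frame
from .errors import EmptyCohortError, GeneNotFoundError
from typing import Optional, Sequence

logger = logging.getLogger(__name__)

__all__ = [
    "CohortParams",
    "CohortSelector",
    "GroupAssignment",
    "MUTANT_GROUPS",
    "classify_line",
    "assign_groups",
]

#: Group labels, in reporting order.
CONTROL = "control"
HOMDEL = "HomDel"
T_HETDEL = "T-HetDel"
HETDEL = "HetDel"
EXCLUDED = "excluded"
MUTANT_GROUPS = (HOMDEL, T_HETDEL, HETDEL)
ALL_GROUPS = (CONTROL,) + MUTANT_GROUPS + (EXCLUDED,)

LOF_CONSEQUENCES = frozenset(
    {
        Consequence.NONSENSE,
        Consequence.FRAMESHIFT,
        Consequence.SPLICE_SITE,
        Consequence.START_LOST,
    }
)


@dataclass(frozen=True)
class CohortParams:
    """Thresholds for classification, on the relative-copies scale (diploid=2)."""

    neutral_lo: float = 1.5
    neutral_hi: float = 2.5
    deep_del_max: float = 0.25
    warn_group_size: int = 5
    min_group_size: int = 2


@dataclass(frozen=True)
class CohortSelector:
    """Optional pre-filters: cancer type, manual curation, mutation predicate.

    ``mutation_filter`` receives each of a line's variant records (any gene)
    and the line is kept if at least one record satisfies it.
    """

    cancer_types: Optional[frozenset[str]] = None
    include_lines: Optional[frozenset[str]] = None
    exclude_lines: Optional[frozenset[str]] = None
    mutation_filter: Optional[Callable[[MutationRecord], bool]] = None

    def __post_init__(self) -> None:
        if self.include_lines and self.exclude_lines:
            both = set(self.include_lines) & set(self.exclude_lines)
            if both:
                raise ValueError(
                    f"lines both included and excluded: {sorted(both)[:5]}"
                )


@dataclass
class GroupAssignment:
    """Partition of a panel into control / mutant subgroups for one GOI.

    The five sets are pairwise disjoint and their union is the input panel;
    ``reasons`` carries exactly one reason code per excluded line.
    """

    goi: str
    control: set[str] = field(default_factory=set)
    hom_del: set[str] = field(default_factory=set)
    t_het_del: set[str] = field(default_factory=set)
    het_del: set[str] = field(default_factory=set)
    excluded: set[str] = field(default_factory=set)
    reasons: dict[str, str] = field(default_factory=dict)

    def group_of(self, label: str) -> set[str]:
        return {
            CONTROL: self.control,
            HOMDEL: self.hom_del,
            T_HETDEL: self.t_het_del,
            HETDEL: self.het_del,
            EXCLUDED: self.excluded,
        }[label]

    def counts(self) -> dict[str, int]:
        return {g: len(self.group_of(g)) for g in ALL_GROUPS}

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for label in ALL_GROUPS:
            for line in sorted(self.group_of(label)):
                rows.append((line, label, self.reasons.get(line, "")))
        return pd.DataFrame(rows, columns=["line_id", "group", "reason"])

    @classmethod
    def from_frame(cls, goi: str, df: pd.DataFrame) -> "GroupAssignment":
        out = cls(goi=goi)
        for r in df.itertuples(index=False):
            out.group_of(r.group).add(r.line_id)
            reason = getattr(r, "reason", "")
            if isinstance(reason, str) and reason:
                out.reasons[r.line_id] = reason
        return out


def classify_line(
    goi: str,
    variants: Iterable[MutationRecord],
    copy_number: float | None,
    params: CohortParams = CohortParams(),
) -> tuple[str, str]:
    """Classify one cell line for the GOI; returns ``(label, reason)``.

    ``variants`` may contain calls for any gene; only GOI records are used.
    ``copy_number`` is the GOI's relative copy number in this line (``None``
    or NaN = unmeasured, in which case the copy-number criteria are
    inapplicable and the line is excluded).
    """
    cn_missing = copy_number is None or pd.isna(copy_number)
    if cn_missing:
        return EXCLUDED, "no_cn"

    goi_variants = {v.key: v for v in variants if v.gene == goi}.values()
    lof = [
        v
        for v in goi_variants
        if v.consequence in LOF_CONSEQUENCES
        or (
            v.is_damaging
            and v.consequence not in (Consequence.MISSENSE, Consequence.SILENT)
        )
    ]
    damaging_missense = any(
        v.consequence is Consequence.MISSENSE and v.is_damaging for v in goi_variants
    )

    deep_del = copy_number < params.deep_del_max
    cn_neutral = params.neutral_lo <= copy_number <= params.neutral_hi

    hom_lof = [v for v in lof if v.zygosity is Zygosity.HOMOZYGOUS]
    het_lof = [v for v in lof if v.zygosity is Zygosity.HETEROZYGOUS]

    if hom_lof:
        return HOMDEL, "homozygous_lof"
    if deep_del:
        return HOMDEL, "deep_deletion" if not lof else "lof_with_deep_deletion"
    if len(het_lof) >= 2:
        return T_HETDEL, "multi_het_lof"
    if len(het_lof) == 1 and len(lof) == 1:
        return HETDEL, "single_het_lof"
    if lof:
        # only unknown-zygosity LoF (alone or mixed), off the deep-deletion band
        return EXCLUDED, "lof_unknown_zygosity"
    if damaging_missense:
        return EXCLUDED, "damaging_missense_only"
    if cn_neutral:
        return CONTROL, "wt_neutral_cn"
    return EXCLUDED, "cn_not_neutral"


def _mutations_by_line(
    mutations: pd.DataFrame | Iterable[MutationRecord],
) -> Mapping[str, list[MutationRecord]]:
    records = (
        records_from_frame(mutations)
        if isinstance(mutations, pd.DataFrame)
        else list(mutations)
    )
    by_line: dict[str, list[MutationRecord]] = {}
    for rec in records:
        by_line.setdefault(rec.line_id, []).append(rec)
    return by_line


def assign_groups(
    goi: str,
    panel: pd.DataFrame,
    mutations: pd.DataFrame | Iterable[MutationRecord],
    cn: GeneMatrix,
    selector: CohortSelector = CohortSelector(),
    params: CohortParams = CohortParams(),
) -> GroupAssignment:
    """Partition a panel of cell lines into cohort groups for the GOI.

    ``panel`` is the sample-annotation DataFrame (``line_id`` and
    ``cancer_type`` columns used).  The selector is applied first — lines it
    removes are kept in the partition as ``excluded`` with a ``selector:*``
    reason — then each surviving line is classified.  Deterministic for
    fixed inputs.
    """
    if len(panel) == 0:
        raise EmptyCohortError("empty cell-line panel")
    if goi not in cn.values.index:
        raise GeneNotFoundError(f"GOI {goi!r} absent from copy-number matrix")

    by_line = _mutations_by_line(mutations)
    cn_row = cn.values.loc[goi]
    assignment = GroupAssignment(goi=goi)

    cancer_by_line = dict(zip(panel["line_id"], panel.get("cancer_type", "")))
    for line in panel["line_id"]:
        variants = by_line.get(line, [])
        reason = None
        if selector.include_lines is not None and line not in selector.include_lines:
            reason = "selector:not_included"
        elif selector.exclude_lines is not None and line in selector.exclude_lines:
            reason = "selector:excluded"
        elif (
            selector.cancer_types is not None
            and cancer_by_line.get(line, "") not in selector.cancer_types
        ):
            reason = "selector:cancer_type"
        elif selector.mutation_filter is not None and not any(
            selector.mutation_filter(v) for v in variants
        ):
            reason = "selector:mutation_filter"
        if reason is not None:
            assignment.excluded.add(line)
            assignment.reasons[line] = reason
            continue

        copy_number = cn_row.get(line, float("nan"))
        label, why = classify_line(goi, variants, copy_number, params)
        assignment.group_of(label).add(line)
        if label == EXCLUDED:
            assignment.reasons[line] = why

    analysed = (
        assignment.control
        | assignment.hom_del
        | assignment.t_het_del
        | assignment.het_del
    )
    if not analysed:
        raise EmptyCohortError(
            f"no cell lines left for GOI {goi!r} after selection/classification"
        )

    counts = assignment.counts()
    logger.info("cohort for %s: %s", goi, counts)
    for label in (CONTROL,) + MUTANT_GROUPS:
        n = counts[label]
        if 0 < n < params.warn_group_size:
            logger.warning("group %s has only %d line(s)", label, n)
    return assignment


def check_group_sizes(
    assignment: GroupAssignment, labels: Sequence[str], params: CohortParams = CohortParams()
) -> None:
    """Enforce the minimum usable group size for a two-group comparison."""
    for label in labels:
        n = len(assignment.group_of(label))
        if n < params.min_group_size:
            raise EmptyCohortError(
                f"group {label!r} has {n} line(s); "
                f"at least {params.min_group_size} required"
            )
        if n < params.warn_group_size:
            logger.warning(
                "group %s has only %d line(s); results will be underpowered", label, n
            )
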