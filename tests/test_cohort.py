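import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

import gimapper as gm
from conftest import make_matrix, rec
from gimapper.cohort import CohortSelector, assign_groups, classify_line
from gimapper.depmap_io import Consequence, MatrixRole, Zygosity
from gimapper.errors import EmptyCohortError, GeneNotFoundError

GOI = "ARID1A"


@pytest.mark.parametrize(
    "variants,cn,expected",
    [
        ([], 2.0, "control"),
        ([rec("L", GOI, Consequence.FRAMESHIFT, Zygosity.HETEROZYGOUS, "p.A1fs")],
         2.0, "HetDel"),
        ([rec("L", GOI, Consequence.NONSENSE, Zygosity.HETEROZYGOUS, "p.R1*"),
          rec("L", GOI, Consequence.NONSENSE, Zygosity.HETEROZYGOUS, "p.R2*")],
         2.0, "T-HetDel"),
        ([rec("L", GOI, Consequence.NONSENSE, Zygosity.HOMOZYGOUS, "p.R1*")],
         2.0, "HomDel"),
        ([], 0.1, "HomDel"),  # deep deletion alone
        ([rec("L", GOI, Consequence.FRAMESHIFT, Zygosity.HETEROZYGOUS, "p.A1fs")],
         0.1, "HomDel"),  # LoF on a deeply deleted locus
        ([rec("L", GOI, Consequence.MISSENSE, Zygosity.HETEROZYGOUS, "p.S1F",
              damaging=True)],
         2.0, "excluded"),  # damaging missense only: neither control nor mutant
        ([rec("L", GOI, Consequence.SPLICE_SITE, Zygosity.UNKNOWN, "p.?")],
         1.0, "excluded"),  # unknown zygosity off the neutral and deep bands
        ([], 3.2, "excluded"),  # amplified: not neutral, not deleted
        ([], np.nan, "excluded"),  # no copy-number measurement
        ([rec("L", "KRAS", Consequence.NONSENSE, Zygosity.HOMOZYGOUS, "p.R1*")],
         2.0, "control"),  # lesions in other genes are ignored
        ([rec("L", GOI, Consequence.SILENT, Zygosity.HETEROZYGOUS, "p.S1=")],
         2.0, "control"),  # silent GOI variant is not LoF
    ],
)
def test_single_line_classification_rules(variants, cn, expected):
    label, _reason = classify_line(GOI, variants, cn)
    assert label == expected


def test_duplicate_variant_records_counted_once():
    v = rec("L", GOI, Consequence.NONSENSE, Zygosity.HETEROZYGOUS, "p.R1*")
    label, _ = classify_line(GOI, [v, v], 2.0)
    assert label == "HetDel"  # one distinct lesion, not trans-het


def test_missing_cn_reason_code():
    label, reason = classify_line(GOI, [], None)
    assert (label, reason) == ("excluded", "no_cn")


def test_hand_panel_partition(hand_panel):
    goi, panel, variants, cn, expected = hand_panel
    assignment = assign_groups(goi, panel, variants, cn)
    got = {
        line: label
        for label in ("control", "HomDel", "T-HetDel", "HetDel", "excluded")
        for line in assignment.group_of(label)
    }
    assert got == expected
    # partition: disjoint and exhaustive
    all_sets = [assignment.group_of(g) for g in
                ("control", "HomDel", "T-HetDel", "HetDel", "excluded")]
    assert sum(len(s) for s in all_sets) == len(panel)
    assert set().union(*all_sets) == set(panel["line_id"])
    # every excluded line carries exactly one reason
    assert set(assignment.reasons) >= assignment.excluded
    assert all(assignment.reasons[l] for l in assignment.excluded)


def test_cancer_type_selector_restricts_groups(hand_panel):
    goi, panel, variants, cn, _ = hand_panel
    assignment = assign_groups(
        goi, panel, variants, cn,
        selector=CohortSelector(cancer_types=frozenset({"pancreas"})),
    )
    analysed = (assignment.control | assignment.hom_del
                | assignment.t_het_del | assignment.het_del)
    assert analysed <= {"L1", "L2", "L3", "L4"}
    # filtered-out lines remain in the partition, as excluded with a reason
    assert assignment.reasons["L5"] == "selector:cancer_type"


def test_include_exclude_selectors(hand_panel):
    goi, panel, variants, cn, _ = hand_panel
    assignment = assign_groups(
        goi, panel, variants, cn,
        selector=CohortSelector(include_lines=frozenset({"L1", "L4"})),
    )
    assert assignment.control == {"L1"}
    assert assignment.hom_del == {"L4"}
    with pytest.raises(ValueError, match="included and excluded"):
        CohortSelector(include_lines=frozenset({"L1"}),
                       exclude_lines=frozenset({"L1"}))


def test_selector_leaving_nothing_is_empty_cohort(hand_panel):
    goi, panel, variants, cn, _ = hand_panel
    with pytest.raises(EmptyCohortError):
        assign_groups(goi, panel, variants, cn,
                      selector=CohortSelector(cancer_types=frozenset({"brain"})))


def test_goi_missing_from_cn_matrix(hand_panel):
    _, panel, variants, cn, _ = hand_panel
    with pytest.raises(GeneNotFoundError):
        assign_groups("NOSUCH", panel, variants, cn)


# ---------------------------------------------------------------------------
# property tests

_consequences = st.sampled_from(list(Consequence))
_zygosities = st.sampled_from(list(Zygosity))


@st.composite
def _variant_sets(draw):
    n = draw(st.integers(0, 4))
    return [
        rec("L", GOI, draw(_consequences), draw(_zygosities), f"p.X{i}",
            damaging=draw(st.booleans()))
        for i in range(n)
    ]


@given(
    variants=_variant_sets(),
    cn=st.one_of(st.none(), st.floats(0.0, 4.0, allow_nan=False)),
)
def test_classification_is_total_and_order_independent(variants, cn):
    label, reason = classify_line(GOI, variants, cn)
    assert label in ("control", "HomDel", "T-HetDel", "HetDel", "excluded")
    assert reason
    label_rev, _ = classify_line(GOI, list(reversed(variants)), cn)
    assert label == label_rev


@given(
    variants=_variant_sets(),
    cn=st.floats(0.0, 4.0, allow_nan=False),
    i=st.integers(0, 1000),
)
def test_adding_het_lof_never_yields_control(variants, cn, i):
    extra = rec("L", GOI, Consequence.NONSENSE, Zygosity.HETEROZYGOUS, f"p.N{i}*")
    label, _ = classify_line(GOI, variants + [extra], cn)
    assert label != "control"


@given(seed=st.integers(0, 10_000))
def test_fuzzed_panels_partition_exhaustively(seed):
    rng = np.random.default_rng(seed)
    n = int(rng.integers(2, 12))
    lines = [f"L{i}" for i in range(n)]
    panel = pd.DataFrame({"line_id": lines, "line_name": lines,
                          "cancer_type": "x", "lineage": "x"})
    variants = []
    for line in lines:
        for i in range(int(rng.integers(0, 3))):
            variants.append(
                rec(line, GOI, list(Consequence)[int(rng.integers(0, 7))],
                    list(Zygosity)[int(rng.integers(0, 3))], f"p.V{i}")
            )
    cn = make_matrix(rng.uniform(0, 4, size=(1, n)), [GOI], lines,
                     role=MatrixRole.COPY_NUMBER)
    try:
        assignment = assign_groups(GOI, panel, variants, cn)
    except EmptyCohortError:
        return  # everything excluded: legal degenerate outcome
    sets = [assignment.group_of(g) for g in
            ("control", "HomDel", "T-HetDel", "HetDel", "excluded")]
    assert sum(len(s) for s in sets) == n  # disjointness + exhaustiveness
    assert set().union(*sets) == set(lines)
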