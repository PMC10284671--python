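import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import gimapper as gm
from conftest import make_matrix
from gimapper.errors import NoDataError
from gimapper.screen import bh_adjust, interaction_score, mann_whitney_u, run_screen
from oracles import bh_oracle, exact_mwu_p, permutation_mwu_p, u_statistic


def test_complete_separation_exact_p():
    # U = 9 (every mutant value beats every control value); of the C(6,3)=20
    # assignments only the two extremes are as extreme → p = 2/20 = 0.1
    res = mann_whitney_u([0.9, 0.8, 0.85], [0.1, 0.2, 0.15])
    assert res.u_stat == 9.0
    assert res.method == "exact"
    assert res.p_value == pytest.approx(0.1, abs=1e-12)


def test_identical_multisets_give_p1():
    res = mann_whitney_u([0.3, 0.5], [0.3, 0.5])
    assert res.p_value == 1.0


def test_all_ties_degenerate():
    res = mann_whitney_u([0.5, 0.5], [0.5, 0.5])
    assert res.method == "degenerate"
    assert np.isnan(res.p_value)


def test_empty_sample_flagged():
    assert mann_whitney_u([], [1.0, 2.0]).method == "insufficient_n"


@given(
    n_a=st.integers(1, 7),
    n_b=st.integers(1, 7),
    seed=st.integers(0, 200),
)
def test_exact_p_matches_enumeration_oracle(n_a, n_b, seed):
    """For every small tie-free configuration the exact p equals the
    exhaustive enumeration over all C(n_a+n_b, n_a) rank arrangements."""
    if n_a + n_b > 8:
        n_b = 8 - n_a
    rng = np.random.default_rng(seed)
    pooled = rng.permutation(np.arange(1.0, n_a + n_b + 1))  # distinct ranks
    a, b = pooled[:n_a], pooled[n_a:]
    res = mann_whitney_u(a, b)
    assert res.method == "exact"
    assert res.u_stat == u_statistic(a, b)
    assert res.p_value == pytest.approx(exact_mwu_p(a, b), abs=1e-12)


def test_asymptotic_close_to_permutation_oracle():
    rng = np.random.default_rng(3)
    a = rng.normal(0.3, 0.1, 30)
    b = rng.normal(0.25, 0.1, 30)
    res = mann_whitney_u(a, b)
    assert res.method == "asymptotic"
    p_perm = permutation_mwu_p(a, b, n_perm=20_000, seed=5)
    assert res.p_value == pytest.approx(p_perm, abs=0.01)


@given(seed=st.integers(0, 100))
def test_u_antisymmetry_and_p_symmetry(seed):
    rng = np.random.default_rng(seed)
    a = rng.uniform(size=int(rng.integers(2, 10)))
    b = rng.uniform(size=int(rng.integers(2, 10)))
    fwd, rev = mann_whitney_u(a, b), mann_whitney_u(b, a)
    assert fwd.u_stat + rev.u_stat == pytest.approx(len(a) * len(b))
    assert fwd.p_value == pytest.approx(rev.p_value, abs=1e-12)


# ---------------------------------------------------------------------------
# interaction score


@pytest.mark.parametrize(
    "p,delta,expected",
    [(0.001, 0.4, 3.0), (1.0, 0.4, 0.0), (0.01, -0.2, -2.0), (0.5, 0.0, 0.0)],
)
def test_interaction_score_definition(p, delta, expected):
    assert interaction_score(p, delta) == pytest.approx(expected, abs=1e-12)


def test_interaction_score_p_zero_clamped_finite():
    score = interaction_score(0.0, 0.5)
    assert np.isfinite(score) and score > 300  # −log10 of the smallest float


# ---------------------------------------------------------------------------
# BH adjustment


def test_bh_hand_computed_step_up():
    # all four raw ps share the adjusted value 0.04 = max_k(p_k·m/k) cummin
    np.testing.assert_allclose(
        bh_adjust([0.01, 0.02, 0.03, 0.04]), [0.04, 0.04, 0.04, 0.04]
    )
    np.testing.assert_allclose(bh_adjust([0.5]), [0.5])


@given(seed=st.integers(0, 200), n=st.integers(1, 50))
def test_bh_matches_oracle_and_bounds(seed, n):
    rng = np.random.default_rng(seed)
    p = rng.uniform(size=n)
    adj = bh_adjust(p)
    np.testing.assert_allclose(adj, bh_oracle(p), atol=1e-12)
    assert np.all(adj >= p) and np.all(adj <= 1.0)


def test_bh_missing_passthrough():
    adj = bh_adjust([0.01, np.nan, 0.04])
    assert np.isnan(adj[1])
    # m = 2: the NaN is excluded from the correction
    np.testing.assert_allclose(adj[[0, 2]], bh_oracle([0.01, 0.04]))


# ---------------------------------------------------------------------------
# run_screen


def test_planted_effects_recovered(benchmark_panel, benchmark_assignment,
                                   benchmark_screen):
    truth = benchmark_panel.truth
    ev = gm.truth_eval(benchmark_screen, truth)
    assert ev["sensitivity"] >= 0.95
    assert ev["sign_accuracy"] == 1.0
    # planted lethal genes all land at the top of the score ranking
    top = benchmark_screen.head(10)["gene"]
    assert set(top) == set(benchmark_panel.config.planted_lethal)


def test_goi_row_retained_and_flagged(benchmark_screen, benchmark_panel):
    goi_rows = benchmark_screen[benchmark_screen["is_goi"]]
    assert list(goi_rows["gene"]) == [benchmark_panel.config.goi]


def test_single_gene_subset_padj_equals_p(benchmark_panel, benchmark_assignment):
    gene = benchmark_panel.config.planted_lethal[0]
    rows = run_screen(
        benchmark_panel.config.goi, benchmark_assignment, "HomDel",
        benchmark_panel.lethality_prob, gene_subset=[gene],
    )
    assert len(rows) == 1
    assert rows.loc[0, "p_adj"] == rows.loc[0, "p_value"]
    assert rows.loc[0, "call"] == "lethal"


def test_unknown_subset_genes_skipped(benchmark_panel, benchmark_assignment):
    gene = benchmark_panel.config.planted_lethal[0]
    rows = run_screen(
        benchmark_panel.config.goi, benchmark_assignment, "HomDel",
        benchmark_panel.lethality_prob, gene_subset=[gene, "NOSUCH"],
    )
    assert list(rows["gene"]) == [gene]


def test_screen_invariant_to_row_and_column_order(benchmark_panel,
                                                  benchmark_assignment,
                                                  benchmark_screen):
    prob = benchmark_panel.lethality_prob
    rng = np.random.default_rng(1)
    shuffled = gm.GeneMatrix(
        values=prob.values.iloc[
            rng.permutation(prob.shape[0]), rng.permutation(prob.shape[1])
        ],
        role=prob.role,
    )
    rows = run_screen(benchmark_panel.config.goi, benchmark_assignment, "HomDel",
                      shuffled)
    pd.testing.assert_frame_equal(rows, benchmark_screen)


def test_swapping_groups_negates_score(benchmark_panel):
    """Anti-symmetry: exchanging mutant and control labels flips Δmedian and
    the interaction score while leaving p unchanged."""
    p = benchmark_panel
    fwd = gm.GroupAssignment(goi=p.config.goi)
    fwd.control.update(l for l, g in p.truth.line_group.items() if g == "control")
    fwd.hom_del.update(l for l, g in p.truth.line_group.items() if g == "HomDel")
    rev = gm.GroupAssignment(goi=p.config.goi)
    rev.control, rev.hom_del = fwd.hom_del, fwd.control
    a = run_screen(p.config.goi, fwd, "HomDel", p.lethality_prob).set_index("gene")
    b = run_screen(p.config.goi, rev, "HomDel", p.lethality_prob).set_index("gene")
    b = b.loc[a.index]
    np.testing.assert_allclose(a["delta_median"], -b["delta_median"], atol=1e-12)
    np.testing.assert_allclose(a["interaction_score"], -b["interaction_score"],
                               atol=1e-12)
    np.testing.assert_allclose(a["p_value"], b["p_value"], atol=1e-12)


def test_null_panel_type_i_rate():
    cfg = gm.SimulationConfig(seed=41, planted_lethal=(), planted_alleviating=())
    panel = gm.simulate_panel(cfg)
    asn = gm.assign_groups(cfg.goi, panel.sample_info, panel.mutations,
                           panel.copy_number)
    rows = run_screen(cfg.goi, asn, "HomDel", panel.lethality_prob)
    frac = float((rows["p_value"] < 0.05).mean())
    assert 0.03 <= frac <= 0.07
    assert float((rows["p_adj"] < 0.05).mean()) <= 0.05


def test_bad_group_and_no_overlap_errors(benchmark_panel, benchmark_assignment):
    p = benchmark_panel
    with pytest.raises(ValueError, match="control"):
        run_screen(p.config.goi, benchmark_assignment, "control", p.lethality_prob)
    renamed = gm.GeneMatrix(
        values=p.lethality_prob.values.rename(columns=lambda c: "X" + c),
        role=p.lethality_prob.role,
    )
    with pytest.raises(NoDataError):
        run_screen(p.config.goi, benchmark_assignment, "HomDel", renamed)


def test_genes_with_too_few_observations_reported_not_dropped(benchmark_assignment,
                                                              benchmark_panel):
    p = benchmark_panel
    prob = p.lethality_prob.values.copy()
    mutants = sorted(benchmark_assignment.hom_del)
    prob.loc["G0100", mutants[1:]] = np.nan  # one mutant observation left
    rows = run_screen(
        p.config.goi, benchmark_assignment, "HomDel",
        gm.GeneMatrix(values=prob, role="lethality_prob"),
    )
    row = rows[rows["gene"] == "G0100"].iloc[0]
    assert np.isnan(row["p_value"]) and row["method"] == "insufficient_n"
    assert row["call"] == "none"
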