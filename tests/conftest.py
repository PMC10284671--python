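import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

import gimapper as gm
from gimapper.depmap_io import Consequence, GeneMatrix, MatrixRole, MutationRecord, Zygosity

settings.register_profile("ci", deadline=None, derandomize=True)
settings.load_profile("ci")


def rec(line, gene="TP53", cons=Consequence.NONSENSE, zyg=Zygosity.HETEROZYGOUS,
        pc="p.R1*", damaging=False):
    return MutationRecord(
        line_id=line, gene=gene, consequence=cons, zygosity=zyg,
        protein_change=pc, is_damaging=damaging,
    )


@pytest.fixture(scope="session")
def benchmark_panel():
    """The planted-GI benchmark condition: 20 vs 20 lines, 2000 genes,
    10 lethal + 10 alleviating genes at Δprob = 0.6, seed 0."""
    return gm.simulate_panel(gm.SimulationConfig(seed=0))


@pytest.fixture(scope="session")
def benchmark_assignment(benchmark_panel):
    p = benchmark_panel
    return gm.assign_groups(p.config.goi, p.sample_info, p.mutations, p.copy_number)


@pytest.fixture(scope="session")
def benchmark_screen(benchmark_panel, benchmark_assignment):
    p = benchmark_panel
    return gm.run_screen(p.config.goi, benchmark_assignment, "HomDel",
                         p.lethality_prob)


@pytest.fixture(scope="session")
def coess_panel():
    """The co-essentiality benchmark: 200 lines, 2000 genes, one 5-gene
    module containing the GOI (loading 0.9) and a 5-gene anti-module
    (loading −0.9) on the same latent factor, noise sd 0.3."""
    return gm.simulate_panel(
        gm.SimulationConfig(seed=0, n_control=180, n_mutant=20)
    )


def make_matrix(values, genes, lines, role=MatrixRole.LETHALITY_PROB):
    return GeneMatrix(
        values=pd.DataFrame(np.asarray(values, float), index=genes, columns=lines),
        role=role,
    )


@pytest.fixture
def hand_panel():
    """Eight hand-classified lines covering every cohort rule.

    Expected partition (worked out from the classification rules by hand):
      L1 control, L2 HetDel, L3 T-HetDel, L4 HomDel (homozygous LoF),
      L5 HomDel (deep deletion), L6 excluded (damaging missense only),
      L7 excluded (no copy number), L8 excluded (non-neutral CN).
    """
    goi = "ARID1A"
    lines = [f"L{i}" for i in range(1, 9)]
    panel = pd.DataFrame(
        {"line_id": lines, "line_name": lines,
         "cancer_type": ["pancreas"] * 4 + ["lung"] * 4,
         "lineage": [""] * 8}
    )
    variants = [
        rec("L2", goi, Consequence.FRAMESHIFT, Zygosity.HETEROZYGOUS, "p.A10fs"),
        rec("L3", goi, Consequence.NONSENSE, Zygosity.HETEROZYGOUS, "p.R20*"),
        rec("L3", goi, Consequence.NONSENSE, Zygosity.HETEROZYGOUS, "p.Q30*"),
        rec("L4", goi, Consequence.NONSENSE, Zygosity.HOMOZYGOUS, "p.R40*"),
        rec("L6", goi, Consequence.MISSENSE, Zygosity.HETEROZYGOUS, "p.S50F",
            damaging=True),
        rec("L7", goi, Consequence.SPLICE_SITE, Zygosity.HETEROZYGOUS, "p.?"),
        # non-GOI passenger on a control line must not matter
        rec("L1", "KRAS", Consequence.MISSENSE, Zygosity.HETEROZYGOUS, "p.G12D",
            damaging=True),
    ]
    cn = make_matrix(
        [[2.0, 2.0, 2.1, 1.9, 0.1, 2.0, np.nan, 3.2]],
        [goi], lines, role=MatrixRole.COPY_NUMBER,
    )
    expected = {
        "L1": "control", "L2": "HetDel", "L3": "T-HetDel", "L4": "HomDel",
        "L5": "HomDel", "L6": "excluded", "L7": "excluded", "L8": "excluded",
    }
    return goi, panel, variants, cn, expected
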