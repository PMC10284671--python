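"""Synthetic DepMap-schema panels with planted ground truth.

Every pipeline stage can be exercised offline against a simulated cancer
cell-line panel whose genetic-interaction and co-essentiality structure is
known by construction:

* **Cohort structure** — mutant lines carry GOI lesions written to satisfy
  the cohort classification rules exactly (homozygous nonsense for HomDel,
  two distinct heterozygous frameshifts for T-HetDel, one for HetDel), with
  copy-number values on the matching band, so group assignment recovers the
  planted groups without error.
* **GI structure** — baseline lethality probabilities are drawn per cell
  from a Beta distribution (default Beta(1, 6): mostly non-essential,
  right-skewed, naturally bounded); planted lethal genes gain +Δprob and
  planted alleviating genes −Δprob in mutant lines, clipped to [0, 1] with
  the clipping rate reported.
* **Co-essentiality structure** — KO-effect profiles of module genes load
  on a shared per-line latent factor (effect = loading × factor + Gaussian
  noise); background genes are independent noise.  An anti-module shares
  the factor with negative loading.
* **Expression gate** — the GOI's log2 expression is shifted by
  ``expr_shift`` in mutant lines.

All randomness flows from one integer seed through ``numpy``'s PCG64
generator; a fixed seed reproduces the panel (and its CSV serialization)
bit-identically.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from .cohort import CONTROL, HETDEL, HOMDEL, MUTANT_GROUPS, T_HETDEL
from .depmap_io import GeneMatrix, MatrixRole

logger = logging.getLogger(__name__)

__all__ = [
    "CoessModule",
    "SimulationConfig",
    "GroundTruth",
    "SimulatedPanel",
    "simulate_panel",
    "write_panel",
    "truth_eval",
]

_CANCER_TYPES = ("pancreas", "lung", "breast", "colorectal")


@dataclass(frozen=True)
class CoessModule:
    """A co-essentiality module: genes loading on one latent factor.

    ``factor`` indexes a shared latent factor so that a module and an
    anti-module (negative loading) can be driven by the same factor.
    """

    genes: tuple[str, ...]
    loading: float = 0.9
    noise_sd: float = 0.3
    factor: int = 0


@dataclass
class SimulationConfig:
    """Panel dimensions, planted effects and noise levels.

    Defaults describe the benchmark screen condition: 20 control vs 20
    mutant lines, 2000 genes, 10 lethal and 10 alleviating interactions
    planted at Δprob = 0.6, one 5-gene co-essential module containing the
    GOI (loading 0.9, noise sd 0.3) and a 5-gene anti-module on the same
    factor (loading −0.9).
    """

    goi: str = "GOI1"
    n_control: int = 20
    n_mutant: int = 20
    n_genes: int = 2000
    mutant_group: str = HOMDEL
    planted_lethal: Optional[tuple[str, ...]] = None  # default: G0001..G0010
    planted_alleviating: Optional[tuple[str, ...]] = None  # default: G0011..G0020
    delta_prob: float = 0.6
    coess_modules: Optional[tuple[CoessModule, ...]] = None
    expr_shift: float = -2.0
    expr_baseline_mean: float = 5.0
    expr_baseline_sd: float = 1.5
    expr_noise_sd: float = 1.0
    beta_a: float = 1.0
    beta_b: float = 6.0
    cn_neutral_mean: float = 2.0
    cn_neutral_sd: float = 0.1
    effect_noise_sd: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.mutant_group not in MUTANT_GROUPS:
            raise ValueError(f"mutant_group must be one of {MUTANT_GROUPS}")
        names = self.gene_names()
        if self.planted_lethal is None:
            self.planted_lethal = tuple(names[0:10]) if self.n_genes >= 30 else ()
        if self.planted_alleviating is None:
            self.planted_alleviating = (
                tuple(names[10:20]) if self.n_genes >= 30 else ()
            )
        overlap = set(self.planted_lethal) & set(self.planted_alleviating)
        if overlap:
            raise ValueError(f"genes planted in both directions: {sorted(overlap)}")
        known = set(names) | {self.goi}
        stray = (set(self.planted_lethal) | set(self.planted_alleviating)) - known
        if stray:
            raise ValueError(f"planted genes outside the panel: {sorted(stray)}")
        if self.coess_modules is None:
            if self.n_genes >= 30:
                # names[-1] is the GOI itself; partners are the 4 genes before it
                partners = tuple(names[-5:-1])
                anti = tuple(names[-10:-5])
                self.coess_modules = (
                    CoessModule(genes=(self.goi,) + partners, loading=0.9,
                                noise_sd=0.3, factor=0),
                    CoessModule(genes=anti, loading=-0.9, noise_sd=0.3, factor=0),
                )
            else:
                self.coess_modules = ()
        for mod in self.coess_modules:
            stray = set(mod.genes) - known
            if stray:
                raise ValueError(f"module genes outside the panel: {sorted(stray)}")

    def gene_names(self) -> list[str]:
        """All gene symbols; the GOI takes the last slot."""
        width = max(4, len(str(self.n_genes)))
        names = [f"G{i:0{width}d}" for i in range(1, self.n_genes)]
        return names + [self.goi]


@dataclass
class GroundTruth:
    """Planted labels the generator guarantees by construction."""

    goi: str
    gi_label: pd.Series  # gene → lethal | alleviating | none
    module_of: pd.Series  # gene → module index (−1 = background)
    line_group: pd.Series  # line_id → control | HomDel | T-HetDel | HetDel
    clip_rate: float = 0.0

    def to_frame(self) -> pd.DataFrame:
        genes = self.gi_label.index
        return pd.DataFrame(
            {
                "gene": genes,
                "gi_label": self.gi_label.values,
                "module": self.module_of.reindex(genes, fill_value=-1).values,
            }
        )


@dataclass
class SimulatedPanel:
    config: SimulationConfig
    sample_info: pd.DataFrame
    mutations: pd.DataFrame
    copy_number: GeneMatrix
    expression: GeneMatrix
    ko_effect: GeneMatrix
    lethality_prob: GeneMatrix
    truth: GroundTruth


def simulate_panel(config: SimulationConfig) -> SimulatedPanel:
    """Generate a complete panel (annotations, mutations, four matrices, truth)."""
    rng = np.random.default_rng(config.seed)
    genes = config.gene_names()
    n_lines = config.n_control + config.n_mutant
    lines = [f"ACH-{i:06d}" for i in range(1, n_lines + 1)]
    groups = [CONTROL] * config.n_control + [config.mutant_group] * config.n_mutant
    mutant_lines = lines[config.n_control :]

    sample_info = pd.DataFrame(
        {
            "line_id": lines,
            "line_name": [f"SIMLINE{i:04d}" for i in range(1, n_lines + 1)],
            "cancer_type": [
                _CANCER_TYPES[i % len(_CANCER_TYPES)] for i in range(n_lines)
            ],
            "lineage": [
                _CANCER_TYPES[i % len(_CANCER_TYPES)] for i in range(n_lines)
            ],
        }
    )

    mutations = _make_mutations(config, lines, groups, rng)
    copy_number = _make_copy_number(config, genes, lines, groups, rng)
    expression = _make_expression(config, genes, lines, groups, rng)
    ko_effect = _make_ko_effect(config, genes, lines, rng)
    lethality_prob, clip_rate = _make_lethality(config, genes, lines, groups, rng)

    gi_label = pd.Series("none", index=pd.Index(genes, name="gene"))
    gi_label[list(config.planted_lethal)] = "lethal"
    gi_label[list(config.planted_alleviating)] = "alleviating"
    module_of = pd.Series(-1, index=pd.Index(genes, name="gene"))
    for k, mod in enumerate(config.coess_modules):
        module_of[list(mod.genes)] = k
    truth = GroundTruth(
        goi=config.goi,
        gi_label=gi_label,
        module_of=module_of,
        line_group=pd.Series(groups, index=pd.Index(lines, name="line_id")),
        clip_rate=clip_rate,
    )
    return SimulatedPanel(
        config=config,
        sample_info=sample_info,
        mutations=mutations,
        copy_number=copy_number,
        expression=expression,
        ko_effect=ko_effect,
        lethality_prob=lethality_prob,
        truth=truth,
    )


def _make_mutations(config, lines, groups, rng) -> pd.DataFrame:
    """GOI lesions per planted group + silent passenger noise.

    Lesion choices are exactly the evidence the cohort rules require:
    HomDel → one homozygous nonsense; T-HetDel → two heterozygous
    frameshifts with distinct protein changes; HetDel → one heterozygous
    frameshift.
    """
    rows = []
    names = config.gene_names()
    for idx, (line, group) in enumerate(zip(lines, groups)):
        if group == HOMDEL:
            rows.append((line, config.goi, "nonsense", "homozygous",
                         f"p.R{100 + idx}*", True))
        elif group == T_HETDEL:
            rows.append((line, config.goi, "frameshift", "heterozygous",
                         f"p.L{200 + idx}fs", True))
            rows.append((line, config.goi, "frameshift", "heterozygous",
                         f"p.Q{400 + idx}fs", True))
        elif group == HETDEL:
            rows.append((line, config.goi, "frameshift", "heterozygous",
                         f"p.L{200 + idx}fs", True))
        # silent passengers in ~20% of lines, never on the GOI
        if rng.random() < 0.2 and config.n_genes > 1:
            gene = names[int(rng.integers(0, config.n_genes - 1))]
            rows.append((line, gene, "silent", "heterozygous",
                         f"p.S{int(rng.integers(1, 500))}=", False))
    return pd.DataFrame(
        rows,
        columns=["line_id", "gene", "consequence", "zygosity", "protein_change",
                 "is_damaging"],
    )


def _make_copy_number(config, genes, lines, groups, rng) -> GeneMatrix:
    vals = rng.normal(config.cn_neutral_mean, 0.15, size=(len(genes), len(lines)))
    vals = np.clip(vals, 1.55, 2.45)  # background genes stay on the neutral band
    m = pd.DataFrame(vals, index=pd.Index(genes, name="gene"), columns=lines)
    goi_cn = np.clip(
        rng.normal(config.cn_neutral_mean, config.cn_neutral_sd, size=len(lines)),
        1.55, 2.45,
    )
    for j, group in enumerate(groups):
        if group == HOMDEL:
            goi_cn[j] = min(abs(rng.normal(0.05, 0.04)), 0.2)  # deep deletion
        elif group == HETDEL:
            goi_cn[j] = rng.normal(1.0, 0.1)  # single-copy loss, not deep
    m.loc[config.goi] = goi_cn
    return GeneMatrix(values=m, role=MatrixRole.COPY_NUMBER)


def _make_expression(config, genes, lines, groups, rng) -> GeneMatrix:
    baseline = rng.normal(
        config.expr_baseline_mean, config.expr_baseline_sd, size=len(genes)
    )
    vals = baseline[:, None] + rng.normal(
        0.0, config.expr_noise_sd, size=(len(genes), len(lines))
    )
    m = pd.DataFrame(vals, index=pd.Index(genes, name="gene"), columns=lines)
    mutant_mask = np.array([g != CONTROL for g in groups])
    m.loc[config.goi, mutant_mask] += config.expr_shift
    m[m < 0] = 0.0  # log2(TPM+1) floor
    return GeneMatrix(values=m, role=MatrixRole.EXPRESSION_MRNA)


def _make_ko_effect(config, genes, lines, rng) -> GeneMatrix:
    gene_means = rng.normal(-0.2, 0.3, size=len(genes))
    vals = gene_means[:, None] + rng.normal(
        0.0, config.effect_noise_sd, size=(len(genes), len(lines))
    )
    m = pd.DataFrame(vals, index=pd.Index(genes, name="gene"), columns=lines)
    n_factors = 1 + max((mod.factor for mod in config.coess_modules), default=-1)
    factors = rng.normal(0.0, 1.0, size=(n_factors, len(lines)))
    for mod in config.coess_modules:
        for gene in mod.genes:
            m.loc[gene] = (
                mod.loading * factors[mod.factor]
                + rng.normal(0.0, mod.noise_sd, size=len(lines))
            )
    return GeneMatrix(values=m, role=MatrixRole.KO_EFFECT)


def _make_lethality(config, genes, lines, groups, rng):
    vals = rng.beta(config.beta_a, config.beta_b, size=(len(genes), len(lines)))
    m = pd.DataFrame(vals, index=pd.Index(genes, name="gene"), columns=lines)
    mutant_mask = np.array([g != CONTROL for g in groups])
    for gene in config.planted_lethal:
        m.loc[gene, mutant_mask] += config.delta_prob
    for gene in config.planted_alleviating:
        m.loc[gene, mutant_mask] -= config.delta_prob
    arr = m.to_numpy()
    clipped = int(((arr < 0) | (arr > 1)).sum())
    clip_rate = clipped / arr.size
    n_planted_cells = (
        (len(config.planted_lethal) + len(config.planted_alleviating))
        * int(mutant_mask.sum())
    )
    if n_planted_cells and clipped > 0.5 * n_planted_cells:
        logger.warning(
            "planted shift clipped %d/%d planted cells (%.1f%% of matrix)",
            clipped, n_planted_cells, 100 * clip_rate,
        )
    m = m.clip(0.0, 1.0)
    return GeneMatrix(values=m, role=MatrixRole.LETHALITY_PROB), clip_rate


# ---------------------------------------------------------------------------
# serialization


def _matrix_to_depmap_csv(matrix: GeneMatrix, path: Path) -> None:
    """Write lines-in-rows with ``"SYMBOL (ENTREZ)"`` headers (DepMap layout)."""
    df = matrix.values.T.copy()
    df.columns = [
        f"{g} ({1000 + i})" for i, g in enumerate(matrix.values.index, start=1)
    ]
    df.index.name = "DepMap_ID"
    df.to_csv(path, float_format="%.17g", lineterminator="\n")


def write_panel(panel: SimulatedPanel, out_dir: str | Path) -> dict[str, Path]:
    """Emit the full CSV fixture set + ``truth.tsv``; returns written paths."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    si = panel.sample_info.rename(
        columns={
            "line_id": "DepMap_ID",
            "line_name": "stripped_cell_line_name",
            "cancer_type": "primary_disease",
        }
    )
    paths["sample_info"] = out / "sample_info.csv"
    si.to_csv(paths["sample_info"], index=False, lineterminator="\n")

    mut = panel.mutations.rename(
        columns={
            "line_id": "DepMap_ID",
            "gene": "Hugo_Symbol",
            "consequence": "Variant_Classification",
            "zygosity": "Variant_annotation_zygosity",
            "protein_change": "Protein_Change",
            "is_damaging": "isDeleterious",
        }
    )
    paths["mutations"] = out / "mutations.csv"
    mut.to_csv(paths["mutations"], index=False, lineterminator="\n")

    for name, matrix in (
        ("copy_number", panel.copy_number),
        ("expression", panel.expression),
        ("gene_effect", panel.ko_effect),
        ("lethality_prob", panel.lethality_prob),
    ):
        paths[name] = out / f"{name}.csv"
        _matrix_to_depmap_csv(matrix, paths[name])

    truth_df = panel.truth.to_frame()
    line_df = panel.truth.line_group.rename("true_group").reset_index()
    paths["truth"] = out / "truth.tsv"
    truth_df.to_csv(paths["truth"], sep="\t", index=False, lineterminator="\n")
    paths["truth_lines"] = out / "truth_lines.tsv"
    line_df.to_csv(paths["truth_lines"], sep="\t", index=False, lineterminator="\n")
    return paths


# ---------------------------------------------------------------------------
# evaluation


def truth_eval(
    screen_rows: pd.DataFrame,
    truth: GroundTruth,
    fdr_threshold: float = 0.05,
) -> dict[str, float]:
    """Confusion-matrix summary of screen calls against planted labels.

    Returns ``sensitivity`` (planted genes called with the correct sign /
    planted genes screened), ``fdr`` (false calls / all calls; 0 when
    nothing is called), and ``sign_accuracy`` (among planted genes that
    received any call).  A call is correct only if its direction matches
    the planted label.
    """
    overlap = screen_rows["gene"].isin(truth.gi_label.index)
    if not overlap.any():
        raise ValueError("no overlap between screened genes and ground truth")
    df = screen_rows.loc[overlap, ["gene", "call"]].copy()
    df["true"] = truth.gi_label.reindex(df["gene"]).values

    planted = df["true"] != "none"
    called = df["call"] != "none"
    correct = called & (df["call"] == df["true"])

    n_planted = int(planted.sum())
    n_called = int(called.sum())
    sensitivity = float(correct[planted].sum() / n_planted) if n_planted else np.nan
    fdr = float((called & ~correct).sum() / n_called) if n_called else 0.0
    called_planted = called & planted
    sign_accuracy = (
        float((df.loc[called_planted, "call"] == df.loc[called_planted, "true"]).mean())
        if called_planted.any()
        else np.nan
    )
    return {"sensitivity": sensitivity, "fdr": fdr, "sign_accuracy": sign_accuracy}
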