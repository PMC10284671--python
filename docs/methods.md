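# Methods

This note records the models, rules and numerical choices behind
`gimapper`, in the order the pipeline runs them, together with what the
synthetic benchmark panels do and do not establish about real data.

## Cohort classification

For a gene of interest (GOI) the classifier sees, per cell line, the
GOI's variant calls and its gene-level relative copy number (diploid
= 2). Definitions:

* **LoF variant** — consequence ∈ {nonsense, frameshift, splice site,
  start lost}, or any non-missense/non-silent consequence carrying a
  damaging annotation. A *damaging missense* is deliberately **not**
  LoF: its functional impact is too uncertain to call the line mutant,
  but it also disqualifies the line from the control group, so a line
  whose only GOI lesion is damaging missense is excluded (conservative
  in both directions).
* **Copy-number bands** — neutral = [1.5, 2.5] relative copies; deep
  deletion < 0.25. Both configurable (`CohortParams`); the defaults sit
  symmetric around diploid and well below one retained copy.

Rules, applied in order: missing copy number → excluded (`no_cn`; the
copy-number criteria are inapplicable, and group membership without them
is not defensible). Homozygous LoF, or deep deletion (with or without a
LoF call) → `HomDel`. Two or more *distinct* heterozygous LoF variants →
`T-HetDel` — a deliberate approximation of trans-heterozygosity, since
gene-level public variant calls carry no phase; distinctness is judged
on (consequence, protein change). Exactly one heterozygous LoF →
`HetDel`. No LoF, no damaging missense, neutral copy number →
`control`. Everything else → excluded with a single reason code
(`lof_unknown_zygosity`, `damaging_missense_only`, `cn_not_neutral`,
`selector:*`). The five groups always partition the panel; selector-
removed lines stay in the partition as excluded so the bookkeeping is
lossless.

Group-size policy: comparisons warn below 5 usable lines per group and
refuse below 2 (a rank test on 1 vs 1 is vacuous); both thresholds are
configurable.

## Expression gate

Welch's unequal-variance *t* with Welch–Satterthwaite degrees of
freedom, two-sided, α = 0.05 by default. The test is two-sided with the
direction (`reduced` / `increased` / `unchanged`) reported separately:
that is strictly more informative than a one-sided "reduction" test and
collapses to it when the user requires `direction == reduced`. No
multiplicity correction — at most six tests run (three subgroups × two
modalities) for one query gene. Degenerate inputs (n < 2, or zero
variance in both groups) yield flagged rows with missing p rather than
exceptions, so a screen over many subgroups never dies mid-run.

## GI screen

Two-sided Mann–Whitney *U* per gene, mutant vs control lethality
probabilities:

* **Exact vs asymptotic** — exact null distribution when
  n₁·n₂ ≤ 400 and the pooled sample is tie-free; otherwise the normal
  approximation with midranks, tie-corrected variance and continuity
  correction. The method used is recorded per row. The 400 cut-off
  keeps the exact path for the small cohorts where the approximation is
  least trustworthy while staying O(n₁·n₂·U) cheap.
* **Two-sided, always** — the screen looks for *both* lethal
  (Δmedian > 0) and alleviating (Δmedian < 0) interactions; a one-sided
  test would silently discard half the biology.
* **Interaction score** — −log₁₀(p)·sign(Δmedian); 0 when the medians
  are equal; p-value underflow is clamped to the smallest positive
  float and logged. The score is monotone in evidence and makes the
  ranked table read top-to-bottom as most-lethal → most-alleviating.
  Δmedian is reported separately so effect size is never conflated with
  significance. The score formula is pluggable in principle; this is
  the package's canonical choice.
* **Multiplicity** — Benjamini–Hochberg step-up across exactly the
  genes tested in the run (genome-wide or the small-scale subset), with
  missing p-values excluded from *m* and passed through. Calls require
  adjusted p < FDR threshold (default 0.05) with matching sign.
* **Degenerate genes** — fewer than 2 non-missing values in either
  group, or an all-tied pooled sample, yield rows with missing p,
  flagged, never silently dropped.
* Output order is canonical (score descending, gene symbol as
  tie-break), so results are invariant to the row/column order of the
  input matrix.

## Essentiality map

Pearson *r* between the GOI's KO-effect profile and every gene, over
pairwise-complete observations (maximizing n per pair; n reported per
row); *p* from the *t*-transform *t* = *r*√((n−2)/(1−*r*²)) on n−2
degrees of freedom; |r| = 1 maps to p = 0. Pairs with fewer than 3
joint observations or zero variance carry missing r/p. The profile is
computed with vectorized masked sums, so 18 333 genes × 900 lines takes
about two seconds.

**Knee thresholding.** Each ranked coefficient curve (positive r
descending; negative r by magnitude) is cut at its knee: the interior
rank with maximum perpendicular distance to the chord joining the
curve's endpoints. This estimator is parameter-free and exactly
checkable against a brute-force scan; other estimators of the
"unit-invariant knee" family would slot in behind the same interface.
Ties (including exactly linear curves, where all distances are ~0)
break toward the smaller rank — the stricter threshold — using a 1e-12
relative tolerance so floating-point noise cannot push the knee down a
linear curve. Curves shorter than 3 points have no interior and return
their full length (no thresholding), with a warning.

The GOI itself always has r = 1; it is excluded from the positive curve
before knee detection (a guaranteed r = 1 point would distort the
chord) but kept in the output at rank 1, and the reported positive knee
rank is shifted by one so ranks and threshold live on the same scale.
Flags combine the two parts of the thresholding: knee rank AND
unadjusted p < α (default 0.05). A BH-adjusted variant would be
stricter; unadjusted p matches the top-of-curve semantics of knee
thresholding, where the knee — not the p-value — does the heavy
lifting.

## Synthetic panels

The generator emits a full DepMap-schema fixture set (sample
annotations, MAF-like mutations, copy number, expression, KO effect,
lethality probability) whose ground truth is known by construction:

* **Lesions match the classifier's rules exactly** — HomDel lines get a
  homozygous nonsense variant plus deep-deleted copy number (~0.05–0.2);
  T-HetDel two distinct heterozygous frameshifts; HetDel one, with
  single-copy loss (~1.0). Control lines are wild-type on the neutral
  band. Cohort recovery is therefore exact, which is the point: it
  isolates classifier defects from simulation noise. About 20% of
  lines also carry a silent passenger variant in a random background
  gene, which must not affect classification.
* **Lethality probabilities** — i.i.d. Beta(1, 6) per cell (mean 0.14:
  most knockouts are not lethal, matching the right-skew of dependency
  probabilities). Planted lethal/alleviating genes shift mutant cells
  by ±Δprob (default 0.6) and are clipped to [0, 1]; the clip rate is
  reported and a warning fires if more than half the planted cells
  clip. Alleviating genes at Δ = 0.6 clip heavily at 0 by construction
  — the test of the screen is sign and detection, not the realized
  effect size.
* **KO effect** — module genes are loading × (per-line latent factor)
  + N(0, noise sd); an anti-module reuses the same factor with negative
  loading. Background genes are independent noise around per-gene
  means, so background correlations are O(1/√n_lines). Defaults: one
  5-gene module containing the GOI at loading 0.9, one 5-gene
  anti-module at −0.9, noise sd 0.3.
* **Expression** — per-gene baselines N(5, 1.5) in log2(TPM+1) units
  with N(0, 1) per-line noise; the GOI drops by 2 log2 units in mutant
  lines (a strong but realistic knockout-like reduction).
* **Benchmark sizes** — screens: 2000 genes × (20 + 20) lines, 10 + 10
  planted genes (runs in ~2 s); co-essentiality: the same gene count at
  200 lines, where background correlation noise (~0.07 sd) separates
  cleanly from 0.9-loading modules; a DepMap-scale configuration
  (18 333 × 900) exercises the vectorized paths end to end in well
  under a minute.

All randomness derives from a single integer seed through numpy's PCG64
stream; fixed seed ⇒ byte-identical CSVs.

**What the synthetic panels do not model:** lineage and batch structure,
screen-quality covariates, copy-number/expression coupling, correlated
missingness, or realistic linkage between mutations and the rest of the
genome. Passing the benchmarks demonstrates that the statistics,
bookkeeping and thresholds do what they claim under their own
assumptions — not that any particular biological discovery on real
DepMap data is correct. On real data the cohort sizes are unbalanced
(hundreds of controls vs tens of mutants), which the Mann–Whitney and
Welch tests tolerate but which lowers power; the expression gate exists
precisely to keep underpowered or unconvincing subgroups out of the
screen.

## False-discovery behaviour

BH controls the *expected* false-discovery proportion. With 20 strong
planted effects among 2000 genes at q = 0.05, roughly one null gene is
expected to slip past the adjusted threshold per panel, so any single
panel's observed FDP lands above 0.05 on a nontrivial fraction of
seeds. The test suite therefore checks FDR control as an average over
ten replicate panels (with per-replicate sensitivity and sign checks),
and the acceptance script reports the single-panel observed FDR as-is.

## Reproducibility

Every CLI output carries a `*.manifest.json` (inputs with SHA-256
digests, parameters, seed, package version, timestamp). Result TSVs are
serialized with 17 significant digits and re-read with round-trip float
parsing, so write→read is bit-exact; replaying any step with identical
inputs reproduces its table byte-for-byte. The library applies
canonical sort orders (score/r descending with gene-symbol tie-breaks)
so results are independent of input row and column order up to
floating-point summation effects in the correlation sums.
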