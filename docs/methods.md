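# Methods

This note documents the models, parameter choices, numerical conventions,
and known limitations of `tmescope`. It states nothing the test suite or
`scripts/acceptance.py` does not itself compute.

## Quality control

A cell passes QC iff total UMI ≥ `min_umi` (default 1000) **and** Shannon
diversity ≥ `min_shannon` (default 3). The Shannon index uses the natural
log — the convention of the ecology `diversity` functions the threshold was
designed around — so 3 corresponds to e³ ≈ 20 effectively expressed genes;
on a log₂ scale the same threshold would be meaningless. Cells exactly *at*
a threshold are kept: the filters remove strictly smaller values, and this
boundary is tested. The Shannon filter is computed on raw counts (it
precedes normalization in the pipeline order). Mitochondrial fraction
(`MT-` symbol prefix, case-insensitive) is reported per cell and never
filtered on unless `max_mito_frac` is set explicitly.

QC is idempotent, and on the null generator the removal fraction matches
the analytic log-normal library-size tail within Monte-Carlo tolerance
(both asserted in the suite).

## Normalization and embedding

Normalization is `log1p(scale · c / total)` with `scale = 1e4`, the
convention of the standard single-cell toolchains; sparsity is preserved
exactly (a zero count maps to 0). Highly variable genes are ranked by the
residual of log-variance against a lowess trend on log-mean (frac 0.3);
the top `n_hvg` (default 2000) are z-scaled per gene, clipped at ±10 to
bound outlier leverage, and passed to a full-SVD PCA (`n_pcs` default 30)
whose component signs are fixed by the largest-magnitude loading, making
the embedding bit-reproducible. The kNN graph (default k = 20, Euclidean
in PC space) is symmetrized and has no self-loops.

## Clustering and cell typing

Clustering is Leiden modularity optimization (RB-configuration objective)
on the kNN graph, deterministic given the seed, with cluster ids relabeled
by decreasing size. The resolution parameter matters in a way the
synthetic data makes visible: tumor cells carry per-patient expression
shifts, so at low resolution one patient's epithelial and EMT tumor cells
can merge into a single patient cluster. The examples and acceptance runs
use resolution 1.0–1.6 and note why.

The module score bins genes into `n_bins = 24` equal-frequency bins by
mean expression and samples `n_ctrl = 100` control genes per signature
gene from the same bin — without replacement when the bin is large enough,
with replacement otherwise, so small synthetic gene universes cannot
crash the sampler. The score is invariant to adding a constant to every
gene in every cell, and a random gene set scores ~0 on average (both
asserted).

Labels are assigned per *cluster*, matching the practice of naming
clusters rather than individual cells: the winning panel must beat the
runner-up's cluster-mean score by `min_margin` (default 0.05 score units;
the margin exists to prevent coin-flip labels, and its value is a design
choice — no quantitative adjudication rule is published for this step).
A panel counts as *passed* when its cluster-mean score is ≥ `min_margin`
above zero — zero being chance level for a control-matched score. A
cluster passing both the ETC and EMT panels is labeled EMT, because
EMT-positive tumor cells co-express epithelial markers and the mesenchymal
program is the discriminating evidence. (An earlier rule that compared the
EMT panel only against the *third-best* panel mislabeled pure epithelial
clusters whose EMT score was negative but less negative than the stroma
panels; the fix is regression-tested.)

Cell-cycle phase is G1S / G2M / non-cycling by comparing the two phase
module scores against each other and a threshold; the phase gene lists are
user inputs.

## Composition

Percentages are per patient with `Unknown` in the denominator; rows sum to
100 exactly. Presentation rounding (one decimal, `< 0.1` for nonzero
values below 0.05) happens only at export. A published 16-patient PDAC
composition table ships as package data for arithmetic cross-checks; its
`< 0.1` censored entries are parsed as 0, which is the only policy that
reproduces that table's printed two-decimal TAM mean exactly. Re-averaging
its primary-tumor columns reproduces the published means for ETC, TAM and
TIL; the published CAF mean (21.7) is not reproducible from the printed
column, whose mean is 21.27 — we treat the published 21.7 as an arithmetic
slip and leave the corresponding acceptance check red rather than adjust
either side.

## Marker signatures

`find_markers` prefilters to genes detected in ≥ `min_pct = 0.1` of either
group with |lfc| ≥ `min_lfc = 0.25`, where lfc = ln((mean expm1 + 1) in /
(mean expm1 + 1) out) — the v3 conventions of the toolchain that
popularized this test, since no parameters are published for the step.
The Wilcoxon rank-sum test uses midranks, a tie-corrected variance, and a
continuity correction; for n₁+n₂ ≤ 12 it switches to exact enumeration
over all C(n, n₁) midrank assignments with a two-sided p of
2·min(tails) capped at 1. The `method` field of every row records which
path produced the p-value. BH adjustment is applied within each cell
type's tested set; ranking is ascending p, ties by descending |lfc|, then
gene name — a documented tie rule, since the published top-20 lists do not
state one.

A caveat the suite verifies rather than hides: under a null relabeling the
prefilter *induces* significance. Genes are selected on the same
in-vs-out contrast the test then evaluates, so the few genes that pass
`min_lfc` under the null carry selection-biased p-values. With the
prefilter disabled the BH-adjusted p-values are well calibrated; with it
enabled, at most a trace of genes is tested at all under the null. Treat
the prefilter as a relevance filter, not as part of the inferential
guarantee.

Enrichment is the hypergeometric upper tail P(X ≥ k) over flat gene sets
intersected with an explicit universe, BH-adjusted across terms; no
ontology structure is bundled or interpreted.

## Subtype scoring

Subtype signatures are scored per cell by the same module score and
summarized by cell type or patient; the highest-mean group per signature
is flagged. Published subtype gene lists are user inputs in the two-column
TSV dialect — tests and examples use synthetic analogues, so a green test
establishes the scoring machinery, not the content of any published list.

## Signature survival

The score construction is deliberately rank-like and integer-valued:
gene ≥ cohort median → 1 (patients *at* the median score 1; the median of
an even cohort is the midpoint of the central order statistics; a constant
gene contributes 1 to everyone), summed over the signature genes present
in the cohort. Missing genes shrink k rather than being imputed.
Expression units are taken as given — median binarization is invariant to
any monotone per-gene transformation, which is why the unit ambiguity of
public bulk cohorts is tolerable here.

Stratification takes the ⌈n/4⌉ highest and lowest scores; patients tied
at a boundary score are all included in the adjacent group (deterministic
and auditable; integer scores in [0, 20] make boundary ties routine), so
groups may exceed ⌈n/4⌉. All scores identical, or coinciding quartile
boundaries, raise an error rather than fabricate a split. The middle half
never enters the comparison.

The log-rank statistic is the standard Mantel–Cox sum of
observed-minus-expected events over 2×2 tables at each distinct event
time with hypergeometric variance; χ² = (O₁−E₁)²/V, p from χ²(1). The
hazard ratio is the Mantel–Haenszel O/E ratio with a log-scale 95% CI —
the convention of the graphing software named for this analysis — with a
Cox partial-likelihood HR available via `hr_method="cox"` as a
cross-check. Both the χ² (against an independent implementation, 1e-6 on
100 random fixtures) and the KM estimator (hand-computed tables; exact
match to the empirical survival function without censoring) are verified.

## Synthetic data

`simulate_sc` draws counts gene-wise from a negative binomial with mean
`base_mean · marker_fold^(marker of own type) · exp(patient shift, tumor
types only) · library factor` and a single global dispersion (size)
`nb_dispersion`. Defaults: 2000 genes, base mean 1.0 (≈2000 UMI/cell so
the default QC threshold bites only the library-size tail), marker fold 8,
10 markers/type, dispersion 2.0 (typical scRNA-seq overdispersion),
library-factor SD 0.35 log units, patient shift SD 0.4. The patient shift
is drawn per (patient, gene): a scalar per patient would only rescale
library size — which normalization removes — and could not reproduce the
patient-segregated tumor clusters the model exists to emulate. Not
modeled: doublets, ambient RNA, batch chemistry, gene–gene correlation
beyond the planted programs. A green recovery test therefore establishes
the pipeline's behavior under the stated generative model, not robustness
to those artifacts.

`simulate_bulk` draws a unit-variance latent per patient; signature genes
are latent + N(0, 1) noise (signal and noise variance equal — a
deliberate, fixed choice standing in for the typical attenuation between a
cell-type abundance and any single gene's bulk expression), background
genes are standard normal. Survival is exponential with
`hazard = h0 · exp(beta · z / Δ)` where Δ = 2·φ(Φ⁻¹(0.75))/0.25 ≈ 2.5422
is the expected separation between the top- and bottom-quartile means of a
standard normal. This scaling defines `beta` as the log hazard ratio
between the latent's top and bottom quartiles — the estimand of the
quartile-stratified analysis — rather than per latent SD; without it a
planted per-SD effect would be recovered ~2.5× too large on the log scale
by construction. Censoring is an independent exponential whose rate is
solved (Brent) so the expected censored fraction equals `censor_rate`
(default 0.3, typical of the aggressive-disease cohorts this emulates)
against the realized hazards; `censor_rate = 0` yields all events exactly.

Measured behavior (asserted in the suite at the stated sizes): the
quartile log-rank rejects at 0.050 under `beta = 0`; the median recovered
HR under a planted quartile HR of 2.76 is ≈ 2.3–2.5 (attenuation from
score noise), inside the ±25% recovery band; recovery is monotone in
beta.

## Orchestration

`run_all` executes QC → normalize → embed → cluster → annotate →
composition → markers → subtype scores → survival from one
`PipelineConfig` (constructible from TOML), writes TSV/JSON outputs plus a
manifest with parameter echo and SHA-256 checksums, resumes from completed
stages under an identical config hash, and produces byte-identical outputs
across reruns with the same seed. There is no command-line interface: the
library functions and the `examples/` scripts are the interface.

## Limitations

- Cell typing is marker-panel-based only; no supervised classifier or
  copy-number evidence is implemented.
- The composition module reports no between-tissue statistical tests.
- Survival is two-group univariate; no covariate-adjusted Cox modeling,
  competing risks, or time-dependent effects.
- The prefiltered marker test's p-values are conditional on selection (see
  above); the top-20 signature is a ranking device, not a set of
  individually calibrated discoveries.
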