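# tmescope

Single-cell dissection of the solid-tumor microenvironment, as a tested,
reusable Python library. `tmescope` implements the complete analysis path a
pancreatic-cancer (PDAC) single-cell study walks: per-cell quality control,
cell typing by marker-panel module scores, per-patient cellular composition,
cell-type marker signatures, subtype-signature scoring, and a signature-score
survival analysis on bulk cohorts — plus a synthetic-data generator that
plants ground truth for every one of those stages.

It is written for computational biologists who want the individual
computations as importable, individually testable functions rather than a
monolithic notebook.

## The computations

**QC.** A cell is kept iff its library size is ≥ 1000 UMIs *and* its Shannon
diversity H = −Σᵢ pᵢ ln pᵢ (over its gene-count proportions) is ≥ 3 —
natural log, so H = 3 means roughly e³ ≈ 20 effectively expressed genes.
Mitochondrial fraction (`MT-` prefix) is reported, not filtered.
Normalization is log1p(10⁴ · c/total).

**Module score.** For a gene set S, score(cell) = mean expression of S −
mean expression of control genes drawn from the same average-expression
bins (24 bins, 100 controls per signature gene). Zero is chance level, so
scores are comparable across sets and cells.

**Cell typing.** Leiden clustering on a kNN graph in PCA space; each
cluster takes the marker panel with the highest mean module score if it
beats the runner-up by a margin (default 0.05), else `Unknown`. A cluster
positive on both the epithelial-tumor and EMT panels is called EMT.

**Composition.** Per patient, 100 · n(type)/n(cells); rows sum to 100 with
`Unknown` in the denominator.

**Marker signatures.** One-vs-rest Wilcoxon rank-sum per gene (midranks,
tie-corrected normal approximation with continuity correction; exact
enumeration for n₁+n₂ ≤ 12) after a detection (≥10 %) and natural-log
fold-change (≥0.25, pseudocount 1 on de-logged means) prefilter; BH
adjustment; top 20 per type by p-value form the signature. Hypergeometric
over-representation against user-supplied gene sets.

**Signature survival.** On a patients × genes bulk cohort: binarize each
signature gene against its cohort median (≥ median → 1), sum to an integer
score in [0, k], take the top and bottom score quartiles (boundary ties
join the adjacent group), and compare them with the Kaplan–Meier estimator
and the Mantel–Cox log-rank test. HR = (O₁/E₁)/(O₂/E₂) with
CI₉₅ = exp(ln HR ± 1.96·√(1/E₁+1/E₂)); a Cox partial-likelihood HR is
available as a cross-check.

**Synthetic data.** `simulate_sc` draws negative-binomial counts with
planted marker programs, log-normal library sizes, and per-(patient, gene)
shifts applied only to tumor cell types — so tumor cells segregate by
patient while stroma mixes. `simulate_bulk` plants a per-patient latent
signature level that drives both signature-gene expression and an
exponential hazard; `beta` is the log hazard ratio between the top and
bottom latent quartiles, the exact quantity the survival pipeline
estimates.

## Worked example

```python
import math, tmescope as tm

cohort, truth = tm.simulate_bulk(
    tm.BulkSimConfig(n_patients=200, n_genes=100, beta=math.log(2.76), seed=4))
signature = tm.GeneSet("planted", list(cohort.expr.columns[:20]))
res = tm.signature_survival(cohort, signature)
print(f"HR = {res.hr:.2f}, 95% CI {res.ci95[0]:.2f}-{res.ci95[1]:.2f}, "
      f"p = {res.p_value:.2e}")
```

prints

```
HR = 2.49, 95% CI 1.53-4.03, p = 1.96e-05
```

— the 50 highest-scoring patients die ~2.5× faster than the 54
lowest-scoring ones (boundary ties grew the low group past n/4 = 50); the
planted quartile hazard ratio was 2.76, and the estimate is attenuated
slightly by the gene-level noise in the 20-gene score. `examples/` holds
one short script per capability (QC, annotation + composition, marker
signatures + enrichment, subtype scores, survival), each printing the
numbers it computes.

## Acceptance script

```sh
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

re-runs the whole pipeline from scratch on generated data — single-cell
simulation through QC, clustering, annotation, composition and top-20
signatures, the subtype-score summary, the bulk survival analysis, and the
orchestrated `run_all` — printing what each stage computed and writing the
results JSON to `--out`. All randomness derives from `--seed`.
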