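"""Stratify a bulk cohort by a signature score and test survival.

Each signature gene is binarized against its cohort-wide median
(>= median -> 1), the 0/1 values are summed into a per-patient score, and
the top and bottom score quartiles are compared by Kaplan-Meier curves and
the Mantel-Cox log-rank test with a Mantel-Haenszel hazard ratio.
"""

import math

import tmescope as tm

cfg = tm.BulkSimConfig(n_patients=200, n_genes=100, beta=math.log(2.76), seed=4)
cohort, truth = tm.simulate_bulk(cfg)
print(f"cohort: {len(cohort.patients)} patients, "
      f"{cohort.clinical['os_event'].mean():.0%} with observed events")

signature = tm.GeneSet("planted", list(cohort.expr.columns[:20]))
res = tm.signature_survival(cohort, signature)

print(f"high group n={res.n_high}, low group n={res.n_low} "
      f"(middle half excluded)")
print(f"log-rank chi-square = {res.chi_square:.2f}, p = {res.p_value:.2e}")
print(f"HR (high vs low) = {res.hr:.2f}, 95% CI {res.ci95[0]:.2f}-{res.ci95[1]:.2f}")
# The planted high-vs-low-quartile hazard ratio is 2.76; the estimate is
# attenuated slightly by gene-level noise in the score.
print(res.km_high.head(4))
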