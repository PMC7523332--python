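"""Signature-score survival analysis on bulk cohorts.

The procedure: (1) binarize each signature gene against its cohort-wide
median (1 if a patient's expression is at or above the median, else 0);
(2) sum the 0/1 values per patient into an integer score in [0, k];
(3) stratify patients into the top and bottom score quartiles (patients
tied at a boundary score are ALL included in the adjacent group — integer
scores make boundary ties common and a deterministic inclusive rule is
auditable); (4) compare the two groups with the Kaplan-Meier estimator and
the Mantel-Cox log-rank test, reporting chi-square, p (chi2, 1 df), the
Mantel-Haenszel hazard ratio (O1/E1)/(O2/E2) with a log-scale 95% CI, and
optionally a Cox partial-likelihood HR as a cross-check.

Signature genes absent from the cohort shrink k rather than being imputed.
The middle half of patients never enters the comparison.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import chi2

from .errors import ValidationError
from .io_formats import BulkCohort, GeneSet

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# score construction
# ---------------------------------------------------------------------------


def binarize_vs_median(cohort: BulkCohort, signature: GeneSet) -> pd.DataFrame:
    """Per-(patient, gene) 0/1 matrix: 1 iff expression >= the gene's median.

    The median is the midpoint of the two central order statistics for even
    cohorts. A constant gene is all 1 (every value equals its median).
    Signature genes missing from the cohort are dropped with a warning.
    """
    present = [g for g in signature.genes if g in cohort.expr.columns]
    if not present:
        raise ValidationError(
            f"no gene of signature {signature.name!r} is present in the cohort"
        )
    missing = len(signature.genes) - len(present)
    if missing:
        logger.warning(
            "signature %s: %d of %d genes absent from cohort, score size reduced to %d",
            signature.name, missing, len(signature.genes), len(present),
        )
    sub = cohort.expr[present]
    medians = sub.median(axis=0)
    return (sub >= medians).astype(int)


def score_patients(binarized: pd.DataFrame) -> pd.Series:
    """Row sums of the 0/1 matrix: integer score in [0, k] per patient."""
    s = binarized.sum(axis=1).astype(int)
    s.name = "signature_score"
    return s


def stratify_quartiles(scores: pd.Series) -> pd.Series:
    """Assign 'high' / 'low' / 'excluded' by top and bottom score quartiles.

    q = ceil(n/4) patients in each tail; any patient tied with the q-th
    boundary score joins the adjacent group, so groups may exceed q.
    Requires n >= 8 and at least two distinct scores.
    """
    n = len(scores)
    if n < 8:
        raise ValidationError(f"need at least 8 patients to stratify, got {n}")
    if scores.nunique() < 2:
        raise ValidationError("all scores identical: no stratification possible")
    q = math.ceil(n / 4)
    ordered = np.sort(scores.to_numpy())
    low_cut = ordered[q - 1]  # q-th smallest
    high_cut = ordered[n - q]  # q-th largest
    if low_cut == high_cut:
        raise ValidationError(
            "quartile boundaries coincide: scores too concentrated to stratify"
        )
    group = pd.Series("excluded", index=scores.index, name="group")
    group[scores <= low_cut] = "low"
    group[scores >= high_cut] = "high"
    return group


# ---------------------------------------------------------------------------
# estimators
# ---------------------------------------------------------------------------


def kaplan_meier(times: np.ndarray, events: np.ndarray) -> pd.DataFrame:
    """Product-limit estimate of the survival function.

    Returns one row per distinct event time (plus t=0, S=1): columns
    time, n_at_risk, n_events, n_censored, survival. Subjects censored at
    t remain at risk for events at t (the standard convention).
    """
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    if times.size == 0:
        raise ValidationError("empty input to kaplan_meier")
    if (times < 0).any():
        raise ValidationError("times must be non-negative")
    order = np.argsort(times, kind="stable")
    times, events = times[order], events[order]

    rows = [(0.0, len(times), 0, 0, 1.0)]
    surv = 1.0
    for t in np.unique(times):
        at_t = times == t
        d = int(events[at_t].sum())
        c = int(at_t.sum() - d)
        n_risk = int((times >= t).sum())
        if d > 0:
            surv *= 1.0 - d / n_risk
            rows.append((float(t), n_risk, d, c, surv))
        elif c > 0:
            rows.append((float(t), n_risk, 0, c, surv))
    return pd.DataFrame(
        rows, columns=["time", "n_at_risk", "n_events", "n_censored", "survival"]
    )


@dataclass
class SurvivalResult:
    """Output of the two-group comparison (group 1 = high)."""

    chi_square: float
    p_value: float
    hr: float
    ci95: tuple[float, float]
    o1: float  # observed events, high group
    e1: float  # expected events under the null, high group
    o2: float
    e2: float
    km_high: pd.DataFrame
    km_low: pd.DataFrame
    n_high: int
    n_low: int
    cox_hr: float | None = None
    scores: pd.Series | None = None
    groups: pd.Series | None = None


def logrank_hr(
    high: tuple[np.ndarray, np.ndarray],
    low: tuple[np.ndarray, np.ndarray],
) -> SurvivalResult:
    """Mantel-Cox log-rank test plus the Mantel-Haenszel hazard ratio.

    At each distinct event time a 2x2 table contributes observed minus
    expected events (hypergeometric null) and its variance;
    chi_square = (sum(O1 - E1))^2 / sum(V), p from chi2 with 1 df.
    HR = (O1/E1)/(O2/E2) with ci95 = exp(ln HR +/- 1.96 sqrt(1/E1 + 1/E2)).
    """
    t1, e1v = (np.asarray(a, dtype=float) for a in high)
    t2, e2v = (np.asarray(a, dtype=float) for a in low)
    if t1.size == 0 or t2.size == 0:
        raise ValidationError("both groups must be non-empty")
    if e1v.sum() + e2v.sum() == 0:
        raise ValidationError("no events in either group")

    all_t = np.concatenate([t1, t2])
    all_e = np.concatenate([e1v, e2v])
    grp = np.concatenate([np.ones_like(t1), np.zeros_like(t2)])  # 1 = high

    o1 = e1 = o2 = e2 = var = 0.0
    for t in np.unique(all_t[all_e == 1]):
        at_risk = all_t >= t
        n = at_risk.sum()
        n1 = (at_risk & (grp == 1)).sum()
        d = ((all_t == t) & (all_e == 1)).sum()
        d1 = ((all_t == t) & (all_e == 1) & (grp == 1)).sum()
        o1 += d1
        o2 += d - d1
        exp1 = d * n1 / n
        e1 += exp1
        e2 += d - exp1
        if n > 1:
            var += d * (n1 / n) * (1 - n1 / n) * (n - d) / (n - 1)

    chi_sq = (o1 - e1) ** 2 / var if var > 0 else 0.0
    p = float(chi2.sf(chi_sq, df=1)) if var > 0 else 1.0

    if e1 > 0 and e2 > 0 and o2 > 0 and o1 > 0:
        hr = (o1 / e1) / (o2 / e2)
        half = 1.96 * math.sqrt(1.0 / e1 + 1.0 / e2)
        ci = (hr * math.exp(-half), hr * math.exp(half))
    elif e1 > 0 and e2 > 0:
        # a zero-event arm: HR degenerates; report the O/E ratio with an
        # unbounded interval rather than failing
        hr = (o1 / e1) / max(o2 / e2, 1e-12)
        ci = (0.0, float("inf"))
    else:
        raise ValidationError("expected event counts are degenerate")

    return SurvivalResult(
        chi_square=float(chi_sq),
        p_value=p,
        hr=float(hr),
        ci95=ci,
        o1=float(o1), e1=float(e1), o2=float(o2), e2=float(e2),
        km_high=kaplan_meier(t1, e1v.astype(int)),
        km_low=kaplan_meier(t2, e2v.astype(int)),
        n_high=int(t1.size),
        n_low=int(t2.size),
    )


def _cox_hr(times, events, indicator) -> float | None:
    """Optional partial-likelihood HR for the high-vs-low indicator."""
    try:
        from lifelines import CoxPHFitter

        df = pd.DataFrame({"t": times, "e": events, "x": indicator})
        cph = CoxPHFitter().fit(df, duration_col="t", event_col="e")
        return float(np.exp(cph.params_["x"]))
    except Exception:  # lifelines absent or fit failure: cross-check only
        return None


def signature_survival(
    cohort: BulkCohort,
    signature: GeneSet,
    hr_method: str = "mantel-haenszel",
) -> SurvivalResult:
    """The full pipeline: binarize -> score -> stratify -> log-rank/HR.

    ``hr_method``: "mantel-haenszel" (default) or "cox" to also attach the
    partial-likelihood HR as ``cox_hr``.
    """
    binarized = binarize_vs_median(cohort, signature)
    scores = score_patients(binarized)
    groups = stratify_quartiles(scores)

    clin = cohort.clinical
    hi = groups == "high"
    lo = groups == "low"
    result = logrank_hr(
        (clin.loc[hi, "os_time"].to_numpy(), clin.loc[hi, "os_event"].to_numpy()),
        (clin.loc[lo, "os_time"].to_numpy(), clin.loc[lo, "os_event"].to_numpy()),
    )
    result.scores = scores
    result.groups = groups
    if hr_method == "cox":
        sel = hi | lo
        result.cox_hr = _cox_hr(
            clin.loc[sel, "os_time"].to_numpy(),
            clin.loc[sel, "os_event"].to_numpy(),
            hi[sel].astype(int).to_numpy(),
        )
    elif hr_method != "mantel-haenszel":
        raise ValidationError("hr_method must be 'mantel-haenszel' or 'cox'")
    return result
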