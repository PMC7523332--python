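"""One-vs-rest Wilcoxon marker detection, top-k signatures, and enrichment.

Marker genes of a cell type are found by testing each gene's log-normalized
expression in cells of that type against all other labeled cells (Unknown
included) with a Wilcoxon rank-sum test, after prefiltering to genes
detected in at least ``min_pct`` of either group with an absolute log fold
change of at least ``min_lfc``.  The log fold change is the natural log of
the ratio of de-logged group means with a pseudocount of 1.  P-values are
BH-adjusted within the tested set; genes are ranked by ascending p-value,
ties broken by descending |lfc|, then gene name.  The top 20 per type form
that type's signature.

The rank-sum test uses exact permutation enumeration when n1+n2 <= 12
(method reported as "exact") and otherwise a normal approximation with
midranks, tie-corrected variance, and continuity correction ("normal").
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy.stats import hypergeom, norm, rankdata
from statsmodels.stats.multitest import multipletests

from .cell_typing import AnnotatedCells
from .errors import ValidationError
from .io_formats import GeneSet
from .qc import NormMatrix

logger = logging.getLogger(__name__)

EXACT_LIMIT = 12  # total sample size at or below which the exact test runs


@dataclass
class WilcoxonResult:
    u_statistic: float  # U for the first sample
    p_value: float
    method: str  # "exact" or "normal"


def wilcoxon_rank_sum(x: np.ndarray, y: np.ndarray) -> WilcoxonResult:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney) test.

    Midranks for ties. If every pooled value is identical the test carries
    no information and p = 1 by convention.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n1, n2 = len(x), len(y)
    if n1 < 1 or n2 < 1:
        raise ValidationError("both samples must be non-empty")
    pooled = np.concatenate([x, y])
    ranks = rankdata(pooled)
    r1 = ranks[:n1].sum()
    u1 = r1 - n1 * (n1 + 1) / 2.0

    if np.all(pooled == pooled[0]):
        return WilcoxonResult(u1, 1.0, "degenerate")

    if n1 + n2 <= EXACT_LIMIT:
        # enumerate all C(n, n1) assignments of the pooled midranks
        n = n1 + n2
        total = math.comb(n, n1)
        base = n1 * (n1 + 1) / 2.0
        count_le = count_ge = 0
        for comb in combinations(range(n), n1):
            u = ranks[list(comb)].sum() - base
            if u <= u1 + 1e-9:
                count_le += 1
            if u >= u1 - 1e-9:
                count_ge += 1
        p = min(1.0, 2.0 * min(count_le, count_ge) / total)
        return WilcoxonResult(u1, p, "exact")

    mean_u = n1 * n2 / 2.0
    n = n1 + n2
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = ((tie_counts**3 - tie_counts).sum()) / (n * (n - 1))
    var_u = n1 * n2 / 12.0 * (n + 1 - tie_term)
    if var_u <= 0:
        return WilcoxonResult(u1, 1.0, "degenerate")
    z = (u1 - mean_u - np.sign(u1 - mean_u) * 0.5) / math.sqrt(var_u)
    p = min(1.0, 2.0 * norm.sf(abs(z)))
    return WilcoxonResult(u1, p, "normal")


def _group_stats(X, idx: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """(mean of expm1, fraction nonzero) per gene over the given cells."""
    sub = X[:, idx].copy()
    pct = np.asarray((sub > 0).mean(axis=1)).ravel()
    sub.data = np.expm1(sub.data)  # expm1(0) == 0, so sparsity is safe
    m = np.asarray(sub.mean(axis=1)).ravel()
    return m, pct


def find_markers(
    nm: NormMatrix,
    ann: AnnotatedCells,
    cell_type: str,
    min_pct: float = 0.1,
    min_lfc: float = 0.25,
) -> pd.DataFrame:
    """Rank one-vs-rest marker genes of a cell type.

    Returns rows (cell_type, gene, p_value, adjusted_p, log_fold_change,
    pct_in, pct_out, u_statistic, method, rank) sorted by rank.
    """
    labels = ann.labels.loc[nm.cells]
    in_mask = (labels == cell_type).to_numpy()
    if in_mask.sum() == 0:
        raise ValidationError(f"cell type {cell_type!r} absent from annotation")
    if in_mask.sum() < 3:
        raise ValidationError(f"cell type {cell_type!r} has fewer than 3 cells")
    out_mask = ~in_mask
    if out_mask.sum() == 0:
        raise ValidationError("no cells outside the target type")

    X = nm.values
    in_idx, out_idx = np.flatnonzero(in_mask), np.flatnonzero(out_mask)
    m_in, pct_in = _group_stats(X, in_idx)
    m_out, pct_out = _group_stats(X, out_idx)
    lfc = np.log((m_in + 1.0) / (m_out + 1.0))

    tested = np.flatnonzero(
        ((pct_in >= min_pct) | (pct_out >= min_pct)) & (np.abs(lfc) >= min_lfc)
    )
    if tested.size == 0:
        return pd.DataFrame(
            columns=["cell_type", "gene", "p_value", "adjusted_p", "log_fold_change",
                     "pct_in", "pct_out", "u_statistic", "method", "rank"]
        )

    dense = np.asarray(X[tested, :].todense())
    rows = []
    for row, gi in zip(dense, tested):
        res = wilcoxon_rank_sum(row[in_idx], row[out_idx])
        rows.append((nm.genes[gi], res.p_value, lfc[gi], pct_in[gi], pct_out[gi],
                     res.u_statistic, res.method))
    table = pd.DataFrame(
        rows, columns=["gene", "p_value", "log_fold_change", "pct_in", "pct_out",
                       "u_statistic", "method"]
    )
    table.insert(0, "cell_type", cell_type)
    table["adjusted_p"] = multipletests(table["p_value"], method="fdr_bh")[1]
    table["_abs_lfc"] = table["log_fold_change"].abs()
    table = table.sort_values(
        by=["p_value", "_abs_lfc", "gene"], ascending=[True, False, True]
    ).drop(columns="_abs_lfc").reset_index(drop=True)
    table["rank"] = np.arange(1, len(table) + 1)
    return table


def find_all_markers(
    nm: NormMatrix,
    ann: AnnotatedCells,
    min_pct: float = 0.1,
    min_lfc: float = 0.25,
    exclude: tuple[str, ...] = ("Unknown",),
) -> pd.DataFrame:
    """find_markers for every labeled cell type, concatenated."""
    parts = []
    for t in sorted(set(ann.labels) - set(exclude)):
        if (ann.labels == t).sum() >= 3:
            parts.append(find_markers(nm, ann, t, min_pct=min_pct, min_lfc=min_lfc))
    if not parts:
        raise ValidationError("no cell type with >= 3 cells to test")
    return pd.concat(parts, ignore_index=True)


def top_k_signature(marker_table: pd.DataFrame, k: int = 20) -> dict[str, GeneSet]:
    """First k ranked genes per cell type; fewer than k takes all, warning."""
    out = {}
    for t, grp in marker_table.groupby("cell_type", sort=False):
        grp = grp.sort_values("rank")
        if len(grp) < k:
            logger.warning("cell type %s: only %d ranked genes (< %d)", t, len(grp), k)
        out[t] = GeneSet(str(t), list(grp["gene"].head(k)))
    return out


@dataclass
class EnrichmentResult:
    term: str
    k: int  # query genes in the term
    n: int  # query size (within universe)
    K: int  # term size (within universe)
    N: int  # universe size
    p_value: float
    adjusted_p: float = float("nan")


def hypergeom_enrich(
    query: GeneSet, terms: list[GeneSet], universe: list[str]
) -> list[EnrichmentResult]:
    """Over-representation of a query set in each term set.

    p = P(X >= k) with X ~ Hypergeometric(N, K, n), where all sets are
    intersected with the universe first; BH adjustment across terms.
    """
    uni = set(universe)
    if not uni:
        raise ValidationError("empty universe")
    q = set(query.genes) & uni
    n, N = len(q), len(uni)
    results = []
    for term in terms:
        t = set(term.genes) & uni
        K = len(t)
        k = len(q & t)
        p = float(hypergeom.sf(k - 1, N, K, n)) if k > 0 else 1.0
        results.append(EnrichmentResult(term.name, k, n, K, N, min(p, 1.0)))
    if results:
        adj = multipletests([r.p_value for r in results], method="fdr_bh")[1]
        for r, a in zip(results, adj):
            r.adjusted_p = float(a)
    return results
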