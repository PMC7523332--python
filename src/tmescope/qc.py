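"""Per-cell quality control, log-normalization, and the PCA/kNN embedding.

QC removes cells with library size < ``min_umi`` or per-cell Shannon
diversity < ``min_shannon`` (natural log; a threshold of 3 corresponds to
roughly e^3 ~ 20 effectively expressed genes).  Cells exactly AT a
threshold are kept — the filters remove strictly smaller values.
Mitochondrial fraction ("MT-" symbol prefix) is reported per cell but
never filtered on by default.

Normalization is the standard library-size log transform
``log1p(scale * c / total)`` with scale 1e4.  The embedding selects highly
variable genes by variance standardized against a lowess mean-variance
trend, z-scales them (clipped at +/-10), runs PCA, and builds a symmetric
k-nearest-neighbor graph in PC space.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp
from sklearn.decomposition import PCA
from sklearn.neighbors import NearestNeighbors
from statsmodels.nonparametric.smoothers_lowess import lowess

from .errors import ValidationError
from .io_formats import CountMatrix

MITO_PREFIX = "MT-"


@dataclass
class QcThresholds:
    min_umi: int = 1000
    min_shannon: float = 3.0
    max_mito_frac: float | None = None  # reported, not filtered, by default

    def __post_init__(self) -> None:
        if self.min_umi < 0 or self.min_shannon < 0:
            raise ValidationError("QC thresholds must be non-negative")


@dataclass
class QcReport:
    """Per-cell QC metrics plus a per-sample kept/removed summary."""

    per_cell: pd.DataFrame  # total_umi, shannon, mito_frac, kept
    per_sample: pd.DataFrame  # n_in, n_kept, n_removed
    empty_result: bool = False


@dataclass
class NormMatrix:
    """Log-normalized expression with the filtered matrix's labels."""

    genes: list[str]
    cells: list[str]
    values: sp.csr_matrix  # genes x cells, float
    cell_meta: pd.DataFrame
    scale: float = 1e4

    @property
    def n_genes(self) -> int:
        return len(self.genes)

    @property
    def n_cells(self) -> int:
        return len(self.cells)


@dataclass
class Embedding:
    cells: list[str]
    coords: np.ndarray  # cells x n_pcs
    graph: sp.csr_matrix  # symmetric kNN adjacency, no self-loops
    hvg: list[str]
    cell_meta: pd.DataFrame


def shannon_index(counts: np.ndarray) -> float:
    """Shannon diversity H = -sum p_i ln p_i over a cell's gene counts.

    Natural log; zero counts contribute nothing. All-zero input is a
    contract violation.
    """
    c = np.asarray(counts, dtype=float)
    if c.size == 0 or c.sum() <= 0:
        raise ValidationError("shannon_index requires at least one positive count")
    if (c < 0).any():
        raise ValidationError("counts must be non-negative")
    c = c[c > 0]
    p = c / c.sum()
    return float(-(p * np.log(p)).sum())


def _per_cell_metrics(m: CountMatrix) -> pd.DataFrame:
    csc = m.counts.tocsc()
    totals = np.asarray(csc.sum(axis=0), dtype=float).ravel()
    # H = ln(total) - (1/total) * sum c*ln(c), vectorized over the sparse data
    clogc = csc.copy().astype(float)
    clogc.data = clogc.data * np.log(clogc.data)
    s_clogc = np.asarray(clogc.sum(axis=0)).ravel()
    with np.errstate(divide="ignore", invalid="ignore"):
        shannon = np.where(totals > 0, np.log(np.where(totals > 0, totals, 1)) - s_clogc / np.where(totals > 0, totals, 1), np.nan)
    mito_rows = [i for i, g in enumerate(m.genes) if g.upper().startswith(MITO_PREFIX)]
    if mito_rows:
        mito = np.asarray(csc[mito_rows, :].sum(axis=0), dtype=float).ravel()
        mito_frac = np.divide(mito, totals, out=np.zeros_like(totals), where=totals > 0)
    else:
        mito_frac = np.zeros_like(totals)
    return pd.DataFrame(
        {"total_umi": totals, "shannon": shannon, "mito_frac": mito_frac},
        index=pd.Index(m.cells, name="barcode"),
    )


def qc_filter(m: CountMatrix, t: QcThresholds | None = None) -> tuple[CountMatrix, QcReport]:
    """Keep cells with total UMI >= min_umi AND Shannon index >= min_shannon.

    Idempotent: filtering an already-filtered matrix changes nothing. An
    empty result is allowed and flagged in the report.
    """
    if m.n_cells == 0:
        raise ValidationError("qc_filter requires a non-empty matrix")
    t = t or QcThresholds()
    metrics = _per_cell_metrics(m)
    kept = (metrics["total_umi"] >= t.min_umi) & (metrics["shannon"].fillna(-1.0) >= t.min_shannon)
    if t.max_mito_frac is not None:
        kept &= metrics["mito_frac"] <= t.max_mito_frac
    metrics["kept"] = kept.to_numpy()

    sample = m.cell_meta["sample_id"]
    per_sample = pd.DataFrame(
        {
            "n_in": sample.groupby(sample).size(),
            "n_kept": kept.groupby(sample).sum().astype(int),
        }
    )
    per_sample["n_removed"] = per_sample["n_in"] - per_sample["n_kept"]

    idx = np.flatnonzero(kept.to_numpy())
    filtered = CountMatrix(
        m.genes,
        [m.cells[i] for i in idx],
        m.counts[:, idx],
        m.cell_meta.iloc[idx],
        gene_ids=m.gene_ids,
    )
    return filtered, QcReport(metrics, per_sample, empty_result=len(idx) == 0)


def log_normalize(m: CountMatrix, scale: float = 1e4) -> NormMatrix:
    """Entry-wise log1p(scale * count / cell_total); sparsity preserved."""
    totals = m.umi_per_cell().astype(float)
    if (totals <= 0).any():
        raise ValidationError("log_normalize requires every cell total > 0 (run QC first)")
    csc = m.counts.tocsc().astype(float)
    per_entry_total = np.repeat(totals, np.diff(csc.indptr))
    csc.data = np.log1p(scale * csc.data / per_entry_total)
    return NormMatrix(m.genes, list(m.cells), csc.tocsr(), m.cell_meta, scale=scale)


def _highly_variable(nm: NormMatrix, n_hvg: int) -> np.ndarray:
    """Indices of the n_hvg genes with the highest trend-standardized variance."""
    X = nm.values  # genes x cells
    n = X.shape[1]
    mean = np.asarray(X.mean(axis=1)).ravel()
    sq = X.copy()
    sq.data = sq.data**2
    var = np.asarray(sq.mean(axis=1)).ravel() - mean**2
    var = var * n / max(n - 1, 1)
    expressed = mean > 0
    if expressed.sum() <= n_hvg:
        return np.flatnonzero(expressed) if expressed.any() else np.arange(min(n_hvg, len(mean)))
    lm = np.log10(mean[expressed])
    lv = np.log10(var[expressed] + 1e-12)
    trend = lowess(lv, lm, frac=0.3, return_sorted=False)
    std_var = lv - trend
    order = np.flatnonzero(expressed)[np.argsort(std_var)[::-1]]
    return np.sort(order[:n_hvg])


def embed(
    nm: NormMatrix,
    n_hvg: int = 2000,
    n_pcs: int = 30,
    k_neighbors: int = 20,
    seed: int = 0,
) -> Embedding:
    """HVG selection, per-gene scaling (clipped at 10), PCA, kNN graph.

    Deterministic given ``seed``; PC signs are fixed so that each
    component's largest-magnitude loading is positive.
    """
    if n_pcs > min(nm.n_cells, n_hvg):
        raise ValidationError("n_pcs must not exceed min(n_cells, n_hvg)")
    if n_hvg > nm.n_genes:
        n_hvg = nm.n_genes
    hvg_idx = _highly_variable(nm, n_hvg)
    X = np.asarray(nm.values[hvg_idx, :].todense(), dtype=float).T  # cells x hvg
    mu = X.mean(axis=0)
    sd = X.std(axis=0, ddof=1)
    sd[sd == 0] = 1.0
    X = np.clip((X - mu) / sd, -10.0, 10.0)

    n_pcs_eff = min(n_pcs, min(X.shape))
    pca = PCA(n_components=n_pcs_eff, svd_solver="full", random_state=seed)
    coords = pca.fit_transform(X)
    # deterministic sign convention
    signs = np.sign(pca.components_[np.arange(n_pcs_eff), np.abs(pca.components_).argmax(axis=1)])
    signs[signs == 0] = 1.0
    coords = coords * signs

    k = min(k_neighbors, nm.n_cells - 1)
    nn = NearestNeighbors(n_neighbors=k + 1).fit(coords)
    adj = nn.kneighbors_graph(coords, mode="connectivity")
    adj.setdiag(0)
    adj.eliminate_zeros()
    adj = adj.maximum(adj.T)  # symmetrize

    return Embedding(list(nm.cells), coords, sp.csr_matrix(adj), [nm.genes[i] for i in hvg_idx], nm.cell_meta)
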