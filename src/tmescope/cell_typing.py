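"""Clustering, module scores with expression-matched controls, and cell typing.

The module score of a gene set in a cell is the mean log-normalized
expression of the set's genes minus the mean expression of control genes
drawn from the same average-expression bins — so a positive score means
the program is expressed above what genes of comparable abundance would
give by chance.  Cells are labeled at the *cluster* level: each cluster
gets the marker panel with the highest mean module score, provided it
beats the runner-up by a margin; otherwise the cluster is "Unknown".

A cluster scoring above margin on both the epithelial-tumor (ETC) and EMT
panels is labeled EMT: EMT-positive tumor cells co-express epithelial
markers, and the mesenchymal program is the discriminating evidence.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import pandas as pd
import igraph as ig
import leidenalg

from .errors import ValidationError
from .io_formats import GeneSet, read_gene_sets
from .qc import Embedding, NormMatrix

logger = logging.getLogger(__name__)

#: marker panels shipped by default (ETC, CAF, EMT, TIL, TAM, Endo, DC).
#: The ambiguous symbols "CD1" and "G-CSF" sometimes quoted for DC and
#: macrophage panels are omitted; FCER1A alone marks DC and CD68 alone TAM.
DEFAULT_PANEL_RESOURCE = "default_markers.tsv"


@dataclass
class AnnotatedCells:
    """Per-cell cluster id, cell-type label, module scores, cycle phase."""

    obs: pd.DataFrame  # index barcode; columns cluster, label (+ patient_id, tissue, phase)
    module_scores: pd.DataFrame  # index barcode; one column per scored set

    def __post_init__(self) -> None:
        for col in ("cluster", "label"):
            if col not in self.obs.columns:
                raise ValidationError(f"AnnotatedCells.obs missing column {col!r}")

    @property
    def labels(self) -> pd.Series:
        return self.obs["label"]

    @property
    def clusters(self) -> pd.Series:
        return self.obs["cluster"]


def load_default_panel() -> dict[str, GeneSet]:
    path = resources.files("tmescope.data") / DEFAULT_PANEL_RESOURCE
    return {s.name: s for s in read_gene_sets(str(path))}


def cluster(e: Embedding, resolution: float = 0.8, seed: int = 0) -> pd.Series:
    """Leiden community detection on the kNN graph.

    Cluster ids are 0..K-1 ordered by decreasing size; deterministic given
    ``seed`` and invariant (up to relabeling) to cell order.
    """
    adj = e.graph
    if adj.shape[0] == 0:
        raise ValidationError("empty graph")
    src, dst = adj.nonzero()
    keep = src < dst  # undirected: each edge once
    g = ig.Graph(n=adj.shape[0], edges=list(zip(src[keep].tolist(), dst[keep].tolist())))
    part = leidenalg.find_partition(
        g,
        leidenalg.RBConfigurationVertexPartition,
        resolution_parameter=resolution,
        seed=seed,
        n_iterations=-1,
    )
    membership = np.asarray(part.membership)
    # relabel by decreasing cluster size, ties by first appearance
    sizes = pd.Series(membership).value_counts()
    order = {old: new for new, old in enumerate(sizes.index)}
    relabeled = np.array([order[m] for m in membership])
    return pd.Series(relabeled, index=pd.Index(e.cells, name="barcode"), name="cluster")


def module_score(
    nm: NormMatrix,
    gs: GeneSet,
    n_bins: int = 24,
    n_ctrl: int = 100,
    seed: int = 0,
    control_genes: list[str] | None = None,
) -> pd.Series:
    """Mean expression of a gene set minus expression-matched controls.

    Genes are ranked by mean expression across cells and cut into
    ``n_bins`` equal-frequency bins; each signature gene contributes
    ``n_ctrl`` control genes drawn from its bin (without replacement when
    the bin is large enough, with replacement otherwise).  Passing
    ``control_genes`` overrides the sampling entirely.
    """
    gene_pos = {g: i for i, g in enumerate(nm.genes)}
    present = [g for g in gs.genes if g in gene_pos]
    dropped = len(gs.genes) - len(present)
    if not present:
        raise ValidationError(f"no genes of set {gs.name!r} are present in the matrix")
    if dropped:
        logger.warning("set %s: %d genes absent from matrix, dropped", gs.name, dropped)

    X = nm.values  # genes x cells
    sig_idx = np.array([gene_pos[g] for g in present])
    sig_mean = np.asarray(X[sig_idx, :].mean(axis=0)).ravel()

    if control_genes is not None:
        ctrl_idx = np.array([gene_pos[g] for g in control_genes if g in gene_pos])
        if ctrl_idx.size == 0:
            raise ValidationError("control_genes has no overlap with the matrix")
    else:
        rng = np.random.default_rng(seed)
        gene_means = np.asarray(X.mean(axis=1)).ravel()
        order = np.argsort(gene_means, kind="stable")
        n_genes = len(order)
        bins_eff = min(n_bins, n_genes)
        bin_of = np.empty(n_genes, dtype=int)
        bin_of[order] = (np.arange(n_genes) * bins_eff) // n_genes
        members = {b: np.flatnonzero(bin_of == b) for b in range(bins_eff)}
        picks = []
        for gi in sig_idx:
            pool = members[bin_of[gi]]
            if len(pool) >= n_ctrl:
                picks.append(rng.choice(pool, size=n_ctrl, replace=False))
            else:
                picks.append(rng.choice(pool, size=n_ctrl, replace=True))
        ctrl_idx = np.concatenate(picks)
    ctrl_mean = np.asarray(X[ctrl_idx, :].mean(axis=0)).ravel()

    return pd.Series(sig_mean - ctrl_mean, index=pd.Index(nm.cells, name="barcode"), name=gs.name)


def score_panels(
    nm: NormMatrix,
    panel: dict[str, GeneSet],
    n_bins: int = 24,
    n_ctrl: int = 100,
    seed: int = 0,
) -> pd.DataFrame:
    """Module score of every panel for every cell (one column per panel)."""
    cols = {}
    for name, gs in panel.items():
        cols[name] = module_score(nm, gs, n_bins=n_bins, n_ctrl=n_ctrl, seed=seed)
    return pd.DataFrame(cols)


def assign_labels(
    clusters: pd.Series,
    nm: NormMatrix,
    panel: dict[str, GeneSet],
    min_margin: float = 0.05,
    n_bins: int = 24,
    n_ctrl: int = 100,
    seed: int = 0,
    scores: pd.DataFrame | None = None,
) -> AnnotatedCells:
    """Label each cluster by its best-scoring marker panel.

    The winning panel must beat the runner-up's cluster-mean module score
    by at least ``min_margin``, else the cluster is "Unknown". Clusters
    whose top two panels are ETC and EMT (both above the rest by margin)
    are labeled EMT.
    """
    if scores is None:
        scores = score_panels(nm, panel, n_bins=n_bins, n_ctrl=n_ctrl, seed=seed)
    scores = scores.loc[clusters.index]
    cluster_means = scores.groupby(clusters).mean()

    labels_by_cluster: dict[int, str] = {}
    for cid, row in cluster_means.iterrows():
        ranked = row.sort_values(ascending=False)
        if len(ranked) == 1:
            labels_by_cluster[cid] = ranked.index[0]
            continue
        # a panel is "passed" when its score is positive beyond the margin
        # (the module score is already control-adjusted, so 0 is chance level)
        passed = set(row.index[row >= min_margin])
        if {"ETC", "EMT"} <= passed:
            # double-positive tumor cluster: the mesenchymal program decides
            labels_by_cluster[cid] = "EMT"
        elif ranked.iloc[0] - ranked.iloc[1] >= min_margin:
            labels_by_cluster[cid] = ranked.index[0]
        else:
            labels_by_cluster[cid] = "Unknown"

    obs = pd.DataFrame(index=clusters.index)
    obs["cluster"] = clusters
    obs["label"] = clusters.map(labels_by_cluster)
    for col in ("patient_id", "tissue", "sample_id"):
        if col in nm.cell_meta.columns:
            obs[col] = nm.cell_meta.loc[clusters.index, col]
    return AnnotatedCells(obs=obs, module_scores=scores)


def cycle_phase(
    nm: NormMatrix,
    g1s_set: GeneSet,
    g2m_set: GeneSet,
    thresh: float = 0.0,
    n_bins: int = 24,
    n_ctrl: int = 100,
    seed: int = 0,
) -> pd.Series:
    """Per-cell cycling phase from G1/S and G2/M module scores.

    G1S if its score exceeds both the G2/M score and ``thresh``; G2M
    symmetrically; otherwise "non-cycling".
    """
    if g1s_set is None or g2m_set is None:
        raise ValidationError("both G1/S and G2/M gene sets are required")
    s1 = module_score(nm, g1s_set, n_bins=n_bins, n_ctrl=n_ctrl, seed=seed)
    s2 = module_score(nm, g2m_set, n_bins=n_bins, n_ctrl=n_ctrl, seed=seed)
    phase = np.where(
        (s1 > s2) & (s1 > thresh),
        "G1S",
        np.where((s2 > s1) & (s2 > thresh), "G2M", "non-cycling"),
    )
    return pd.Series(phase, index=s1.index, name="cycle_phase")
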