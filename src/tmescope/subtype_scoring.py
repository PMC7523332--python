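"""Score transcriptomic subtype signatures per cell and summarize by group.

Published PDAC subtype gene lists (classic / QM, basal, squamous, ADEX,
...) are user inputs in the two-column gene-set TSV dialect; each is
scored per cell with the expression-matched-control module score, then
summarized by cell type or by patient.  The group with the highest mean
score per signature is flagged — the violin-plot "highest scoring cell
type" readout.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import pandas as pd

from .cell_typing import AnnotatedCells, module_score
from .errors import ValidationError
from .io_formats import GeneSet
from .qc import NormMatrix

logger = logging.getLogger(__name__)


@dataclass
class SubtypeScoreSummary:
    """Per-(signature, group) summary statistics, violin-ready."""

    table: pd.DataFrame  # columns: signature, group, n_cells, mean, median, q25, q75, flagged
    grouping: str  # "cell_type" or "patient"


def score_subtypes(
    nm: NormMatrix,
    ann: AnnotatedCells,
    subtype_sets: list[GeneSet],
    n_bins: int = 24,
    n_ctrl: int = 100,
    seed: int = 0,
) -> pd.DataFrame:
    """One module-score column per subtype signature (cells as rows).

    Sets without any gene in the matrix are skipped with a warning.
    """
    cols = {}
    for gs in subtype_sets:
        try:
            cols[gs.name] = module_score(nm, gs, n_bins=n_bins, n_ctrl=n_ctrl, seed=seed)
        except ValidationError:
            logger.warning("subtype set %s has no genes in the matrix; skipped", gs.name)
    if not cols:
        raise ValidationError("no subtype set overlaps the matrix genes")
    scores = pd.DataFrame(cols)
    return scores.loc[ann.obs.index]


def summarize_by(
    scores: pd.DataFrame, ann: AnnotatedCells, grouping: str = "cell_type"
) -> SubtypeScoreSummary:
    """Summary statistics per group; the highest-mean group is flagged."""
    if grouping == "cell_type":
        labels = ann.labels
    elif grouping == "patient":
        if "patient_id" not in ann.obs.columns:
            raise ValidationError("annotation lacks patient_id metadata")
        labels = ann.obs["patient_id"]
    else:
        raise ValidationError("grouping must be 'cell_type' or 'patient'")

    rows = []
    for sig in scores.columns:
        s = scores[sig]
        grouped = s.groupby(labels)
        stats = pd.DataFrame(
            {
                "n_cells": grouped.size(),
                "mean": grouped.mean(),
                "median": grouped.median(),
                "q25": grouped.quantile(0.25),
                "q75": grouped.quantile(0.75),
            }
        )
        best = stats["mean"].idxmax()
        for grp, r in stats.iterrows():
            rows.append(
                (sig, grp, int(r["n_cells"]), r["mean"], r["median"], r["q25"], r["q75"], grp == best)
            )
    table = pd.DataFrame(
        rows, columns=["signature", "group", "n_cells", "mean", "median", "q25", "q75", "flagged"]
    )
    return SubtypeScoreSummary(table, grouping)


def long_format(scores: pd.DataFrame, ann: AnnotatedCells) -> pd.DataFrame:
    """Cell-level long table (barcode, cell_type, patient, signature, score)."""
    out = scores.copy()
    out["cell_type"] = ann.labels
    if "patient_id" in ann.obs.columns:
        out["patient_id"] = ann.obs["patient_id"]
    id_vars = [c for c in ("cell_type", "patient_id") if c in out.columns]
    return out.reset_index(names="barcode").melt(
        id_vars=["barcode"] + id_vars, var_name="signature", value_name="score"
    )
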