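"""Per-patient cell-type composition tables and tissue-level summaries.

Percentages are 100 * (cells of a type) / (all labeled cells of the
patient); "Unknown" counts in the denominator and appears as its own
column, so every row sums to exactly 100.  Presentation rounding (one
decimal, with "< 0.1" substituted for nonzero values below 0.05) only
happens at export; full precision is kept internally.

A published 16-patient PDAC reference composition (10 primary tumors, 6
metastatic biopsies; columns CAF, DC, EMT, Endo, ETC, TAM, TIL) ships as
package data for cross-checks; its "< 0.1" censored entries are parsed as
0 for computation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

from .cell_typing import AnnotatedCells
from .errors import ValidationError

logger = logging.getLogger(__name__)

REFERENCE_RESOURCE = "pdac_reference_composition.tsv"


@dataclass
class CompositionTable:
    """Patient x cell-type percentages plus per-patient tissue and cell count."""

    fractions: pd.DataFrame  # index patient_id; cell-type columns, percent
    tissue: pd.Series  # per patient
    n_cells: pd.Series  # per patient
    atol: float = 1e-6  # printed/rounded tables may relax this

    def __post_init__(self) -> None:
        sums = self.fractions.sum(axis=1)
        if not np.allclose(sums, 100.0, atol=self.atol):
            raise ValidationError("composition rows must each sum to 100")


def composition(ann: AnnotatedCells) -> CompositionTable:
    """Percentage of each patient's cells carrying each label."""
    obs = ann.obs
    if "patient_id" not in obs.columns:
        raise ValidationError("annotation lacks patient_id metadata")
    counts = pd.crosstab(obs["patient_id"], obs["label"])
    n_cells = counts.sum(axis=1)
    empty = n_cells[n_cells == 0].index
    if len(empty):
        logger.warning("excluding %d patients with zero cells", len(empty))
        counts = counts.drop(index=empty)
        n_cells = n_cells.drop(index=empty)
    frac = counts.div(n_cells, axis=0) * 100.0
    tissue = obs.groupby("patient_id")["tissue"].first().reindex(frac.index) \
        if "tissue" in obs.columns else pd.Series("primary", index=frac.index)
    return CompositionTable(frac, tissue, n_cells)


def composition_summary(ct: CompositionTable, tissue: str | None = None) -> pd.DataFrame:
    """Unweighted per-type mean plus min/max across patients of one tissue."""
    frac = ct.fractions
    if tissue is not None:
        keep = ct.tissue == tissue
        if not keep.any():
            raise ValidationError(f"no patients with tissue {tissue!r}")
        frac = frac.loc[keep[keep].index]
    return pd.DataFrame({"mean": frac.mean(), "min": frac.min(), "max": frac.max()})


def format_table(ct: CompositionTable) -> pd.DataFrame:
    """Presentation view: one decimal, '< 0.1' for nonzero values below 0.05."""
    def fmt(v: float) -> str:
        if 0 < v < 0.05:
            return "< 0.1"
        return f"{v:.1f}"

    out = ct.fractions.map(fmt)
    out.insert(0, "tissue", ct.tissue)
    return out


def load_reference_composition(path: str | Path | None = None) -> CompositionTable:
    """Load the shipped (or a user-supplied) printed composition table.

    Censored "< 0.1" entries are parsed as 0; the printed values are kept
    as-is (their rows sum to ~100 only up to printing precision, so the
    row-sum invariant is relaxed to +/-0.5 for this table).
    """
    if path is None:
        path = resources.files("tmescope.data") / REFERENCE_RESOURCE
    raw = pd.read_csv(str(path), sep="\t", dtype=str).set_index("patient_id")
    tissue = raw.pop("tissue")
    printed = raw.map(lambda s: 0.0 if s.strip().startswith("<") else float(s))
    n_cells = pd.Series(np.nan, index=printed.index, name="n_cells")
    return CompositionTable(printed, tissue, n_cells, atol=0.5)
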