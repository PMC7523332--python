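"""Readers and writers for every on-disk artifact the pipeline touches.

Formats are deliberately plain text: the 10x Genomics MTX triplet
(MatrixMarket coordinate integer ``matrix.mtx`` + ``barcodes.tsv`` +
``features.tsv``, optionally gzipped), two-column gene-set TSVs, and
patient-level expression/clinical TSVs for bulk cohorts.  Cell metadata
(sample, patient, tissue) travels in a ``cell_meta.tsv`` sidecar next to
the triplet rather than being encoded into barcodes, so the triplet itself
stays standard.

Gene identity throughout the package is the *symbol* column of
``features.tsv``; Ensembl-style IDs are carried along as optional metadata.
Duplicate symbols are disambiguated by suffixing ``.1``, ``.2``, ... —
never summed, since summing would silently change counts.
"""

from __future__ import annotations

import gzip
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp

from .errors import FormatError, ValidationError

logger = logging.getLogger(__name__)

TISSUES = ("primary", "metastasis")


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass
class SampleSheet:
    """One row per sample: where its MTX triplet lives and who it came from."""

    table: pd.DataFrame  # columns: sample_id, path, patient_id, tissue

    def __post_init__(self) -> None:
        required = {"sample_id", "path", "patient_id", "tissue"}
        missing = required - set(self.table.columns)
        if missing:
            raise ValidationError(f"sample sheet missing columns: {sorted(missing)}")
        if self.table["sample_id"].duplicated().any():
            raise ValidationError("sample_id values must be unique")
        bad = set(self.table["tissue"]) - set(TISSUES)
        if bad:
            raise ValidationError(f"tissue must be one of {TISSUES}, got {sorted(bad)}")


@dataclass
class CountMatrix:
    """Sparse genes x cells UMI counts with per-cell sample metadata.

    ``cell_meta`` is indexed by barcode and carries ``sample_id``,
    ``patient_id`` and ``tissue`` columns; ``gene_ids`` (optional) holds the
    feature-file ID column aligned with ``genes``.
    """

    genes: list[str]
    cells: list[str]
    counts: sp.csr_matrix  # genes x cells, non-negative integers
    cell_meta: pd.DataFrame
    gene_ids: list[str] | None = None

    def __post_init__(self) -> None:
        self.counts = sp.csr_matrix(self.counts)
        if self.counts.shape != (len(self.genes), len(self.cells)):
            raise ValidationError(
                f"counts shape {self.counts.shape} does not match "
                f"{len(self.genes)} genes x {len(self.cells)} cells"
            )
        if len(self.cell_meta) != len(self.cells):
            raise ValidationError("cell_meta must have one row per cell")
        if self.counts.nnz and self.counts.data.min() < 0:
            raise ValidationError("counts must be non-negative")
        if len(set(self.genes)) != len(self.genes):
            raise ValidationError("gene symbols must be unique (apply suffix policy)")

    @property
    def n_genes(self) -> int:
        return len(self.genes)

    @property
    def n_cells(self) -> int:
        return len(self.cells)

    def umi_per_cell(self) -> np.ndarray:
        return np.asarray(self.counts.sum(axis=0)).ravel()

    def equals(self, other: "CountMatrix") -> bool:
        return (
            self.genes == other.genes
            and self.cells == other.cells
            and (self.counts != other.counts).nnz == 0
            and self.cell_meta.reindex(columns=other.cell_meta.columns).equals(other.cell_meta)
        )


@dataclass
class GeneSet:
    """A named list of gene symbols (marker panel, subtype signature, ...)."""

    name: str
    genes: list[str]

    def __post_init__(self) -> None:
        if not self.genes:
            raise ValidationError(f"gene set {self.name!r} is empty")
        if len(set(self.genes)) != len(self.genes):
            raise ValidationError(f"gene set {self.name!r} has duplicate symbols")


@dataclass
class BulkCohort:
    """Patient x gene expression with overall-survival outcomes.

    ``expr`` is indexed by patient_id; ``clinical`` carries ``os_time`` and
    ``os_event`` (1 = death observed, 0 = censored) on the same index and in
    the same order. Expression values are used as given; the unit string is
    recorded but never interpreted.
    """

    expr: pd.DataFrame
    clinical: pd.DataFrame
    expression_unit: str = "as-provided"

    def __post_init__(self) -> None:
        if not self.expr.index.equals(self.clinical.index):
            raise ValidationError("expr and clinical must share the same patient index")
        if self.expr.columns.duplicated().any():
            raise ValidationError("gene columns must be unique")
        if (self.clinical["os_time"] < 0).any():
            raise ValidationError("os_time must be non-negative")
        if not self.clinical["os_event"].isin([0, 1]).all():
            raise ValidationError("os_event must be 0/1")

    @property
    def patients(self) -> list[str]:
        return list(self.expr.index)

    @property
    def genes(self) -> list[str]:
        return list(self.expr.columns)


# ---------------------------------------------------------------------------
# helpers
# ---------------------------------------------------------------------------


def _find(dir: Path, stem: str) -> Path:
    """Locate stem or stem.gz in dir, else raise FormatError naming the file."""
    for name in (stem, stem + ".gz"):
        p = dir / name
        if p.exists():
            return p
    raise FormatError(f"missing file {stem}(.gz) in {dir}")


def _open_text(path: Path):
    if path.suffix == ".gz":
        return gzip.open(path, "rt", encoding="utf-8")
    return open(path, "rt", encoding="utf-8")


def dedupe_symbols(symbols: list[str]) -> list[str]:
    """Suffix repeated symbols with .1, .2, ... (first occurrence unchanged)."""
    seen: dict[str, int] = {}
    out = []
    for s in symbols:
        k = seen.get(s, 0)
        out.append(s if k == 0 else f"{s}.{k}")
        seen[s] = k + 1
    return out


# ---------------------------------------------------------------------------
# sample sheet
# ---------------------------------------------------------------------------


def read_sample_sheet(path: str | Path) -> SampleSheet:
    path = Path(path)
    if not path.exists():
        raise FormatError(f"sample sheet not found: {path}")
    table = pd.read_csv(path, sep="\t", dtype=str)
    sheet = SampleSheet(table)
    for _, row in table.iterrows():
        p = (path.parent / row["path"]).resolve() if not Path(row["path"]).is_absolute() else Path(row["path"])
        if not p.exists():
            raise ValidationError(f"sample {row['sample_id']}: path does not exist: {p}")
    return sheet


# ---------------------------------------------------------------------------
# 10x MTX triplet
# ---------------------------------------------------------------------------


def read_10x_mtx(dir: str | Path) -> CountMatrix:
    """Read a 10x-style MTX triplet (plus optional ``cell_meta.tsv`` sidecar).

    Accepts gzipped or plain files and the legacy ``genes.tsv`` name for the
    feature file. Counts must be integral; duplicate gene symbols are
    suffixed ``.1``, ``.2``, ...
    """
    dir = Path(dir)
    mtx_path = _find(dir, "matrix.mtx")
    barcodes_path = _find(dir, "barcodes.tsv")
    try:
        features_path = _find(dir, "features.tsv")
    except FormatError:
        features_path = _find(dir, "genes.tsv")

    with _open_text(mtx_path) as fh:
        mat = scipy.io.mmread(fh)
    coo = sp.coo_matrix(mat)
    if coo.nnz and not np.allclose(coo.data, np.round(coo.data)):
        raise ValidationError(f"non-integer entries in {mtx_path}")
    counts = sp.csr_matrix((coo.data.astype(np.int64), (coo.row, coo.col)), shape=coo.shape)

    with _open_text(barcodes_path) as fh:
        cells = [line.rstrip("\n").split("\t")[0] for line in fh if line.strip()]

    gene_ids: list[str] = []
    symbols: list[str] = []
    with _open_text(features_path) as fh:
        for line in fh:
            if not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) >= 2:
                gene_ids.append(parts[0])
                symbols.append(parts[1])
            else:
                gene_ids.append(parts[0])
                symbols.append(parts[0])
    genes = dedupe_symbols(symbols)

    if counts.shape != (len(genes), len(cells)):
        raise FormatError(
            f"matrix.mtx header {counts.shape} does not match "
            f"{len(genes)} features x {len(cells)} barcodes"
        )

    meta_path = dir / "cell_meta.tsv"
    if meta_path.exists():
        cell_meta = pd.read_csv(meta_path, sep="\t", dtype=str).set_index("barcode")
        cell_meta = cell_meta.reindex(cells)
    else:
        cell_meta = pd.DataFrame(
            {"sample_id": dir.name, "patient_id": dir.name, "tissue": "primary"},
            index=pd.Index(cells, name="barcode"),
        )
    return CountMatrix(genes, cells, counts, cell_meta, gene_ids=gene_ids)


def write_10x_mtx(m: CountMatrix, dir: str | Path) -> None:
    """Write the MTX triplet plus ``cell_meta.tsv``; round-trips through
    :func:`read_10x_mtx` bit-faithfully."""
    dir = Path(dir)
    dir.mkdir(parents=True, exist_ok=True)
    coo = sp.coo_matrix(m.counts)
    with open(dir / "matrix.mtx", "w", encoding="utf-8", newline="\n") as fh:
        fh.write("%%MatrixMarket matrix coordinate integer general\n%\n")
        fh.write(f"{m.n_genes} {m.n_cells} {coo.nnz}\n")
        order = np.lexsort((coo.row, coo.col))  # column-major, the MTX convention
        for i, j, v in zip(coo.row[order], coo.col[order], coo.data[order]):
            fh.write(f"{i + 1} {j + 1} {int(v)}\n")
    with open(dir / "barcodes.tsv", "w", encoding="utf-8", newline="\n") as fh:
        fh.writelines(b + "\n" for b in m.cells)
    ids = m.gene_ids if m.gene_ids is not None else m.genes
    with open(dir / "features.tsv", "w", encoding="utf-8", newline="\n") as fh:
        for gid, sym in zip(ids, m.genes):
            fh.write(f"{gid}\t{sym}\tGene Expression\n")
    meta = m.cell_meta.copy()
    meta.index.name = "barcode"
    meta.to_csv(dir / "cell_meta.tsv", sep="\t", lineterminator="\n")


def concat_count_matrices(matrices: list[CountMatrix]) -> CountMatrix:
    """Column-wise concatenation of matrices sharing one gene list."""
    if not matrices:
        raise ValidationError("nothing to concatenate")
    genes = matrices[0].genes
    for m in matrices[1:]:
        if m.genes != genes:
            raise ValidationError("count matrices must share an identical gene list")
    counts = sp.hstack([m.counts for m in matrices], format="csr")
    cells = [c for m in matrices for c in m.cells]
    meta = pd.concat([m.cell_meta for m in matrices])
    return CountMatrix(genes, cells, counts, meta, gene_ids=matrices[0].gene_ids)


def load_samples(sheet: SampleSheet, base_dir: str | Path | None = None) -> CountMatrix:
    """Read every sample of a sheet and concatenate, stamping metadata."""
    parts = []
    for _, row in sheet.table.iterrows():
        p = Path(row["path"])
        if base_dir is not None and not p.is_absolute():
            p = Path(base_dir) / p
        m = read_10x_mtx(p)
        meta = m.cell_meta.copy()
        meta["sample_id"] = row["sample_id"]
        meta["patient_id"] = row["patient_id"]
        meta["tissue"] = row["tissue"]
        cells = [f"{row['sample_id']}:{c}" for c in m.cells]
        meta.index = pd.Index(cells, name="barcode")
        parts.append(CountMatrix(m.genes, cells, m.counts, meta, gene_ids=m.gene_ids))
    return concat_count_matrices(parts)


# ---------------------------------------------------------------------------
# gene-set TSV
# ---------------------------------------------------------------------------


def read_gene_sets(path: str | Path) -> list[GeneSet]:
    """Two-column TSV (set_name, gene) with header -> one GeneSet per name.

    Genes keep file order; duplicates within a set are dropped with a
    warning.
    """
    path = Path(path)
    if not path.exists():
        raise FormatError(f"gene-set file not found: {path}")
    table = pd.read_csv(path, sep="\t", dtype=str)
    if table.shape[1] < 2 or len(table) == 0:
        raise ValidationError(f"gene-set file {path} must have >=2 columns and >=1 row")
    name_col, gene_col = table.columns[:2]
    sets = []
    for name, grp in table.groupby(name_col, sort=False):
        genes, seen = [], set()
        for g in grp[gene_col]:
            if g in seen:
                logger.warning("duplicate gene %s in set %s dropped", g, name)
                continue
            seen.add(g)
            genes.append(g)
        sets.append(GeneSet(str(name), genes))
    return sets


def write_gene_sets(sets: list[GeneSet], path: str | Path) -> None:
    rows = [(s.name, g) for s in sets for g in s.genes]
    pd.DataFrame(rows, columns=["set_name", "gene"]).to_csv(
        Path(path), sep="\t", index=False, lineterminator="\n"
    )


# ---------------------------------------------------------------------------
# bulk cohort
# ---------------------------------------------------------------------------


def read_bulk_cohort(
    expr: str | Path, clinical: str | Path, expression_unit: str = "as-provided"
) -> BulkCohort:
    """Load a patients x genes expression TSV plus a clinical TSV.

    Patients are intersected between the two tables; the clinical table's
    order wins. Expression values are taken as given (the unit is recorded,
    not interpreted).
    """
    expr_df = pd.read_csv(Path(expr), sep="\t", index_col=0)
    clin = pd.read_csv(Path(clinical), sep="\t", dtype={"patient_id": str})
    for col in ("patient_id", "os_time", "os_event"):
        if col not in clin.columns:
            raise ValidationError(f"clinical table missing column {col!r}")
    clin = clin.set_index("patient_id")
    expr_df.index = expr_df.index.astype(str)
    shared = [p for p in clin.index if p in set(expr_df.index)]
    if not shared:
        raise ValidationError("no overlapping patients between expression and clinical tables")
    dropped = (len(expr_df) - len(shared)) + (len(clin) - len(shared))
    if dropped:
        logger.info("dropping %d non-overlapping patients", dropped)
    return BulkCohort(
        expr_df.loc[shared], clin.loc[shared, ["os_time", "os_event"]], expression_unit
    )


def write_bulk_cohort(cohort: BulkCohort, expr: str | Path, clinical: str | Path) -> None:
    ex = cohort.expr.copy()
    ex.index.name = "patient_id"
    ex.to_csv(Path(expr), sep="\t", lineterminator="\n")
    cl = cohort.clinical.copy()
    cl.index.name = "patient_id"
    cl.to_csv(Path(clinical), sep="\t", lineterminator="\n")
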