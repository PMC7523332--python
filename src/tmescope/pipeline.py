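"""End-to-end orchestration with one config, fixed seeds, and a manifest.

``run_all`` executes the stage order QC -> normalize -> embed -> cluster ->
annotate -> composition -> markers/top-20 signatures -> subtype scores ->
survival, writing every stage's outputs as TSV/JSON into a run directory
together with a ``manifest.json`` (parameters, package version, input
checksums, per-stage output files).  Stages whose outputs already exist in
the run directory under an identical config hash are skipped, so partial
reruns resume.  Given the same config and seed, two runs produce
byte-identical TSV outputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import tomllib
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import __version__
from .cell_typing import assign_labels, cluster, load_default_panel
from .composition import composition, composition_summary, format_table
from .errors import ConfigError, TmescopeError
from .io_formats import (
    BulkCohort,
    CountMatrix,
    GeneSet,
    load_samples,
    read_bulk_cohort,
    read_gene_sets,
    read_sample_sheet,
)
from .qc import QcThresholds, embed, log_normalize, qc_filter
from .signatures import find_all_markers, top_k_signature
from .subtype_scoring import score_subtypes, summarize_by
from .survival import signature_survival

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Every stage's parameters in one place; echoed into the manifest."""

    # inputs (paths may be None when objects are passed to run_all directly)
    sample_sheet: str | None = None
    marker_panel: str | None = None  # gene-set TSV; default panel if None
    subtype_sets: str | None = None
    bulk_expr: str | None = None
    bulk_clinical: str | None = None
    # qc
    min_umi: int = 1000
    min_shannon: float = 3.0
    norm_scale: float = 1e4
    # embedding / clustering
    n_hvg: int = 2000
    n_pcs: int = 30
    k_neighbors: int = 20
    resolution: float = 0.8
    # annotation / scoring
    min_margin: float = 0.05
    n_bins: int = 24
    n_ctrl: int = 100
    # markers
    min_pct: float = 0.1
    min_lfc: float = 0.25
    top_k: int = 20
    # survival
    hr_method: str = "mantel-haenszel"
    seed: int = 0

    @classmethod
    def from_toml(cls, path: str | Path) -> "PipelineConfig":
        with open(path, "rb") as fh:
            raw = tomllib.load(fh)
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def _write_tsv(df: pd.DataFrame, path: Path, index: bool = True) -> None:
    df.to_csv(path, sep="\t", index=index, lineterminator="\n")


def run_all(
    cfg: PipelineConfig,
    out_dir: str | Path,
    counts: CountMatrix | None = None,
    cohort: BulkCohort | None = None,
    subtype_sets: list[GeneSet] | None = None,
    resume: bool = True,
) -> Path:
    """Run every applicable stage; returns the run directory.

    Single-cell stages need ``counts`` or ``cfg.sample_sheet``; the survival
    stage runs when a bulk cohort (object or paths) is available and top-20
    signatures were derived. A stage failure aborts with the stage named;
    the manifest records the partial state.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest_path = out / "manifest.json"
    cfg_hash = hashlib.sha256(
        json.dumps(cfg.to_dict(), sort_keys=True).encode()
    ).hexdigest()

    manifest: dict = {
        "package": "tmescope",
        "version": __version__,
        "config": cfg.to_dict(),
        "config_hash": cfg_hash,
        "stages": {},
        "inputs": {},
    }
    if resume and manifest_path.exists():
        try:
            old = json.loads(manifest_path.read_text())
            if old.get("config_hash") == cfg_hash:
                manifest["stages"] = old.get("stages", {})
        except (json.JSONDecodeError, OSError):
            pass

    def done(stage: str) -> bool:
        entry = manifest["stages"].get(stage)
        return bool(entry) and all((out / f).exists() for f in entry["outputs"])

    def record(stage: str, files: list[str]) -> None:
        manifest["stages"][stage] = {
            "outputs": files,
            "checksums": {f: _sha256(out / f) for f in files},
        }
        manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")

    current = "io"
    try:
        # ---- io ---------------------------------------------------------
        if counts is None and cfg.sample_sheet:
            sheet = read_sample_sheet(cfg.sample_sheet)
            manifest["inputs"]["sample_sheet"] = _sha256(Path(cfg.sample_sheet))
            counts = load_samples(sheet, base_dir=Path(cfg.sample_sheet).parent)
        if cohort is None and cfg.bulk_expr and cfg.bulk_clinical:
            cohort = read_bulk_cohort(cfg.bulk_expr, cfg.bulk_clinical)
        if subtype_sets is None and cfg.subtype_sets:
            subtype_sets = read_gene_sets(cfg.subtype_sets)
        panel = (
            {s.name: s for s in read_gene_sets(cfg.marker_panel)}
            if cfg.marker_panel
            else load_default_panel()
        )

        signatures = None
        if counts is not None:
            # ---- qc -----------------------------------------------------
            current = "qc"
            filtered, report = qc_filter(
                counts, QcThresholds(min_umi=cfg.min_umi, min_shannon=cfg.min_shannon)
            )
            if not done("qc"):
                _write_tsv(report.per_cell, out / "qc_per_cell.tsv")
                _write_tsv(report.per_sample, out / "qc_per_sample.tsv")
                record("qc", ["qc_per_cell.tsv", "qc_per_sample.tsv"])

            # ---- normalize / embed / cluster ----------------------------
            current = "embed"
            nm = log_normalize(filtered, scale=cfg.norm_scale)
            emb = embed(
                nm, n_hvg=cfg.n_hvg, n_pcs=cfg.n_pcs,
                k_neighbors=cfg.k_neighbors, seed=cfg.seed,
            )
            clusters = cluster(emb, resolution=cfg.resolution, seed=cfg.seed)

            # ---- annotate -----------------------------------------------
            current = "annotate"
            ann = assign_labels(
                clusters, nm, panel, min_margin=cfg.min_margin,
                n_bins=cfg.n_bins, n_ctrl=cfg.n_ctrl, seed=cfg.seed,
            )
            if not done("annotate"):
                _write_tsv(ann.obs.join(ann.module_scores), out / "annotation.tsv")
                record("annotate", ["annotation.tsv"])

            # ---- composition --------------------------------------------
            current = "composition"
            ct = composition(ann)
            if not done("composition"):
                _write_tsv(format_table(ct), out / "composition.tsv")
                _write_tsv(composition_summary(ct), out / "composition_summary.tsv")
                record("composition", ["composition.tsv", "composition_summary.tsv"])

            # ---- signatures ---------------------------------------------
            current = "signatures"
            markers = find_all_markers(
                nm, ann, min_pct=cfg.min_pct, min_lfc=cfg.min_lfc
            )
            signatures = top_k_signature(markers, k=cfg.top_k)
            if not done("signatures"):
                _write_tsv(markers, out / "marker_table.tsv", index=False)
                sig_rows = [
                    {"set_name": name, "gene": g}
                    for name, gs in signatures.items()
                    for g in gs.genes
                ]
                _write_tsv(pd.DataFrame(sig_rows), out / "top_signatures.tsv", index=False)
                record("signatures", ["marker_table.tsv", "top_signatures.tsv"])

            # ---- subtype scores -----------------------------------------
            if subtype_sets:
                current = "subtype_scores"
                scores = score_subtypes(
                    nm, ann, subtype_sets,
                    n_bins=cfg.n_bins, n_ctrl=cfg.n_ctrl, seed=cfg.seed,
                )
                if not done("subtype_scores"):
                    summary = summarize_by(scores, ann, grouping="cell_type")
                    _write_tsv(summary.table, out / "subtype_scores.tsv", index=False)
                    record("subtype_scores", ["subtype_scores.tsv"])

        # ---- survival ---------------------------------------------------
        if cohort is not None and signatures:
            current = "survival"
            results = {}
            for name, gs in signatures.items():
                try:
                    res = signature_survival(cohort, gs, hr_method=cfg.hr_method)
                except TmescopeError as exc:
                    logger.warning("survival for %s skipped: %s", name, exc)
                    continue
                results[name] = {
                    "chi_square": res.chi_square,
                    "p_value": res.p_value,
                    "hr": res.hr,
                    "ci95": list(res.ci95),
                    "n_high": res.n_high,
                    "n_low": res.n_low,
                }
            if not done("survival"):
                (out / "survival.json").write_text(
                    json.dumps(results, indent=2, sort_keys=True) + "\n"
                )
                record("survival", ["survival.json"])
    except TmescopeError as exc:
        manifest["failed_stage"] = current
        manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
        raise TmescopeError(f"stage {current!r} failed: {exc}") from exc

    manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return out
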