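"""End-to-end pipeline: preprocessing → selection → stability → benchmarks.

Runs the computational stages in a fixed order on file inputs, writes
TSV results plus a machine-readable run manifest (parameters, input
checksums, package version), and is deterministic given the same
configuration and seed.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import pandas as pd

from . import __version__
from .expression import (ExpressionMatrix, GeneAnnotation, ReplicateMap,
                         ValidationError, preprocess)
from .normalize import (delta_cq_normalize, dpcr_regression,
                        expression_ratio_normalize, rank_concordance)
from .selection import (abundance_filter, biotype_filter, intersection_summary,
                        rank_sum_order, top_n_sets)
from .stability import CqTable, stability_suite

log = logging.getLogger("evref")


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class PipelineConfig:
    """All inputs and stage parameters of a pipeline run."""

    expression: str                 # genes × samples TSV
    replicates: str                 # sample → source TSV
    annotation: str                 # gene annotation TSV or GTF
    out_dir: str
    unit: str = "rpkm"              # unit of the expression TSV
    cq: str | None = None           # long-format Cq CSV (optional)
    dpcr: str | None = None         # condition/copies/Cq CSV (optional)
    exclude_genes: str | None = None  # one gene ID per line (optional)
    target: str | None = None       # target gene for normalization
    references: list[str] = field(default_factory=list)
    top_n: int = 1000
    top_k: int = 50
    rpkm_threshold: float = 1000.0
    biotype_keep: str = "protein_coding"
    stability_scale: str = "cq"
    seed: int = 0

    @classmethod
    def from_json(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            return cls(**json.load(fh))


def _sha256(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def _load_annotation(path: str) -> GeneAnnotation:
    if path.endswith((".gtf", ".gff", ".gtf.gz")):
        return GeneAnnotation.from_gtf(path)
    return GeneAnnotation.from_tsv(path)


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute all configured stages; returns the run manifest.

    Output files land in ``config.out_dir``; any stage error raises
    :class:`StageError` naming the stage.
    """
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "package": "evref",
        "version": __version__,
        "parameters": asdict(config),
        "inputs": {},
        "outputs": [],
    }

    stage = "expression_io"
    try:
        log.info("[%s] %s", time.strftime("%H:%M:%S"), stage)
        for key in ("expression", "replicates", "annotation", "cq", "dpcr",
                    "exclude_genes"):
            path = getattr(config, key)
            if path:
                manifest["inputs"][key] = {"path": str(path), "sha256": _sha256(path)}
        matrix = ExpressionMatrix.from_tsv(config.expression, unit=config.unit)
        replicates = ReplicateMap.from_tsv(config.replicates)
        annotation = _load_annotation(config.annotation)
        averaged = preprocess(matrix, replicates, annotation)
    except Exception as exc:  # noqa: BLE001 — stage boundary
        raise StageError(stage, exc) from exc

    stage = "candidate_selection"
    try:
        log.info("[%s] %s", time.strftime("%H:%M:%S"), stage)
        exclude: set[str] = set()
        if config.exclude_genes:
            exclude = {line.strip() for line in open(config.exclude_genes)
                       if line.strip()}
        sets = top_n_sets(averaged, n=config.top_n)
        shared_counts = intersection_summary(sets)
        table = rank_sum_order(averaged)
        shared = set.intersection(*sets.values()) - exclude
        candidates = abundance_filter(table, averaged, shared,
                                      threshold=config.rpkm_threshold,
                                      top_k=config.top_k)
        candidates = biotype_filter(candidates, annotation, keep=config.biotype_keep)
        _write(shared_counts.to_frame(), out_dir / "shared_counts.tsv", manifest)
        report = candidates.table.copy()
        report.index.name = "gene_id"
        _write(report, out_dir / "candidate_report.tsv", manifest)
        survivors = candidates.survivors
    except Exception as exc:
        raise StageError(stage, exc) from exc

    cq_table = None
    if config.cq:
        stage = "stability_suite"
        try:
            log.info("[%s] %s", time.strftime("%H:%M:%S"), stage)
            cq_table = CqTable.from_long_csv(config.cq)
            stability = stability_suite(cq_table, input_scale=config.stability_scale)
            stability.index.name = "gene_id"
            _write(stability, out_dir / "stability.tsv", manifest)
        except Exception as exc:
            raise StageError(stage, exc) from exc

    if cq_table is not None and config.target and config.references:
        stage = "normalization_benchmark"
        try:
            log.info("[%s] %s", time.strftime("%H:%M:%S"), stage)
            rows = []
            for ref in config.references:
                rna = expression_ratio_normalize(averaged, config.target, ref)
                qpcr = delta_cq_normalize(cq_table, config.target, ref)
                # Cq columns are sources here; align on the common labels
                conc = rank_concordance(rna, qpcr)
                rows.append({"reference": ref, "spearman_rho": conc.rho})
            _write(pd.DataFrame(rows).set_index("reference"),
                   out_dir / "concordance.tsv", manifest)
        except Exception as exc:
            raise StageError(stage, exc) from exc

    if config.dpcr:
        stage = "dpcr_benchmark"
        try:
            log.info("[%s] %s", time.strftime("%H:%M:%S"), stage)
            df = pd.read_csv(config.dpcr)
            rel = 2.0 ** -(df["cq_target"] - df["cq_reference"])
            fit = dpcr_regression(df["copies_per_ul"], rel)
            _write(pd.DataFrame([{"slope": fit.slope, "intercept": fit.intercept,
                                  "r_squared": fit.r_squared}]),
                   out_dir / "dpcr_regression.tsv", manifest, index=False)
        except Exception as exc:
            raise StageError(stage, exc) from exc

    manifest["candidates"] = survivors
    with open(out_dir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest


def _write(df: pd.DataFrame, path: Path, manifest: dict, index: bool = True) -> None:
    df.to_csv(path, sep="\t", float_format="%.6g", index=index)
    manifest["outputs"].append(str(path))
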