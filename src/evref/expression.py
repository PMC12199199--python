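"""Expression-matrix containers and preprocessing.

The analysis starts from a gene × sample abundance matrix (raw read counts
or RPKM) together with a map assigning each sequencing replicate to its
biological source (e.g. one of twelve EV-producing cell lines).  Three
preprocessing steps precede candidate selection:

1. RPKM computation from raw counts and gene lengths,
2. zero-masking: a gene undetected in *any* replicate of a source is set to
   zero in *all* replicates of that source, so that "no expression in any
   replicate" becomes "source average is zero",
3. replicate averaging down to one column per biological source.

The fixed pipeline order is zero_mask → average_replicates → selection.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

VALID_UNITS = ("counts", "rpkm")

#: canonical biotype vocabulary used by the candidate biotype filter
BIOTYPES = ("protein_coding", "pseudogene", "lncRNA", "scRNA", "mitochondrial", "other")

# common annotation spellings → canonical biotype
_BIOTYPE_ALIASES = {
    "protein_coding": "protein_coding",
    "protein-coding": "protein_coding",
    "pseudogene": "pseudogene",
    "processed_pseudogene": "pseudogene",
    "unprocessed_pseudogene": "pseudogene",
    "transcribed_processed_pseudogene": "pseudogene",
    "transcribed_unprocessed_pseudogene": "pseudogene",
    "lncrna": "lncRNA",
    "lincrna": "lncRNA",
    "antisense": "lncRNA",
    "scrna": "scRNA",
    "mt_rrna": "mitochondrial",
    "mt_trna": "mitochondrial",
    "mitochondrial": "mitochondrial",
    "other": "other",
}


class ValidationError(ValueError):
    """Raised when an input fails its structural invariants."""


@dataclass
class ExpressionMatrix:
    """Gene × sample abundance matrix with an explicit unit flag.

    Parameters
    ----------
    values
        DataFrame with gene IDs as index and sample (or source) IDs as
        columns.  All entries must be finite and non-negative.
    unit
        Either ``"counts"`` or ``"rpkm"``.  Selection operations require
        ``rpkm``.
    """

    values: pd.DataFrame
    unit: str

    def __post_init__(self) -> None:
        if self.unit not in VALID_UNITS:
            raise ValidationError(f"unit must be one of {VALID_UNITS}, got {self.unit!r}")
        v = self.values
        if v.index.has_duplicates:
            dup = v.index[v.index.duplicated()].unique().tolist()
            raise ValidationError(f"duplicate gene IDs: {dup[:5]}")
        if v.columns.has_duplicates:
            dup = v.columns[v.columns.duplicated()].unique().tolist()
            raise ValidationError(f"duplicate sample IDs: {dup[:5]}")
        arr = v.to_numpy(dtype=float)
        if not np.isfinite(arr).all():
            raise ValidationError("expression values must be finite")
        if (arr < 0).any():
            raise ValidationError("expression values must be non-negative")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    @classmethod
    def from_tsv(cls, path: str | Path, unit: str) -> "ExpressionMatrix":
        """Read a genes-in-rows TSV (first column gene ID, header = samples)."""
        df = pd.read_csv(path, sep="\t", index_col=0)
        df.index = df.index.astype(str)
        df.index.name = None
        df.columns = df.columns.astype(str)
        return cls(df.astype(float), unit)

    def to_tsv(self, path: str | Path) -> None:
        out = self.values.copy()
        out.index.name = "gene_id"
        out.to_csv(path, sep="\t", float_format="%.6g")


@dataclass
class ReplicateMap:
    """Assignment of samples to biological sources (and sources to groups)."""

    sample_to_source: dict[str, str]
    source_to_group: dict[str, str] | None = None

    @property
    def sources(self) -> list[str]:
        seen: dict[str, None] = {}
        for src in self.sample_to_source.values():
            seen.setdefault(src, None)
        return list(seen)

    def samples_of(self, source: str) -> list[str]:
        return [s for s, src in self.sample_to_source.items() if src == source]

    def validate_against(self, matrix: ExpressionMatrix) -> None:
        """Every matrix sample must map to exactly one source."""
        missing = [s for s in matrix.sample_ids if s not in self.sample_to_source]
        if missing:
            raise ValidationError(f"samples without a source assignment: {missing}")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "ReplicateMap":
        """Two-column TSV sample_id/source_id; optional third column group_id."""
        df = pd.read_csv(path, sep="\t", dtype=str)
        if df.shape[1] < 2:
            raise ValidationError("replicate map needs at least two columns (sample, source)")
        sample_to_source = dict(zip(df.iloc[:, 0], df.iloc[:, 1]))
        if len(sample_to_source) != len(df):
            raise ValidationError("duplicate sample IDs in replicate map")
        source_to_group = None
        if df.shape[1] >= 3 and df.iloc[:, 2].notna().any():
            source_to_group = dict(zip(df.iloc[:, 1], df.iloc[:, 2]))
        return cls(sample_to_source, source_to_group)

    def to_tsv(self, path: str | Path) -> None:
        rows = []
        for sample, source in self.sample_to_source.items():
            row = {"sample_id": sample, "source_id": source}
            if self.source_to_group is not None:
                row["group_id"] = self.source_to_group.get(source, "")
            rows.append(row)
        pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


@dataclass
class GeneAnnotation:
    """Per-gene symbol, biotype and length.

    ``table`` is indexed by gene ID with columns ``symbol``, ``biotype``
    (canonical vocabulary, see :data:`BIOTYPES`) and ``length_bp`` (may be
    NaN when only biotypes are needed, e.g. for the biotype filter).
    """

    table: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        required = {"symbol", "biotype", "length_bp"}
        missing = required - set(self.table.columns)
        if missing:
            raise ValidationError(f"annotation missing columns: {sorted(missing)}")
        bad = set(self.table["biotype"].dropna()) - set(BIOTYPES)
        if bad:
            raise ValidationError(f"unknown biotypes: {sorted(bad)}")
        lengths = self.table["length_bp"].dropna()
        if (lengths <= 0).any():
            offenders = lengths.index[lengths <= 0].tolist()
            raise ValidationError(f"non-positive gene lengths: {offenders[:5]}")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.table.index)

    def biotype(self, gene_id: str) -> str | None:
        if gene_id not in self.table.index:
            return None
        b = self.table.at[gene_id, "biotype"]
        return None if pd.isna(b) else str(b)

    def lengths(self, gene_ids: list[str]) -> pd.Series:
        missing = [g for g in gene_ids if g not in self.table.index
                   or pd.isna(self.table.at[g, "length_bp"])]
        if missing:
            raise ValidationError(f"genes without annotated length: {missing[:10]}")
        return self.table.loc[gene_ids, "length_bp"].astype(float)

    @staticmethod
    def normalize_biotype(raw: str) -> str:
        key = str(raw).strip().lower().replace(" ", "_")
        return _BIOTYPE_ALIASES.get(key, "other")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "GeneAnnotation":
        """Read a TSV with columns gene_id, symbol, biotype[, length_bp]."""
        df = pd.read_csv(path, sep="\t", dtype={0: str})
        df = df.set_index(df.columns[0])
        df.index.name = "gene_id"
        df["biotype"] = df["biotype"].map(cls.normalize_biotype)
        if "length_bp" not in df.columns:
            df["length_bp"] = np.nan
        return cls(df[["symbol", "biotype", "length_bp"]])

    @classmethod
    def from_gtf(cls, path: str | Path) -> "GeneAnnotation":
        """Build annotation from a GTF.

        Biotype comes from the ``gene_biotype``/``gene_type`` attribute
        (genes on chromosome MT, or with an MT- symbol prefix, are classed
        mitochondrial).  Gene length is the summed merged-exon span of the
        longest annotated transcript — a consistent convention, which is
        all RPKM requires.
        """
        import gffutils

        db = gffutils.create_db(
            str(path), ":memory:", force=True, keep_order=True,
            disable_infer_genes=True, disable_infer_transcripts=True,
        )
        rows = {}
        for gene in db.features_of_type("gene"):
            gid = gene.attributes.get("gene_id", [gene.id])[0]
            symbol = gene.attributes.get("gene_name", [gid])[0]
            raw_bt = (gene.attributes.get("gene_biotype")
                      or gene.attributes.get("gene_type") or ["other"])[0]
            biotype = cls.normalize_biotype(raw_bt)
            if gene.seqid in ("MT", "chrM", "chrMT") or symbol.startswith("MT-"):
                biotype = "mitochondrial"
            best = 0
            for tx in db.children(gene, featuretype="transcript"):
                spans = sorted((e.start, e.end) for e in db.children(tx, featuretype="exon"))
                merged, total = [], 0
                for s, e in spans:
                    if merged and s <= merged[-1][1] + 1:
                        merged[-1] = (merged[-1][0], max(merged[-1][1], e))
                    else:
                        merged.append((s, e))
                total = sum(e - s + 1 for s, e in merged)
                best = max(best, total)
            rows[gid] = {"symbol": symbol, "biotype": biotype,
                         "length_bp": best if best > 0 else np.nan}
        df = pd.DataFrame.from_dict(rows, orient="index")
        df.index.name = "gene_id"
        return cls(df)

    def to_tsv(self, path: str | Path) -> None:
        out = self.table.copy()
        out.index.name = "gene_id"
        out.to_csv(path, sep="\t", float_format="%.6g")


def compute_rpkm(counts: ExpressionMatrix, annotation: GeneAnnotation) -> ExpressionMatrix:
    """Reads Per Kilobase per Million mapped reads from a raw count matrix.

    RPKM(g, s) = count(g, s) · 1e9 / (length_bp(g) · total_counts(s)), with
    the per-sample total taken as the column sum of the count matrix.
    """
    if counts.unit != "counts":
        raise ValidationError("compute_rpkm requires a matrix with unit='counts'")
    lengths = annotation.lengths(counts.gene_ids)
    totals = counts.values.sum(axis=0)
    zero_cols = totals.index[totals <= 0].tolist()
    if zero_cols:
        raise ValidationError(f"all-zero sample columns: {zero_cols}")
    rpkm = counts.values.mul(1e9).div(lengths.to_numpy(), axis=0).div(totals, axis=1)
    return ExpressionMatrix(rpkm, unit="rpkm")


def zero_mask(matrix: ExpressionMatrix, replicates: ReplicateMap) -> ExpressionMatrix:
    """Zero a gene across all replicates of a source if any replicate is zero.

    Idempotent; applied before averaging so that "no expression in any
    replicate" is equivalent to "source average is zero".
    """
    replicates.validate_against(matrix)
    out = matrix.values.copy()
    for source in replicates.sources:
        cols = [s for s in replicates.samples_of(source) if s in out.columns]
        if not cols:
            continue
        dead = (out[cols] == 0).any(axis=1)
        out.loc[dead, cols] = 0.0
    return ExpressionMatrix(out, unit=matrix.unit)


def average_replicates(matrix: ExpressionMatrix, replicates: ReplicateMap) -> ExpressionMatrix:
    """Arithmetic mean over each source's replicates; one column per source."""
    replicates.validate_against(matrix)
    cols = {}
    for source in replicates.sources:
        samples = [s for s in replicates.samples_of(source) if s in matrix.values.columns]
        if not samples:
            raise ValidationError(f"source {source!r} has no samples in the matrix")
        cols[source] = matrix.values[samples].mean(axis=1)
    return ExpressionMatrix(pd.DataFrame(cols), unit=matrix.unit)


def preprocess(matrix: ExpressionMatrix, replicates: ReplicateMap,
               annotation: GeneAnnotation | None = None) -> ExpressionMatrix:
    """Full preprocessing: (RPKM if counts) → zero-mask → source averages."""
    if matrix.unit == "counts":
        if annotation is None:
            raise ValidationError("count input requires an annotation with gene lengths")
        matrix = compute_rpkm(matrix, annotation)
    masked = zero_mask(matrix, replicates)
    return average_replicates(masked, replicates)
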