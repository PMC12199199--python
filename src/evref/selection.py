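"""Candidate reference-transcript selection.

Starting from a source-averaged RPKM matrix, reference candidates are the
transcripts that are (i) inside every source's top-N abundance set,
(ii) among the top-k of the rank-sum ordering, (iii) at or above an RPKM
floor in *every* source, and (iv) protein-coding.  In the twelve-source EV
study these filters take ~14,000 detected genes to 58 shared transcripts,
11 robustly abundant ones, and 7 protein-coding candidates.

Ranking conventions
-------------------
Within a source, rank 1 is the most abundant gene; ties are broken by
lexical gene-ID order so rank sums are integers and runs are reproducible.
A low rank sum marks a consistently abundant gene.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .expression import ExpressionMatrix, ValidationError, GeneAnnotation


@dataclass
class SharedCounts:
    """Per-source decomposition of top-N sets into common/partial/unique."""

    n_common: int
    partial: pd.Series  # per source: shared with ≥1 but not all others
    unique: pd.Series   # per source: in no other source's set
    n: int              # the top-N set size

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame({"partial": self.partial, "unique": self.unique})
        df.insert(0, "common", self.n_common)
        df.index.name = "source_id"
        return df


@dataclass
class CandidateSet:
    """Ordered candidate table with per-gene filter flags.

    ``table`` is indexed by gene ID in rank-sum order, with boolean columns
    ``passed_top50``, ``passed_rpkm_threshold``, ``passed_biotype`` obeying
    passed_biotype ⇒ passed_rpkm_threshold ⇒ passed_top50.
    """

    table: pd.DataFrame
    threshold: float = 1000.0
    top_k: int = 50
    top_n: int = 1000

    @property
    def survivors(self) -> list[str]:
        """Genes passing every filter applied so far."""
        last = "passed_biotype" if "passed_biotype" in self.table.columns else "passed_rpkm_threshold"
        return list(self.table.index[self.table[last]])

    @classmethod
    def from_gene_list(cls, genes: list[str], **params) -> "CandidateSet":
        """Candidate set for genes already known to pass the abundance filters.

        Useful to apply the biotype filter directly to a published list of
        abundance-filtered transcripts.
        """
        table = pd.DataFrame({"passed_top50": True, "passed_rpkm_threshold": True},
                             index=pd.Index(genes, name="gene_id"))
        return cls(table, **params)


def _source_ranks(avg_matrix: ExpressionMatrix) -> pd.DataFrame:
    """Ordinal within-source ranks (1 = most abundant, lexical tie-break)."""
    genes = np.asarray(avg_matrix.gene_ids)
    ranks = {}
    for source in avg_matrix.sample_ids:
        vals = avg_matrix.values[source].to_numpy(dtype=float)
        order = np.lexsort((genes, -vals))  # descending value, then gene ID
        r = np.empty(len(genes), dtype=int)
        r[order] = np.arange(1, len(genes) + 1)
        ranks[source] = r
    return pd.DataFrame(ranks, index=avg_matrix.gene_ids)


def top_n_sets(avg_matrix: ExpressionMatrix, n: int = 1000) -> dict[str, set[str]]:
    """The n most abundant genes per source (ties by lexical gene-ID order).

    Genes with zero abundance are never included; a source with fewer than
    n positively expressed genes is an error.
    """
    if n > len(avg_matrix.gene_ids):
        raise ValidationError(f"n={n} exceeds the {len(avg_matrix.gene_ids)}-gene universe")
    ranks = _source_ranks(avg_matrix)
    sets = {}
    for source in avg_matrix.sample_ids:
        positive = int((avg_matrix.values[source] > 0).sum())
        if n > positive:
            raise ValidationError(
                f"source {source!r} has only {positive} genes with positive abundance (< n={n})")
        sets[source] = set(ranks.index[ranks[source] <= n])
    return sets


def intersection_summary(sets: dict[str, set[str]]) -> SharedCounts:
    """Common / partially shared / unique counts across per-source sets."""
    if len(sets) < 2:
        raise ValidationError("need at least two sets to intersect")
    names = list(sets)
    common = set.intersection(*sets.values())
    partial, unique = {}, {}
    for name in names:
        others = set.union(*(sets[o] for o in names if o != name))
        uniq = sets[name] - others
        unique[name] = len(uniq)
        partial[name] = len(sets[name]) - len(common) - len(uniq)
    sizes = {len(s) for s in sets.values()}
    return SharedCounts(
        n_common=len(common),
        partial=pd.Series(partial),
        unique=pd.Series(unique),
        n=sizes.pop() if len(sizes) == 1 else max(len(s) for s in sets.values()),
    )


def rank_sum_order(avg_matrix: ExpressionMatrix) -> pd.DataFrame:
    """Per-source abundance ranks, their sum, and the rank-sum ordering.

    Returns a DataFrame indexed by gene ID, sorted ascending by
    ``rank_sum`` (ties by gene ID), with one rank column per source plus
    ``rank_sum`` and ``order_index`` (1-based position in the ordering).
    """
    ranks = _source_ranks(avg_matrix)
    out = ranks.copy()
    out["rank_sum"] = ranks.sum(axis=1)
    # stable sort on a lexically presorted index → ties resolve by gene ID
    out = out.sort_index(kind="mergesort").sort_values("rank_sum", kind="mergesort")
    out["order_index"] = np.arange(1, len(out) + 1)
    return out


def abundance_filter(table: pd.DataFrame, avg_matrix: ExpressionMatrix,
                     shared: set[str], threshold: float = 1000.0,
                     top_k: int = 50, restrict_to_shared: bool = True) -> CandidateSet:
    """Triple filter: shared across all sources, top-k rank sum, RPKM floor.

    ``passed_top50``: gene is in the shared set and within the top-k of the
    rank-sum ordering (by default the ordering restricted to shared genes;
    with ``restrict_to_shared=False`` the genome-wide ordering is used).
    ``passed_rpkm_threshold`` additionally requires source-averaged RPKM ≥
    ``threshold`` in every source — one source below the floor excludes
    the gene.
    """
    universe = set(table.index)
    if universe != set(avg_matrix.gene_ids):
        raise ValidationError("rank-sum table and matrix cover different gene universes")
    unknown = shared - universe
    if unknown:
        raise ValidationError(f"shared genes absent from the matrix: {sorted(unknown)[:5]}")

    if restrict_to_shared:
        sub = table.loc[table.index.isin(shared)]
        top = set(sub.index[:top_k])
    else:
        top = set(table.index[:top_k]) & shared

    robust = (avg_matrix.values >= threshold).all(axis=1)
    out = table.loc[table.index.isin(shared)].copy()
    out["passed_top50"] = out.index.isin(top)
    out["passed_rpkm_threshold"] = out["passed_top50"] & robust.reindex(out.index).fillna(False)
    cs = CandidateSet(out, threshold=threshold, top_k=top_k)
    if not out["passed_rpkm_threshold"].any():
        warnings.warn("abundance filter left no surviving candidates", stacklevel=2)
    return cs


def biotype_filter(candidates: CandidateSet, annotation: GeneAnnotation,
                   keep: str = "protein_coding") -> CandidateSet:
    """Retain only candidates of the kept biotype (default protein-coding)."""
    table = candidates.table.copy()
    active = table.index[table["passed_rpkm_threshold"]]
    missing = [g for g in active if annotation.biotype(g) is None]
    if missing:
        raise ValidationError(f"candidates without a biotype annotation: {missing}")
    biotypes = pd.Series({g: annotation.biotype(g) for g in active})
    table["passed_biotype"] = False
    passed = biotypes.index[biotypes == keep]
    table.loc[passed, "passed_biotype"] = True
    return CandidateSet(table, threshold=candidates.threshold,
                        top_k=candidates.top_k, top_n=candidates.top_n)


def membership_check(avg_matrix: ExpressionMatrix, query_genes: list[str],
                     top_k: int = 50) -> pd.DataFrame:
    """Is each query gene among the top-k of the rank-sum ordering?

    Absent genes are reported non-member with ``in_universe=False``.
    """
    table = rank_sum_order(avg_matrix)
    rows = []
    for gene in query_genes:
        if gene in table.index:
            pos = int(table.at[gene, "order_index"])
            rows.append({"gene_id": gene, "in_universe": True,
                         "order_index": pos, "member": pos <= top_k})
        else:
            rows.append({"gene_id": gene, "in_universe": False,
                         "order_index": pd.NA, "member": False})
    return pd.DataFrame(rows).set_index("gene_id")


def select_variable_target(avg_matrix: ExpressionMatrix,
                           exclude: set[str] | None = None) -> pd.Series:
    """Rank-variability score for choosing a variably expressed target gene.

    Considers genes with positive abundance in every source, scores them by
    the standard deviation of their per-source abundance ranks (high score =
    erratic rank, like RAB13 in the EV study), and returns scores sorted
    descending.  Excluded genes are omitted.
    """
    exclude = exclude or set()
    ranks = _source_ranks(avg_matrix)
    everywhere = (avg_matrix.values > 0).all(axis=1)
    keep = [g for g in avg_matrix.gene_ids if everywhere[g] and g not in exclude]
    if not keep:
        return pd.Series(dtype=float, name="rank_sd")
    scores = ranks.loc[keep].std(axis=1, ddof=1) if ranks.shape[1] > 1 else pd.Series(0.0, index=keep)
    scores.name = "rank_sd"
    return scores.sort_values(ascending=False, kind="mergesort")
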