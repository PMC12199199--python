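"""Reference-gene stability assessment from RT-qPCR Cq tables.

Implements the four classical reference-gene stability algorithms and
their aggregate ranking:

* **Comparative Delta-Ct** — a gene's stability is the mean, over all
  other candidates, of the standard deviation across samples of the
  pairwise Cq difference.  A stable pair differs by a constant number of
  cycles in every sample.
* **BestKeeper** — per-gene SD and CV% of raw Cq, plus the Pearson
  correlation of each gene with the BestKeeper index (the per-sample
  geometric mean of all candidates' Cq).  Genes are ranked by Cq SD.
* **NormFinder** — a model-based estimate of gene-wise variation: Cq is
  mapped to a log2 abundance scale (y = −Cq), an additive gene + sample
  model is fitted, and each gene's residual variance is estimated with the
  degrees-of-freedom correction of Andersen et al.'s model, optionally
  decomposed into intra-group variance and inter-group bias when sample
  groups are supplied.
* **geNorm** — relative quantities Q = E^(Cq_min − Cq) are compared
  pairwise; a gene's M value is the mean SD of its log2 ratios with every
  other candidate, and the least stable gene is excluded stepwise until
  the two most stable remain.

The comprehensive rank is the geometric mean of the four per-algorithm
ranks (the aggregation popularised by RefFinder), ties averaged before
aggregation.

All standard deviations are sample SDs (ddof=1).  Lower values mean more
stable throughout; rank 1 is the most stable gene.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .expression import ValidationError


@dataclass
class CqTable:
    """Gene × sample quantification-cycle table.

    Parameters
    ----------
    values
        DataFrame of Cq values, genes in rows, samples in columns.  NaN
        marks a missing measurement; genes with any missing value are
        dropped (with a warning) before stability analysis.
    efficiency
        Optional per-gene amplification efficiency in (1, 2]; default 2
        (perfect doubling) for every gene.
    groups
        Optional sample → group map (e.g. tissue-origin categories).
    """

    values: pd.DataFrame
    efficiency: pd.Series | None = None
    groups: dict[str, str] | None = None

    def __post_init__(self) -> None:
        if self.values.index.has_duplicates or self.values.columns.has_duplicates:
            raise ValidationError("duplicate gene or sample IDs in Cq table")
        arr = self.values.to_numpy(dtype=float)
        if np.isinf(arr).any():
            raise ValidationError("Cq values must be finite (use NaN for missing)")
        if self.efficiency is not None:
            eff = self.efficiency.reindex(self.values.index)
            if ((eff <= 1) | (eff > 2)).fillna(False).any():
                raise ValidationError("amplification efficiencies must lie in (1, 2]")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    def efficiencies(self) -> pd.Series:
        if self.efficiency is None:
            return pd.Series(2.0, index=self.values.index)
        return self.efficiency.reindex(self.values.index).fillna(2.0)

    def complete(self) -> "CqTable":
        """Drop genes with any missing Cq (no imputation), warning per gene."""
        incomplete = self.values.index[self.values.isna().any(axis=1)]
        if len(incomplete):
            warnings.warn(
                f"excluding genes with missing Cq values: {list(incomplete)}",
                stacklevel=2)
        keep = self.values.drop(index=incomplete)
        eff = None if self.efficiency is None else self.efficiency.drop(
            index=incomplete, errors="ignore")
        return CqTable(keep, eff, self.groups)

    @classmethod
    def from_long_csv(cls, path: str | Path) -> "CqTable":
        """Read a long-format CSV with columns gene, sample, cq[, efficiency][, group]."""
        df = pd.read_csv(path)
        df.columns = [c.strip().lower() for c in df.columns]
        required = {"gene", "sample", "cq"}
        if not required <= set(df.columns):
            raise ValidationError(f"long Cq CSV needs columns {sorted(required)}")
        wide = df.pivot_table(index="gene", columns="sample", values="cq", aggfunc="mean")
        wide.index.name = None
        wide.columns.name = None
        eff = None
        if "efficiency" in df.columns and df["efficiency"].notna().any():
            eff = df.groupby("gene")["efficiency"].first()
        groups = None
        if "group" in df.columns and df["group"].notna().any():
            groups = dict(df.dropna(subset=["group"])
                            .groupby("sample")["group"].first())
        return cls(wide, eff, groups)


def _rank_ascending(values: pd.Series) -> pd.Series:
    """Average-tie ranks, 1 = smallest (most stable)."""
    return pd.Series(stats.rankdata(values.to_numpy()), index=values.index)


def _require(cq: CqTable, min_genes: int) -> pd.DataFrame:
    table = cq.complete().values
    if len(table) < min_genes:
        raise ValidationError(
            f"stability analysis needs at least {min_genes} complete genes, got {len(table)}")
    return table


def delta_ct_stability(cq: CqTable) -> pd.DataFrame:
    """Comparative Delta-Ct stability: mean SD of pairwise Cq differences."""
    table = _require(cq, 3)
    genes = list(table.index)
    arr = table.to_numpy(dtype=float)
    values = {}
    for i, gi in enumerate(genes):
        sds = [np.std(arr[i] - arr[j], ddof=1) for j in range(len(genes)) if j != i]
        values[gi] = float(np.mean(sds))
    out = pd.DataFrame({"delta_ct_value": pd.Series(values)})
    out["delta_ct_rank"] = _rank_ascending(out["delta_ct_value"])
    return out


def bestkeeper(cq: CqTable) -> pd.DataFrame:
    """BestKeeper descriptors: Cq SD, CV%, and correlation with the index.

    The index is the per-sample geometric mean of all candidates' Cq; the
    primary ranking key is the Cq SD (ascending).  The classical advisory
    flag ``sd_acceptable`` marks genes with SD ≤ 1.
    """
    table = _require(cq, 1)
    sd = table.std(axis=1, ddof=1)
    mean = table.mean(axis=1)
    cv = sd / mean * 100.0
    index = pd.Series(stats.gmean(table.to_numpy(dtype=float), axis=0),
                      index=table.columns)
    if np.isclose(index.std(ddof=1), 0.0):
        warnings.warn("BestKeeper index has zero variance; correlations undefined",
                      stacklevel=2)
        r = pd.Series(np.nan, index=table.index)
    elif len(table) == 1:
        r = pd.Series(1.0, index=table.index)
    else:
        r = table.apply(lambda row: np.nan if np.isclose(row.std(ddof=1), 0.0)
                        else float(np.corrcoef(row, index)[0, 1]), axis=1)
    out = pd.DataFrame({
        "bestkeeper_sd": sd,
        "bestkeeper_cv": cv,
        "bestkeeper_r": r,
        "sd_acceptable": sd <= 1.0,
    })
    out["bestkeeper_rank"] = _rank_ascending(out["bestkeeper_sd"])
    return out


def _normfinder_variances(y: np.ndarray) -> np.ndarray:
    """Gene-wise residual variance estimates for the additive model.

    For g genes × n samples with y_ij = α_i + β_j + ε_ij and gene-specific
    Var(ε_ij) = σ_i², the two-way residuals r_ij satisfy
    E[Σ_j r_ij²/(n−1)] = (1 − 2/g)σ_i² + Σ_k σ_k²/g², which inverts to the
    df-corrected estimator below.  Negative estimates truncate to 0.
    """
    g, n = y.shape
    r = y - y.mean(axis=1, keepdims=True) - y.mean(axis=0, keepdims=True) + y.mean()
    s2 = (r ** 2).sum(axis=1) / (n - 1)
    total = s2.sum()
    var = (g / (g - 2)) * (s2 - total / (g * (g - 1)))
    return np.maximum(var, 0.0)


def normfinder(cq: CqTable, input_scale: str = "cq") -> pd.DataFrame:
    """NormFinder stability values (model-based gene-wise variation).

    ``input_scale="cq"`` negates Cq onto a log2 abundance scale
    (y = −Cq); ``"expression"`` takes log2 of positive expression values.
    With sample groups on the table, the stability value combines the
    intra-group residual SD and the inter-group bias of each gene; without
    groups it is the df-corrected residual SD of the additive
    gene + sample model.  Lower is more stable.
    """
    table = _require(cq, 3)
    if input_scale == "cq":
        y = -table.to_numpy(dtype=float)
    elif input_scale == "expression":
        arr = table.to_numpy(dtype=float)
        if (arr <= 0).any():
            raise ValidationError("expression input to normfinder must be positive")
        y = np.log2(arr)
    else:
        raise ValidationError(f"unknown input_scale {input_scale!r}")

    genes = list(table.index)
    samples = list(table.columns)
    if cq.groups:
        group_of = {s: cq.groups.get(s) for s in samples}
        if any(g is None for g in group_of.values()):
            raise ValidationError("grouped NormFinder requires a group for every sample")
        labels = sorted(set(group_of.values()))
        cols = {a: [i for i, s in enumerate(samples) if group_of[s] == a] for a in labels}
        small = [a for a in labels if len(cols[a]) < 2]
        if small:
            raise ValidationError(f"groups with fewer than 2 samples: {small}")
        # sample-centered abundances: remove per-sample (library) effects
        z = y - y.mean(axis=0, keepdims=True)
        group_mean = np.stack([z[:, cols[a]].mean(axis=1) for a in labels], axis=1)
        bias = group_mean - group_mean.mean(axis=1, keepdims=True)
        intra = np.stack([_normfinder_variances(y[:, cols[a]]) for a in labels], axis=1)
        n_a = np.array([len(cols[a]) for a in labels])
        value = (np.abs(bias) + np.sqrt(intra / n_a)).mean(axis=1)
    else:
        value = np.sqrt(_normfinder_variances(y))
    out = pd.DataFrame({"normfinder_value": pd.Series(value, index=genes)})
    out["normfinder_rank"] = _rank_ascending(out["normfinder_value"])
    return out


@dataclass
class GenormResult:
    """geNorm M values, stepwise exclusion order, and final ranking."""

    m_values: pd.Series            # initial M over the full candidate panel
    exclusion_order: list[str]     # first-excluded (least stable) first
    final_pair: tuple[str, str]
    ranking: pd.Series             # rank 1.5/1.5 for the final pair, then 3, 4, ...

    def to_frame(self) -> pd.DataFrame:
        order = {g: i + 1 for i, g in enumerate(self.exclusion_order)}
        return pd.DataFrame({
            "genorm_m": self.m_values,
            "genorm_rank": self.ranking,
            "genorm_exclusion_step": pd.Series(order).reindex(self.m_values.index),
        })


def _log_quantities(cq: CqTable, input_scale: str) -> pd.DataFrame:
    """log2 relative quantities: E^(Cq_min − Cq) per gene, or log2 expression."""
    table = cq.complete().values
    if input_scale == "cq":
        eff = cq.efficiencies().reindex(table.index)
        log2_e = np.log2(eff.to_numpy())[:, None]
        cqs = table.to_numpy(dtype=float)
        return pd.DataFrame(
            (cqs.min(axis=1, keepdims=True) - cqs) * log2_e,
            index=table.index, columns=table.columns)
    if input_scale == "expression":
        arr = table.to_numpy(dtype=float)
        if (arr <= 0).any():
            raise ValidationError("geNorm requires strictly positive quantities")
        return pd.DataFrame(np.log2(arr), index=table.index, columns=table.columns)
    raise ValidationError(f"unknown input_scale {input_scale!r}")


def _genorm_m(log_q: pd.DataFrame) -> pd.Series:
    genes = list(log_q.index)
    arr = log_q.to_numpy(dtype=float)
    m = {}
    for i, gi in enumerate(genes):
        vs = [np.std(arr[i] - arr[j], ddof=1) for j in range(len(genes)) if j != i]
        m[gi] = float(np.mean(vs))
    return pd.Series(m)


def genorm(cq: CqTable, input_scale: str = "cq") -> GenormResult:
    """geNorm expression-stability measure with stepwise exclusion.

    M_j is the mean across other candidates of the SD of log2 quantity
    ratios; the gene with the highest M is removed and M recomputed until
    two genes remain (they share ranks 1–2).  Ties on M break toward the
    lexically last gene ID so exclusion is deterministic.
    """
    log_q = _log_quantities(cq, input_scale)
    if len(log_q) < 3:
        raise ValidationError("geNorm needs at least 3 complete genes")
    initial_m = _genorm_m(log_q)
    remaining = log_q.copy()
    exclusion: list[str] = []
    while len(remaining) > 2:
        m = _genorm_m(remaining)
        worst = m[m == m.max()].index.max()  # lexically last among ties
        exclusion.append(worst)
        remaining = remaining.drop(index=worst)
    pair = tuple(sorted(remaining.index))
    ranking = pd.Series(index=initial_m.index, dtype=float)
    ranking[list(pair)] = 1.5
    for step, gene in enumerate(reversed(exclusion)):
        ranking[gene] = 3 + step
    return GenormResult(m_values=initial_m, exclusion_order=exclusion,
                        final_pair=pair, ranking=ranking)


def genorm_v(cq: CqTable, input_scale: str = "cq") -> pd.Series:
    """Pairwise-variation statistic V(n/n+1) for choosing how many references.

    V_n is the SD across samples of log2(NF_n / NF_{n+1}), where NF_n is
    the geometric mean quantity of the n most stable genes in geNorm's
    reverse-exclusion order.  Advisory only.
    """
    res = genorm(cq, input_scale)
    log_q = _log_quantities(cq, input_scale)
    order = list(res.final_pair) + list(reversed(res.exclusion_order))
    v = {}
    for n in range(2, len(order)):
        nf_n = log_q.loc[order[:n]].mean(axis=0)
        nf_n1 = log_q.loc[order[:n + 1]].mean(axis=0)
        v[f"V{n}/{n + 1}"] = float(np.std(nf_n - nf_n1, ddof=1))
    return pd.Series(v)


def comprehensive_rank(ranks: pd.DataFrame) -> pd.DataFrame:
    """RefFinder-style aggregate: geometric mean of per-algorithm ranks.

    ``ranks`` holds one column per algorithm over a common gene universe.
    The final ordering is ascending by geometric mean, ties broken by
    arithmetic mean of ranks, then lexical gene ID.
    """
    if ranks.isna().any().any():
        raise ValidationError("rank matrix contains missing values (mismatched universes?)")
    geo = np.exp(np.log(ranks.to_numpy(dtype=float)).mean(axis=1))
    out = pd.DataFrame({"comprehensive_value": pd.Series(geo, index=ranks.index)})
    out["mean_rank"] = ranks.mean(axis=1)
    out = out.sort_index(kind="mergesort")
    out = out.sort_values(["comprehensive_value", "mean_rank"], kind="mergesort")
    out["comprehensive_rank"] = np.arange(1, len(out) + 1)
    return out.drop(columns="mean_rank")


def stability_suite(cq: CqTable, input_scale: str = "cq") -> pd.DataFrame:
    """Run all four algorithms plus the comprehensive ranking.

    Returns one row per gene with each algorithm's stability value and
    rank, geNorm's exclusion step, and the comprehensive value/rank,
    ordered by the comprehensive rank.
    """
    complete = cq.complete()
    dct = delta_ct_stability(complete)
    bk = bestkeeper(complete)
    nf = normfinder(complete, input_scale=input_scale)
    gn = genorm(complete, input_scale=input_scale).to_frame()
    merged = dct.join(bk).join(nf).join(gn)
    ranks = merged[["delta_ct_rank", "bestkeeper_rank", "normfinder_rank", "genorm_rank"]]
    comp = comprehensive_rank(ranks)
    merged = merged.join(comp)
    return merged.sort_values("comprehensive_rank")
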