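"""Target-transcript normalization and cross-platform benchmarking.

A target transcript (e.g. a variably expressed gene such as RAB13, or an
engineered cargo mRNA) is normalized against a candidate reference either
as a 2^−ΔCq relative quantity (RT-qPCR, ΔCq = Cq_target − Cq_reference)
or as an RPKM ratio (RNA-seq).  Agreement between quantification
platforms is summarised by the Spearman rank correlation of the
normalized series, and relative RT-qPCR quantification is benchmarked
against digital-PCR absolute copies by ordinary least squares (R² = 1 is
a perfect linear relationship).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .expression import ExpressionMatrix, ValidationError
from .stability import CqTable


@dataclass
class NormalizedSeries:
    """Per-sample relative quantity of a target against one reference."""

    values: pd.Series               # relative value per sample, > 0
    target: str
    reference: str
    method: str                     # e.g. "rnaseq", "library-cDNA qPCR"
    delta_cq: pd.Series | None = None  # Cq_target − Cq_reference where applicable


@dataclass
class ConcordanceResult:
    """Spearman rank agreement between two normalized series."""

    rho: float
    ranks_a: pd.Series              # rank n = highest expression
    ranks_b: pd.Series
    method_a: str = ""
    method_b: str = ""


@dataclass
class RegressionFit:
    """OLS of relative quantity (y) on absolute dPCR copies (x)."""

    slope: float
    intercept: float
    r_squared: float


def delta_cq_normalize(cq: CqTable, target: str, reference: str,
                       method: str = "qPCR") -> NormalizedSeries:
    """Relative target quantity 2^−ΔCq per sample.

    Samples missing either Cq are skipped with a warning.
    """
    if target == reference:
        raise ValidationError("target and reference gene must differ")
    for gene in (target, reference):
        if gene not in cq.values.index:
            raise ValidationError(f"gene {gene!r} not in the Cq table")
    t = cq.values.loc[target]
    r = cq.values.loc[reference]
    ok = t.notna() & r.notna()
    skipped = list(t.index[~ok])
    if skipped:
        warnings.warn(f"samples without both Cq values skipped: {skipped}", stacklevel=2)
    delta = (t - r)[ok]
    rel = np.power(2.0, -delta)
    return NormalizedSeries(values=rel, target=target, reference=reference,
                            method=method, delta_cq=delta)


def expression_ratio_normalize(avg_matrix: ExpressionMatrix, target: str,
                               reference: str, method: str = "rnaseq") -> NormalizedSeries:
    """Relative target quantity RPKM_target / RPKM_reference per source."""
    if target == reference:
        raise ValidationError("target and reference gene must differ")
    for gene in (target, reference):
        if gene not in avg_matrix.values.index:
            raise ValidationError(f"gene {gene!r} not in the expression matrix")
    t = avg_matrix.values.loc[target]
    r = avg_matrix.values.loc[reference]
    ok = r > 0
    dropped = list(r.index[~ok])
    if dropped:
        warnings.warn(f"sources with zero reference RPKM excluded: {dropped}", stacklevel=2)
    return NormalizedSeries(values=(t / r)[ok], target=target,
                            reference=reference, method=method)


def rank_concordance(a: NormalizedSeries, b: NormalizedSeries) -> ConcordanceResult:
    """Spearman ρ between two normalized series over their common samples.

    Values are ranked ascending so the highest expression receives rank n
    (average ranks on ties); ρ = 1 means identical orderings, −1 exactly
    reversed.
    """
    common = a.values.index.intersection(b.values.index)
    if len(common) < 3:
        raise ValidationError("rank concordance needs at least 3 common samples")
    va = a.values.loc[common]
    vb = b.values.loc[common]
    ranks_a = pd.Series(stats.rankdata(va), index=common)
    ranks_b = pd.Series(stats.rankdata(vb), index=common)
    rho = float(stats.spearmanr(va, vb).statistic)
    return ConcordanceResult(rho=rho, ranks_a=ranks_a, ranks_b=ranks_b,
                             method_a=a.method, method_b=b.method)


def dpcr_regression(copies: pd.Series, relquant: pd.Series) -> RegressionFit:
    """OLS of 2^−ΔCq relative quantity on dPCR absolute copies/μl.

    ``copies`` and ``relquant`` are aligned on their index (one entry per
    experimental condition); at least 3 paired conditions are required and
    the copies must vary.
    """
    common = copies.index.intersection(relquant.index)
    if len(common) < 3:
        raise ValidationError("dPCR regression needs at least 3 paired conditions")
    x = copies.loc[common].to_numpy(dtype=float)
    y = relquant.loc[common].to_numpy(dtype=float)
    if np.isclose(np.std(x), 0.0):
        raise ValidationError("absolute copies have zero variance; regression undefined")
    fit = stats.linregress(x, y)
    if np.isclose(np.std(y), 0.0):
        r2 = 0.0
    else:
        r2 = float(fit.rvalue ** 2)
    return RegressionFit(slope=float(fit.slope), intercept=float(fit.intercept),
                         r_squared=r2)
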