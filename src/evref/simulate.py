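"""Synthetic multi-source EV expression, Cq and dPCR data with planted truth.

The generator emulates the statistical structure of the twelve-source EV
RNA-seq study and its validation experiments:

* a gene × replicate RPKM matrix with log-normal abundances (log2 RPKM
  baseline ~ N(5, 3)), twelve biological sources with two to three
  replicates each, per-replicate Bernoulli dropout for low-abundance
  genes, a planted panel of high-abundance low-variance reference genes
  and one variably expressed RAB13-like target;
* RT-qPCR Cq tables derived from the same true abundances,
  Cq = c0 − log2(abundance) + Gaussian noise, so Cq is inversely
  log2-proportional to template amount;
* a loaded-vs-control cargo-mRNA dPCR experiment in which copies/μl are
  Poisson counts proportional to abundance and the loaded condition is a
  fixed fold f above the control.

All three readouts derive from one :class:`SyntheticTruth`, drawn from
independent substreams of a single seed, so they are mutually consistent:
with all noise off, the Spearman ρ between RPKM-ratio and 2^−ΔCq
normalization is exactly 1 and the dPCR loaded/control ratio is exactly f.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np
import pandas as pd

from .expression import ExpressionMatrix, GeneAnnotation, ReplicateMap, ValidationError
from .stability import CqTable

_BIOTYPE_PROBS = {
    "protein_coding": 0.72,
    "pseudogene": 0.10,
    "lncRNA": 0.10,
    "scRNA": 0.03,
    "mitochondrial": 0.01,
    "other": 0.04,
}


@dataclass
class SyntheticConfig:
    """Study-condition parameters of the generator.

    Defaults mirror the design of the EV reference-transcript study:
    12 sources with 3 replicates, ~5000 detected genes, five planted
    reference transcripts whose source-averaged RPKM clears the
    1000-RPKM filter everywhere, and one variably expressed target.
    """

    n_sources: int = 12
    replicates_per_source: int = 3
    n_genes: int = 5000
    n_reference: int = 5
    n_variable: int = 1
    baseline_log2_mean: float = 5.0
    baseline_log2_sd: float = 3.0
    # planted references: baseline log2 RPKM range and inter-source sd
    reference_log2_low: float = 13.0
    reference_log2_high: float = 15.0
    sigma_ref: float = 0.2
    sigma_var: float = 2.0              # variable-target inter-source sd
    background_source_sd: float = 2.5   # inter-source sd of background genes
    sigma_rep: float = 0.3              # replicate noise, log2 scale
    dropout_prob: float = 0.5
    dropout_log2_threshold: float = 1.0
    variable_log2_mean: float = 8.0
    # RT-qPCR model: Cq = cq_intercept − log2(abundance) + N(0, sigma_cq)
    cq_intercept: float = 35.0
    sigma_cq: float = 0.25
    # per-planted-reference extra Cq noise sd (two zero-noise references)
    reference_extra_cq_sd: Sequence[float] = (0.0, 0.0, 1.0, 1.5, 2.0)
    # dPCR loading experiment
    dpcr_scale: float = 10.0            # copies/μl per unit abundance
    fold_enrichment: float = 8.0
    loading_control_log2: float = 8.0   # control-condition target log2 abundance
    prep_factors: Sequence[float] = (1.0, 0.6)  # TFF/UF vs UC loading efficiency
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_reference + self.n_variable > self.n_genes:
            raise ValidationError("more planted genes than genes in the matrix")
        for name in ("sigma_ref", "sigma_var", "sigma_rep", "sigma_cq",
                     "background_source_sd"):
            if getattr(self, name) < 0:
                raise ValidationError(f"{name} must be non-negative")
        if not 0 <= self.dropout_prob <= 1:
            raise ValidationError("dropout_prob must be a probability")
        if len(self.reference_extra_cq_sd) < self.n_reference:
            raise ValidationError(
                "reference_extra_cq_sd needs one entry per planted reference")


@dataclass
class SyntheticTruth:
    """Planted parameters that determine every generated observable."""

    reference_ids: list[str]
    variable_id: str
    source_log2: pd.DataFrame = field(repr=False)  # genes × sources, true log2 abundance
    fold_enrichment: float = 8.0
    seed: int = 0

    def abundance(self) -> pd.DataFrame:
        return np.power(2.0, self.source_log2)


def _rng(config: SyntheticConfig, stream: int) -> np.random.Generator:
    """Independent substream per readout (0 expression, 1 Cq, 2 dPCR)."""
    return np.random.default_rng(
        np.random.SeedSequence(entropy=config.seed, spawn_key=(stream,)))


def generate_expression(config: SyntheticConfig
                        ) -> tuple[ExpressionMatrix, ReplicateMap, GeneAnnotation, SyntheticTruth]:
    """Simulate the replicate-level RPKM matrix plus map, annotation, truth."""
    rng = _rng(config, 0)
    n_g, n_s, n_r = config.n_genes, config.n_sources, config.replicates_per_source
    gene_ids = np.array([f"ENSGS{i:011d}" for i in range(n_g)])
    planted = rng.choice(n_g, size=config.n_reference + config.n_variable, replace=False)
    ref_idx = planted[: config.n_reference]
    var_idx = planted[config.n_reference:]

    baseline = rng.normal(config.baseline_log2_mean, config.baseline_log2_sd, size=n_g)
    baseline[ref_idx] = rng.uniform(config.reference_log2_low,
                                    config.reference_log2_high, size=len(ref_idx))
    baseline[var_idx] = config.variable_log2_mean

    source_sd = np.full(n_g, config.background_source_sd)
    source_sd[ref_idx] = config.sigma_ref
    source_sd[var_idx] = config.sigma_var
    dev = rng.normal(0.0, 1.0, size=(n_g, n_s)) * source_sd[:, None]
    source_log2 = baseline[:, None] + dev

    sources = [f"SRC{i + 1:02d}" for i in range(n_s)]
    samples, sample_to_source = [], {}
    for src in sources:
        for r in range(1, n_r + 1):
            sid = f"{src}_r{r}"
            samples.append(sid)
            sample_to_source[sid] = src
    groups = {src: f"G{(i % 5) + 1}" for i, src in enumerate(sources)}

    rep_noise = rng.normal(0.0, config.sigma_rep, size=(n_g, n_s, n_r))
    values = np.power(2.0, source_log2[:, :, None] + rep_noise)
    low = source_log2 < config.dropout_log2_threshold
    drop = rng.random(size=(n_g, n_s, n_r)) < config.dropout_prob
    values = np.where(low[:, :, None] & drop, 0.0, values)

    matrix = ExpressionMatrix(
        pd.DataFrame(values.reshape(n_g, n_s * n_r), index=gene_ids, columns=samples),
        unit="rpkm")
    replicates = ReplicateMap(sample_to_source, source_to_group=groups)

    biotypes = rng.choice(list(_BIOTYPE_PROBS), size=n_g, p=list(_BIOTYPE_PROBS.values()))
    biotypes[planted] = "protein_coding"
    symbols = np.array([f"GENE{i}" for i in range(n_g)], dtype=object)
    symbols[ref_idx] = [f"REFG{k + 1}" for k in range(len(ref_idx))]
    symbols[var_idx] = [f"VARG{k + 1}" for k in range(len(var_idx))]
    lengths = rng.integers(500, 5001, size=n_g)
    annotation = GeneAnnotation(pd.DataFrame(
        {"symbol": symbols, "biotype": biotypes, "length_bp": lengths},
        index=gene_ids))

    truth = SyntheticTruth(
        reference_ids=list(gene_ids[ref_idx]),
        variable_id=str(gene_ids[var_idx[0]]) if len(var_idx) else "",
        source_log2=pd.DataFrame(source_log2, index=gene_ids, columns=sources),
        fold_enrichment=config.fold_enrichment,
        seed=config.seed)
    return matrix, replicates, annotation, truth


def generate_cq(truth: SyntheticTruth, config: SyntheticConfig,
                genes: Sequence[str] | None = None) -> CqTable:
    """Cq table for a gene subset: c0 − log2(abundance) + Gaussian noise.

    Planted references additionally receive gene-specific extra noise per
    ``config.reference_extra_cq_sd`` (two references carry none, making
    them the ground-truth most stable pair).  Zero-abundance entries give
    a missing Cq.
    """
    rng = _rng(config, 1)
    if genes is None:
        genes = list(truth.reference_ids) + [truth.variable_id]
    missing = [g for g in genes if g not in truth.source_log2.index]
    if missing:
        raise ValidationError(f"genes not in the simulated truth: {missing}")
    log2_ab = truth.source_log2.loc[list(genes)]
    extra = pd.Series(0.0, index=log2_ab.index)
    for k, ref in enumerate(truth.reference_ids):
        if ref in extra.index:
            extra[ref] = config.reference_extra_cq_sd[k]
    noise_sd = np.sqrt(config.sigma_cq ** 2 + extra.to_numpy() ** 2)
    noise = rng.normal(0.0, 1.0, size=log2_ab.shape) * noise_sd[:, None]
    cq = config.cq_intercept - log2_ab + noise
    cq = cq.where(np.isfinite(cq))  # zero abundance → −inf log2 → missing
    return CqTable(cq)


def generate_dpcr(truth: SyntheticTruth, config: SyntheticConfig, target: str,
                  expectation: bool = False) -> pd.DataFrame:
    """Loaded-vs-control dPCR copies/μl for the target across preparations.

    Each preparation (e.g. TFF/UF and UC isolations) has a loading
    efficiency factor; within a preparation the loaded condition's
    expected abundance is ``fold_enrichment`` × the control's.  Copies are
    Poisson counts with mean ``dpcr_scale × abundance`` (the expectation
    itself with ``expectation=True``).
    """
    if target not in truth.source_log2.index:
        raise ValidationError(f"target {target!r} not in the simulated truth")
    rng = _rng(config, 2)
    control = 2.0 ** config.loading_control_log2
    rows = []
    preps = [f"prep{i + 1}" for i in range(len(config.prep_factors))]
    for prep, factor in zip(preps, config.prep_factors):
        for condition, abundance in (("control", control * factor),
                                     ("loaded", control * factor * config.fold_enrichment)):
            mean_copies = config.dpcr_scale * abundance
            copies = mean_copies if expectation else float(rng.poisson(mean_copies))
            rows.append({"prep": prep, "condition": condition,
                         "abundance": abundance, "copies_per_ul": copies})
    return pd.DataFrame(rows, index=[f"{r['prep']}_{r['condition']}" for r in rows])


def generate_loading_experiment(truth: SyntheticTruth, config: SyntheticConfig,
                                target: str, reference: str,
                                expectation: bool = False) -> pd.DataFrame:
    """Paired dPCR copies and RT-qPCR Cq for the loading benchmark.

    Adds target and reference Cq (reference abundance constant across
    conditions: the mean planted-reference level) and the 2^−ΔCq relative
    quantity to the per-condition dPCR table.
    """
    df = generate_dpcr(truth, config, target, expectation=expectation)
    # qPCR noise on its own substream so it never perturbs the dPCR counts
    rng = np.random.default_rng(
        np.random.SeedSequence(entropy=config.seed, spawn_key=(2, 1)))
    ref_log2 = float(truth.source_log2.loc[reference].mean())
    sd = 0.0 if expectation else config.sigma_cq
    cq_t = config.cq_intercept - np.log2(df["abundance"]) + rng.normal(0, 1, len(df)) * sd
    cq_r = config.cq_intercept - ref_log2 + rng.normal(0, 1, len(df)) * sd
    df = df.copy()
    df["cq_target"] = cq_t
    df["cq_reference"] = cq_r
    df["relquant"] = 2.0 ** -(df["cq_target"] - df["cq_reference"])
    return df


def fold_enrichment_estimate(experiment: pd.DataFrame,
                             value_col: str = "copies_per_ul") -> float:
    """Loaded/control ratio of ``value_col``, averaged over preparations."""
    ratios = []
    for _, sub in experiment.groupby("prep"):
        loaded = float(sub.loc[sub["condition"] == "loaded", value_col].mean())
        control = float(sub.loc[sub["condition"] == "control", value_col].mean())
        ratios.append(loaded / control)
    return float(np.mean(ratios))
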