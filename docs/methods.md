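# Methods note

This note records the models, conventions and parameter choices behind
`evref`. It describes what the code computes and why; all empirical
numbers live in the test-suite and `scripts/acceptance.py` outputs, not
here.

## 1. Expression preprocessing

Input is a genes × samples matrix of either raw counts or RPKM, a
replicate map (sample → source, optionally source → group), and a gene
annotation (symbol, biotype, transcript length in bp).

- **RPKM** from counts: `count · 10^9 / (length_bp · total_counts)`,
  with per-sample library sizes. Genes without an annotated length are
  an error, not silently dropped.
- **Zero-masking:** if a gene has zero expression in *any* replicate of
  a source, it is set to zero in *all* replicates of that source before
  averaging. Rationale: a transcript that fails to appear in one
  biological replicate is not a robust cargo of that source, and
  averaging over a dropout would manufacture spurious low abundance.
- **Replicate averaging:** arithmetic mean of replicate RPKM per
  source. The fixed pipeline order is mask → average → selection.

## 2. Candidate selection

- **Top-N sets:** the N (default 1000) most abundant genes per source,
  ordinal ranks with lexical gene-ID tie-break so results are
  deterministic. The intersection across sources defines the *shared*
  set; partial/unique counts are reported alongside.
- **Rank-sum ordering:** genes are ranked per source (rank 1 = most
  abundant) and ordered by the integer sum of ranks, ties broken
  lexically. The ordering is invariant under any per-source strictly
  monotone transform of abundance (a property test enforces this).
- **Abundance filter:** a candidate must be shared by all sources, lie
  in the top-k (default 50) of the rank-sum ordering restricted to the
  shared set, and have ≥ 1000 RPKM (default) in *every* source. The
  "every source" floor is the robustness requirement: a reference must
  be reliably detectable in each source individually.
- **Biotype filter:** keep `protein_coding` (default). Mitochondrial
  rRNA-like, lncRNA, pseudogene and other biotypes are excluded because
  they are poor RT-qPCR reference candidates (aberrant reverse
  transcription, polyadenylation and probe-design issues).
- A **variable-target selector** picks the gene with the largest SD of
  per-source abundance ranks, i.e. a transcript whose relative level
  genuinely differs between sources — the natural demonstration target
  for normalization.

## 3. Stability algorithms

All standard deviations are sample SDs (ddof = 1). Missing Cq values
cause a gene to be dropped (with a warning) before the suite runs; the
algorithms themselves assume complete tables.

- **Comparative Delta-Ct:** for gene *i*, mean over *j ≠ i* of
  `SD_samples(Cq_i − Cq_j)`. Shift-invariant per sample, so global
  loading differences cancel.
- **BestKeeper:** per-gene Cq SD is the primary ranking statistic; CV%
  (= 100·SD/mean Cq) and Pearson *r* against the per-sample geometric
  mean Cq index are reported, plus the conventional SD ≤ 1 advisory
  flag. With a single gene the index correlation is trivially 1; zero
  variance yields an undefined *r* (NaN with a warning).
- **NormFinder (ungrouped default):** on `y = −Cq`, the two-way
  additive model `y_ij = μ + α_i + β_j + ε_ij` is fitted by row/column
  means; with `s_i² = Σ_j r_ij²/(n−1)` from the residuals and
  `S = Σ_k s_k²`, the gene variance estimate is
  `σ̂_i² = (g/(g−2)) · (s_i² − S/(g·(g−1)))`, truncated at 0; the
  stability value is `√σ̂_i²`. The correction removes the bias that the
  fitted sample effects absorb part of each gene's noise. The grouped
  mode returns `|inter-group bias| + √(intra-group variance / n_group)`
  averaged over groups; it deliberately omits the original
  empirical-Bayes shrinkage of group differences — a documented
  simplification that preserves the ordering in the regimes exercised
  here.
- **geNorm:** quantities `Q = E^(Cq_min − Cq)` with efficiency E = 2 by
  default (perfect doubling per cycle; per-gene efficiencies can be
  supplied). `M_j` is the mean over partners *k* of
  `SD_samples(log2(Q_j/Q_k))`. The highest-M gene is excluded stepwise
  until two remain; these share rank 1.5. An M-tie at exclusion removes
  the lexically last gene, keeping runs deterministic. V(n/n+1), the SD
  of `log2(NF_n/NF_{n+1})` over samples with NF the geometric-mean
  normalization factor, is provided as an advisory statistic.
- **Comprehensive rank:** geometric mean of the four method ranks,
  re-ranked; ties broken by arithmetic mean of ranks, then lexically.

## 4. Normalization and benchmarking

- **ΔCq normalization:** relative quantity `2^−(Cq_target − Cq_ref)`
  per sample; samples missing either Cq are skipped with a warning.
- **Expression-ratio normalization:** `RPKM_target / RPKM_ref` per
  source; sources where the reference is zero are excluded with a
  warning.
- **Concordance:** Spearman ρ over the common samples (average ranks on
  ties, highest value gets rank n); at least 3 common samples required.
- **dPCR regression:** ordinary least squares of the ΔCq relative
  quantity on absolute copies/μl across loading-experiment conditions
  (≥ 3 required; constant copies is an error, constant relquant gives
  R² = 0). A linear relation with high R² says the ΔCq readout tracks
  absolute abundance, which is the point of the benchmark. Fold
  enrichment is estimated as the loaded/control ratio averaged over
  preparations, computable from either the copies or the relquant side.

## 5. Synthetic cohort generator

`SyntheticConfig` defaults define the study conditions; they emulate
the magnitudes of a multi-source EV RNA-seq + RT-qPCR study, not any
particular dataset.

| parameter | default | role |
|---|---|---|
| n_sources / replicates_per_source | 12 / 3 | cohort shape |
| n_genes | 5000 | transcriptome scale |
| baseline log2 RPKM | N(5, 3) | background abundance spread |
| background inter-source SD | 2.5 | between-source heterogeneity; calibrated so the shared set and abundance-filter survivors land at the order of magnitude seen in real multi-source EV screens (tens shared, ~10–16 survivors) |
| planted references | 5, baseline log2 ~ U(13, 15), inter-source SD 0.2 | abundant and stable by construction |
| planted variable target | 1, mean log2 8, inter-source SD 2.0 | demonstration target |
| replicate noise SD | 0.3 (log2) | technical replicate scatter |
| dropout | p = 0.5 below log2 abundance 1 | sparsity of weak transcripts |
| Cq model | `35 − log2(abundance) + N(0, 0.25)` | ideal-efficiency qPCR readout |
| per-reference extra Cq SD | (0, 0, 1.0, 1.5, 2.0) | a noise ladder so the stability suite has a planted ordering to recover; the first two references are strictly the most stable |
| dPCR copies | Poisson(10 · abundance) | shot-noise counting |
| loading experiment | fold 8, two preps (1.0, 0.6), loading control log2 8 | benchmark ground truth |

Randomness is split into independent substreams
(`np.random.SeedSequence(seed, spawn_key=(stream,))`): expression, Cq,
dPCR, and loading-experiment qPCR noise. Changing one stage's draws
therefore never perturbs another's, and everything is reproducible from
a single integer seed.

What the generator does **not** emulate: amplification-efficiency
variation between genes, inter-run batch effects, RNA degradation,
between-platform systematic bias beyond independent noise, or realistic
biotype-specific abundance distributions (biotypes are sampled i.i.d.).

## 6. Numerical conventions

- ddof = 1 everywhere a variance/SD over samples is taken.
- All orderings (top-N, rank-sum, geNorm exclusion, comprehensive rank)
  resolve ties deterministically, ultimately by lexical gene ID, so
  repeated runs are byte-identical.
- TSV outputs use `%.6g`; the pipeline manifest records SHA-256
  checksums of inputs and the full parameter set.
- Exit codes: 0 success, 2 input/validation error, 3 stage failure.

## 7. Limitations

- The grouped NormFinder mode omits empirical-Bayes shrinkage (see
  §3); for very small group counts its values differ from the original
  implementation even though orderings generally agree.
- geNorm cannot rank its final pair; both members receive rank 1.5 by
  convention, which propagates into the comprehensive rank.
- The selection cascade presumes RPKM comparability across sources;
  strong library-composition effects would call for a different
  normalization upstream.
- The generator's calibrated heterogeneity (background SD 2.5) targets
  order-of-magnitude realism of shared/survivor counts, not any exact
  published figure; analyses that depend on the precise tail shape of
  between-source variation should not rely on it.
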