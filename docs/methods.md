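# Methods

## Data model and preprocessing

A `TimeSeriesExpression` holds one tissue's gene × time matrix for one
feeding condition, sampled at strictly increasing clock times within a single
24-h cycle (≥ 3 time points; the canonical design uses 12 points every 2 h).
A `StudyDataset` collects all (condition, tissue) series and enforces a
shared time grid within each condition.

Preprocessing order is fixed: biological replicates are averaged
(arithmetic mean per time point) before any filtering or normalization;
detection filtering then keeps genes whose averaged expression exceeds a
threshold (default 0) at every time point; gene-set filtering restricts to an
annotation universe (e.g. mitochondrially annotated genes); min-max
normalization maps each gene to (x − min)/(max − min) across its own time
points. "Detected" has no universal definition for processed expression
matrices; strictly-positive-at-all-time-points is the weakest reading and the
threshold is exposed as a parameter.

Min-max normalization is applied **only** on correlation/clustering paths.
Pearson correlation is invariant under positive per-gene affine maps, so
normalization cannot change any correlation-derived quantity (property-tested
to 1e-10); it exists so that exported matrices and cluster waveforms are
comparable across genes. Amplitude analyses always use unscaled values.
Constant (zero temporal variance) genes are dropped with a warning before any
correlation, since r is undefined for them; pairs involving them appear in
neither numerator nor denominator of any summary.

## Correlation summaries and significance

Within a tissue, all gene pairs are correlated with the sample Pearson
coefficient over the time series (time is treated as plain sample order; no
circular statistics, matching the straight product-moment convention for
these designs). Synchronization strength is the mean |r| over unordered
off-diagonal pairs; a flag reproduces the diagonal-inclusive reading (the
diagonal adds only a constant offset). Significance uses the parametric
transform t = r√(n−2)/√(1−r²) with n−2 degrees of freedom, two-tailed,
**unadjusted**: pair counts at α = 0.05 are descriptive summaries of matrix
structure, not gene-level hypothesis tests, so no multiplicity correction is
appropriate. At n = 12 the critical |r| is 0.576. Counting uses the
equivalent critical-|r| comparison for speed, with an exact p-value fallback
at boundary ties.

Condition contrasts per tissue use an unpaired two-tailed t-test on the two
populations of off-diagonal |r| values (the gene pair is the unit of
observation — a deliberate, isolated choice, since matrix-level contrasts
have no canonical unit), with pooled variance by default and Welch available.

## Hierarchical ordering and wave clustering

All clustering is agglomerative complete linkage on the dissimilarity
d = 1 − r (scipy implementation; deterministic ordering). Matrix display
order comes from the dendrogram leaf order. Temporal waves are obtained by
cutting the tree at a fixed height, default 1.0 — the r = 0 boundary, so
members of one wave are non-negatively correlated. Wave similarity is
computed on per-tissue min-max normalized profiles concatenated in a fixed
(sorted) tissue order, because averaging tissues first can cancel anti-phase
organs; a whole-body-mean mode is available. Genes missing from any tissue
are skipped with a warning in concatenated mode.

## Whole-body synchronization score

For gene g present and non-constant in tissues s = 1..m, the score is the
signed sum of same-gene Pearson correlations over all unordered tissue pairs,
computed as (‖Σ_s z_gs‖² − m)/2 with z the centered unit-norm profiles —
algebraically identical to the pairwise sum but O(T) rather than O(T²) per
gene. |S_g| ≤ C(m, 2), with equality at +C(m,2) iff all pairwise r = 1.
Default eligibility requires presence in every tissue, so all scores share
the C(T, 2) ceiling (231 at T = 22); an opt-out scores genes over their
available pairs and reports `n_pairs_used` per gene.

The clock-like threshold is calibrated from a benchmark panel:

- `largest_gap` (default): midpoint of the single largest drop between
  consecutive sorted benchmark scores;
- `first_gap`: midpoint of the first drop (from the top) exceeding
  f × median gap (f = 3), falling back to `largest_gap` when no drop
  qualifies;
- `manual`: a user-supplied score value.

Midpoint-of-gap is reported as the numeric threshold; the pass set is
identical to "score ≥ the last gene above the drop". Genes pass at
score ≥ threshold.

## Inter-tissue analyses

Tissue-pair matrices are built exactly like intra-tissue ones but across the
tissue boundary, in two first-class modes: `all_pairs` (|genes_A| × |genes_B|
entries; the default for pair-level summaries, consistent with treating the
cross matrix "in the same manner" as the intra matrix) and `same_gene` (the
construction the whole-body score uses). Pair summaries average |entries| and
count significant entries; Σ|r| per tissue sums pair-level mean |r| over
incident pairs — aggregating means rather than raw entry sums keeps tissues
with different gene counts comparable. Relative condition changes are
(TRF − ALF)/ALF (ratio mode available). The network stage exports a plain
edge table; layout/rendering belongs to external graph tools.

## Pathway-term enrichment

Hierarchy paths ("A > B > C", ";"-separated multiples) are split so every
level of every path is one term occurrence for the gene; a term appearing in
two of a gene's paths counts twice (occurrence mode, the default; a per-gene
de-duplicated mode exists because the counting convention in deposited
pipelines of this style is ambiguous). Cluster rankings report term frequency
and term ratio (cluster count / universe count; always in (0, 1]), top 5 per
metric, ties broken by the other metric then alphabetically. "Metabolism" is
excluded by default (case-sensitive after trimming). No p-values: this is a
descriptive composition ranking, not an enrichment test.

## Amplitude

Amplitude is max − min of the replicate-averaged waveform in original units
(no cosinor fit — the convention is range-based; a half-range option is off
by default). Extreme-value ties resolve to the earliest time point for
deterministic peak phases. Per-tissue condition effects are summarized as
log2(TRF/ALF) amplitude ratios tested against 0 with a one-sample t-test;
the raw-ratio-vs-1 alternative is a parameter.

## Synthetic-data generator

Each gene g in tissue s follows
x = b_g + a_{g,s}·cos(2π(t − φ_{g,s})/24) + ε, ε ~ N(0, noise_sd²) per
replicate, negative values clipped at 0 (count logged; rare under the
defaults). Phases encode the planted coordination structure: *aligned* genes
share a per-gene global phase jittered per tissue by N(0, dispersion²)
wrapped mod 24; *benchmark* genes are aligned genes with dispersion × 0.25
and amplitude × 2 (a strong clock-gene panel); *scattered* genes draw
independent uniform phases per tissue and condition. An optional fixed
global-phase grid assigns aligned genes to discrete phase groups (used for
wave-recovery checks). Decoy benchmarks — scattered genes appended to the
panel — emulate the weak tail of a curated clock-gene list and give gap-based
calibration a decline to find.

Defaults are the emulated study conditions: 22 tissues × 12 time points ×
2 replicates × 2 conditions; 500 genes with 10% aligned including 12
benchmarks and 3 decoys; per-tissue phase dispersion 6 h (ALF) vs 1.5 h
(TRF); TRF amplitude gain 1.5 for aligned genes. Where the design prescribes
no value, defaults were chosen once as a realistic regime for normalized
expression data and kept: baseline 10 ± 2, amplitude 3 ± 0.5 (signal
variance ≈ 4.5), replicate noise SD 1 (effective SD ≈ 0.7 after averaging two
replicates, i.e. signal-to-noise ≈ 9 — rhythms clearly detectable but noise
non-negligible). RNG streams are split per (condition, tissue) from the
single seed, so enlarging the tissue panel never reshuffles earlier draws.

What the generator does **not** emulate: count-distribution noise
(negative-binomial sampling, library-size effects), non-sinusoidal waveform
shapes, inter-gene expression correlation beyond shared phase, tissue-
specific baselines, or feeding physiology. Passing tests therefore establish
the correctness and calibration behaviour of the *method* under a known
rhythmic model, not performance guarantees on real RNA-seq data.

## Numerical and determinism choices

Correlations are computed as products of centered unit-norm profile vectors,
clipped to [−1, 1], symmetrized, unit diagonal. Complete-linkage merge
heights match a naive O(G³) agglomeration oracle on tie-free fixtures; tie
order follows scipy's deterministic convention. Written tables use `repr`
float formatting, so write→read round-trips are bit-exact and repeated runs
with one seed are byte-identical. Problem sizes in the test and acceptance
runs (up to 22 tissues × 500 genes) were chosen so the full pipeline
completes in seconds on a single CPU while exercising the full study design.

## Known limitations

- The score treats tissues exchangeably; no weighting by tissue quality or
  gene detectability.
- Gap-based calibration assumes the benchmark panel spans strong and weak
  synchronizers; a panel of uniformly strong genes yields a threshold inside
  the strong cluster (the decoy mechanism exists for exactly this reason).
- The t-test on |r| populations treats gene pairs as independent
  observations, which overstates degrees of freedom; p-values are comparative
  descriptors, consistent with the descriptive framing of the pair counts.
- No rhythmicity testing (cosinor/JTK-style) and no multiple-testing
  correction, by design.
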