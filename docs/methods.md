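# Methods

This note documents the statistical procedures, the default parameters and
why they were chosen, the design decisions taken where the design was
genuinely open, and the limits of what the synthetic benchmark demonstrates.

## Preprocessing

Probe-level signals pass through a fixed three-step chain.

1. **Quality filter.** Entries with signal-to-noise ratio strictly below 2
   are marked undetected (the strict inequality matters: snr = 2.0 is
   retained).  The cutoff is configurable (`snr_min`, default 2).
2. **Log + mean scaling.** Detected intensities greater than 1 are replaced
   by ln x divided by the mean of the same sample's logged detected
   intensities.  Two readings were open here and are resolved as follows:
   * the mean is *per sample*, over its own detected logged intensities —
     this keeps each sample's scaling self-contained;
   * intensities in (0, 1] are treated as undetected rather than clamped,
     because "greater than 1" is a strict condition and the logarithm of
     such values would produce nonpositive pseudo-intensities.
   The log base is provably immaterial — a change of base rescales numerator
   and denominator alike — and this is property-tested by running the step
   with bases e and 10.
3. **Relative intensity.** Each detected entry is divided by its sample
   total, so every sample's detected probes sum to exactly 1.  This step is
   idempotent; the per-sample sum-to-one invariant (±1e−9) is asserted
   throughout the test suite.  A sample left with no usable probes raises a
   `DegenerateSampleError` naming the sample.

Differences of relative intensities are reported in percentage points
(fraction × 100), matching how such deltas are conventionally quoted.

## Diversity and category comparisons

Indices are computed on each sample's relative intensities: richness S
(detected count), Shannon H (nats), inverse Simpson 1/Σp², Pielou H/ln S,
Simpson evenness (1/Σp²)/S.  S = 1 leaves Pielou undefined; it is reported
as NaN with a warning.  All group comparisons use the Welch
(unequal-variance) form of the t test: where only "Student t tests" is
specified, Welch is the safer default under unequal group variances, and
with balanced groups of equal variance it coincides with the pooled test.

Group-level "detected" means detected in at least one of the group's
samples; the shared/unique partition and its shared percentage
(|A∩B| / |A∪B| × 100) are computed on those sets.

## Community tests

Bray–Curtis dissimilarity d(i,j) = Σ|x_i − x_j| / Σ(x_i + x_j) feeds three
permutation tests, each implemented from its defining statistic:

* **PERMANOVA**: pseudo-F from the distance-based sum-of-squares
  decomposition, SS_total = Σ_{i<j} d²/N and SS_within pooled per group.
* **ANOSIM**: R = (mean between-group rank − mean within-group rank)/(M/2),
  M = N(N−1)/2, with midrank ties.
* **MRPP**: δ = Σ_g (n_g/N) · mean within-group distance, weights n_g/N
  (the conventional choice); chance-corrected A = 1 − δ/E[δ] with E[δ] the
  permutation mean.

For two-group designs with at most 10,000 distinct label assignments the
engine enumerates all of them (6+6 gives 924), making p values exact and
seed-independent; otherwise it samples 999 permutations and applies the
(x+1)/(n+1) convention, so p is never 0.  PERMANOVA and ANOSIM reject for
large statistics; MRPP rejects for *small* δ, so its p value counts
assignments with δ ≤ observed.  Exact enumeration is implemented for
two-group designs only; multi-group designs fall back to sampling.

Ordination is classical PCoA (double-centering of squared dissimilarities).
Negative eigenvalues — the signature of non-Euclidean dissimilarities — are
reported, never silently dropped; coordinates use the positive part of the
spectrum, with a deterministic sign convention.

## RMT network inference

Within each lake, Pearson correlations are computed across that lake's
samples for genes detected in at least half of them (correlation over 6
samples is fragile already; heavier missingness makes it meaningless).  By
default the matrix is restricted to the ten core element-cycling gene
families (cellobiase, FTHFS, gdh, rubisco, glucoamylase, mcrA, narG, nrfA,
sox, xylA); `families=None` uses all detected genes.  Zero-variance genes
are excluded with a warning.

**Threshold selection.** For each candidate threshold the matrix is
hard-thresholded (|r| < S_t → 0, unit diagonal kept) and its eigenvalue
nearest-neighbor spacing distribution tested against the Poisson law
P(s) = e^(−s):

* *Degeneracy collapse.* Thresholded matrices carry heavily degenerate
  eigenvalues — isolated rows contribute exact 1s, and a correlation matrix
  estimated from n samples has rank < n, contributing exact 0s.  Duplicates
  (to 8 decimals) are collapsed to one representative before unfolding;
  otherwise zero spacings swamp the statistics.  At least 100 distinct
  eigenvalues (configurable) are required to evaluate a threshold.
* *Unfolding.* The cumulative spectral function is interpolated by a
  monotone piecewise cubic (PCHIP) through quantile knots, about one knot
  per 15 levels (capped at 15).  This local, monotone unfolding adapts to
  the strongly non-uniform spectra of thresholded matrices (a dense bulk
  plus isolated block eigenvalues), where a global polynomial fit badly
  distorts the spacings; the polynomial variant remains available
  (`method="poly"`, default degree 5).  Unfolded spacings are rescaled to
  mean exactly 1.  The type-I error of the resulting test at α = 0.05,
  measured on Poisson-spaced spectra of 60–500 levels, is 0.03–0.06.
* *Goodness of fit.* Chi-square on bins of width 0.5 over s ∈ [0, 5] with
  an open right tail, pooling sparse tail bins to an expected count of at
  least 5; α_rmt = 0.05.

S_t is the smallest grid value (default grid 0.30–0.99, step 0.01) whose
NNSD is Poisson-consistent — the transition-detection convention of
RMT-based network pipelines.  Far above the transition the matrix fragments
into many near-identical 2–3-gene blocks whose near-degenerate eigenvalues
cluster and reject Poisson again; those rejections are over-thresholding
artifacts, not part of the GOE→Poisson transition, so they do not veto the
selection (requiring consistency at *every* larger threshold turns out to be
unsatisfiable on few-sample data for exactly this reason).  With 6 samples
per group the Poisson-consistent window can shrink to a single grid point
whose p hovers around α; the pipeline then falls back to the most
Poisson-like threshold among those retaining at least half the genes'
eigenvalues, flagged as `max_p_fallback` in the report, and the full
per-threshold trace is always returned for audit.

**Network and topology.** Edges connect gene pairs with |r| ≥ S_t, carrying
the correlation's sign; thresholding uses |r| so that one threshold yields
both positive and negative links.  Degree-0 genes are dropped — "network
size" counts connected genes.  Statistics: avgK = 2L/n (an exact identity,
asserted as such); harmonic geodesic distance HD = (n(n−1)/2)/Σ(1/d_ij)
with disconnected pairs contributing zero reciprocal distance, which keeps
HD finite on the heavily fragmented networks this method produces; average
clustering including degree-<2 nodes as 0; R² of the OLS fit of
log frequency on log degree over nonempty degree bins (a scale-free
screening statistic, not a rigorous power-law estimator); modularity from
CNM greedy agglomeration (networkx implementation, deterministic for a
fixed graph; communities are reported ordered by smallest member).  Hub
genes are the top-k by degree, ties broken by gene ID.

## Null model

The "random network" ensemble is Maslov–Sneppen double-edge-swap
randomization holding every node's degree fixed.  The chain performs
`swap_factor × L` *attempts* (default 10×L), counting proposals rejected for
self-loops or duplicate edges; the lazy switch chain with uniformly proposed
edge pairs has the uniform distribution over degree-constrained simple
graphs as its stationary law, which the test suite verifies against
exhaustive enumeration on a 7-node graph (chain means within 2 Monte-Carlo
SEs of the enumeration means, stable from 10×L to 30×L).  Graphs admitting
no valid swap (stars, a lone triangle) are returned unchanged with a
warning.  Edge signs are reassigned at random, preserving the global
positive/negative counts.  Connectedness is *not* enforced — the empirical
networks are themselves highly disconnected.

Ensembles default to 100 replicates with per-replicate seeds derived from a
master seed by fixed increments.  For HD, avgCC and modularity the summary
reports the null mean ± SD and z = (empirical − mean)/SD; "significantly
non-random" is operationalized as |z| > 2, with no normality assumption
beyond that convention.  A zero null SD yields an infinite z with a
degeneracy flag.

## Synthetic data generator

The generator emulates the statistical regime of a two-lake GeoChip-style
comparison; its defaults are the package's study conditions.

* **Catalog**: configurable probe count across 12 functional categories
  with realistic weights; gene families per category include the ten core
  element-cycling families; phylogenetic domains drawn with weights
  proportional to the study-scale counts (archaea 1065 : fungi 3708 :
  bacteria 33732 : unclassified 483).
* **Detectability**: each probe has a latent uniform shared between lakes;
  a lake detects the probe if the latent falls below its richness fraction
  (defaults 0.83 for HL, 0.68 for RAL — a per-sample richness ratio of
  ~1.22), XOR a small independent flip (2%).  The nearly nested construction
  reproduces the strongly asymmetric unique-gene counts of real two-lake
  comparisons.  Detected probes additionally drop out per sample with
  probability 0.08, giving within-group richness variance.  Undetectable or
  dropped probes are still emitted with S/N drawn below 2, so the quality
  filter is genuinely exercised.
* **Intensities**: lognormal, log-scale location 2.0 and scale 0.6.
  Category effects multiply the first lake's raw intensities (defaults:
  carbon ×1.15, nitrogen ×1.12, sulfur ×0.85, phosphorus ×0.85).  These
  sizes were set so that planted effects are reliably detectable (p < 0.05
  in ≥80% of replicates) with 6 samples per lake after the per-sample
  normalization — the regime in which such category differences are
  reported as consistently significant.
* **Correlated blocks**: module members' log-intensities are
  z = sign·√ρ·f + √(1−ρ)·ε with a per-sample, per-module latent factor f,
  so the expected within-module Pearson correlation is exactly ρ
  (alternating signs for negative ρ).  Defaults plant 30 modules of 10
  probes at ρ = 0.85 in the HL-like lake and 7 modules of 20 probes at
  ρ = 0.98 in the RAL-like lake, inside the core network families: many
  small, weakly cohesive blocks versus fewer, larger, tighter ones.  This
  mirrors the empirical contrast in RMT-thresholded functional gene
  networks — the humic lake's network fragments into hundreds of small
  modules with low clustering, the clearwater lake's is more locally
  cohesive — and makes the pipeline report HD_HL > HD_RAL and
  avgCC_HL < avgCC_RAL in roughly 85% of replicate datasets at the default
  6+6 design.  That figure sits close to its 80% acceptance line on
  purpose-free grounds: with 6 samples the Pearson sampling error is ~0.45,
  so the lake contrast travels through one grid step of threshold
  selection and is intrinsically marginal.  An optional global background
  correlation (default 0) supports calibration experiments.

**What the generator does not model**: probe cross-hybridization and dye
chemistry, sequence-level structure, spatial array artifacts,
between-array batch effects, heavy-tailed sample-level covariance beyond
the planted factors.  Passing tests therefore show that the algorithms
recover known structure under the stated statistical assumptions — not that
real GeoChip data satisfy those assumptions.

## Problem sizes used in the test and acceptance suites

* Unit fixtures: 800–3,000 probes, 6+6 samples.
* Planted-effect recovery: 20 replicates at the full default configuration
  (5,000 probes).
* Lake-contrast direction: 100 replicates at the default configuration.
* Threshold recovery: 25 replicates, 600 genes, modules at ρ = 0.95 over a
  0.2 background, **16 samples per group** — at n = 6 the Pearson sampling
  error (~0.45) exceeds the background correlation itself, so threshold
  recovery is only a meaningful calibration at a sample size where
  correlations are estimable (at n = 16 the error is ~0.26 against a 0.75
  separation).
* NNSD calibration: 100 Poisson and 100 GOE spectra of 350 levels; type-I
  error additionally measured on 500 spectra of 300 levels.
* Null-model exactness: exhaustive enumeration of all 460 simple graphs on
  7 nodes with the reference degree sequence, against 400-sample chains.

## Known limitations

* Pearson correlation over 6 samples is statistically fragile; roughly
  0.4% of null gene pairs exceed |r| = 0.95 at n = 6, so a substantial
  share of links at any realistic threshold is sampling noise.  The
  package reports this regime faithfully rather than repairing it; studies
  wanting stable networks need more replicates per site.
* The NNSD transition on few-sample data can be a single grid point; the
  audit trace and the `st_method` flag exist so users can see when the
  fallback fired.
* The power-law R² is a screening statistic on log–log binned frequencies;
  it is not a maximum-likelihood exponent fit and should not be read as a
  rigorous scale-free test.
* Exact permutation enumeration covers two-group designs only; multi-factor
  or stratified designs are out of scope.
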