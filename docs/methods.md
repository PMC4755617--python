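# Methods

## The ecosystem diversity index

A tumor section is represented as a set of classified cells — cancer,
lymphocyte, or stromal — with coordinates in micrometres.  The section is
divided into square regions (quadrats) of side `r` (default 200 μm), and
each region `j` is scored with the Shannon diversity index of its
cell-type proportions,

    d_j = − Σ_i p_i ln p_i ,      i ∈ {cancer, lymphocyte, stromal},

with the usual entropy convention `0·ln 0 = 0`.  With m = 3 classes
`0 ≤ d_j ≤ ln 3 ≈ 1.0986` nats: 0 for a region dominated by one class,
ln 3 for exact equal thirds.  The natural logarithm is a fixed convention;
any base rescales all scores monotonically.

The vector of regional scores D = (d_1, …, d_n) from all sections of a
tumor is pooled and modelled as a univariate Gaussian mixture,

    D ~ Σ_{k=1..K} ω_k N(μ_k, σ_k²),

with unequal per-component variances.  For each K in 1..5 the mixture is
fitted by EM and scored with the Bayesian information criterion

    BIC(K) = −2 log L + (3K − 1) ln n ,

with 3K − 1 free parameters (K means, K variances, K − 1 weights).  The
K minimising BIC — ties broken toward the smaller K — is the tumor's
**ecosystem diversity index (EDI)**: the number of distinct levels of
local microenvironmental diversity coexisting in the tumor.  Components
are reported in ascending order of mean, so cluster 1 is the
lowest-diversity cluster and cluster K the highest; each retained region
receives the maximum-posterior component as its cluster label, which maps
the mixture back onto the section for inspection.  Tumors with EDI = 5
form the "EDI-high" subtype; 1–4 are "EDI-low".

## Parameters that matter

| parameter        | default | units  | why |
|------------------|---------|--------|-----|
| `region_size`    | 200     | μm     | the scale with the highest clustering stability (166 μm is a close second); configurable, and `scale_scan` reports the evidence per scale |
| `min_cells`      | 10      | cells  | proportions from a handful of cells make d_j unstable; excluded regions are counted and reported |
| `min_regions`    | 5       | regions| below this the mixture fit is meaningless |
| `k_max`          | 5       | —      | caps the index and avoids vanishingly small clusters |
| `n_restarts`     | 10      | —      | EM restarts: one quantile-spread initialisation plus random-mean restarts; the best log-likelihood wins |
| `tol`            | 1e-8    | loglik | EM stopping rule on the log-likelihood increase |
| `variance_floor` | 1e-6    | nats²  | lower bound on σ_k², preventing likelihood blow-up on (near-)coincident scores |
| `random_state`   | 0       | —      | seeds the restarts; identical inputs + seed give bit-identical results |

Fits are a function of the *multiset* of scores (data are sorted
internally), so region order never affects the result; this also makes
the full-data subtype exactly reproducible when all regions are
"subsampled" at fraction 1.0.

## EM details

K = 1 is solved in closed form (sample mean and variance).  For K ≥ 2 the
E and M steps are the standard responsibility-weighted updates in one
dimension, with variances floored after every M step.  The first start
places means at the (i + ½)/K quantiles of the data with equal weights
and the pooled variance; remaining starts draw means uniformly from the
data range.  A fit that exhausts `max_iter` (500) without the
log-likelihood increment dropping below `tol` is flagged
`converged=False` rather than raised.

Goodness of fit is summarised per tumor by the Pearson correlation
between the sorted scores and the mixture quantiles at plotting positions
(i − ½)/n, the quantiles obtained by monotone numerical inversion of the
mixture CDF.  The diagnostic is NaN (flagged, not an error) for n < 3 or
zero-variance data.

## Scale and stability experiments

* `scale_scan` re-tiles, re-scores and re-selects K at several region
  sizes (default 166, 200, 250, 333, 500 μm) and reports cells/region,
  regions/tumor, the EDI and the Q-Q diagnostic per size.  Sizes that
  leave too few regions are marked unavailable, not fatal.
* `clustering_instability` is the standard deviation of the selected K
  over bootstrap resamples of the regions.  The bootstrap is *smoothed*:
  resampled scores are jittered with a Gaussian kernel at the Silverman
  bandwidth `0.9·sd·n^(−1/5)`.  A plain bootstrap duplicates continuous
  scores exactly, and an unequal-variance mixture fits those ties as
  spurious variance-floor spike components, inflating K on essentially
  every replicate; the smoothed bootstrap restores the continuity of the
  underlying score distribution and is the standard remedy when
  resampling continuous data.
* `region_subsample_stability` draws subsets of round(f·n) regions
  *without* replacement (modelling loss of tumor area, not a variance
  estimate — hence no replacement), re-selects K, dichotomises at
  EDI = 5, and reports agreement with the full-data subtype over
  (default) 200 repeats for f ∈ {1.00, 0.95, 0.90, 0.85, 0.80}.
* `cross_scale_correlation` reports the Pearson correlation of per-tumor
  EDI vectors between sizes over a cohort; entries for a size with
  constant EDI are undefined (NaN) and the diagonal is 1 by convention.

All resampling is driven by a single seed and is reproducible
bit-for-bit.

## Cohort statistics

Survival analysis uses disease-specific survival administratively
censored at 120 months (the 10-year endpoint): times beyond the cap are
set to 120 with the event flag cleared, applied idempotently at
validation.  Kaplan–Meier curves and the log-rank test compare EDI
subtypes; Cox proportional-hazards models (Efron handling of ties, via
lifelines) provide uni- and multivariate hazard ratios with 95%
confidence intervals.  Rank-deficient designs and non-convergence are
raised as errors rather than silently reported.

The combined prognostic index crosses the EDI subtype with TP53 status:
favorable (EDI-low ∧ TP53 wild-type, code 0), adverse (EDI-high ∧ TP53
mutant, code 2), intermediate (all others, code 1); the ordinal code
enters a Cox model as a single covariate.

Copy-number enrichment tests each gene and direction (gain: call > 0,
loss: call < 0) with a two-sided Fisher's exact test of the 2×2
group-by-aberration table; genes with no variation are reported with
p = 1 and flagged.  Raw p-values are reported alongside
Benjamini–Hochberg adjusted ones.  The expression screen computes
per-gene Pearson correlation with the EDI score and converts the
correlation-test p-values to tail-area (Storey-type) q-values: π₀ is
estimated from the right tail of the p-value histogram on a λ grid of
0.05–0.95, smoothed with a cubic spline and evaluated at the largest λ.
Genomic instability is the aberrant fraction of total segment length.

## What the synthetic data emulate — and what they do not

`simulate_cellmap` builds habitat mosaics: axis-aligned rectangular
habitats, each with a fixed cell-type composition and density, populated
by a homogeneous Poisson process with independent multinomial cell types.
The default K-level mosaic (`mosaic_spec`) uses one horizontal strip per
diversity level, aligned with the default 200-μm grid so the intended
number of regional-diversity levels is unambiguous, with target Shannon
levels evenly spaced in [0.15, 1.06] nats.

Two generator settings are design rules rather than arbitrary choices:

* **5-SD separation.** The sampling SD of the plug-in Shannon score from
  a region with `c` cells is ≈ 0.83/√c at the worst composition.  The
  defaults (300 expected cells/region, levels ~0.23 nats apart for K = 5)
  keep adjacent mixture components ≈ 5 sampling SDs apart, the separation
  at which component-count recovery is reliable.
* **Distance from the entropy boundary.** A habitat with Shannon level
  very near 0 yields many exactly single-type regions, i.e. a point mass
  at d = 0 that a mixture correctly resolves as an extra spike component.
  The lowest default level (0.15 nats) keeps the score distribution
  continuous so the intended K is also the statistically correct K.

Features of real H&E data the mosaics do *not* emulate: irregular tissue
boundaries and holes, spatially varying density, cell-classification
error (an optional label-flip rate could be added, but sampling noise is
deliberately the only noise source), gradual habitat transitions, and
section-to-section differences within a tumor.  Passing recovery tests
therefore demonstrate the statistical behaviour of the estimator under
its own model, not robustness to image-analysis artefacts.

One consequence worth knowing: when the tiling is incommensurate with the
habitat geometry (e.g. scanning a strip mosaic at 166 μm), boundary
sliver tiles have genuinely lower occupancy and hence higher sampling
variance of d_j, which an unequal-variance mixture can read as an extra
component.  This is a property of quadrat scores under partial tiles, not
an artefact of the implementation; on real sections the min-cell filter
and the scale sweep are the instruments for judging it.

`simulate_cohort` draws exponential survival times under exact
proportional hazards with uniform censoring calibrated numerically to a
target censoring rate; `simulate_cna` plants an aberration block with
multiplied odds in the EDI-high group; `simulate_expression` provides
null or planted-signal screens.

## Numerical choices and degenerate inputs

* Half-open tiles `[x0 + c·r, x0 + (c+1)·r)` assign every cell to exactly
  one region; the grid origin defaults to the per-section bounding-box
  minimum, making the tiling translation invariant.
* BIC ties break toward the smaller K (parsimony; avoids inflating EDI).
* Empty cell maps, all-regions-filtered profiles, infeasible K (n < K)
  and non-positive survival times raise typed errors; non-convergence of
  EM and undefined diagnostics (constant data, no events) are flagged in
  the result instead.
* Sections of one tumor are pooled into a single score vector before
  clustering — the simplest combination rule consistent with one EDI per
  tumor from multiple sections.
* Problem sizes used by the shipped experiments: 100 mosaics per K for
  recovery, a 400-region mosaic with 200 repeats for subsampling
  stability, 200 cohorts of n = 1000 for hazard-ratio recovery (50 in the
  acceptance script), and 2000-gene screens for FDR checks.

## Known limitations

* Three cell classes only; finer stromal/immune subtypes would need a
  larger `m` and change the score range.
* The index is scale dependent by construction; 200 μm is a default, not
  a universal optimum, and `scale_scan` should be consulted on new data.
* EDI is an integer in 1..5: coarse by design, and insensitive to
  differences *within* a component count.
* The min-cell filter is a declared analysis decision, not derived from
  the method; its value interacts with region size and tissue density.
* Plug-in Shannon scores are biased low by ≈ (m−1)/(2c) for c cells per
  region; the bias shifts component means slightly but cancels within a
  tumor scored at one scale.
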