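# Methods

## The per-site model

Each CpG is fit independently by ordinary least squares of the
methylation fraction (beta, in [0, 1]) on age in weeks, using the
site's complete cases only (missing cells are excluded, not imputed).
The slope is the site's gradient in fraction/week; inference is a
two-sided t-test on n − 2 degrees of freedom. Two degenerate regimes
are handled explicitly:

- **Zero variance in beta** (a flat site): the site carries no age
  information. It is flagged `degenerate`, assigned gradient 0 and
  p = 1, and excluded from the null-proportion estimate, which it would
  otherwise inflate.
- **Zero residual variance with a nonzero slope** (an exactly linear
  trend, which noiseless synthetic data produces): the t statistic is
  infinite and the p-value is guarded at the smallest positive normal
  double rather than underflowing to 0, so downstream log-transforms
  and q-value arithmetic stay finite. "Exact" is judged relative to the
  total sum of squares (residual SS ≤ 1e−16 × total SS).

Sites with fewer than three complete cases, or constant ages among
their complete cases, are skipped with the reason recorded on the
result table. No covariates beyond age are modelled.

## Multiple testing

Storey positive-FDR q-values: pi0 is estimated from the p-value
distribution — for m ≥ 100 p-values, pi0(lambda) = #{p > lambda} /
(m(1 − lambda)) over the grid lambda = 0.05, 0.10, …, 0.95 is smoothed
with a cubic polynomial and read off at lambda = 0.95; for smaller m
the grid is too noisy and the single fixed-lambda = 0.5 estimate is
used. pi0 is clipped to [1/m, 1]. Then q_(i) = pi0 · m · p_(i) / i,
monotonised from the largest p downwards. Degenerate sites receive
q = 1 directly.

Three selection regimes mirror common practice across platforms:
q ≤ threshold for genome-scale studies, Benjamini–Hochberg adjusted
p ≤ threshold for targeted assays (the adjustment method is recorded in
the output metadata since "adjusted p" is not otherwise
self-describing), and raw p ≤ threshold for small-n array studies.

## Filters and normalisation

- **Coverage filter** (count data): a site is retained if its total
  read depth reaches `min_coverage` (default 50×) in at least
  `min_samples_at_coverage` samples; the sample minimum is deliberately
  a required, cohort-specific parameter. In retained sites, individual
  cells below the depth floor are set missing rather than kept as noisy
  estimates.
- **Detection filter** (array data): cells whose detection p-value
  exceeds 0.01 (strictly; a cell at exactly 0.01 is retained) are set
  missing, and sites losing every sample are dropped.
- **Class-wise quantile normalisation**: array probes fall into design
  classes (red channel, green channel, type II) with different
  intensity distributions. Within each class, every sample's values are
  ranked (average ranks on ties) and replaced by the class's mean
  empirical quantile function evaluated at the mid-rank plotting
  positions, with linear interpolation where samples have unequal
  numbers of present values. For complete, tie-free data this is the
  classic sorted-means method and is exactly idempotent. Classes with
  fewer than two sites pass through unchanged with a warning.

## Regions

Coordinates are 0-based half-open everywhere internally; the bismark
coverage format's 1-based start column is converted at the boundary
(pos = start − 1) and back on write. Each selected aDMP at `pos`
contributes [pos − flank, pos + flank) with flank defaulting to 100 bp,
so an isolated aDMP yields exactly a 200 bp region (a closed-interval
reading would give 201 bp and break that minimum). Strictly overlapping
extensions merge transitively; book-ended intervals do not merge by
default (`merge_touching` flips this). A merged region carries its
member count, the member gradient of maximum magnitude with its sign
retained (magnitude is the quantity compared across species, but the
direction is still informative), and the minimum member p-value. Flanks
are clipped at coordinate 0 and never cross chromosomes.

## Exact small-sample inference

- **Spearman**: rho is computed from average ranks. For n ≤ 9 with no
  ties, the two-sided p is exact — the fraction of all n! rank pairings
  with |rho| ≥ |rho observed| (for six species, a perfectly monotone
  pairing gives p = 2/720 ≈ 0.0028). Beyond that, or with ties, the
  large-sample t approximation is used and the method string says so.
- **Wilcoxon rank-sum**: the statistic is the first sample's rank sum
  W. For m + n ≤ 20 with no ties, the null distribution of W is built
  by count convolution (a subset-sum dynamic programme over ranks
  1..m+n) and the two-sided p is the probability of a deviation from
  the null mean at least as large as observed; complete separation of
  6 vs 6 gives 2/924 ≈ 0.0022. Otherwise the tie-corrected normal
  approximation is used (via the standard Mann–Whitney implementation)
  and flagged.

The lifespan comparison correlates the per-species mean of
−log10 |gradient| (log base 10, recorded in outputs; rank-based
statistics are base-invariant) with T_max. Because −log10 |g| grows as
ageing slows, a rate that decreases with lifespan appears as rho = +1
against T_max. Zero gradients have no defined rate and are excluded
with a logged count; a species with only zero gradients raises.

Paired-context analysis regresses context B's gradients on context A's
with an intercept (the through-origin slope is reported alongside,
since the choice is substantive only when the intercept is far from 0),
and reports per-site ratios for sites with |gradient_a| ≥ 1e−6/week —
smaller denominators make ratios numerically meaningless, and excluded
sites are counted, not silently dropped. The top-subset ratio averages
gradient_b/gradient_a over the k pairs with the largest |gradient_b|.

## Synthetic data

The generators emulate the statistical structure of ageing cohorts, not
any particular dataset:

- A fraction `frac_admps` of sites receive nonzero slopes; signs are
  ±1 with equal probability (real aDMPs both gain and lose
  methylation), magnitudes uniform in [0.7, 1.3] × `gradient_scale`.
- Ages are uniform over the configured range. Species panels default to
  [2%, 60%] of T_max (in weeks), and the default rate rule sets
  `gradient_scale` = 0.02/T_max(years). Because the age window scales
  with T_max while the slope scales with 1/T_max, every species
  traverses the same total methylation change (~0.6) over its window —
  the pattern seen when a short-lived species' aDMPs move as far in
  months as a long-lived species' do in decades.
- Intercepts for drifting sites are drawn from the band that keeps the
  noiseless trajectory inside [0.02, 0.98] over the age range, so
  noiseless data never clips and slope recovery is exact to machine
  precision. Non-aDMP intercepts are uniform on [0.02, 0.98].
- Beta-mode noise is additive Gaussian on the fraction scale with
  clipping to [0, 1]. Clipping biases slopes for trajectories that
  approach the boundary under large noise; an alternative logit-normal
  mode (`noise_model="logit"`) adds noise on the logit scale and
  respects (0, 1) without clipping, for bias-sensitive uses.
- Count mode draws total depth Poisson(`depth_mean`) and methylated
  counts binomial at the true beta; zero-depth cells are missing.
  Sequencing noise replaces the additive noise term.
- Correspondence tables include each candidate site pair independently
  with probability `conserved_fraction` (Bernoulli, so the mapped count
  is binomial rather than fixed-size) and draw match fractions uniform
  on [0.9, 1.0].
- Paired contexts share sites and slope signs; context B's slope
  magnitudes are `scale_factor` × context A's, each context's
  intercepts re-drawn feasibly for its own age window (context A
  defaulting to a human-blood-like 988–5252 weeks, context B to a
  mouse-like 8–52 weeks).

What the generators do **not** emulate: probe-level array artefacts
(dye bias, type I/II chemistry beyond a class label), read-level
sequence structure, spatial correlation between neighbouring CpGs,
nonlinear (logistic or paediatric-accelerated) age trajectories, and
cohort-specific residual noise magnitudes — the noise defaults make
inference exercises well-posed rather than matching any real cohort.
Passing tests therefore demonstrate correctness of the machinery under
the stated generative model, not performance claims about real data.

## Problem sizes and numerical choices

The test suite and the acceptance script run desk-scale problems chosen
to make each property sharp: 120 sites × 12 samples per species for the
six-species panel (noiseless, so the rank ordering is exact), 5 000
sites × 50 samples for null calibration (binomial 99% bounds on the
type-I error at alpha = 0.05), 15 gradient pairs with 30 samples per
context for the 21× ratio recovery, and ≤ 200-instance enumeration
cross-checks for the exact tests. Seeds are fixed in tests; every
generator is bit-reproducible given its seed. Ties in quantile
normalisation use average ranks; region merging is stable-sorted by
(chrom, start).

## Known limitations

- The q-value pi0 smoother is a cubic polynomial fit over the lambda
  grid, not a spline with df = 3; for well-behaved p distributions the
  two agree closely, but pathological distributions may differ in the
  second decimal of pi0.
- The exact Spearman enumeration is O(n!) and is capped at n = 9.
- `filter_detection` requires a detection-p matrix aligned to the beta
  matrix; it does not compute detection p-values from raw intensities.
- Cross-species site correspondence is consumed, never computed: the
  package reads liftOver-style output (inclusive minMatch threshold,
  default 0.9) and rejects ambiguous duplicate mappings.
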