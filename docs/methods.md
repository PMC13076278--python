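# Methods

## Problem and model

`effdyn` studies how the *relative* efficiency of regional healthcare
systems evolves: whether regions converge to a common performance level or
settle into persistent "efficiency clubs".  The pipeline has five stages.

**1. Efficiency measurement (DEA).**  Each region-year is a decision-making
unit with input vector `x` (e.g. physicians, nurses, beds) and output
vector `y` (e.g. outpatient visits, inpatient admissions).  The
input-oriented radial score is

    theta* = min { theta : sum_j lambda_j x_j <= theta x_o,
                           sum_j lambda_j y_j >= y_o, lambda >= 0 },

with the convexity constraint `sum lambda_j = 1` added under variable
returns to scale (BCC) and omitted under constant returns (CCR).  The BCC
score is pure technical efficiency (PTE), the CCR score overall technical
efficiency (TE), and scale efficiency is SE = TE/PTE.  Scores are radial
only; slacks are reflected implicitly in the projection.  By default each
unit is evaluated against the cross-section of its own year
(`frontier_scope="per_year"`), since a contemporaneous frontier is what
"annual efficiency scores" usually mean; a pooled frontier is available as
a sensitivity flag.  LP feasibility/optimality tolerance is 1e-9 (HiGHS);
`theta` is clipped to (0, 1] only at that tolerance.  When the optimal
intensity weights are degenerate, any optimal vertex is reported — `theta`
is unique, `lambda` need not be.

**2. State discretisation.**  Pooled PTE values are cut at their 33rd/67th
percentiles (terciles; quartiles as robustness) using linear-interpolation
empirical quantiles.  Intervals are lower-closed: a score equal to a
threshold belongs to the state above, so frontier ties at 1.0 always land
in the top state.  With a heavy mass point at 1.0 the upper threshold can
equal 1.0; the classifier warns when tercile shares leave [0.25, 0.42].
Thresholds are computed once on the pooled sample and reused for any
subset, keeping states comparable across years and regions.

**3. Markov dynamics.**  Transition counts pool all adjacent-year pairs
within regions (missing years break the chain; nothing is bridged), and
`p_ij = n_ij / n_i.` is the MLE.  Rows with no observations are reported
as undefined, never imputed, and a stationary distribution is refused for
such estimates.  The stationary vector solves `pi P = pi, sum pi = 1` by a
least-squares solve on `(P' − I)` stacked with the normalisation row;
irreducibility is checked on the positive-entry digraph and a reducible
chain raises an error carrying the communicating-class structure instead
of a bogus `pi`.  Power iteration is kept as an independent cross-check.
The mobility index `1 − trace(P)/K` summarises persistence.

**4. Spatial Markov.**  The neighbourhood indicator of region r in year t
is the unweighted mean state of its contiguity neighbours in year t (self
excluded).  Pooled lag values are cut at their terciles (same quantile and
boundary conventions as stage 2) into low/medium/high contexts, and the
context at the *origin* year conditions each t→t+1 transition; a separate
matrix is estimated per context.  Per-context count matrices sum exactly
to the pooled count matrix over non-island regions — an integer identity
asserted on every run.  Islands (regions with no neighbours) are excluded
with a logged count; users can add bridge edges to the edge list instead.
A `same_region` scheme replaces geographic neighbours with the other
members of a configured region group, as a robustness variant.

**5. Transition equations.**  Upward (`1{S_{t+1} > S_t}`) and downward
mobility indicators are regressed on origin-year covariates
(doctor–nurse ratio, staff per 10k population, beds per staff, log GDP per
capita) by ordinary least squares with year and region-group indicator
blocks.  Each model uses only its at-risk sample: top-state origins cannot
move up and are dropped from the upward model, bottom-state origins from
the downward model — which is why the two models have different n.
Covariances are cluster-robust by region with the CR1 factor
`G/(G−1) · (N−1)/(N−k)`; with singleton clusters this reduces exactly to
HC1.  p-values use a t reference with G−1 degrees of freedom.  These are
descriptive association models, not causal estimates.

## Synthetic data generator

No public micro-panel accompanies this problem, so the generator supplies
panels whose every downstream quantity has a known truth.  Defaults are
the study conditions: 31 regions x 20 years, 3 inputs, 2 outputs, latent
states driven by the published 3-state kernel in `effdyn.reference`
(diagonal persistence 0.72–0.89).

* **Latent process.**  Initial states are drawn from the kernel's
  stationary vector; each subsequent step draws from the kernel row of the
  current state.  With `spatial_coupling = q`, a region instead copies a
  uniformly chosen neighbour's previous state with probability q — the
  simplest mechanism that makes transitions depend on neighbourhood
  context without committing to a structural story.
* **Efficiency and technology.**  State s carries radial efficiency
  `level_s`, default (0.78, 0.90, 1.00): under the kernel's stationary
  occupancy this puts pooled mean true efficiency near 0.87, consistent
  with the published pooled PTE mean of 0.884.  The top level is exactly 1
  so frontier units exist.  Outputs are log-normal with region-level scale
  heterogeneity; the frontier input requirement is
  `x_k = base_k (w_k · y/y_base)^{c_k}` with exponents drawn once per
  config from [1.10, 1.35].  Because the requirement is monotone and
  convex in outputs and the technology region-invariant, the production
  set is convex: every noise-free frontier unit is BCC-efficient, and an
  inefficient unit sharing a frontier unit's outputs scores exactly its
  configured level.  Inefficiency enters radially on inputs
  (`x = x_frontier / efficiency`), matching the DEA orientation;
  multiplicative log-normal noise (default sd 0.05, a modest measurement
  error) is applied on top.
* **Covariates and effects.**  Covariates are normal with region random
  intercepts around fixed means/sds on realistic scales (e.g. beds per
  staff 0.63 ± 0.09).  A configured effect `beta` shifts the upward
  (or downward) mass of the kernel row by `beta · (z − mu)` — linear in
  the centred raw covariate, so an LPM slope on the raw covariate recovers
  `beta` directly.  *Validity domain:* the tilt is truncated at the
  feasible probability range, so the linearity (and hence the nominal
  slope) holds only while `|beta · (z − mu)|` stays below the base
  upward mass (~0.11).  With sd(z) = 0.09 this means effects up to ~0.5
  are in the linear range; larger effects (e.g. 1.0) remain strongly
  detectable but their fitted slope is attenuated by the truncation.
  Recovery checks therefore use 0.5 for unbiasedness and 1.0 for
  detection.
* **Adjacency.**  Rook lattice on the nearest rectangle with aspect ratio
  at most 2 (31 regions occupy 31 cells of a 4x8 grid); tiny n falls back
  to a path.  Real adjacency structures can be supplied as edge lists.

What the generator does **not** emulate: real provincial geography or
magnitudes beyond orders of magnitude, serial correlation in covariates
beyond a static region intercept, output-side inefficiency, technology
change over time, and measurement error correlated with size.  Passing
tests therefore certify the estimators' behaviour under a known DGP, not
conclusions about any real healthcare system.

## Numerical choices and degenerate inputs

* DEA LPs: HiGHS, tolerance 1e-9; nonpositive quantities rejected before
  solving; `te > pte` beyond 1e-7 aborts with diagnostics (it would signal
  an LP inconsistency, since the CRS frontier envelops the VRS frontier).
* Quantiles: linear interpolation throughout; consequential when >33% of
  scores sit at 1.0, which is why the convention is fixed and documented.
* Stationary solve residual tolerance scales with the row-sum deviation of
  an externally supplied (rounded) matrix.
* Identity/reducible kernels are legal generator inputs (they freeze the
  chain); the stationary solver refuses them with an absorbing-structure
  report, and the generator then initialises states uniformly.
* All randomness flows from one `numpy` Generator seeded by the config;
  identical configs give byte-identical panels.

## Known limitations

* With small cross-sections (≲10 units per year) DEA's upward small-sample
  bias makes most units frontier-efficient, so tercile classification of
  DEA scores degenerates — the classifier warns, and the Monte-Carlo
  checks run on latent truth states where the target quantity is defined.
* The stationary vector of an *estimated* matrix inherits amplified
  sampling noise when persistence is high: at ~600 observed transitions
  its per-component error is commonly above 0.05.  Long-run shares from
  panels of this size should be read with that uncertainty in mind.
* Sub-panel stationary vectors (period or region subsets) describe the
  relative ranking structure within the subset, not absolute efficiency
  change.
* Cluster-robust inference relies on a moderate number of clusters (~31);
  with very few clusters the t(G−1) reference is still optimistic.

## Problem sizes used in the test suite

Monte-Carlo checks use the default 31x20 panel across 50–100 seeds;
DEA property suites use 200–600 random instances with n ≤ 6 units and at
most 2 inputs/outputs, where the independent bisection oracle is cheap;
long-chain consistency checks use single-region chains of 2·10^4–10^5
steps.  The full suite runs in about a minute on one CPU.
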