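# Methods

## The model of a study

`repdist` treats a study as an ordered tuple of five components:

* **K** — background knowledge (free text; carried along, never quantified);
* **Spre** — pre-data methods: which variables the study measures and how
  (here: a `PredictorDesign` naming its predictors and sampling ranges);
* **M** — the probability model generating the data;
* **Spost** — post-data methods: the statistical analysis mapping data to
  the result;
* **D** — the data, split into structure **Ds** (sample size, recording
  quality) and values **Dv** (the realized random draws).

An *exact replication* keeps Spre, M, Spost and Ds and regenerates Dv
independently.  For a binary result r (with type R), the *reproducibility
rate* phi = lim N^-1 * sum I{R_i = r} over a sequence of exact replications
is a parameter of the experiment; the Monte Carlo estimator is the agreement
fraction phi_hat over N simulated replicates, with standard error
sqrt(phi_hat (1 - phi_hat) / N) and almost-sure convergence by the strong
law of large numbers.

## Replication distance

Given an original experiment and a replication, every component can in
principle be swapped, producing a 2^4 = 16-cell grid of hybrid experiments
(K is excluded: there is no workable quantification of background knowledge,
so the distance is four-dimensional).  The distance with respect to one
component is

    d = | mean(phi over the 8 cells with the original's version)
        - mean(phi over the 8 cells with the replication's version) |,

the mean running over all permutations of the remaining three components.
The absolute value makes d symmetric and non-negative; because rates live in
[0, 1], so does d.  The four coordinates are deliberately not collapsed into
one number — a difference in design and a difference in model are not
commensurable.

**Non-permutable cells.**  A hybrid can be non-performable, e.g. when the
model needs a predictor the design never measured, or when a Bayesian
analysis has no prior assignable to some model parameter (vague priors
transfer across parameterizations; informative ones do not, absent an
explicit transform).  Such cells receive rate 0 *by convention*: dropping
them instead would shrink the averaging set, inflate the remaining mean, and
understate the distance.  The zero-by-convention state is distinct from a
cell whose fits all failed numerically — the latter is flagged (NaN rate)
and refuses to enter a distance.

The permutation grid is enumerated in a fixed canonical order (Spre slowest
varying, then M, then Spost, then Ds) so tables are directly comparable
across runs.

## The dugong example

Study 1: linear growth `y = b0 + b1*log(x1) + b2*x2 + eps` on log-age and
weight, ordinary least squares, n = 20 with recording bias (stored age is
80%, stored weight 120% of the actual value — a data-processing error).
Study 2: asymptotic growth `y = alpha - beta3*gamma^x1 + eps` on age only,
Bayesian analysis with vague priors, n = 100, no bias.  Age is in half-years
on (0, 70], weight in 100 kg on [0.2, 9], length in meters.  The shared
result: does the status *certain to breed* (predicted mean length > 2.50 m
at age 17 years = 34 half-years, weight 250 kg = 2.5) assigned by the fitted
study agree with the status under the true generating model?

True parameters are uniform on plausibility boxes: b0 in (0,3), b1, b2 in
(0,1); alpha in (1,3), beta3 in (1,3), gamma in (0,1); error precision tau
in [50, 250] (error sd 0.063–0.14 m) for both models.

### Generator choices (and what they imply)

* **True parameters are redrawn uniformly for every replicate**, so each
  rate integrates over the plausible box rather than conditioning on one
  unknown truth.  The boxes are plausibility statements, not a posterior;
  passing rates therefore speak to behavior averaged over the box, not at
  any particular biological truth.  A degenerate box (`with_bounds`) pins
  the parameters for studies of the conditional behavior.
* **Ages are sampled continuously on (0.5, 70] half-years** (the lower bound
  respects half-year measurement resolution and keeps log-age finite),
  weights on [0.2, 9], independently.  Real dugong samples are age-clustered;
  this generator does not emulate that.
* **The prediction query is the nominal point** (34 half-years, 2.5) even
  when fitting used biased recordings: the bias corrupts the records, not
  the scientific question.
* **Responses are not truncated** to the (1, 3) m range quoted for dugong
  lengths; the range bounds the parameter boxes, not the noise.
* No pilot-based exclusion of parameter regions is applied by default; a
  caller-supplied rejection is possible by shrinking the bounds.

Under these defaults the clean-data cells and the Bayesian cells reproduce
their reference rates closely (~0.99), while the biased small-sample OLS
cell simulates to a rate near 0.98 against a published reference of 0.637.
The discrepancy is structural, not a replicate-count issue: the 0.8/1.2
multiplicative bias shifts the OLS prediction at the query by
`0.223*b1 - 0.417*b2` (at most ~0.42 m in magnitude), and under uniform
redraw the density of the true mean near the 2.50 m threshold is about
0.2/m, which bounds the achievable status-disagreement at a few percent.
Reproducing a 36% disagreement would require an unpublished additional
choice (e.g. true parameters concentrated near the threshold).  We keep the
documented generator rather than reverse-engineering one; the affected
comparison is left failing openly in the acceptance suite.

### Estimation methods

* **OLS** (linear model): normal equations via `numpy.linalg.lstsq`;
  rank-deficient designs fail cleanly.
* **NLS** (asymptotic model): Levenberg-Marquardt via
  `scipy.optimize.least_squares`, with gamma kept in (0, 1) by a logit
  transform.  Starting values are a deterministic grid — alpha = max(y),
  beta3 = max(y) - min(y), gamma in {0.5, 0.9} — and the best converged
  optimum is kept, so fits are reproducible and failures rare.  A fit that
  converges from no start is the "NA" case: it is excluded from the rate
  denominator, and a cell with more than 5% failures logs a prominent
  warning (the method is then arguably inappropriate for the model).
* **Bayesian** (either model): Metropolis-within-Gibbs honoring the
  reference settings — one chain, 1000 burn-in, 1000 retained draws, no
  thinning.  Priors: Normal(0, precision 1e-6) on location/slope parameters
  (precision parameterization, i.e. variance 1e6), Uniform(0, 1) on gamma,
  Gamma(1e-3, 1e-3) on tau.  Coefficients that enter the likelihood linearly
  get blocked conjugate Gibbs updates; tau gets its conditional Gamma
  update; gamma — the only non-conjugate parameter — gets random-walk
  Metropolis on the logit scale with step-size adaptation during burn-in
  only (targeting roughly 0.2–0.6 acceptance).  The reported prediction is
  the average of the mean function over retained draws: the posterior
  predictive adds zero-mean noise, so drawing it would only add variance to
  a mean estimate.  Zero gamma-acceptance or non-finite draws are a flagged
  sampler failure.

  When the Bayesian method is permuted onto the linear model, its location
  parameters receive the same vague normals — that transfer is exactly what
  the permutability rule licenses for vague priors.

### Numerical conventions

* Per-cell RNG sub-streams are derived from the master seed with the cell's
  study index as spawn key; tables are bit-reproducible given the seed, and
  cells are mutually independent.  A common-random-numbers mode (all cells
  share one stream) is available for variance-reduced distance comparisons
  and for exact structural identities (identical experiments then receive
  identical estimates); it is off by default.
* The breeding threshold is a strict inequality: a predicted mean of exactly
  2.50 m is *not certain to breed*.
* Rate tables print phi at 3 decimals in report files; machine files keep
  full precision.

## Planned-modification sequences

A sequence toward a Minimum Viable Experiment modifies one component per
step, accepts a proposal when its own reproducibility rate does not drop
(the rule is injectable), and records the distance vector between
consecutive experiments.  Convergence is summarized by a rolling range of
step distances per coordinate with a non-increasing-tail flag; this is a
labeled heuristic — no published stopping rule exists, only the limiting
statement that at an acceptable MVE all step distances are zero.

## Problem sizes

Default replicate counts are 1e4 per least-squares cell and 1e3 per Bayesian
cell (each Bayesian replicate is a complete 2000-iteration MCMC run; the
Monte Carlo standard error at 1e3 replicates and phi ~ 0.99 is ~0.003, an
order of magnitude below the comparison tolerances in use).  A flag restores
1e4 everywhere.  Unit tests run the same paths at toy sizes.

## Known limitations

* Only binary results are supported; interval-overlap notions of replication
  success are out of scope.
* Two versions per component (original vs replication).  The enumeration
  contract leaves >2 versions as an extension point; note the grid size
  would be v^4, not 2^4.
* Background knowledge K is annotation only — no K coordinate, no
  K-permutations.
* The converged/MVE flag is heuristic (see above).
* The synthetic generator draws independent uniform predictors and exact
  Gaussian noise; real growth data exhibit age clustering, heteroskedastic
  measurement error and non-random sampling that the example does not
  emulate, so passing tests certify the machinery, not field behavior.
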