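# Methods

`tgpmove` estimates continuous-time animal movement trajectories from GPS
telemetry with Bayesian treed Gaussian processes (TGPs), then turns the
posterior trajectory samples into movement descriptors with credible
intervals. This note records the model, the numerical choices, the
synthetic-data generator used for validation, and the known limitations.

## Model

Each coordinate series is modeled independently. For one animal, the
easting observations `y1(t)` and northing observations `y2(t)` each get
their own treed GP on time; trajectory samples recombine the two chains by
MCMC sample index, which is valid under the independence assumption and is
what makes every downstream derived quantity a proper posterior sample.

**Per-leaf GP.** Within one partition cell (leaf) of standardized time,

    y | beta, sigma2 ~ N(F beta, sigma2 (C + g I)),
    C_ij = exp(-|t_i - t_j|^p / d),

with a linear-in-time mean (`F = [1, t]`), power-exponential correlation of
range `d` and exponent `p`, and nugget `g` absorbing GPS error relative to
the process variance `sigma2`. The mean coefficients carry a conjugate
normal prior `N(m0, sigma2 / tau I)` and `sigma2` an inverse-gamma prior,
so both are integrated out analytically: the leaf marginal likelihood and
the posterior predictive are multivariate Student-t distributions
conditional only on `(d, g)`. `d` and `g` get independent log-normal
hyperpriors (a deliberate simplification of the mixture-of-gammas
hyperpriors used by the classical treed-GP software; log-normals are
weakly informative and have trivially computable densities for the
reversible-jump bookkeeping).

**Tree prior and moves.** The partition is a binary tree over standardized
time `[0, 1]`. A node at depth `q` splits with probability
`alpha (1 + q)^(-beta)` (defaults 0.5 and 2, the standard Bayesian-CART
choice), the split value uniform over the candidate set — midpoints of
consecutive distinct observed times — restricted to candidates that leave
at least `min_leaf_size` observations (default 10) on each side. A node
with no valid candidate has split probability zero, which makes the prior
proper: it sums to one over the finite set of valid trees (verified by
exhaustive enumeration in the tests). Posterior exploration uses
grow / prune / change / swap moves (probabilities 0.2 / 0.2 / 0.4 / 0.2)
with Metropolis–Hastings acceptance; new leaves created by grow (and merged
leaves created by prune) receive hyperparameters drawn from the hyperprior,
the simplest dimension-matching scheme, so the hyperprior densities cancel
from the acceptance ratio and only the marginal-likelihood, tree-prior and
selection-probability terms remain. Rotate moves from the classical
software are omitted: they affect mixing only, not correctness, and the
constant-likelihood prior-recovery tests confirm the implemented move set
targets the prior exactly. The "limiting linear model" leaf type is out of
scope; every leaf is a full GP.

**Chain defaults.** 12,000 iterations, burn-in 2,000, thinning 10,
retaining K = 1,000 states — the settings used in the field study this
package's workflow follows. Each iteration is one tree move plus one
random-walk Metropolis sweep over every leaf's `(log d, log g)` (step sizes
0.5, configurable). Convergence is assessed from the log-joint trace and
the effective sample size (ESS) of predicted locations; ESS uses the
autocovariance with Geyer's initial-positive-sequence truncation, is capped
at K, and a constant series returns K by documented convention. The default
ESS pass threshold equals K.

**Prediction.** Posterior predictive trajectories are drawn on a uniform
Δt grid spanning the fitted period (extrapolation off by default): for each
retained state and each leaf, one *joint* draw from the leaf's full
Student-t predictive covariance over the grid times in that leaf, so each
sample k is a coherent path rather than pointwise noise. Continuity is not
enforced across leaf boundaries — abrupt jumps at partition boundaries are
precisely how the treed model represents sudden behavioral transitions.
By default prediction targets the latent path (nugget excluded); a flag
includes the nugget to predict new noisy observations instead. Both modes
are available because the classical software's figures do not disclose
which is shown.

**Kernel exponent.** `p = 2` (Gaussian kernel) is the default, matching
the treed-GP software tradition. For movement data whose paths are rough —
anything resembling a correlated random walk, i.e. most wildlife telemetry
— `p = 1` (the exponential kernel, exactly the covariance class of
mean-reverting Ornstein–Uhlenbeck movement and the continuous-time
correlated random walk) is usually the better choice: with `p = 2` the
fine-scale path variation is absorbed into the nugget, and latent-path
intervals become too narrow. The coverage validation below uses `p = 1`
for this reason; this is a model-family choice made once, not a tuning
knob.

## Derived quantities

All derived quantities are deterministic transforms applied independently
to each of the K aligned trajectory samples (the MCMC equivariance
property). Conventions:

- **Displacement**: Euclidean distance between consecutive grid locations;
  K × (M−1) values in meters.
- **Turn angle**: the law-of-cosines interior angle at the middle of each
  location triple, in [0, π]. Straight-line motion gives π and a reversal
  gives 0 — the complement of the heading-change convention common in the
  movement literature; no silent conversion is made. Triples with a
  zero-length leg are flagged undefined (NaN) and counted, never raised.
- **Residence time**: count of grid locations covered by the region
  (boundary inclusive) times Δt, in hours.
- **Contact**: requires an explicit tolerance ε in meters (exact equality
  has probability zero); the contact probability is the fraction of samples
  passing within ε at any grid time.
- **Region classification**: regions must be interior-disjoint; locations
  in no region get the implicit `outside` label; on a shared boundary the
  first-listed region wins.
- **Interval attribution**: a displacement interval belongs to the region
  of its starting grid point, consistent with `[t, t + Δt)` semantics.
- **Window transforms**: apply a within-window op then an across-window op
  (e.g. sum within days, mean across days for average daily distance),
  always within a sample and never across samples; a trailing partial
  window is dropped with a logged count because partial sums bias totals.
- **Population aggregation**: element-wise mean across individuals within
  each sample index k; mismatched K is an error (no silent resampling).
- **Summaries**: means and equal-tailed percentile credible intervals;
  undefined entries are excluded and their count reported.

## Synthetic data

The generator produces what the model assumes but from a *different* model
class, so recovery tests are not circular: the latent path concatenates
mean-reverting Ornstein–Uhlenbeck segments (attractor, reversion timescale
`tau`, stationary sd per regime), continuous across regime boundaries
except in the abrupt-relocation stress case, which emulates an unobserved
fast transit (default 14.2 km across a 2 h fix gap, the magnitude of a
documented real relocation). Observed fixes are the latent path at a
nominal interval (default 1 h) with ±10% jitter, 5% missingness, and
isotropic Gaussian GPS noise (default sd 15 m, typical of wildlife GPS
collars). Populations perturb attractors per animal with seeds spawned
deterministically from a master seed.

What the generator does **not** emulate: habitat-driven movement, fix
success correlated with behavior, heavy-tailed or location-dependent GPS
error, and diurnal schedules. Passing tests therefore demonstrate correct
inference under regime-switching mean-reverting movement with clean
Gaussian noise, not performance on any particular field dataset.

## Validation scales

The acceptance checks run the full pipeline at sizes chosen for a
single-CPU continuous-integration budget, stated here as the package's own
test-scale choices: changepoint recovery uses ~190 fixes at 0.5 h spacing
with chains of 4,000 iterations (burn-in 1,000, thin 3); coverage uses
96-hour hourly tracks, 40 held-out fixes per seed, chains of 1,200;
the population run uses 11 animals on 96-hour tracks with chains of 700,
K = 100. The bookkeeping identities (K = 1,000 under default settings; 744
hourly displacements and 31 daily totals in a 31-day month at Δt = 1 h)
are exact at any scale.

## Numerical choices

- Cholesky factorizations add a base diagonal jitter of 1e-10 (the
  Gaussian kernel is routinely singular at machine precision), escalating
  tenfold to at most 1e-6 with a logged warning, then failing as a
  numerical error that rejects the offending MCMC move and leaves the
  state unchanged.
- All GP computation happens on standardized scales (time mapped to
  [0, 1], each coordinate centered and scaled to unit variance); raw units
  are restored only at the trajectory-module boundary. A zero-variance
  coordinate (a stationary animal) falls back to scale 1 with a warning.
- arccos arguments are clamped to [−1, 1] before evaluation.
- Per-leaf marginal likelihoods are memoized by (interval, d, g, p) within
  a chain; this is an exact cache, not an approximation.
- Reproducibility: each fit spawns per-coordinate substreams from the
  configured seed via `numpy` SeedSequence; refits are bit-identical.

## Limitations

- Coordinates are modeled independently; strongly anisotropic, correlated
  movement (e.g. directed migration along a diagonal) loses cross-coordinate
  correlation in the joint uncertainty, though means remain unbiased.
- Inputs must be projected (meters); no datum or projection handling.
- The treed partition is over time only; splits driven by covariates are
  out of scope.
- Leaf predictives are conditionally independent across leaves, so a
  sampled path can jump at a partition boundary even when the animal's true
  path was continuous there; this is intrinsic to the model class.
- MCMC settings are replacements for, not reproductions of, the classical
  treed-GP software's internal defaults, which are not publicly enumerated.
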