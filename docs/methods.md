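# Methods

## The forecasting model

`teadvice` implements online prediction with expert advice for scalar time
series whose dynamics are unstable — chaotic benchmark maps and rising tumor
biomarkers are the two worked settings.  A pool of *N* experts supplies
advice `f_{i,t}` at every step; after each observation `y_t` each expert is
charged a convex loss `l(f_{i,t}, y_t)` (absolute error by default) and the
forecaster predicts with the weighted average

    p_{t+q} = sum_i w_{i,t} f_{i,t+q},     w_{i,t} ∝ exp(-eta * L_{i,t}).

Three accumulation rules distinguish the schemes:

| scheme     | coefficient `a_k(t)`  | accumulated loss `L_{i,t}`              |
|------------|-----------------------|-----------------------------------------|
| standard   | 1                     | `sum_k l_k`                             |
| temporal   | `lambda^(k-1)` or `lambda^k`, `lambda > 1` | `sum_k lambda^(k-1) l_k` |
| discounted (CZ) | `rho^(t-k-1)`, `0 < rho < 1` | `sum_k rho^(t-k-1) l_k`       |

The temporal scheme (TEA) multiplies each step's loss by an exponentially
*growing* coefficient so recent agreement with the target dominates the
weighting: unstable dynamics forget their past quickly, and so should the
forecaster.  Writing the temporal weight exponent as
`eta * lambda^(t-1) * sum_k lambda^-(t-k) l_k` shows it is a
geometrically discounted loss (discount `1/lambda`) with an *increasing*
effective learning rate, whereas the discounted scheme applies a constant
effective rate to the same discounted loss.  With matched decay
(`lambda = 1/rho`) and equal `eta`, the temporal weights equal the
discounted weights raised to the power `rho^-(t-1)` and renormalized, which
concentrates more mass on the currently reliable experts; this relation is
verified numerically in the test suite.  At `lambda = 1` the temporal
scheme reduces bit-identically to the standard forecaster.

### Assumptions

* Losses are convex in the prediction and nominally bounded by `epsilon`
  (default 1, configuration rather than estimate; exceedances warn).
* The expert pool is fixed during a run; experts built from finite windows
  may expire, in which case they stop accruing loss and predictions
  renormalize over the survivors (the convex-combination contract is kept,
  and an error is raised if no expert survives).
* Weights are maintained in the log domain with min-loss shifting and
  log-sum-exp normalization, so `eta * lambda^(t-1) * loss` far beyond the
  range of `exp` is harmless; only the coefficient itself overflowing
  (around step `1 + log(realmax)/log(lambda)`) raises an error, with that
  usable horizon in the message.

## Regret bounds

For coefficients `a_k` and losses in an interval of width `epsilon`, the
Hoeffding argument of the classical exponentially-weighted-forecaster
analysis gives, for every `eta > 0`,

    regret(t) <= ln(N)/eta + (eta * epsilon^2 / 8) * S(t),
    S(t) = sum_{k<=t} a_k^2,

where the regret is measured in the scheme's own accumulation ("exponential
accumulated loss" for the temporal scheme).  Minimizing over `eta` gives
`eta* = sqrt(8 ln N / (epsilon^2 S))` and the optimal bound
`B* = epsilon * sqrt(S ln N / 2)` with

    standard:   S = t
    temporal:   S = (lambda^(2t) - 1) / (lambda^2 - 1)
    discounted: S = rho^-2 (1 - rho^(2t)) / (1 - rho^2).

The temporal closed forms are guarded by a test that numerically minimizes
the two-term bound (relative agreement 1e-6 over a parameter grid), and the
`lambda -> 1`, `epsilon = 1` limit recovers the textbook
`sqrt((t/2) ln N)`.  The temporal bound lives on the exponentially inflated
loss scale; multiplying it by `rho^(t-1)` (with `lambda = 1/rho`) moves it
onto the discounted scale, where

    normalized temporal bound = rho * discounted bound < discounted bound

for every `0 < rho < 1` — the two bounds share the same geometric sum up to
exactly one factor of `rho`.  Geometric sums are evaluated with `expm1` so
the `lambda -> 1` / `rho -> 1` limits are stable, and the normalized bound
falls back to a log-space product when the raw bound overflows.

### The default learning rate

`eta="auto"` resolves to the classical rate `sqrt(8 ln N / (epsilon^2 T))`
for **every** variant, where `T` is the run horizon.  The per-variant
bound-optimal rate is deliberately *not* the default: for the temporal
scheme it shrinks like `lambda^-(t-1)` to guard the worst case of the
exponential regret, which freezes the weights near uniform for most of a
prediction run (at `N = 1000`, `T = 60`, `lambda = 1/0.9` it is ~0.0065
against 0.96 at `lambda = 1`), and a forecaster whose `lambda > 1`
"extension" underperforms its own `lambda = 1` special case purely through
its default rate is not defensible.  The coefficient growth is the tracking
mechanism, not a scale to cancel.  Bound-optimal rates remain available via
`regret.optimal_eta` and are what the regret-bound experiments use, since
there the bound is the object under study.  `eta` may also be any constant
or a callable schedule keyed by the 1-based step; no specific schedule is
built in.

## Distribution prediction

Assuming each expert's advice is disturbed by Gaussian error with common
standard deviation `sigma`, the predictive distribution is the mixture
`sum_i w_{i,t} N(f_{i,t+q}, sigma^2)`; its mean coincides with the point
prediction.  Quantiles `u_t(Q)` solve `CDF(u) = Q` by bracketing between
`min(c) + sigma z_Q` and `max(c) + sigma z_Q` (rigorous, since the mixture
CDF is pinched between the extreme components' CDFs) followed by Brent root
polishing to 1e-10; the identity `CDF(quantile(Q)) = Q` holds to 1e-8 in
tests.  The seven upper levels 97.5/87.5/75/65/60/55/52.5% are the PSA
surveillance bands: overlooking a high PSA is the costly error, so only the
upper half of the distribution is reported there.

Two parameters are selected on the learning prefix of a target:

* **Decay `lambda`** — grid search (default 100 equally spaced candidates
  strictly inside (1, 2); the open interval is used because larger decays
  degrade the distribution prediction) scored by the absolute error of the
  one-step prediction of the *final* learning point, training on the
  earlier points; ties break to the smallest candidate.
* **Spread `sigma`** — either the final-point absolute error, or (for PSA)
  the mean absolute error between the distribution medians and the
  observations over the learning period.  The learning-period rule needs
  medians before `sigma` is known, so a provisional `sigma` from the
  final-point rule seeds exactly one refinement pass — the minimal reading
  of a two-stage estimate.  A floor `sigma_min = 1e-6` guards perfect fits.

## Expert construction

**Sliding windows.**  Every length-`P` contiguous window of every series in
a database becomes one expert (series `j`, window `i` maps to expert
`(L-P+1)(j-1)+i`), with horizon `P`.  A database of `J` series of length
`L` yields `J(L-P+1)` experts.

**Mechanistic model.**  The intermittent-androgen-suppression (IAS) model
tracks androgen-dependent cells `x1`, reversibly androgen-independent cells
`x2`, and irreversibly independent cells `x3`, with PSA = `x1+x2+x3`.  Each
treatment phase is linear:

    on:  x1' = d1 x1;  x2' = d2 x1 + d3 x2;  x3' = d4 x1 + d5 x2 + d6 x3
    off: x1' = e1 x1 + e2 x2;  x2' = e3 x2;  x3' = e4 x3

(six on-rates: conversion of `x1` into the resistant compartments; four
off-rates: `x2` may revert to `x1`, `x3` cannot).  Pieces are solved
exactly with the matrix exponential, so piecewise composition introduces no
integration error; time is continuous in days and measurement times are
arbitrary reals, matching irregular clinical sampling.  Only the
off-treatment dynamics are exercised in the PSA workflows (the emulated
setting is post-treatment follow-up).

For each candidate rate set, the initial state at the first observation
time is fitted to the first `K >= 3` PSA points (three state dimensions) by
minimizing the summed absolute discrepancy between observed PSA and model
output, plus a barrier `1e15 (1 - x)` for every negative state component at
every evaluated time — effectively a hard nonnegativity constraint.  The
discrepancy is absolute error, consistent with the absolute losses used in
learning.  Because PSA is linear in the initial state, trajectories reduce
to matrix-vector products with precomputed propagators, and the
least-squares solution of that linear system (clipped to the nonnegative
orthant) is supplied as one optimization start — it is the exact optimum
whenever a perfect nonnegative fit exists, at any data magnitude.  Twenty
further Nelder-Mead starts are drawn from `[0, y_1]^3` under a seeded
generator; the best penalty-free optimum wins, rows whose fit fails are
skipped with a warning, and the cost surface is convex (sum of absolute
values of affine functions plus a convex barrier), so multistart simplex
search is reliable.  Each fitted rate set is then run forward and its PSA
trajectory becomes one expert.

## Evaluation protocol

Baselines: persistence (predict the current value) and the running mean of
all past values — the latter is the minimal stateless reading of an
"average" predictor, documented here as an assumption.  For each pair of
methods on each target, points after a burn-in (default 10, where no
learning history exists) are compared by per-point loss; per-point ties
count toward neither, and a method wins a target only with strictly more
than half the compared points, otherwise the target is recorded as a
pair-tie.  Aggregated win counts over `n` targets are judged against exact
two-sided critical values of Binomial(n, 1/2): the upper threshold is the
smallest `c` with `P(X > c) <= alpha/2`, the lower is `n - c`; strictly
more (fewer) wins than the threshold is significant.  At `alpha = 0.05`
this gives 531/469 for `n = 1000` and 71/49 for `n = 120`, and the exact
tails agree with brute-force binomial summation for all tested `n` up to
2000.

Loss curves report both the plain ("standard") accumulated loss of a
forecaster's emitted predictions and the coefficient-weighted
("exponential") accumulation, per expert-pool size; at `lambda = 1` the two
coincide.  Coverage tables report, per quantile level `Q` and learning
length `K`, the fraction of subjects whose next observation falls below the
predicted `u(Q)`.

## Synthetic data

No clinical or audio datasets ship with the package; seeded generators
emulate the study designs.

**Chaotic-map databases** (`toy_database`): `M` parameter draws (Henon
`a ∈ [1.3, 1.4]`, `b ∈ [0.1, 0.2]`; Ikeda `u ∈ [0.7, 0.9]`) times `S`
initial conditions drawn from `[-0.02, 0.02]^2`, each orbit iterated past a
1000-step transient; the recorded `x + y` series are the experts.  Defaults
`M = 100`, `S = 1000` match the full toy-study conditions; the shipped
experiments scale `S` down (20 x 50 experts, series length 60) to run on
one CPU in seconds.  Targets use the fixed chaotic parameters
`a = 1.35, b = 0.15` (Henon) outside the database draw.  Diverging orbits
are discarded and redrawn with a warning.  The series length 60 and the
Ikeda `u` range are package choices; neither is critical to the qualitative
outcomes.

**PSA cohorts** (`synthetic_cohort`): per patient, off-treatment self-rates
`e1, e3, e4` are uniform on `[-0.1, 0.1]`/day, resampled until at least one
is positive (every patient eventually progresses — the clinically
interesting regime), and the reversion coupling `e2` is uniform on
`[0, 0.1]`/day so the linear system is Metzler and cell burdens stay
nonnegative from nonnegative initial states (uniform on `[0.1, 5]` per
compartment, PSA-equivalent units).  Measurements are irregular
(default 8 visits, 20–60 days apart); observation noise is additive
Gaussian (default sd 0.1) clipped at zero, matching the Gaussian error
kernel of the distribution predictor.  These ranges are synthetic
conventions, not estimates from any dataset: with growth up to 0.1/day
sustained over months, simulated PSA can span many more decades than real
post-operative cohorts do, so passing tests demonstrate the machinery
(fitting, weighting, calibration), not clinical realism.  All generators
are bit-reproducible under a fixed seed.

## What the shipped experiments show — and do not show

* The regret-bound suite runs random bounded-loss instances at the
  bound-optimal rate and observes zero violations; this checks the bound
  machinery, not predictive skill.
* Calibration-by-construction draws each subject's next observation from
  its own predictive mixture, so coverage near `Q` validates the quantile
  pipeline; at the 200-subject design size the per-level binomial sd is
  ~0.035, so individual runs fluctuate by a few percentage points.
* Parameter recovery on noise-free cohorts shows the fit-plus-weighting
  loop identifies the generating rate set; with noise or model mismatch the
  top-weight criterion would soften.
* The Henon comparison shows the temporal scheme beating the standard
  forecaster in accumulated absolute error on a majority of seeded
  replicates at the scaled-down design (20 x 50 experts, 60-step targets,
  `rho = 0.9`, shared auto rate).  Win margins depend on the expert count
  and decay, as expected.

## Known limitations

* No specialist/sleeping-expert variants, no losses beyond
  absolute/squared, no per-expert heteroscedastic `sigma`, no non-Gaussian
  error kernels.
* Treatment schedules are user-supplied; no relapse-threshold switching
  logic is modeled.
* The 10 IAS rate parameters are never estimated from the target subject —
  the design imports them from previous subjects by construction.
* The discounted-scheme bound assumes a decay `rho` that does not vary with
  time, and no high-probability or anytime bounds are provided.
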