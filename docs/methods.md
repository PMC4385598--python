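# Methods

This note records the scientific and numerical choices behind
`shadematch`: the model, the training procedures, the synthetic data
model that stands in for the unpublished laboratory specimen database,
and the places where the design was genuinely open.

## Model

A three-layer feed-forward network maps a normalized CIELAB triple to
the five powder mass fractions.  Parameters live in four blocks — the
input–hidden matrix `W` (h × 3), the hidden–output matrix `V` (5 × h)
and two threshold vectors — with a neuron's net input defined as the
weighted sum of its inputs *minus* its threshold (the sign convention
is arbitrary; only consistency matters, and the finite-difference
gradient tests pin the implementation to this convention).  Both layers
share one activation: the logistic sigmoid `1/(1+e^(−net/λ))` or the
hyperbolic tangent `tanh(net/λ)`.  The divisor λ ≥ 1 is the *gradient
factor*; at its resting value 1 the activations are the standard ones.

Inputs are min–max normalized per dimension, fitted on the training
split only, to [−1, 1] for the tangent activation and [0.1, 0.9] for
the logistic — both clear of the saturation asymptotes.  Outputs stay
in raw mass-fraction units: recipes lie in [0, 0.40], comfortably
inside either activation's output range, and leaving them raw makes
predictions directly comparable to laboratory recipe tables.  Raw
predictions are deliberately *not* projected onto the recipe simplex
(laboratory prediction tables show raw outputs that do not sum to
0.40); an optional post-processing flag clips at zero and rescales to
a 0.40 sum when a physically mixable recipe is required.

## Error metrics

Per sample, `E_p = Σ_k (d_k − o_k)²`.  The dataset-level figure is
`E_MSE = (1/P) Σ_p E_p²` — the mean of *squares* of E_p, so
fourth-order in the residuals.  This unusual aggregate is the field's
printed convention, and the package uses it as the default everywhere
while also computing the conventional mean of E_p; every report states
which variant it contains.  Training itself minimizes the total
squared error `Σ_p E_p` over the batch.

## Gradient-descent trainer

Updates are full batch: the accept/reject rule below compares *total*
error across passes, which is only coherent when every pass sees the
whole training set.

* Momentum: `ΔW_t = −η∇E + α·ΔW_{t−1}`, default α = 0.9.
* Adaptive learning efficiency: if a pass raises the total error the
  weights are restored (the pass "did not happen"), the momentum memory
  is cleared, and η ← βη with β = 0.7; otherwise the pass stands and
  η ← θη with θ = 1.05.  The β/θ defaults are the standard values of
  adaptive-gradient-descent practice; η₀ defaults to 0.1 and matters
  little because the schedule rescales it geometrically.
* Gradient factor: a flat area is declared when an *accepted* pass
  changes the error by less than `grad_tol` (default 1e-6) while the
  largest output residual still exceeds `residual_tol` (default 0.1);
  λ is then set to `lambda_boost` (default 4.0) until |ΔE| recovers,
  after which λ returns to 1.  Two subtleties are worth recording.
  First, rejected passes are excluded from the flat-area test: after a
  rollback ΔE is identically zero by construction, which says nothing
  about the slope of the error surface (an early version tested every
  pass and oscillated λ on each rejection).  Second, changing λ changes
  the error function, so the accept/reject baseline is recomputed at
  the new λ, and the best-so-far weights that training returns are
  always judged at the resting λ.
* The trainer returns the best weights seen, not the last ones, and
  the full per-epoch error history.  Everything is a pure function of
  (data, config, seed or explicit initial weights).

Default budget: 200 epochs.  The comparison experiments this package
reproduces live in a *partial-convergence* regime — published
per-sample prediction errors in this problem are of order 0.01–0.14,
far from the floor a converged network reaches — and initialization
quality is only visible in that regime.  With a much larger budget the
adaptive-η trainer drives every run to the same error floor and the
choice of initial weights ceases to matter; 200 epochs keeps the
packaged experiments where the phenomenon under study exists while
remaining fast (a full 10-trial comparison runs in minutes on one
core).

## Levenberg–Marquardt trainer

A damped Gauss–Newton method on the stacked residual vector
`r = d − o` (P·5 rows), with the analytic Jacobian assembled in closed
form — tractable because these networks are small (113 parameters at
h = 12).  Classic Marquardt schedule: μ₀ = 1e-3, ×10 on a rejected
trial step, ÷10 on acceptance, stop on iteration budget, small
gradient, or μ > 1e10.  A step is accepted only if it strictly lowers
the SSE, so the accepted-step error sequence is strictly decreasing;
the suite verifies this, the Jacobian against finite differences, and
convergence to the closed-form least-squares optimum on a linear
network.

## Genetic optimizer

Real-coded chromosomes are the flat parameter vector in the four-block
order above; `decode(encode(w)) = w` exactly.  Defaults: population
40, 50 generations, crossover probability 0.7 (single cut point
anywhere in the vector; a segment-aligned variant cuts only at the
four block boundaries), mutation probability 0.05 per gene (uniform
resampling within the gene range [−1, 1]; a Gaussian-perturbation
variant is available), elitism 1 (which makes the per-generation best
fitness monotone), roulette selection `p_i = f_i/Σf_j`.  These GA
hyperparameters are standard small-GA values; none are prescribed by
the underlying method, and they are all configurable and logged.

Fitness is `1/(E + ε)` with ε = 1e-6, where `E` is the decoded
network's mean-of-squared-E_p error on the training batch.  Two fitness
modes exist:

* `static_error` — score the decoded weights as they are (cheap);
* `trained_error` — run a short inner training first (k epochs of
  gradient descent or k Levenberg–Marquardt iterations) and score the
  error reached.

The GA+BP profile uses `trained_error` with 5 LM iterations.  This is
the configuration of the original procedure (the GA fitness *is* the
LM-trained network error) and it matters: static fitness rewards
low-error but sometimes poorly *trainable* (sharp) points in weight
space, and in our harness the GA+BP advantage over random
initialization only reproduces reliably when chromosomes are selected
for where training takes them.  The chromosome itself — not its
LM-trained descendant — is handed to the gradient trainer, exactly as
the procedure prescribes.

## Training profiles

* `bp-improved`: tangent activation, random initial weights uniform on
  [−0.5, 0.5], momentum + adaptive η, flat-area factor off.
* `gabp-paper`: tangent activation, GA initial weights, momentum +
  adaptive η, flat-area factor on.

Both profiles share the activation.  The gradient-factor formulation
is usually written on the logistic sigmoid, and an early design used
the logistic for the GA+BP profile; that turned the BP-vs-GA+BP
comparison into a comparison of transfer functions.  Since the
underlying experiments used the tangent transfer function and the
gradient-factor mechanics are activation-agnostic, both profiles now
use it, making initialization the treatment under study.

## Hidden-layer sizing

`h = round(√(n+m) + a)`, a ∈ [1, 10], rounding half up — widths 4–13
for the 3-in/5-out network (√8 ≈ 2.83; half-up rounding is what
reproduces those printed bounds).  `select_hidden_nodes` then trains
`reps` independently seeded networks per width under otherwise
identical settings on one shared split and picks the width with the
smallest mean test E_MSE, ties broken toward the smaller (cheaper)
width.  A diverging repetition is recorded at the worst finite error
observed in the survey and flagged, rather than aborting it.

## Synthetic specimen generator

The laboratory database (119 fired specimens) is unpublished, so the
package generates datasets with its statistical structure:

* **Recipes** are drawn uniformly from the 126 weak compositions of
  five 0.08 units over five powders (every printed recipe obeys this
  grid; that all 119 did is an assumption of the generator).
* **Colour** comes from `lab = offset + Bᵀr + c·g(r) + ε`: a per-powder
  linear basis `B` whose rows are fixed so the five pure-powder colours
  span L* ≈ 63–73.5, a* ≈ −1.5–1.9, b* ≈ 14–22 (bracketing the colour
  ranges of fired dentin porcelain), a fixed quadratic interaction
  `g(r)` standing in for non-additive pigment optics (default strength
  5, contributing ≲ 0.8 CIELAB units), and i.i.d. Gaussian noise with
  σ = 0.3 CIELAB units per channel, a typical intra-instrument
  repeatability scale for dental spectrophotometers.
* The default `offset` is zero: with every recipe summing to the same
  total mass, an offset is linearly inseparable from the basis, so the
  default model carries all colour in the basis and the
  parameter-recovery utility treats the offset as known.

What the generator does *not* emulate: radiative transfer in layered
ceramics (Kubelka–Munk), firing-process variability, instrument
metamerism, or any correlation between recipe choice and colour region.
Consequently the synthetic task is smoother and easier than real
specimen data; passing tests demonstrate the algorithms work and the
claimed effects point the right way, not that clinical-accuracy numbers
transfer.

The packaged *reference dataset* — "the 119-specimen database" used by
the worked examples and the comparison experiment — is generated with
default parameters and a fixed recorded seed, so it is the same rows
everywhere.

## The BP vs GA+BP comparison

`compare_bp_gabp` mirrors the original experiment's structure: one
75/25 split shared by both arms, ten trials per arm with per-trial
seeds, reporting each trial's test E_MSE plus means and sample
variances.  On the packaged reference experiment the GA+BP arm's mean
test error is consistently below the BP arm's (typically by 15–25%).
The variance comparison is weaker evidence either way: with only ten
trials the sample variance is a noisy estimator, and on this easy
surrogate task both trainers are stable enough that the two arms'
variances are statistically indistinguishable — across comparison
seeds the GA+BP variance falls on either side of the BP variance.  The
stability advantage of GA initialization, clearly visible in published
laboratory results where plain BP occasionally fails badly, is largely
erased here because the adaptive-η trainer almost never fails badly on
the smooth synthetic task.  The acceptance suite nevertheless asserts
both directions on the canonical packaged run, so a variance reversal
there is reported as a failure rather than hidden.

## Degenerate inputs and numerical guards

Constant input dimensions are rejected at normalization; empty
datasets cannot be fitted or aggregated; the logistic argument is
clipped at ±500 before exponentiation (the function saturates long
before); non-finite gradients or errors abort training with the error
history attached; all-zero (or any non-positive) fitness vectors are
rejected by roulette selection, which ε in the fitness prevents from
arising in practice.  Seeds derived inside pipelines come from
`numpy.random.SeedSequence` children of the user's single seed and fit
in 31 bits.

## Known limitations

* The surrogate forward model is not an optical model; absolute error
  magnitudes are not comparable to laboratory values.
* The as-printed E_MSE (mean of squared E_p) compresses small errors
  heavily; comparisons across datasets should prefer the conventional
  mean E_p, which the package always reports alongside.
* The GA searches a fixed hypercube [−1, 1]ⁿ of initial weights;
  nothing adapts the search range to the network size.
* Ten-trial variances, the stability evidence format of the underlying
  experiment, have wide sampling error; treat variance comparisons as
  descriptive.
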