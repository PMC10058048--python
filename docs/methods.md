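# Methods

## Data and encoding

The packaged dataset is a 27-run 3×3×3 full factorial design of
microwave-assisted chamomile extraction: microwave power (400/600/800 W),
extraction time (20/30/40 min), and solid-to-solvent ratio 1:X with
X ∈ {40, 60, 80}. The ratio is encoded as the solvent parts X, so "more
solvent" is numerically larger; the yield response is the total phenolic
content (TPC) in mg gallic-acid equivalents per g. Power is treated in
watts throughout. Duplicated design points are rejected rather than
averaged, and missing values are not imputed — the loader reports the
offending row and column instead.

Inputs and the response are min-max scaled onto [−1, 1], the natural range
for a tanh hidden layer; the scaler is fitted on the full dataset once per
analysis so all ensemble members share one coordinate system, and all
reported metrics are transformed back to raw mg/g. The equivariance of the
raw-unit metrics to the target interval (e.g. [0, 1] instead of [−1, 1]) is
covered by a test.

## Network and training

The surrogate is a single-hidden-layer perceptron, 3-8-1, tanh hidden
activations and a linear output. Training minimises the sum of squared
residuals on the training split by Levenberg–Marquardt: solve
(JᵀJ + λI)δ = −Jᵀr with the analytic Jacobian (verified against central
finite differences), accept a step only if the training SSE strictly
decreases (λ ×0.1 on acceptance, ×10 on rejection). Defaults: λ₀ = 10⁻³,
λ ceiling 10¹⁰, at most 500 iterations, SSE-change tolerance 10⁻¹⁰ (scaled
units), gradient tolerance 10⁻⁸. Weights are initialised i.i.d. uniform on
[−0.5, 0.5]. The 70/30 split draws round(0.7·n) training points (ties
rounded half away from zero) from a seeded permutation; with n = 27 that is
19 train / 8 test. The test split is reporting-only: with eight points,
validation-based early stopping would be noise.

A 3-8-1 network has 41 free parameters against 19 training points, so each
fit interpolates its training split almost exactly (train R² ≈ 1) and
single-network test metrics are volatile. That is deliberate: the ensemble
of 20 fits (seeds base, base+1, …, base+19, each with a fresh split and
initialisation) is the estimator. The champion (best test R², ties by lower
test MAE then lower seed) is kept for parity reporting; the ensemble *mean*
prediction, which smooths the interpolation artifacts, is the default
objective for optimisation.

## Relative importance

The contribution of input i to the output is attributed through the
connection weights: RIᵢ% = (Σₖ wᵢₖwₖⱼ) / (Σᵢ|Σₖ wᵢₖwₖⱼ|)·100, summing over
the hidden neurons k = 1…8 and normalising over the inputs i = 1…3. Biases
are excluded — they carry no input index, which is the standard
connection-weights convention. Signed values are kept per member (the sign
marks direction of effect); the ensemble summary reports mean and
population SD of |RI| per factor, since importance bars are conventionally
positive. Σ|RI| = 100 to 10⁻⁹ is enforced as a property test over random
weight draws.

## Particle swarm search

The optimum of the fitted surface is located by the canonical
inertia-weight particle swarm: v ← ωv + c₁r₁(pbest−x) + c₂r₂(gbest−x),
x ← clip(x+v), with ω = 0.729, c₁ = c₂ = 1.49445 (constriction-equivalent
constants), 40 particles, velocity capped at half of each factor's range
and zeroed on clipped dimensions, at most 200 iterations, stalling when the
global best improves by < 10⁻⁸ over 30 iterations. Positions initialise
uniformly in the box, velocities uniformly within the cap. The global-best
trace is retained (and is non-decreasing by construction). The continuous
argmax is primary; an optional snap rounds to whole watts, minutes and
solvent parts for practical reporting.

## Synthetic surfaces and what passing tests show

The generator draws yields from a full quadratic in the three factors
(linear + pure quadratic + pairwise interactions) plus i.i.d. Gaussian
noise. This is the simplest family with interior optima and factor
interactions, and its box-constrained argmax is computable exactly: the
stationary point of the quadratic when the Hessian is negative definite,
otherwise a 201-points-per-axis grid scan refined by bounded L-BFGS-B. A
"chamomile-like" preset ships whose coefficients were frozen once from an
ordinary-least-squares quadratic fit to the packaged table (artifact
constants, not measured claims); its default noise SD of 1.5 mg/g
represents a replicate-scale error of roughly 3% of the mean yield, chosen
because the design has no replicates from which to estimate one.

Recovery tests run the entire pipeline on noiseless concave surfaces
sampled at the 27-point grid and require the recovered argmax to lie within
10% of each factor's range of the analytic argmax, averaged over five
independent base seeds. Passing shows the machinery (scaling, training,
ensembling, swarm search) finds a known optimum of a smooth surface from
grid data; it does not certify behaviour under model misspecification,
replicate noise structure, or factors outside the tested box.

## Design choices and limitations

- **Ensemble-mean objective.** A single interpolating network has spurious
  bumps between grid points; averaging 20 of them yields a usable surface.
  The champion objective remains selectable.
- **Problem sizes.** All analyses use the full 27-run design, 20-member
  ensembles, and five-seed replications where variability across seeds is
  itself reported; these sizes make every driver and the whole test suite
  run in seconds while leaving the estimators' variability visible.
- **Reference comparison.** The runner `headline_checks` compares a report
  against the reference findings for this dataset. The data-table checks
  (max 59.56 mg/g at 800 W/40 min/1:80; runner-up 58.435 mg/g) are exact.
  The model-derived checks are soft: the factor ranking
  (solvent > … > power) holds for most seeds, but the reference optimum
  (400 W, 30 min, 1:80, predicted 59.56 mg/g) is only partially
  reproducible from the data itself — the measured yield at exactly
  (400 W, 30 min, 1:80) is 46.16 mg/g, while (400 W, 30 min, 1:60) gives
  58.435 mg/g, so a faithful fit places the solvent coordinate of the
  optimum near 1:60–1:65 and its predicted yield near 56–58 mg/g. The
  discrepancy is reported, not hidden.
- **Degenerate inputs.** Constant factor columns, duplicate design points,
  empty tables, non-finite weights, all-zero connection products and
  non-finite objective values raise typed errors naming the offender.
- **Out of scope.** No architecture search beyond the hidden-neuron count,
  no regularisation, no alternative trainers or importance measures, no
  genetic-algorithm optimiser, no replicate averaging.
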