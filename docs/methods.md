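# Methods

This note documents the models, numerical choices and design decisions
behind `fixfit`, in the spirit of a model-documentation page: what is
computed, under which assumptions, with which defaults, and what the
synthetic experiments do and do not demonstrate.

## 1. The identifiability estimate

A forward model is a deterministic map from I native parameters to a
D-dimensional output. The pipeline trains fully connected
encoder–bottleneck–decoder networks to reproduce that map while forcing all
information through a linear bottleneck of width k. If the map factors
through a k-dimensional quantity (as the Kepler orbit factors through
(e, l)), a k-width network can in principle reach the same error as wider
ones; if not, a capacity gap appears. The estimated number of identifiable
latent parameters k\* is therefore read off the saturation point of the
validation error as a function of k.

*Selection rule.* At each k we train several replicates from different
seeds and record each replicate's minimal validation MSE. Let k_min be the
width with the lowest mean error. k\* is the smallest k whose replicate
errors are not significantly worse than k_min's under a one-sided Welch
t-test at α = 0.05. The test is deliberately conservative with few
replicates: a genuinely saturated k is rarely rejected, while the error
gap below the true dimension is typically many standard errors wide. The
statistical test behind "not significantly worse" is a configuration point
(`select_k(..., alpha=...)`), not a law; with replicate counts this small,
rank-based tests have essentially no power, which is why a t-test is the
default.

*Degenerate cases.* If all widths perform identically, the rule returns the
smallest swept k. Replicates that diverge (non-finite loss) are recorded as
NaN and excluded; at least two finite replicates per width are required.

## 2. Network engine

No deep-learning framework is part of the dependency set; the networks here
are small and dense, so the engine is a compact numpy implementation:

* Dense layers, Glorot-uniform initialization, biases at zero.
* Activations: tanh (Kepler preset), ReLU (glucose/brain presets), linear
  bottleneck and output layers in all presets. The linear bottleneck keeps
  the latent space an unconstrained affine readout of the encoder.
* Adam (lr 1e-3, β₁ 0.9, β₂ 0.999, ε 1e-8) on mean squared error,
  shuffled minibatches of 256, float32 arithmetic.
* Early stopping on the validation MSE with best-weight restoration;
  training stops `patience` epochs after the last improvement.
* Everything is seeded through `numpy.random.default_rng`; identical
  (spec, data, config, seed) reruns are bit-identical on a given platform.

Presets mirror the three bundled models: 4→14→14→k→110→110→100 (tanh),
6→50→50→k→150→300→300→D (ReLU; D = 289 for the inclusive 5-minute grid),
and 11→21→21→k→(D+10)→D for the brain model, where D = n(n−1)/2 scales
with the region count.

*Training budgets.* The replicate/epoch budget is a cost/variance
trade-off, not part of the method. Defaults are 10 replicates and 5000
epochs with patience 200; the bundled experiments and the acceptance script
run a reduced budget chosen in advance (3 replicates; 1000 epochs/patience
100 for the Kepler net, 500 epochs/patience 100 for the ~20× costlier
glucose net). The k\* readout was designed to be robust at this budget
because the selection rule compares replicate distributions, not single
runs.

## 3. Forward models

### Kepler orbit

Closed form: r(θ) = l / (1 + e cos θ) with e = |r₀³ω₀²/(G m₂) − 1| and
l = r₀⁴ω₀²/(G m₂); G = 0.5 in rescaled units so all sampled parameters are
O(1). Outputs are ln r at 100 evenly spaced θ ∈ [0, 2π] (endpoint
inclusive). An independent oracle integrates the radial equation of motion
(states r, ṙ, θ; conserved L = r₀²ω₀; adaptive RK45 at rtol 1e-8/atol
1e-10) and agrees with the closed form to better than 1e-3 relative; it is
used only in tests. For r₀³ω₀² < G m₂ the printed composite formulas make
r₀ the apoapsis rather than the closest approach; the code follows the
formulas on both branches and `apsis_branch` records which geometry a
sample is on.

### βIG glucose regulation

Three states (glucose G, insulin I, β-cell mass β) with meal boluses as
Dirac impulses: at each meal time G jumps by u_ext and integration
restarts, which treats the impulse exactly. I(0) and the endogenous input
u₀ are chosen to zero dG and dI at t = 0. The fixed points G₀ = 5 mM and
β₀ = 300 (a.u.) follow the standard operating point of this model lineage
(fasting glucose 5 mM; β₀ sets a plausible fasting insulin of ≈ 8.7 µU/ml)
and are configurable, since different sources scale β differently. μ± are
fixed because they move β by < 1%/day — confirmed by the drift experiment
below.

*Integrator.* A vectorized fixed-step RK4 (default dt = 0.1 min) advances
the whole Sobol batch simultaneously, segmented at meal times; outputs are
linearly interpolated onto the 5-minute grid (289 points over an inclusive
24 h). dt = 0.1 keeps h·λ ≤ ≈1.5 for the stiffest admissible parameter
corner (C + S_i·I up to ≈ 15/min), comfortably inside the RK4 stability
region; halving dt changes G by < 1e-4 relative, and the batch path matches
a scipy adaptive reference (rtol 1e-8) to ~1e-5. The batch integrator is
what makes hundreds-to-thousands of 24 h simulations cheap enough to run
routinely.

*Peak statistic.* `peak_decrease` reports 100·(h₁ − h₂)/h₁ for the
dominant glucose peaks of the first and second inter-meal windows. Strong
insulin feedback produces a damped rebound ripple after the post-meal
undershoot; windowing on meal times keeps the statistic tied to the meal
response (the intended "first and second post-meal peaks") instead of that
ripple. A windowless first-two-peaks mode is available for generic traces.

### Larter–Breakspear brain network

Per region: mean excitatory voltage V, inhibitory voltage Z, open-K⁺
fraction W, coupled through a connectome-weighted average of excitatory
firing rates with global coupling c. The 19 background parameters sit at
the standard whole-brain defaults (unitless, 1 step = 1 ms); 11 parameters
are free with narrow biological ranges. One deliberate formulation note:
the inhibitory firing rate Q_Z is implemented as a sigmoid of *V* with
threshold Z_T, following the source formulation adopted here; the classical
variant gates Q_Z on Z. The choice changes only how strongly the
inhibitory loop shapes V and is isolated in `firing_rates`.

Integration is fixed-step RK4 at dt = 0.1 ms from seed-deterministic
initial conditions near (0, 0, 0.5), with a configurable burn-in discarded.
The BOLD readout z-scores each region's voltage (making the hemodynamics
scale-free), integrates the Balloon–Windkessel system (κ = 0.65 s⁻¹,
γ = 0.41 s⁻¹, τ = 0.98 s, α = 0.32, ρ = 0.34, V₀ = 0.04 — the canonical
parameterization, exposed in `BW_PARAMS`), samples at TR = 0.8 s, bandpass
filters at 0.01–0.1 Hz with a zero-phase 2nd-order Butterworth (zero-phase
so that Pearson correlations are not distorted by filter delay), and
returns the upper triangle of the correlation matrix (3003 values at 78
regions). Under this parameterization a delta input produces a BOLD peak
≈ 3 s after the impulse (verified against a fine-step adaptive reference);
wider stimuli and other canonical HRF variants peak later.

Exclusions: a simulation is discarded when any region's post-burn-in
peak-to-peak voltage amplitude is below 0.01 (non-oscillatory) or when the
mean upper-triangle FC exceeds 0.3. The mean excludes the diagonal.

*Synthetic connectome.* A measured DTI matrix is not bundled; a synthetic
stand-in connects each region pair with probability `density` (weights
uniform on (0.5, 1.5), symmetric, isolated regions linked to a ring
neighbor so all row sums are positive). It reproduces the *format* and
gross statistics of a structural matrix, not the lognormal weight
distribution, distance dependence or community structure of real
tractography — conclusions about the brain model's parameter space at full
scale therefore require a measured matrix and cluster-scale computing, and
the bundled brain experiments are deliberately small (≈10 regions, minutes
of simulated time).

## 4. Data generation

Sampling uses an unscrambled Sobol sequence with the first (all-zeros)
point skipped — the zero point would sit exactly on every range boundary.
Kepler samples are kept only for eccentricities 0.7 ≤ e ≤ 0.95 (moderate
ellipses); the generator oversamples adaptively until the target retained
count is reached. The default targets (≈2,500 Kepler and 4,000 glucose
samples, ≈9:1 train/validation) are the desk-scale study conditions used
throughout. Kepler outputs are log-transformed; glucose traces are
min-max rescaled to [0, 1] with a *single dataset-wide* range fitted on the
training pool and frozen, preserving relative scale across samples and
avoiding train/validation leakage; FC vectors pass through unchanged.
Filtering, transforms and splitting are pure functions of (inputs, config,
seed), so pipelines rerun byte-identically.

Because simulations are noise-free and deterministic, passing experiments
here demonstrate the *structural* behavior of the method (which parameter
combinations are resolvable in principle). They say nothing about
robustness to observational noise, which the method's own logic handles
downstream (fit noisy data in latent space with an appropriate objective).

## 5. Sensitivity analysis

The uncorrelated SCSA index is computed from samples by fitting all
first-order HDMR component functions jointly: per input, a cubic B-spline
basis with 8 evenly spaced interior knots over the observed range, columns
centered; the concatenated design is solved by ridge-penalized least
squares (penalty 1e-6 of the mean Gram diagonal) against the centered
latent column. S_unc is the ratio of each fitted component's sum of
squares to the total. The joint fit is what makes the index *uncorrelated*:
with filtered (hence correlated) inputs, shared variance is partitioned by
the regression instead of being attributed to every correlated input at
once. For independent inputs and an additive model the indices recover the
classical first-order variance shares (tested to ±0.05 at N = 4096).
Indices below 0.02 are reported as "no influence". Spline order and knot
count are configuration with pinned defaults; second-order interaction
indices are out of scope.

## 6. Global fitting

Latent bounds are the per-coordinate min/max of the training-pool latents
padded by 5% of the range on each side; the optimizer works on the unit
hypercube. Basin-hopping starts at 0.5, proposes uniform displacements of
magnitude ≤ 0.2 clipped into the cube, refines each proposal with L-BFGS-B
(bounded, so the local phase cannot leave the cube — chosen over plain
BFGS for exactly that reason), and accepts hops with Metropolis probability
exp(−Δf/T). T defaults to 1.0 on the RSS scale of normalized outputs and
should be adjusted per model (lower T for sharply funneled objectives).
For decoder-based fits the gradient is analytic (backprop through the
decoder); simulator-based fits use finite differences. Forward-map
failures (e.g. a proposed Kepler parameter set with e ≥ 1) return a large
penalty (1e9) instead of raising, so the search continues. The run stops
after the iteration budget (default 100 hops) or once the best objective
has been stable for 25 consecutive hops.

## 7. Known limitations

* k\* is a statistical readout of a training procedure, and it can only
  count latent directions whose contribution to the outputs exceeds the
  achievable validation-error floor. On the Kepler task the k = 1 → 2 gap
  is ~6× and the readout is stable. On the glucose task at the bundled
  desk scale (4,000 samples, ≤1000 epochs, 3 replicates) the floor is
  ≈ 1.5e-5 (0.4% RMSE of the glucose range) and pilot runs show that
  k = 2 networks already reach it: the third and fourth identifiable
  directions carry less output variance than the floor, so the selected
  k\* is unstable in the 2–5 range, and resolving the full four-dimensional
  structure requires the full-scale budget (≈2× the samples, 5000 epochs,
  patience 200, 10 replicates — available via `TrainConfig` but an order of
  magnitude more compute). Weakly expressed latent dimensions are exactly
  the regime where this scaled-down screening is expected to undercount.
* The latent representation is not unique — any diffeomorphism of it is
  equally valid — so latent coordinates are comparable only within one
  trained replicate.
* The SCSA implementation reports first-order (exclusive) contributions
  only; inputs acting solely through interactions would appear silent in
  all rows.
* The brain model at full 78-region scale, with the associated thousands
  of long simulations, is intentionally out of the desk-scale test
  envelope; its bundled configuration demonstrates mechanics, not
  neuroscience.
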