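# Methods

## Model and observation equations

Tissue kinetics follow the one-tissue compartment model: the myocardial
tissue concentration (Bq/g) is

    C_T(t) = K1 · e^(−k2 t) ⊗ C_A(t),

with influx rate K1 (mL/min/g), efflux rate k2 (1/min), and arterial input
C_A (Bq/mL). A PET voxel or VOI in the myocardium additionally sees blood
signal — true arterial blood volume plus spillover from the LV and RV
cavities caused by limited resolution and motion — so the observed activity
(Bq/mL) is modeled as

    C_PET(t) = ρ (1 − V_A − V_RV) C_T(t) + V_A C_A(t) + V_RV C_RV(t),

frame-averaged over the acquisition schedule. The RV term is optional
(three- vs four-parameter model). The tissue density ρ = 1.05 g/mL that
converts Bq/g to Bq/mL is folded into the observation model rather than
applied to the measured TAC: dividing the whole voxel TAC by ρ would also
divide the blood terms and silently rescale V_A and V_RV, whereas with ρ in
the model every parameter keeps its natural meaning and is exactly
recoverable from synthetic data. `timing_io.density_convert` remains
available as a standalone unit conversion.

All times are seconds from injection internally; K1 and k2 are converted at
the API boundary. TACs are decay-corrected concentrations referenced to
injection time throughout (the acquisition convention most scanners emit);
this assumption is documented rather than configurable.

## Numerical core: exact exponential convolution

The response y(t) = ∫₀ᵗ e^(−k2(t−s)) C_A(s) ds satisfies y' = C_A − k2·y.
For a piecewise-linear input the update across one sampling interval is
closed-form, so y is propagated node-to-node on the union grid of curve
samples and frame edges with no discretization error, and frame averages
follow from the same ODE: ∫ₐᵇ y dt = (∫ₐᵇ C_A dt − Δy)/k2 for k2 > 0, with
the k2 = 0 limit (the running integral, piecewise quadratic) integrated
analytically. Relative agreement with a 1 ms Riemann-sum oracle is limited
only by the input curve's own sampling. The same primitive drives the
basis-function matrix, the forward simulator, and the exponential
dispersion kernel of the blood monitor.

For very small rates (k2·Δt ≲ 1e−10) the ODE identity loses a few digits to
cancellation; the grid floor of 0.01/min keeps this far from mattering, and
k2 = 0 takes the exact branch.

## Fitting: basis function method

For each k2 on a 100-point log-spaced grid over [0.01, 12] /min (covering
rubidium washout at rest through water washout at high stress, granularity
being a free choice), the remaining parameters enter linearly:
θ = (amplitude, V_A[, V_RV]) with amplitude = (1 − V_A − V_RV)·K1. The
weighted linear problem is solved per voxel under amplitude ≥ 0, V_A ≥ 0,
V_RV ≥ 0, V_A + V_RV ≤ 1; the unconstrained solution is used when feasible
(the common case, solved for all voxels at once from shared normal
equations), with NNLS plus a bounded solve on the active face otherwise.
The cap on the blood fractions is exactly 1, not slightly below it:
pure-blood voxels legitimately reach it with amplitude exactly 0, giving
K1 = 0 (the denominator of K1 = amplitude/(1 − V_A − V_RV) is floored at
1e−3); a cap strictly below 1 would force a spurious tissue term whose K1
is inflated by the tiny denominator. Constraint-active solutions carry an
`on_boundary` flag and are never silently altered.

The grid minimizer (ties resolve to the smaller k2) is refined by
golden-section search in log k2 between its grid neighbors — run in
lockstep across voxels, each iteration evaluating one exact basis column
per voxel — for 40–48 iterations, shrinking the bracket by ~10 orders of
magnitude. On noiseless data this recovers off-grid k2 to ≪0.1 %.

WLS weights follow the noise-equivalent-count family:

    w_i = Δt_i² · dcf_i⁻² / max(c_i Δt_i, ε),   dcf_i = e^(λ·mid_i),

normalized to mean 1 — the inverse frame variance implied by Poisson-like
raw counts after decay correction. The exact weight formula is a modeling
choice isolated behind the `FitWeights` type so alternatives plug in.

## Blood processing

The monitor chain is background → calibration → dispersion → delay:

* **Background**: rubidium elution systems leave residual activity in the
  unflushed infusion line, visible as a decaying signal before the bolus.
  An exponential with the rate fixed at the tracer λ is fit on a pre-bolus
  window (closed form) and subtracted; negatives are floored at 0 after,
  never before, the fit. The default window ends 5 s before the detected
  bolus arrival (first sample above 5× the pre-peak median).
* **Calibration**: counts/sensitivity, decay-corrected to injection time.
* **Dispersion**: the external (catheter/detector) dispersion is modeled as
  convolution with (1/τ)e^(−t/τ); its inverse is applied in derivative form,
  c_true = c + τ·dc/dt, with a 3-point moving-average pre-smooth and central
  differences. τ defaults to 2.5 s and is configurable; the derivative form
  round-trips a smooth bolus to <2 % RMS over the peak but overshoots at
  true discontinuities — an inherent property of this correction. No
  internal-body dispersion correction is applied.
* **Delay**: the shift maximizing Pearson correlation between the
  frame-averaged blood curve and the LV TAC, searched at 0.5 s steps over
  ±30 s; ties resolve to the smallest |shift|. Correlating on the frame
  grid matches the resolution of the reference TAC.

## IDIF correction

The LV-cavity IDIF is compared to the arterial curve via peak, tail (the
duration-weighted mean over 160–220 s, i.e. 1 min starting at 2 min 40 s),
and AUC, with percent differences referenced to the arterial value. Four
correction models are estimated per scan by WLS (reusing the NEC weights of
the LV TAC — the weighting for these fits is a package choice): the
one-parameter recovery mixture β·C_A + (1−β)·C_T, the free two-parameter
mixture, the WLS-optimal scale β_s, and the AUC-ratio scale β_AUC. The
tissue reference C_T is the fitted tissue component of the three-parameter
(no RV) model applied to the global myocardium TAC. β for the one-parameter
model is estimated unconstrained and flagged when outside (0, 1] rather
than clipped, preserving its diagnostic value. In the population workflow
IDIFs are multiplied by the reciprocal of the mean per-tracer β_AUC
(arithmetic mean across scans).

## Flow and extraction

Water: MBF = k2·p with p = 0.91 mL/g. Rubidium: the generalized
Renkin-Crone model K1 = MBF·(1 − a·e^(−b/MBF)), where b reflects the basal
permeability–surface-area product and a its flow dependence; extraction
E = K1/MBF → 1 as flow → 0 and → 1 − a as flow → ∞. The model is strictly
increasing in flow for a ∈ (0,1), b > 0 (verified numerically across a
parameter grid), so flow is recovered from K1 by Brent root-finding on a
default bracket of [1e−3, 10] mL/min/g.

(a, b) are estimated from paired (MBF, K1) measurements by weighted
orthogonal distance regression (scipy.odr), with per-point weights equal to
reciprocal error variances on each axis — e.g. the reciprocal VOI voxel
variances of the two parametric maps. The objective can have shallow
valleys at small n, so a 5×5 grid of starts over a ∈ [0.5, 0.95],
b ∈ [0.2, 1.0] plus (0.8, 0.5) is tried and the lowest objective wins.
Standard errors come from the ODR asymptotic covariance; a seeded
pair-resampling bootstrap is available for small n. The unweighted variant
is exposed (it is known to yield higher estimates). Bundled reference
parameter sets — (0.77, 0.39) for AUC-scaled IDIFs and (0.74, 0.51) for
uncorrected IDIFs on TOF/PSF reconstructions — serve as defaults for
K1 → MBF conversion.

## Agreement statistics

Deming regression (closed form; the variance ratio δ is the y-to-x error
variance ratio, default 1 since no protocol-specific value is better
motivated; jackknife SEs), Lin's concordance correlation on population
moments, and Bland-Altman on percent differences with the **pair mean** as
denominator — deliberately distinct from the curve-validation metric, which
uses the arterial reference as denominator. The reproducibility coefficient
is 1.96 × the sample SD of those percent differences.

## Synthetic data: what it emulates and what it does not

The phantom is concentric cylinders — LV cavity (radius 10 mm), myocardial
shell (thickness 10 mm), optional RV crescent (8 mm) — on a 48³ grid of
2.036 × 2.036 × 2.0 mm voxels, the smallest geometry exhibiting
LV/RV/myocardium spillover structure. The input function is a gamma-variate
bolus (shape α = 2, arrival 10 s, peak 25 s, peak 50 kBq/mL — typical of a
weight-independent rubidium elution) plus an exponential recirculation tail
anchored to 15 % of the peak at 3 min; all shape parameters are
configurable and the curve is linear in its amplitude by construction.
Resolution is a Gaussian blur applied per frame before noise; noise is
Gaussian with variance noise_scale² · value · dcf²/Δt, chosen so the NEC
weights are exactly inverse-variance, rather than a full Poisson list-mode
simulation. The monitor simulation applies delay, exponential dispersion,
decay un-correction, sensitivity, a decaying background, and count-like
noise, in that order. Every stochastic draw derives from one integer seed.

What passing tests on this phantom demonstrate: the estimators are
mutually consistent, exactly invert their own forward model, and are
unbiased at the simulated noise level. What they do not demonstrate:
robustness to cardiac/respiratory motion, reconstruction artifacts,
non-Gaussian noise, anatomical variability, or VOI placement error — none
of which the generator models.

## Study conditions and problem sizes

The reference simulation study uses six flow levels (0.5, 0.9, 1.5, 2.5,
3.6, 5.0 mL/min/g) spanning rest to high stress, the 32-frame 4-min
schedule (20×3 s, 6×10 s, 6×20 s), myocardial V_A = 0.30 and V_RV = 0.05,
rubidium washout k2 = 0.08 + 0.04·MBF, and water K1 = MBF, k2 = MBF/p. Its
default is noiseless and blur-free, making the pipeline exactly invertible;
noise and blur are opt-in. The Monte Carlo extraction-recovery study draws
9 subjects × 2 conditions per replicate from rest ~ N(0.96, 0.20²) and
stress ~ N(3.73, 0.96²) mL/min/g (population spread of healthy adults),
applies 5 % proportional measurement error on both axes — parametric-map
SEs on modern TOF/PSF reconstructions are small relative to inter-subject
spread — and fits 500 replicates with the known measurement variances as
weights. Test and acceptance runs use 16³–48³ phantom grids and 1 s or
0.2 s input-curve sampling; these sizes are stated here as the package's
reference conditions.

## Known limitations

* The dispersion correction is a derivative-form inverse; heavy monitor
  noise requires stronger pre-smoothing than the default 3-point window.
* NEC weights assume the frame noise model above; scanner-specific weight
  schemes should be supplied through `FitWeights`.
* The basis-function fitter assumes the input curve is noiseless; input
  noise propagates into all voxels coherently.
* `fit_parametric` fits voxels independently; no spatial regularization.
* The ODR asymptotic SEs understate uncertainty at very small n; use the
  bootstrap there.
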