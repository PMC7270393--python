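# Methods

This note documents the models implemented in `lungkin`, the choices made
where the design was genuinely open, and what the synthetic data do and do
not establish about real scans.

## Quantification model

The measured PET signal in a lung region or voxel is modelled as

    C_model(t) = (1 − V_b) · C_tissue(t) + V_b · C_wb(t − Δ)

where `C_wb` is the arterial whole-blood curve, `V_b` the fractional blood
volume and Δ a time shift between the blood and tissue clocks (positive Δ:
tissue lags blood; bounded to ±30 s by default).  The (1 − V_b) factor is
the volume-conserving convention; a pure-additive variant
(`convention="additive"`) is available because the literature uses both.
Both the plasma term driving the tissue and the whole-blood term are
shifted by the same Δ.

Tissue kinetics follow the one- or two-tissue compartment model:

* 1TCM: impulse response `K1 · exp(−k2 t)`, total distribution volume
  `V_T = K1/k2` (ml plasma per cm³ tissue);
* 2TCM: bi-exponential impulse response with the standard `α1/α2` roots of
  the system `(k2, k3, k4)`, and `V_T = K1/k2 · (1 + k3/k4)`.  `k4 = 0`
  (irreversible trapping) leaves `V_T` undefined and is flagged rather
  than reported.

The forward solution is computed analytically: the plasma input lives on a
uniform 1-s grid and is treated as piecewise linear, so the convolution
with `exp(−θt)` satisfies an exact first-order recursion per grid step
(evaluated with an IIR filter; a series expansion below θ·dt = 1e−4 avoids
cancellation, and θ = 0 degenerates to the running integral).  Model TACs
are exact frame averages of this fine-grid curve (trapezoid within each
frame).  The test suite verifies the solver against a stiff ODE
integration of the same compartment equations to ~1e−8 relative.

Air-fraction correction is deliberately absent: the TAC is modelled as
measured, and `V_T` refers to the physical voxel volume including air.

## Input function

The arterial plasma input is image-derived: the whole-blood TAC of an
aortic-arch ROI, linearly interpolated from frame mid-times onto a 1-s
grid with a (0, 0) anchor at injection and constant hold beyond the last
mid-time (linear interpolation avoids the overshoot of splines on bolus
peaks; constant hold is needed when the fitted time shift moves the input
window).  The plasma curve is the whole-blood curve times the
plasma-to-blood activity ratio `r`, taken as the unweighted mean of
per-sample plasma/whole-blood ratios across the manual arterial samples
(the per-sample CoV is returned so near-constancy can be inspected).
Whether to average per-sample ratios or take a ratio of averages was an
open choice; the per-sample mean is the default and the quantity is a
plain argument, so either convention can be supplied.

Because a constant ratio is what one expects when the tracer is excluded
from blood cells, `r = 1/(1 − Hct)` is provided as a hematocrit shortcut;
on cohorts generated under the cell-exclusion assumption the two estimates
agree by construction.

Metabolite correction multiplies the plasma curve by a parent-fraction
model but is **not** applied by default: quantification uses total plasma
activity, and the correction exists for comparison only.  The parent
fraction uses a Richards (generalized-logistic) family,

    f(t) = f∞ + (1 − f∞) · g(t)/g(0),
    g(t) = (1 + ν·exp(B(t − M)))^(−1/ν),

normalized by g(0) so that f(0) = 1 exactly (only parent compound at
injection).  Defaults (f∞ = 0.5639, B = 0.4169 min⁻¹, M = 0.1 min,
ν = 10) describe a moderately metabolized tracer with f(30 min) = 0.69
and f(60 min) = 0.60.

## Multilinear Logan analysis

For frames with mid-time beyond the linearity onset t*, the operational
equation

    C_T(T) = P1·∫₀ᵀ Cp dt + P2·∫₀ᵀ C_T dt,    V_T = −P1/P2,

is fitted by OLS with `C_T(T)` as the response — the multilinear
rearrangement that keeps the noisy TAC out of denominators.  Integrals are
trapezoidal with a (0, 0) anchor: the input on its 1-s grid (sampled at
frame mid-times), the TAC over mid-times.  For a one-tissue system the
equation is exact at every T, so noiseless V_T converges to K1/k2 up to
integration error (≲0.3% on the 38-frame schedule).

The graphical V_T of an *uncorrected* TAC absorbs the intravascular
signal: it converges to `(1 − V_b)·K1/k2 + V_b/r` and is additionally
perturbed at finite times by the residual `V_b/r·Cp(T)` term.  The
pipeline therefore removes the blood contribution first, using the V_b and
Δ from the 1TCM fit (`blood_volume_corrected_tac`), which puts the Logan
V_T on the compartment-model scale; fitting the raw TAC remains possible
and is documented as a systematic difference.  `t*` defaults to 10 min;
`select_tstar` picks the earliest frame boundary whose post-t*
classic-Logan points deviate from their own line fit by <10% maximum
relative error, falling back to 10 min with a warning.  The classic
ratio-form plot is provided for inspection only.

## Basis-function parametric imaging

Each voxel TAC is decomposed on a table of exponential basis functions:
frame-averaged convolutions of the (shifted) plasma input with
`exp(−θ_j t)` for J = 100 exponents log-spaced between
θ_min = 0.1·ln2/20.4 ≈ 0.0034 min⁻¹ (10% of the ¹¹C decay constant) and
θ_max = 0.6 min⁻¹, plus the frame-averaged whole-blood column.  The voxel
time shift is fixed from the ROI-level compartment fit; per-voxel shifts
are not identifiable at realistic voxel noise.

The sparse nonnegative fit proceeds in two stages:

1. a positive-lasso path (30 penalty values, geometric grid) proposes
   candidate tissue supports — only the supports matter, so loose
   coordinate-descent convergence is accepted;
2. every candidate support (plus the blood-only model) is refit by exact
   nonnegative least squares with the blood column always present, so the
   coefficients entering V_T are unpenalized, and the support minimizing
   the Gaussian-RSS AIC `n·ln(RSS/n) + 2(p+1)` is selected.  RSS values
   below 1e−12 of the signal energy are floored: below that the residual
   is numerical dust and AIC would otherwise reward meaningless extra
   components.

The model order (MO) counts tissue components after two adjustments:
chains of adjacent grid nodes merge into one component (an off-grid rate
is represented by a doublet of neighbouring exponents — grid
discretization, not extra kinetics), and components carrying less than
1e−3 of the total coefficient mass are ignored as numerical dust.

Outputs per voxel: `V_b = φ_b`, `MO`, and the raw sums `K1_raw = Σφ_j`,
`V_T_raw = Σφ_j/θ_j` (always recomputable from the stored coefficients).
Under the volume-conserving convention the tissue coefficients absorb a
(1 − V_b) factor, so the reported `K1` and `V_T` are the raw sums rescaled
by 1/(1 − φ_b), putting them on the compartment-model scale; both raw and
rescaled values are kept.  Voxel-wise estimation runs only inside the
inclusion labels (lung, optionally aorta); heart/liver and background
voxels carry NaN.

## Model comparison

`AIC = n·ln(RSS/n) + 2p` (no small-sample correction by default; AICc
available) and the one-tailed (right) F test
`F = ((RSS₁−RSS₂)/(p₂−p₁)) / (RSS₂/(n−p₂))` compare the nested 1TCM/2TCM
fits; the preferred model is the AIC minimizer, with the F p-value
reported alongside.  When both fits reach the optimizer's numerical noise
floor (RSS below 1e−12 of the signal energy) the comparison is declared a
tie and the simpler model preferred — on noiseless data the RSS ratio at
the floor is floating-point dust and would otherwise decide the
comparison at random.  Poorly identified 2TCM parameters are surfaced via
relative standard errors (from the Gauss–Newton covariance); a parameter
with rel. SE > 50% is listed as non-identifiable.

Fits are weighted nonlinear least squares (uniform weights by default; a
duration/decay heuristic `w ∝ duration·exp(−λt)` is available since the
appropriate weighting is acquisition-dependent), started from a
deterministic 3×3 grid over K1 ∈ {0.01, 0.03, 0.05} and
k2 ∈ {0.005, 0.015, 0.05} — no random restarts, for reproducibility.
V_b and Δ are free in both models by default (they can be fixed, e.g.
from a prior 2TCM fit); whether the simpler model should share them is a
convention choice, and symmetry keeps the AIC comparison fair.

## Test–retest and time stability

Per subject, `VAR = |V_T,test − V_T,retest| / mean · 100` (symmetric,
scale-invariant).  Cohort reliability uses the one-way random-effects
ICC(1,1) = (MS_B − MS_W)/(MS_B + MS_W) for k = 2 sessions — the standard
choice for PET test-retest; the two-way consistency ICC(3,1) is available.
Cohort summaries report mean ± SD of test and retest V_T, mean (min–max)
and median VAR, ICC and n per method × duration; medians are emphasized
because test-retest cohorts are small.

Time-stability analysis truncates each TAC to the frames ending within a
target duration (default grid 30–90 min in 10-min steps), refits each
method, and summarizes across subjects the median V_T ratio to the
full-duration reference and the median recomputed VAR.  Durations leaving
fewer than 5 frames are skipped with a warning.

## Synthetic data

The generator emulates a bolus-injection ¹¹C lung study:

* **Frame schedule** — 9×10, 2×15, 3×20, 4×30, 4×60, 4×180, 12×360 s:
  38 frames, 93 min.
* **Whole-blood curve** — `A(1 − e^{−r t})·Σ wᵢe^{−μᵢt}` with rise
  6 min⁻¹ and washout (2.0, 0.25, 0.015) min⁻¹ at weights
  (0.70, 0.20, 0.10): a sharp bolus peak (~20 s), a several-fold drop over
  the first 10 min, slow decline thereafter.  An exponential rise is used
  rather than a gamma-variate factor so that zero washout rates produce a
  plateau (a clean limit case).  These shape parameters are illustrative,
  not estimates of any measured curve; the amplitude (~45–75 kBq/cm³)
  varies across subjects like an injected-dose difference.
* **Plasma curve** — whole blood × r, with r = 1/(1 − Hct) from a
  subject-level hematocrit ~N(0.44, 0.03).
* **Lung kinetics** — one-tissue truths drawn uniformly from
  K1 ∈ [0.02, 0.05] ml/cm³/min, k2 ∈ [0.01, 0.02] min⁻¹,
  V_b ∈ [0.05, 0.27], Δ ∈ [0, 10] s — the observed ranges for this kind
  of slowly equilibrating lung radioligand (V_T ≈ 1–5 ml/cm³).
* **Noise** — Gaussian per frame with
  `var = scale²·value·e^{λt}/duration`, λ = ln2/20.4 min⁻¹: the standard
  count-statistics frame-weighting heuristic.  The default scale 0.05
  yields a few-percent late-frame noise on ROI TACs; values are not
  clipped at zero.
* **Test–retest cohorts** — session-2 parameters are session-1 values
  times independent lognormal factors with CoV 7% per parameter (K1, k2,
  V_b and input amplitude), chosen so that V_T (whose CoV is then ≈√2×7%)
  shows a median test-retest VAR near 10% once fit noise is added.
  Blood-sample tables are generated at the nominal manual sampling times
  (2.5–90 min).
* **Phantom** — a 32×32×24 grid with two lung ellipsoids (~2500 voxels),
  an aorta tube carrying the whole-blood curve, and heart/liver blocks
  meant to be excluded.  V_b follows a periphery→hilum gradient; K1 and
  V_T increase apex→base (k2 = K1/V_T per voxel).  Geometry is schematic,
  desk-scale — not anatomical.

What passing tests show: the estimators are consistent and mutually
coherent on data generated by exactly the assumed models, at realistic
parameter values and noise.  What they do not show: robustness to
breathing motion, air-content variation, scanner physics (scatter, PSF,
attenuation errors), input-function dispersion or delay miscalibration,
or model misspecification — none of which the generator emulates.

## Problem sizes and numerics

The shipped analyses use a 100-draw recovery sweep, the 2488-lung-voxel
phantom, 6-subject cohorts (12 sessions) for model selection and time
stability, and a 1000-pair cohort for the variability calibration check —
sizes at which every result in the README reproduces in minutes on a
laptop.  Optimizer tolerances are `xtol = ftol = 1e−12` with analytic
forward curves, giving noiseless parameter recovery at ≲1e−9 relative;
the DEPICT path uses 30 penalty values and NNLS refits.  Degenerate
inputs (empty masks, all-zero TACs, single blood samples, zero total
variance, t* beyond the acquisition) raise or warn explicitly rather than
returning silent numbers.

## Known limitations

* The graphical and basis-function V_T are tied to the compartment scale
  through the (1 − V_b) correction; under the additive blood convention
  the correction is skipped and the scales differ accordingly.
* MO counting depends on the declared merge and dust rules; other
  reasonable rules shift MO at boundary voxels (where partial-volume
  mixtures genuinely contain two kinetics).
* The AIC noise-floor tie rule is a numerical guard, not a statistical
  statement; with any realistic noise it never triggers.
* Richards defaults describe one metabolism profile; fitting real parent
  fractions should always re-estimate them.
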