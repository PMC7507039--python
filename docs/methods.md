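# Methods

This note documents the models, the numerical choices and the synthetic
data that the package's tests exercise, and what those tests do and do
not demonstrate about real data.

## Signal model and T1 mapping

All image synthesis and inversion uses the spoiled gradient-echo (SPGR)
steady-state closed form

    S = M0 · sin(α) · (1 − E1) / (1 − E1·cos(α)),   E1 = exp(−TR/T1),

at TR = 3.2 ms, TE = 1.6 ms (T2* decay at this echo time is neglected —
the standard assumption for permeability work at short TE). T1 and M0 are
estimated per voxel from the seven-angle variable-flip-angle block
(2°, 5°, 10°, 15°, 20°, 25°, 30°) by the classical linearization: S/sin α
regressed on S/tan α has slope E1 and intercept M0(1 − E1), so one
ordinary least-squares line per voxel yields both parameters in closed
form. Voxels with mean signal below 10⁻⁶ of the series maximum, or with a
slope estimate outside (10⁻⁶, 1 − 10⁻⁶), are marked `fit_ok = False` and
excluded downstream rather than propagating garbage. An iterative
nonlinear refinement exists (`method="nls"`) but is off by default; on
noiseless data the two agree to machine precision, and the linear form is
what a clinical workstation computes. No B1 / flip-angle-error correction
is applied; with miscalibrated transmit fields the absolute T1 (and hence
concentration) would be biased, which is a known limitation of VFA
mapping in general.

## Concentration conversion

The dynamic series (45 frames, one every 8 s, flip angle 15°) is inverted
frame by frame for R1(t) given the pre-contrast M0 map, and

    C(t) = (R1(t) − R1(0)) / r1,

with relaxivity r1 = 3.6 /(s·mM) (gadodiamide at 3 T). R1(0) comes from
the pre-contrast T1 map by default (the T1 block is acquired before
injection); a config switch re-estimates it per voxel from the mean of
the first 5 frames, which trades noise for immunity to any static
T1-map error. Signals at or beyond the SPGR saturation bound M0·sin α are
non-invertible; such samples become NaN and are counted in a QC log.
Negative concentrations from noise are deliberately *not* clipped — 
clipping would bias low-permeability estimates upward.

## Input function

Two routes:

* **Measured**: the mean concentration curve over a venous-sinus mask,
  divided by (1 − hematocrit), hematocrit 0.45. The venous curve is used
  directly as the arterial input, without delay or dispersion correction,
  matching common clinical practice for brain permeability studies (the
  superior sagittal sinus gives a partial-volume-free blood signal).
* **Population**: a deterministic analytic curve — a gamma-variate
  first-pass bolus (amplitude 2.5 mM, time-to-peak 0.25 min) plus the
  classical bi-exponential gadolinium washout (amplitudes 3.99 and
  4.78 kg/L scaled by the 0.1 mmol/kg dose; rates 0.144 and 0.0111 /min)
  with a 0.1-min exponential rise, zero before the bolus-arrival
  parameter (40 s, i.e. frame 6 of 45). The peak plasma concentration is
  ≈ 3.3 mM, a realistic single-dose value.

## Extended Tofts model and fitting

The tissue model is Ct = Vp·Cp + Ktrans·(Cp ⊛ exp(−kep t)), kep =
Ktrans/Ve. Times are seconds everywhere in the containers; Ktrans and kep
are in 1/min, with the unit conversion confined to the kinetic module.

**Quadrature.** The convolution solves dCe/dt = Ktrans·Cp − kep·Ce.
Writing this in integral form and applying trapezoidal quadrature to both
integrals on the acquisition grid gives the implicit (Crank–Nicolson)
recursion the forward model uses. The point of this choice is
consistency: the linear least-squares fit inverts *exactly* this
discretization, so solver and forward model agree to machine precision on
noiseless data and the discretization error (second order in the frame
spacing; < 0.1% against the constant-input closed form Ct =
Ve·c·(1 − e^(−kep t)) at the default 8-s spacing) cancels out of
round-trip tests. Halving the frame spacing shrinks the closed-form error
monotonically.

**Linear solver (default).** The reformulation
Ct = β₁∫Cp − β₂∫Ct + β₃Cp with β₂ = kep, β₃ = Vp, β₁ = Ktrans + kep·Vp is
solved per voxel by least squares. Ktrans is computed from the *raw*
coefficients as β₁ − β₂β₃ before any clipping: this combination stays
unbiased under noise, whereas clipping a slightly negative kep to zero
first would systematically drag low Ktrans estimates down (an effect of
roughly −20% at Ktrans ≈ 0.003 /min, SNR 50, in our simulations).
Estimates outside the physiological box (Ktrans ≥ 0, 0 < Ve ≤ 1,
0 ≤ Vp ≤ 1) are then clipped and flagged rather than discarded, so ROI
statistics remain computable; flag counts are reported.

**Parsimony guard.** When the pure-plasma model Ct = Vp·Cp fits as well
as the full model (residual difference below 10⁻¹² of the curve's energy)
the fitter returns the reduced model with Ktrans pinned at 0. Without
this, the no-exchange case sits on a non-identifiable ridge (Ve → 0
mimics Vp) on which the nonlinear solver can wander to arbitrary Ktrans.

**Nonlinear cross-check.** Bounded trust-region least squares (Ktrans ∈
[0, 5] /min, Ve ∈ (0, 1], Vp ∈ [0, 1]) initialized at the linear
estimate, with tight (10⁻¹²) convergence tolerances; deterministic given
the initial point. It is a validation tool: on noisy low-permeability
voxels it is *less* robust than the linear solver (bound-hugging
outliers), which is why the linear form is the default everywhere.

**Baseline handling.** Each curve's mean over the pre-bolus frames is
subtracted before fitting (default on). Static offsets — e.g. from a
noisy T1-map baseline — otherwise project onto the ramp-like regressors
and bias Ktrans at the low end.

## Morphometry

Areas are pixel counts times the squared pixel spacing; no sub-pixel
contour integration (adequate at the fixture resolutions, where one pixel
is 0.01 mm²). Stenosis degree is the narrowing percentage
(1 − LA/LA_ref)·100 — the grading thresholds (mild < 50 ≤ moderate ≤ 70 <
severe, occlusion above threshold) only make sense for the narrowing
percentage, not for the raw lumen ratio, so that is the convention
implemented. The occlusion threshold is configurable (90% default, 99%
stricter variant — both in clinical use). Extent boundaries are inclusive
at 1/3 (focal) and 2/3 (full-length).

## Cohort statistics

Thin, explicit wrappers over scipy.stats, mirroring an SPSS-style
workflow: Shapiro–Wilk normality gate at α = .05; Levene's test (center =
mean, the SPSS default) choosing pooled vs Welch t; Wilcoxon rank-sum
with exact p for combined n ≤ 20 without ties, normal approximation with
tie correction otherwise (medians and IQRs reported alongside); Pearson
chi-square **without** continuity correction; Fisher's exact test
(two-sided by the minimum-likelihood rule). For 2×2 tables the dispatcher
reports the chi-square p as primary and attaches Fisher's p plus a
warning when any expected count is below 5 — with n = 33-ish groups the
uncorrected chi-square is what the reference workflow produces, and both
numbers are always visible. The test suite checks each wrapper against an
independent brute-force oracle (hypergeometric enumeration over all
tables with N ≤ 30, rank-assignment enumeration, the summary-statistic t
algebra) and checks type-I-error calibration by simulation.

## Synthetic data: what it does and does not emulate

The phantom is a forward model of the acquisition chain: per-region T1
and M0, SPGR signals for the VFA block, extended-Tofts concentration
curves for the dynamic block, blood (plasma × (1 − hematocrit)) in the
sinus region. Noise is additive Gaussian on the magnitude signal with
SD = (mean pre-contrast dynamic signal)/SNR, applied to both series —
chosen over Rician noise for analytic tractability; at the SNR ≥ 20
regimes tested the difference is small but real data at very low signal
would be Rice-distributed. Not modelled: motion, B1 inhomogeneity,
partial-volume mixing at region boundaries, bolus dispersion between the
sinus and tissue, or k-space/reconstruction effects. Passing
parameter-recovery tests therefore demonstrates the correctness and noise
robustness of the estimation chain, not the accuracy of clinical Ktrans
values under scanner imperfections.

Unstated acquisition details were fixed once at field-typical values and
exposed as configuration: frame spacing 8 s (45 frames ≈ 6 min), 5
pre-contrast frames with bolus arrival at frame 6, dynamic flip angle
15°, r1 = 3.6 /(s·mM), hematocrit 0.45, blood T1 1700 ms, default grid
32×32×4 voxels for desk-scale runtime.

The cohort generator reproduces count-level fields exactly for every
seed — group sizes 23/10/3, per-group risk-factor counts, the over-55
counts, sex counts, and the stage-by-stenosis cells (which pin the
infarct-stage margins 10/3/10 and the occlusion count 8) — by assigning
flags to seeded random subsets of exactly the configured size. Continuous
fields are truncated-normal draws at the configured group means/SDs: ages
within their published ranges, stratified so the over-55 count is exact;
Ktrans values truncated at 0. Values the source tables do not state were
chosen once as plausible: the no-event group's mirror-side Ktrans
(0.006 ± 0.002, close to its lesion value so the within-patient contrast
is non-significant), the moyamoya age SD (5 years), and the
moderate/severe split inside "moderate-to-severe" cells (seeded coin
flip; tests only assert at the category level). Non-vasculitis patients
get unremarkable permeabilities and seeded stenosis patterns, since the
source tabulates neither.

## Problem sizes

Default test and acceptance runs use 200-voxel uniform lesion phantoms at
SNR 50 for noisy recovery (mean fitted Ktrans within 5% of truth at
0.098 /min; ~1–2% bias at 0.003–0.007 /min with per-seed spread of ~3% of
the mean), 64-voxel phantoms for noiseless round trips (< 0.1% error),
and a 12×12×2 phantom for the end-to-end demo. These sizes were chosen so
the full suite runs in seconds while keeping the Monte-Carlo spread of
every asserted mean well inside its tolerance.

## Known limitations

* No B1 correction in T1 mapping; no Rician noise model.
* The venous input function is used without delay/dispersion correction.
* Pixel-count areas are first-order; sub-pixel accuracy would need
  contour integration.
* The statistics layer deliberately applies no multiple-testing
  correction (matching the reference workflow it mirrors).
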