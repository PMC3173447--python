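# Methods

## Signal model and units

Breast DCE series in this regime sample 8 frames at 0, 1.36, 2.47, 3.59,
5.10, 6.21, 7.32 and 8.44 min, with injection immediately after the first
(baseline) frame. Because acquisition resumes well after the bolus first
pass, arterial and tumor gadolinium concentrations stay low (< 2 mM), and
signal enhancement is taken proportional to concentration: the relative
concentration is the time course minus the mean of the declared pre-contrast
frames (default one baseline frame; the baseline value is exactly zero).
The proportionality constant R is fixed to 1 for both tissue and artery.
This is legitimate because the Tofts integral is linear in C_p and C_t, so
a shared R cancels in the fitted parameters; only *relative* parameter
changes between two exams of the same patient are interpreted. Negative
post-subtraction values are retained as noise — the fit must tolerate them —
and no T1 mapping, B1 correction or signal-nonlinearity correction is
attempted (out of scope for this protocol class).

Consequences of the unit convention, verified by test:

* rescaling tissue and artery curves by the same factor leaves both
  K^trans and V_e unchanged;
* rescaling only the AIF amplitude (relative vs absolute units) leaves the
  efflux rate k_ep invariant while K^trans and V_e scale inversely with the
  amplitude. Percent changes across two exams sharing one scale are
  therefore unit-free. (Note V_e is *not* invariant under AIF-only
  rescaling — it cannot be, since V_e = K^trans/k_ep.)

## Arterial input functions

**Theoretical.** The Weinmann population biexponential
C_p(t) = D(a₁e^(−m₁t) + a₂e^(−m₂t)), a₁ = 3.99, a₂ = 4.78 kg/L,
m₁ = 0.144, m₂ = 0.0111 min⁻¹, D in mmol/kg (default 0.1). On the frame
clock the decay is started at a configurable injection offset `t0`
defaulting to the first post-contrast frame time (1.36 min), with C_p = 0
before it; the exact alignment is not observable from decay-phase data and
is exposed as a parameter. Actual body weight is likewise unobservable
here, so D is a plain configuration value.

**Measured.** A 9-pixel in-plane square (seed pixel + 8 neighbours, single
slice) is defined at the first post-contrast frame and reproduced at every
frame, optionally translated by externally supplied integer in-plane shifts
to mirror manual motion correction — no automatic registration. The mean
square signal is baseline-subtracted; units are relative (R = 1), no
hematocrit correction. A quality flag (warning) is raised when the
post-contrast peak does not exceed 1.5× the baseline standard deviation
over the square.

**Model clock for sampled inputs.** A sampled AIF carries its own `t0` (the
first post-contrast frame time). Convolution starts there: the unobserved
rise between injection and the first sample must not be linearly
interpolated as a ramp — doing so adds roughly 10% of the input integral
and biases K^trans low by tens of percent. Fitting is therefore
decay-phase-only, consistent with the acquisition assumption.

## Forward model and fitting

`tofts_forward` evaluates the convolution on a uniform grid (Δt = 0.01 min,
≈ 100× finer than the 1.11-min frame spacing). C_p is linearly interpolated
onto the grid (or evaluated analytically when biexponential constants are
known) and each step contributes its **exact** integral against the
exponential kernel, accumulated by the stable recursion
I[j+1] = I[j]·e^(−k_ep·Δt) + g[j] (evaluated with `scipy.signal.lfilter`).
A plain trapezoid step rule was rejected: its relative error ≈ (k_ep Δt)²/12
reaches ~8×10⁻⁴ at k_ep = 10 min⁻¹, whereas the exponential-kernel weights
keep the worst-case error below 10⁻⁷ over the tested parameter grid at the
same Δt, cost unchanged. Small k_ep·Δt uses series forms of the weights to
avoid cancellation; the recursion cannot overflow at any admissible k_ep.
The closed form for a biexponential input,
C_t = D·K^trans·Σᵢ aᵢ(e^(−k_ep t) − e^(−mᵢ t))/(mᵢ − k_ep), with the
removable singularity at k_ep = mᵢ evaluated by its limit t·e^(−k_ep t),
serves as the independent oracle and as the fast simulation path.

Per-curve fitting is bounded nonlinear least squares (`scipy` trust-region
reflective): K^trans ∈ [0, 10] min⁻¹, V_e ∈ [10⁻³, 1], start (0.1, 0.3).
On reported non-convergence a 3×3 log-spaced multistart grid is swept and
the lowest-RSS solution kept, ties broken toward lower K^trans. A curve
with no positive sample short-circuits to the degenerate K^trans = 0 fit
(flagged). Voxelwise maps apply the same fit over an ROI after an
enhancement pre-filter: voxels whose peak enhancement stays below 3× the
baseline noise level are masked out (necrotic/non-enhancing tissue), where
the noise level is user-supplied or estimated as the spatial SD of the
baseline frame over the ROI. Excluded voxels carry NaN and a False mask
bit, never zeros. Tumor curves are fitted on the unsmoothed subtracted
course.

## Response classification

Maps are summarized by the median over fitted voxels; percent change is
100·(post − pre)/pre. Cutoff semantics are inclusive toward responder: a
change ≤ cutoff is a responder, a strictly larger change flags
non-response. This boundary convention is pinned by the reference cohort,
where three patients sit exactly on their operating cutoffs and must count
as responders for the published counts to hold. The combined rule flags
non-response when *either* K^trans or V_e fails to drop below its cutoff;
the WHO size rule calls response at a ≥ 50% size decrease. Diagnostic rates
are reported both as raw fractions and as integer percents (rounded half
away from zero, matching printed-table style), with exact Clopper-Pearson
95% intervals for sensitivity and specificity.

## Statistics

AUC is pair-counting (ties = ½), identical by construction to the
trapezoidal area under the empirical ROC (verified on random fixtures to
10⁻¹²). For non-responder detection the positive class is grade C+D and the
score is the percent change (less negative ⇒ more suspicious); the
complete-responder analysis uses grade A as positive with the score
negated. Paired AUCs from the two AIF routes are compared with the DeLong
placement-value covariance estimator and a two-sided z test (p = 1 with a
flag on degenerate variance); its type-I error is calibrated by simulation.
Mann-Whitney U uses exact enumeration for tie-free samples with n·m ≤ 400,
otherwise the midrank normal approximation with tie-corrected variance and
continuity correction; Kruskal-Wallis uses midranks with the
1 − Σ(t³−t)/(N³−N) tie correction and a χ²(k−1) p-value. Two groups are
accepted (the three-group form is the primary use) so the reduction
H = z² against the uncorrected Mann-Whitney deviate is testable. P-values
are two-sided unless requested otherwise.

On the reference cohort the package asserts *significance calls* at
α = 0.05, not p-value digits: the packaged table holds integer-rounded
percents while the original analysis ran on unrounded source data, so
recomputed digits differ slightly (e.g. the three-group V_e test gives
H ≈ 9.87, p ≈ 0.007 rather than the printed 0.0092; one published
theoretical-AIF AUC of 0.48 recomputes to 0.49, and the published
K^trans-route DeLong p of 0.1475 is not recoverable from the rounded table
at all, recomputing to ≈ 0.001). All count-based operating points
reproduce exactly, which validates comparing at printed precision.

## Synthetic data

**Phantom.** A (24, 24, 6) grid at the 8 protocol frame times: constant
baseline signal 100 a.u.; spherical lesions following the closed-form Tofts
curve with known (K^trans, V_e); a 3×3 in-plane artery column through all
slices carrying the frame-aligned Weinmann input, so the measured-AIF
extractor recovers the generating curve exactly in the noise-free case.
The returned generating AIF is expressed in signal units (amplitude absorbs
the 100 a.u./mM gain, using linearity in dose), which under R = 1 is the
input a fit of the phantom should be driven by — making noise-free
end-to-end recovery exact to fit tolerance. Noise is Rician by default
(magnitude MRI; Gaussian available for analytic checks) with σ given as a
fraction of the peak artery signal. Lesion/artery overlap is rejected;
output is bit-identical under a fixed seed.

What the phantom does *not* emulate: anatomy and coil sensitivity, k-space
sampling, T1/T2* saturation effects, partial-volume mixing at the artery
edge, and non-rigid motion. Passing recovery tests therefore demonstrate
correctness of the numerical chain under the model's own assumptions, not
robustness to the full physics of clinical acquisitions.

**Cohort.** Percent changes are drawn per Sataloff group from logistic
distributions parameterized by a location (the group median) and a *scale
in standard-deviation units* (logistic s = scale·√3/π). Defaults follow the
clinically observed pattern for measured-AIF changes (V_e medians −90/−75/−52
for A/B/C+D, SD 12; K^trans medians −94/−89/−23, SD 15) with a 5%
heavy-tail mixture (scale ×8) producing outliers such as large V_e
increases in non-responders; theoretical-AIF changes get weaker, partly
inverted separation (SD 40 for K^trans) to mimic the poorer discrimination
of a population input. V_e and size changes are truncated at −100%;
K^trans changes are unbounded above. SD semantics (rather than the logistic
s-parameter) were chosen because they match the reference cohort's group
spreads and give the intended ≈ 99% three-group Kruskal-Wallis power at the
default separation, versus ≈ 77% under s-parameter semantics.

## Problem sizes and numerical defaults

Default validation scales, chosen to keep every check fast on one CPU while
leaving sampling error well inside the asserted bounds: forward-model
agreement on a 3×3 (K^trans, V_e) grid at the 8 frame times; noise-free map
recovery on a 27-voxel lesion; Monte-Carlo recovery at 2% Rician noise over
50 seeded phantoms; AUC equivalence on 200 random fixtures; rank-test
type-I calibration over 200 null simulations at the cohort's group sizes
(6, 7, 11); DeLong calibration over 1000 paired replicates at 40+40.
Convolution Δt = 0.01 min; fit tolerances are `scipy.least_squares`
defaults.

## Known limitations

* Absolute kinetic parameters are out of reach by design (no T1 mapping,
  relative units); only within-patient percent changes are meaningful.
* The measured-AIF route interpolates 8 decay-phase samples; first-pass
  peak information is absent, so K^trans from measured AIFs is on an
  arbitrary per-study scale.
* The extended Tofts plasma-volume term, 2CXM, deconvolution approaches,
  and automatic artery detection/registration are deliberately not
  implemented.
* The packaged cohort is integer-rounded; analyses needing unrounded source
  data (p-value digits) are reproduced at the level of significance calls
  only.
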