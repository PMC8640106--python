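# Methods

`mrsphase` re-implements, as a tested pipeline with synthetic ground
truth, the computational chain of a 7 T proton-MRS study of
nitroglycerin (GTN)-provoked migraine attacks: spectral simulation,
preprocessing, metabolite fitting with Cramér–Rao uncertainty,
water-referenced absolute quantification, rule-based clinical phase
coding, and a phase-coded linear mixed model. This note documents the
models, the parameters that matter, and the design decisions taken where
the design was genuinely open.

## Study design being emulated

A provocation day with three scan sessions at fixed times — Baseline
(−30 min), GTN-90 and GTN-270 (90 and 270 min after the start of a
20-min GTN infusion at 0.5 µg/kg/min) — in 24 female migraine-without-aura
patients and 13 healthy controls. Migraine-like attacks start at a
subject-specific onset time; each scan is therefore labelled with a
migraine *phase* (interictal, preictal, ictal, postictal) rather than
only a session time, and the statistical model isolates phase effects
from session and group effects.

## Synthetic data generator

### Cohort

`simulate.simulate_cohort` draws subjects with age, weight, voxel tissue
fractions (GM 0.59 ± 0.03, WM 0.35 ± 0.04, CSF the remainder), a
responder flag (migraine subjects only, default probability 0.875), an
attack onset uniform on [45, 345] min, and an attack duration that is
log-normal with median 8 h (σ_log = 0.5) — long enough that a postictal
scan is rare (≈1 subject per cohort), matching the single postictal case
the design anticipates. Responders are premonitory with probability
19/21 and mimic their usual attack with probability 20/21.

Per-session true concentrations are *subject baseline + phase effect*:
the baseline is drawn per metabolite from the defaults in
`DEFAULT_BASELINE_CONCENTRATIONS` (plausible occipital values, e.g.
tNAA 12, glutamate 9, GABA 1.2 mmol/L — generator parameters, not
literature claims, since the emulated study does not print its baseline
means), and the phase effects default to the study-scale effect table
(`DEFAULT_PHASE_EFFECTS`), whose headline entry is a +0.45 mmol/L
preictal GABA shift. Concentration read-out noise (`residual_sd`,
default 0.5 mmol/L) represents the combined measurement error of one
session.

### Spectra

Each metabolite is a 1–3 line simplified multiplet (Lorentzian lines;
broad Gaussian lines for the macromolecule background) with proton-count
weights, an intrinsic linewidth, and a T2. The forward model ties signal
amplitude to concentration exactly as the quantifier inverts it:

    S_m = g · c_m · (N_H/2) · (f_gm + f_wm) · exp(−TE/T2_m)
    S_w = g · C_w · Σ_i f_i d_i A_i(TR, TE),   A_i = e^(−TE/T2_i)(1 − e^(−TR/T1_i))

with C_w = 55,510 mmol/L and the water densities/relaxation constants
listed in `RelaxationTable` (GM/WM/CSF densities 0.78/0.65/0.97; water
T1 2130/1220/4425 ms; water T2 50/55/141 ms; glutamate T2 93 ms).
Distortions: per-channel complex sensitivities, a decaying-exponential
eddy-current phase applied identically to water and metabolite FIDs,
per-average frequency drift referenced to the first average (the scanner
is calibrated at acquisition start; an absolute common offset would be
unobservable to an aligner that uses the first average as reference),
a common "shim" Lorentzian broadening (6 Hz default), and additive
white circular Gaussian noise. The default noise SD (3.0 per channel
per average) was chosen once so that default 32-channel/32-average
sessions show realistic quality numbers: metabolite CRLBs of a few
percent, edited-GABA CRLB around 10% (retained by the 15% rule), and a
high LCModel-style SNR.

MEGA-edited sessions alternate edit-off/edit-on averages; in the on
condition each edited metabolite is scaled by (1 + edit_co_factor), so
the on−off difference retains exactly `edit_co_factor` (default 0.5 for
GABA; shared between simulator and quantifier as the editing
efficiency) of its off-condition signal while singlets cancel.

What the generator does **not** emulate: J-evolution and true multiplet
lineshapes (an external density-matrix basis would be needed), B0/B1
maps, chemical-shift displacement, lipid contamination, subject motion,
frequency drift within an average, or non-Lorentzian shim lineshapes.
Passing tests therefore demonstrate the *self-consistency and
calibration* of the chain (estimators unbiased, uncertainties honest,
corrections exactly inverting the modelled distortions), not robustness
against every artefact of in vivo data.

## Preprocessing

Order: coil combination → eddy-current correction → frequency alignment
→ averaging/difference.

* **Combination** phases each channel by the conjugate phase of the
  first point of its water reference and weights by water-reference
  amplitude (normalised to sum 1); amplitude/noise-variance weighting is
  available by flag. Weight normalisation means the combined scale is a
  sensitivity-weighted average; it cancels in quantification because the
  water reference shares it.
* **Eddy correction** is the Klose method: multiply by
  exp(−i·phase(water(t))). It is exact for any phase distortion common
  to water and metabolite signals.
* **Alignment** maximises the inner product of magnitude spectra
  against the first average: an FFT cross-correlation locates the
  nearest bin, a bounded scalar search (tolerance 1e−10 Hz) refines it.
  Search window ±20 Hz; an estimate at the bound is flagged and warned
  about; flat objectives tie-break to zero shift.
* **Averaging** is the arithmetic mean; MEGA difference is
  mean(on) − mean(off).

`preprocess_session` refuses non-`SpectralSession` input, so an already
processed result cannot be double-corrected; provenance lists each step
exactly once.

## Fitting and uncertainty

The linear-combination fitter is a transparent surrogate for
commercial LC fitting, *not* a reimplementation of LCModel: it has no
lineshape regularisation and no soft concentration-ratio priors.
Model: nonnegative metabolite amplitudes over the basis, a cubic
B-spline baseline with knot spacing 1 ppm (the analog of unit node
spacing in spline-baseline LC fitting; configurable), and three shared
nuisance parameters — zero-order phase, frequency shift, common
Lorentzian broadening. Separable least squares: the amplitude/spline
subproblem is solved exactly by bounded linear least squares inside a
Nelder–Mead search over the nuisance triple, multi-started at
frequency shifts −5/0/+5 Hz. Collinear basis pairs (|r| > 0.9999 on
the window) are rejected with the offending pair named.

Edited GABA and creatine are fit as single Lorentzians in the frequency
domain (exact DFT of a sampled decaying exponential, so the fitted
amplitude is on the time-domain amplitude scale); the GABA area is
divided by the editing efficiency and both areas by the weight fraction
their line carries in the default multiplet, putting them on the same
scale as LC amplitudes. The phase parameter is confined to ±90° so the
sign of the area is carried by the amplitude and negative areas can be
flagged. Overlap of the 3.01-ppm GABA and 2.95-ppm glutathione lines
with creatine 3.03 biases the creatine area by ~10% on full-basis
simulations (window ±0.15 ppm); this affects only the creatine-SNR
quality metric, and the fit is exact on isolated lines.

Uncertainties are CRLBs from the Fisher information J'J/σ² at the
optimum under white Gaussian noise, with σ estimated from the
signal-free 8–10 ppm region; reported as percent of the amplitude.
Quality metrics follow the printed definitions: SNR = (spectrum maximum
− mean baseline)/(2·RMS residual) on 0.2–4.2 ppm; creatine SNR =
creatine area / noise SD at 8–10 ppm; NAA FWHM by linear interpolation
at half height on a fourfold zero-filled spectrum (so the measurement
is not limited by the 1.95 Hz raw grid), with Hz = ppm × proton MHz by
construction.

## Quantification

Gasparovic-style compartment formula (the emulated study cites the
method rather than printing a formula; this package writes it out):

    c = (S_m/S_w) · (2/N_H) · C_w · Σ_i f_i d_i A_i / (e^(−TE/T2_m) · (f_gm + f_wm))

Metabolite T1 saturation is deliberately omitted (TR 5 s); division by
(f_gm + f_wm) refers concentrations to parenchyma, with a
voxel-referenced mode by flag since the original referencing is not
printed. QC: a metabolite is excluded for all records when its CRLB
exceeds 15% in strictly more than 50% of records (exactly 50% retains);
artifact-flagged spectra are excluded record-wise.

## Clinical rules

A migraine-like attack requires either (1) VRS ≥ 4 with ≥2 of the four
ICHD-3 C features and the D requirement (nausea/vomiting or photophobia
plus phonophobia), or (2) a headache mimicking the usual attack and
treated with acute medication; onset must fall within 12 h of GTN
start. Duration requirements are waived, as appropriate for provoked
attacks. Onset is the earliest assessment at which either criterion
holds (for criterion 2, the first nonzero-VRS assessment of the treated
episode). Phase at a scan: interictal before GTN and for all controls
and nonresponders; preictal before onset; ictal from onset (a scan
exactly at onset counts as ictal — documented tie-break) until attack
end; postictal after. Attack end is the first sustained VRS-0 time when
recorded, otherwise absent. A per-subject manual override flag mirrors
clinical adjudication of anomalous cases (e.g. a control with a high
end-of-day VRS), and feeds the sensitivity analyses.

The bundled worked-example cohort (`datasets.load_example_cohort`)
encodes a published-style provocation day: 21/24 responders (87.5%),
7/13 controls with unspecific headache (53.8%), 20/21 mimicry (95.2%),
onsets 45–345 min, 3 nonresponders. One subject (P22, VRS 2 at first
assessment, peak 5, untreated) is classified via criterion 1 at the
peak assessment; the printed-style early onset of that subject is not
reproducible from its own printed features, a known inconsistency that
does not touch any aggregate.

## Phase mixed model

Per metabolite, post-GTN concentrations (GTN-90, GTN-270) are the
outcome; fixed effects are diagnosis, scan session, migraine phase
(reference interictal), session×diagnosis, age, and the subject's
Baseline concentration (ANCOVA-style; modelling Baseline as both an
outcome session and a covariate simultaneously would double-use it).
Random effects walk a fallback ladder: unstructured covariance over the
observed phase levels first (iteration-capped — with ≤2 outcome
observations per subject it is essentially never identifiable), then a
random intercept. A compound-symmetry rung would coincide with the
random intercept at ≤2 observations per subject, so it is not a
separate rung. Inference is Wald-t with residual degrees of freedom
(n − rank(X); a Satterthwaite approximation is not available for this
backend), 95% CIs, p-values uncorrected for multiplicity by design.

Degenerate cohorts in which *every* migraine subject responds leave no
post-GTN interictal migraine observation; the phase dummies then alias
diagnosis, the fixed design is rank deficient, and the contrasts are
reported per metabolite as inestimable rather than failing. Monte-Carlo
aggregates average over estimable replicates and report the count.

Estimated marginal means are computed per session×diagnosis at the
grand covariate means with the phase distribution as observed in each
cell; adding a constant to all outcomes shifts every EMM by exactly
that constant. The sensitivity suite refits the model under named
subject-exclusion sets (postictal responder, non-premonitory
responders, anomalous control) and reports sign-stability of the
preictal contrast.

## Calibration results computed by the test suite

The tests and `scripts/acceptance.py` verify, among others: noiseless
end-to-end concentration recovery to 1e−4 relative; eddy/alignment
inversion to 1e−10 / 0.1 Hz; CRLB within 25% of Monte-Carlo SD (200
replicates) and within 1% of a numerical-Hessian oracle; recovery of
the injected +0.45 mmol/L preictal GABA effect in the mean over 200
simulated cohorts; and a preictal type-I error within [0.03, 0.08] at
the nominal 5% level over 500 null cohorts.

## Problem sizes and numerical choices

Monte-Carlo suites run at reduced acquisition size (1–2 channels, 2
averages, 1024–2048 points) because the calibration properties checked
are invariant to channel/average count; the cohort-level statistics run
at full cohort size (24+13). Optimiser tolerances: amplitude subproblem
`lsq_linear` tol 1e−12; Nelder–Mead xatol 1e−4 on the nuisance triple;
Lorentzian `least_squares` xtol/ftol 1e−14; alignment refinement xatol
1e−10 Hz. Degenerate inputs (zero-noise spectra, empty cells,
rank-deficient designs, pure-CSF voxels, zero water) raise or flag
explicitly rather than returning silent numbers.

## Known limitations

Simplified multiplets mean absolute overlap-driven biases (e.g. the
creatine line fit) are milder than in vivo; the LC surrogate's CRLBs
are honest for its own model class but not a substitute for LCModel's
regularised errors; the mixed model's unstructured rung is effectively
decorative at 2 observations per subject; and no attempt is made to
model scanner hardware (pulse profiles, B0/B1 inhomogeneity) or
segmentation — tissue fractions are inputs.
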