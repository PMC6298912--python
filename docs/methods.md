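# Methods

## The bolus wash-in model

A bolus of microbubble contrast agent transits a perfused region as a
positively skewed concentration pulse. On linearised CEUS data (intensity
proportional to local microbubble concentration) the ROI-mean
time–intensity curve is modelled as

    f(t) = O + A · LN(t − t0; μ, σ),   t > t0;   f(t) = O otherwise,

where LN is the lognormal density. The lognormal is the standard
single-pass bolus shape for wash-in-only records: it is causal, skewed,
and flat at arrival, and it gives closed forms for every derived
parameter. It is a modelling choice, not a claim about any vendor
implementation; the model registry (`ceusquant.tic_model.BOLUS_MODELS`)
leaves room for alternatives such as the gamma-variate.

Assumptions: a single bolus pass (no recirculation or destruction
modelling), a stationary ROI (probe clamped during acquisition, so no
motion correction), and linearised intensities. Log-compressed inputs
must be decompressed first (`linearize_log_compressed`, default dynamic
range 40 dB, matching a typical small-animal contrast acquisition).

## Baseline and arrival estimation

The baseline is estimated from the earliest 10% of samples. Because a
55 s record at 36 frames/s puts the first 10% at 0–5.5 s — which usually
contains part of the wash-in — the median and MAD are taken over the
*lower half* of that window (for a monotone rise the pre-arrival plateau
populates the lower half), and one refinement pass re-estimates them from
the samples strictly before the detected arrival. Arrival is the first
crossing of baseline + k·MAD with k = 5 (the MAD is floored at 1e-9 of
the baseline so noiseless plateaus still admit detection). A curve that
never crosses is flagged "not detected". Note that any threshold
detector lags the true t0 on smooth data: the lognormal leaves baseline
tangentially, so the crossing typically occurs 0.1–0.5 s after arrival.
This estimate only seeds the fit, which refines t0 freely.

## Fitting

Bounded trust-region least squares (`scipy.optimize.least_squares`) over
(O, A, μ, σ, t0) with an analytic Jacobian. Bounds: O ∈ [0, max y],
A ∈ [0, 10·range(y)·duration], μ ∈ [ln 0.1, ln 60], σ ∈ [0.05, 3],
t0 ∈ [0, duration/2] (t0 measured from the first sample; the recorded
`time_origin` restores the absolute clock). Initialisation: baseline
estimate for O, trapezoidal area of the baseline-subtracted curve for A,
σ₀ = 0.5, μ₀ from the argmax via the mode relation, t0 from the arrival
guess shrunk by 20% to compensate detection lag. Eight seeded
multi-starts perturb this guess; the lowest-RSS solution is returned, and
multi-starting stops early once the RMS residual falls below 1e-8 of the
curve's range (a numerically perfect fit). A curve constant to machine
precision is returned as a converged A = 0 fit flagged non-perfused.

## Parameter extraction

PE, TTP, AUC, MTT and PI use the lognormal closed forms (see README).
The maximum slope is located numerically — a geometric grid of 4000
points between t0 and the peak, then bounded scalar minimisation of −f′
to 1e-12 — because its closed form adds nothing over the analytic
derivative. Two conventions are explicit:

* **Rise time.** The "x-axis" crossed by the maximum-slope tangent is
  the baseline level O (equivalently zero of the baseline-subtracted
  curve), making RT and WiAUC independent of O.
* **WiAUC start.** "Starting enhancement" is the tangent intercept t_i
  (consistent with the RT construction); `washin_start="arrival"`
  switches to t0. The integral uses the lognormal CDF, exact for the
  model (the tests cross-check it against trapezoidal quadrature).
* **MTT origin.** MTT is the first moment of the normalised bolus
  measured from arrival t0 — transit time, not arrival delay — whereas
  TTP is measured from the acquisition origin. Published summary tables
  generally cannot disambiguate the MTT origin; ours is documented here.
* **Units.** PI = AUC/MTT and WiPI = WiAUC/RT are reported in a.u.
  (a.u.·s divided by s); summary tables sometimes print a.u./s for these
  ratios, which is dimensionally inconsistent with their definitions.

AUC extrapolates to infinite time via the closed form; the fraction of
bolus area beyond the end of the record is reported separately as a
diagnostic (`auc_truncation_diagnostic`), ~1e-9 for a 55 s record with
typical murine kinetics. Non-perfused fits yield zero amplitudes and NaN
time parameters; non-converged fits are refused.

## Synthetic data

The generator emulates the study design the package targets: two arms
(decapeptyl-treated vs. saline control mice), three timepoints (day 0,
10, 20), 10 animals per arm, one CEUS ovary per animal, 55 s wash-in
records at 36 frames/s, ovaries of 1–2.5 mm diameter. Defaults encode the
published per-group mean ± SD of every measured parameter (two B-mode
diameters and nine CEUS parameters) as truncated-normal generative
targets. Per animal, a ground-truth bolus curve is back-solved from the
drawn PE with template kinetics — σ = 0.5, exp(μ) uniform on 4–8 s,
arrival uniform on 1–3 s, baseline 5 a.u. — a one-parameter inversion
that keeps curves realistic while matching the drawn peak exactly. TIC
noise defaults to additive Gaussian at 2% of the peak; cine backgrounds
carry static 10% multiplicative speckle. One caveat is inherent to
drawing the nine CEUS parameters independently: a single physical curve
cannot jointly realise nine independent draws, so only PE (and hence A)
is tied to the ground-truth curve; the remaining draws are measurement
emulations for the statistics layer. Published per-timepoint SDs suggest
the effective CEUS n varied by timepoint; the generator exposes
`n_per_group` rather than asserting one.

What passing tests show — and don't. The generator reproduces the
sampling structure (group effects, acquisition grid, noise scale), not
ultrasound physics: no attenuation, no speckle inside the ROI, no probe
or breathing motion, no recirculation. Recovery results therefore bound
performance under the stated noise model only.

## Statistics

Welch's two-tailed unequal-variance t-test per parameter × timepoint,
implemented from summary statistics (matching how published tables are
reported) with the sample-level route delegating to it; agreement with
`scipy.stats.ttest_ind(equal_var=False)` is asserted in tests. No
multiplicity correction by default — the emulated design tests each cell
at α = 0.05 — with an optional Benjamini–Hochberg switch (statsmodels)
for reuse. The experimental unit is the animal. Cells missing an arm are
reported as NaN rather than aborting the comparison.

## Problem sizes and numerical checks

The suite and acceptance script use: 100 noisy 1980-sample acquisitions
for recovery (median relative errors ~0.2% for PE/AUC, ~0.08% for TTP at
2%-of-peak noise), 20 random draws against a brute-force grid oracle
(scale-aware uniform/geometric grids with parabolic vertex refinement;
worst disagreement ~2e-6 relative), 1000 simulated null studies × 33
cells for type-I calibration (≈4.9% at α = 0.05), and 500 replicates at
n = 6 per arm for the day-20 PE power (≈72–74%). Short cine loops
(seconds, 12–36 fps, 64×64 px) keep image-level tests light; durations
and frame rates are arguments everywhere, with the study defaults
(55 s, 36 fps) unchanged.

## Known limitations

Wash-out, destruction–replenishment and recirculation are out of scope.
ROI masks are static; drifting acquisitions need upstream registration.
The fit assumes a single bolus; double injections or severe clipping will
converge to the dominant lobe. The lognormal stand-in will mismatch
vendor numbers derived from a different kernel, particularly RT/WiAUC,
which depend on tangent conventions.
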