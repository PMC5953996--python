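# Methods

## Scope and data model

The package operates entirely at the time–activity-curve (TAC) level. A
dynamic acquisition is a contiguous frame schedule; each region (left-
atrial blood pool, global left ventricle, LAD/LCx/RCA territories) is one
frame-averaged concentration (kBq/mL) per frame. Two named schedules
reproduce the standard protocols: 32 frames (21×3, 1×9, 1×15, 1×21, 1×27,
7×30 s; 345 s total) for dynamic CZT-SPECT and 24 frames (14×5, 3×10,
3×20, 4×30 s; 280 s) for dynamic water PET. Image reconstruction,
attenuation/scatter correction and segmentation are out of scope; the
simulator stands in for them by emitting region-level TACs directly.

TAC values are frame averages attached to frame midtimes; every definite
integral is taken over the piecewise-linear interpolant through those
points, extended flat to the acquisition boundaries. This is exact for
signals linear within frames and convention for frame-binned dynamic
data. Times are stored in seconds in files and converted to minutes
inside kinetic formulas, because flow is expressed in mL/min/g.

## SPECT arm: net retention with extraction correction

The retention rate is

R = [1/(PV·(t3−t2)) · ∫_{t2}^{t3} (P − S_m·C_a) dt] /
[CF · ∫_0^{t1} (C_a − S_b·P) dt],

with CF fixed at 1 and S_b defaulting to 0 (myocardium-to-blood spillover
assumed negligible). The denominator integrates from acquisition start —
the arterial integral should capture the entire delivered bolus, and
anchoring the lower limit at the detected arrival would systematically
drop the sub-threshold leading edge of the bolus. Window placement is
anchored on the bolus: arrival is the midtime of the first frame whose
blood value exceeds 10% of the blood peak (a level robust to baseline
noise; the exact fraction is uncritical for bolus-shaped inputs), and the
defaults t1 = arrival + 90 s, tissue window arrival + 90–150 s reproduce
the conventional 1.5-min blood-pool phase and 1.5–2.5-min tissue plateau
when injection starts at time zero. Anchoring at the peak frame instead
is available via `RetentionParams(anchor="peak")`; all offsets are
configurable.

S_m (blood→myocardium spillover) is estimated, unless supplied, by linear
least squares of P(t) ≈ sm·C_a(t) + k·∫C_a over the blood-pool-phase
frames — a two-basis design in which genuine uptake is absorbed by the
cumulated-input term — clamped to [0, 1]. A constant blood curve is
rejected as degenerate with advice to supply sm manually.

R is identified with the uptake rate K1 (pure trapping; no washout term
is fitted), and MBF solves K1 = MBF·(1 − A·e^{−B/MBF}) with A = 0.874,
B = 0.443. dK1/dMBF = 1 − A·e^{−B/M}(1 + B/M) is positive for A < 1, so
the inverse is unique; it is found by bisection on [10⁻⁶, 10] mL/min/g to
1e−9 absolute (guaranteed convergence given monotonicity, no derivative
needed). Note the flat extraction curve at high flow makes MBF several
times more sensitive than K1 to measurement error — an intrinsic property
of extraction-corrected retention imaging, visible in the recovery tests.
A negative tissue numerator (possible under heavy noise) clamps R to 0
with a warning; a non-positive input integral raises.

PV defaults to 1.0 (uncorrected tissue signal); recovered MBF scales as
1/PV, so any chosen partial-volume factor rescales flows accordingly.

## PET arm: one-tissue compartment for water

Ct(t) = MBF·∫₀ᵗ C_a(u)·e^{−(MBF/p)(t−u)} du with partition coefficient
p = 0.91 mL/g; the regional prediction is PTF·Ct + Va·C_a, frame-averaged.
MBF ∈ [0.1, 6] mL/min/g, PTF ∈ [0.3, 1.2] g/mL, Va ∈ [0, 0.5] are fitted
by bounded trust-region least squares from three fixed starting triples
(best residual wins); fixed starts keep the fit bit-deterministic. No
delay, dispersion or metabolite correction is applied: simulator and
measurement share a time base, and real-data delay correction is a known
omission.

Because the fit only sees the frame-averaged blood curve, the continuous
input is reconstructed by a short fixed-point refinement that forces the
reconstruction's own frame averages to match the measured values
(12 iterations of v ← v + (measured − frame-average) at the midtime
knots, clamped nonnegative at the end). Without this, frame averaging
flattens the bolus peak and biases fitted flow upward by 2–4% at stress
flows; with it, noiseless recovery is within ~0.3%.

## Synthetic cohorts

The generator emulates the study design: `n_patients` (default 30) × 3
territories, rest plus pharmacological stress, both modalities, with a
per-territory FFR. Conditions (all `SimConfig` fields, chosen once):

- **AIF**: gamma-variate bolus (shape α = 2, time-to-peak 15 s, injection
  delay 5 s, peak 100 kBq/mL) normalized so its mode is exactly at
  delay + time-to-peak, plus a recirculation tail of relative amplitude
  0.02 decaying with 40 s half-life. The tail is kept small and fast so
  that essentially all tracer delivery falls inside the input-integration
  window — the regime the net-retention model assumes; larger late-tail
  recirculation would bias R upward and, amplified by the extraction
  inversion, violate the intended noiseless-recovery behaviour of the
  pipeline. The SPECT stress bolus is scaled ×3 (higher stress dose);
  flow estimates are invariant to common TAC rescaling.
- **Kinetics**: sestamibi-like curves use K1 = forward Renkin–Crone of
  the true MBF with k2 = 0 (trapping); water curves use k1 = MBF,
  k2 = MBF/0.91. Observed curves are PV·Ct + S_m·C_a with PV = 1.0 and
  S_m = 0.30; the global curve is the mean of the three territory curves.
  Matching each arm's own model assumption keeps parameter recovery
  well-posed — model-mismatch effects of real tracers are deliberately
  not simulated.
- **Cohort truth**: disease ~ Bernoulli(12/90); rest MBF ~ N(1.0, 0.2)
  clipped to [0.4, 2.5] mL/min/g; MFR uniform on (2.4, 3.6) normal /
  (1.2, 1.9) diseased; stress MBF = rest × MFR. FFR is drawn from normals
  truncated to (0, 1] — 0.87 ± 0.06 normal, 0.72 ± 0.06 diseased — so a
  realistic minority of territories straddles the 0.8 cutoff and produces
  discordance; `ffr_perfectly_linked=True` instead assigns 0.90/0.75
  deterministically for exact-concordance tests.
- **Noise**: Gaussian with SD = noise_scale·√(max(v, v_floor)/Δt_min),
  v_floor = 1% of the curve maximum — variance proportional to signal and
  inversely proportional to frame length, a count-statistics surrogate
  appropriate for concentration units (true Poisson would require count
  calibration the TAC unit does not carry). The default noise_scale 0.15
  yields ≈5% relative noise on the 30-s tissue-plateau frames at the
  default AIF amplitude.

Everything is drawn from one seeded generator in a fixed order, so output
files are byte-identical under a fixed seed.

What passing tests on these cohorts do **not** show: robustness to
attenuation (absent in the CZT arm of the real protocol and a known
source of MBF overestimation), patient motion, input-function distortion,
tracer-specific washout, or delay/dispersion — none of which the
simulator models. The round-trip recovery results certify the numerics of
the estimators, not field accuracy on patient data.

## Statistical layer

Tie rules are fixed: MFR and stress MBF abnormal strictly below cutoff;
FFR abnormal at or below 0.8. Rates are percentages; a zero-denominator
ratio is NaN, never 0. Kappa is unweighted Cohen's kappa on the 2×2
table. ROC sweeps thresholds over the unique observed scores plus a +∞
sentinel with "abnormal iff score < threshold" (lower score = more
abnormal); AUC is the trapezoid over (1−specificity, sensitivity), which
equals the Mann–Whitney pairwise-concordance statistic, and the reported
cutoff maximizes Youden's J with ties resolved to the smallest cutoff.
Bland–Altman reports mean difference ± 1.96 sample SD. Reported metrics
are rounded to one decimal in tables; raw values are kept in JSON.

## Problem sizes and numerical choices

Simulation runs on a 0.1 s grid (all printed frame boundaries are
multiples of it, so frame averaging is an exact trapezoid). Recovery
experiments use 200 noiseless territories (SPECT) and 100 noisy
replicates (PET); the demonstration cohort is 30 patients. Bisection
tolerance 1e−9; least-squares tolerances 1e−10; spillover clamp [0, 1];
negative noisy TAC values clamp to 0.

## Known limitations

- Region-level only; no voxel data, no 17-segment analysis (segmental
  count statistics would not support it).
- The water-model variant omits delay/dispersion/RV-spillover terms.
- Published population means, AUCs, correlation coefficients and
  agreement statistics of the motivating study depend on its undeposited
  patient data and cannot be recomputed here; the package instead
  verifies its estimators by construction (oracles, round-trips) and
  reproduces the study's printed contingency-table arithmetic exactly.
- Cohen's kappa of the published contingency counts (0.34 SPECT, 0.47
  PET) differs from the agreement values printed alongside them; the
  published statistic's construction is not recoverable from the counts,
  so it is reported but not targeted.
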