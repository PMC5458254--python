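# Methods

## The measurement model

Oxygen-enhanced MRI (OE-MRI) exploits the paramagnetism of molecular
oxygen: when the breathing gas switches from room air to 100% O2,
dissolved oxygen shortens tissue T1 and raises T1-weighted signal in
proportion to how much extra oxygen the tissue actually receives.
Well-perfused tumor enhances; hypoxic tumor barely responds.  The
acquisition is a single-slice dynamic series over three contiguous
stages — pre-oxygen, 100% oxygen, post-oxygen, 5 minutes each by
default — and the per-voxel summary is the percentage of
signal-intensity change

    PSIC = 100 * (SI_max − SI_pre) / SI_pre        [percent]

with `SI_pre` the arithmetic mean over pre-oxygen frames and `SI_max`
the peak of the (optionally smoothed) voxel time course within the
oxygen stage.  Voxels inside a tumor mask with PSIC at or below a
threshold (default 10%) are called low-enhancing (read as hypoxic); the
**low-PSIC area fraction** — low voxels over valid tumor voxels — is the
imaging biomarker carried into the histology and survival analyses.

The companion probe measurement is tissue oxygen partial pressure
(mmHg) from a fiber-optic sensor, summarized per trace as

    delta_pO2 = pO2_max − pO2_pre

where **both** terms are stage means (the `max` subscript is
conventional, not a maximum): `pO2_pre` over the pre-oxygen stage,
`pO2_max` over the oxygen stage.

Working assumptions: no motion between frames, no drift in receiver
gain across stages (PSIC is invariant to a global gain but not to an
additive offset — the test suite asserts the exact algebra of both),
and signal intensities in arbitrary units (no T1 fitting).

## The phantom simulator

Every downstream stage is validated on synthetic phantoms with known
ground truth.  The phantom is a concentric tumor: a necrotic core
(disk, radius 3 mm), a hypoxic penumbra (annulus 3–6 mm), an active
tumor rim (annulus 6–12 mm), and normal tissue elsewhere, on the
acquisition geometry of the modelled experiment (80×80 mm field of
view, 192×96 matrix, i.e. 0.417×0.833 mm pixels, 2-mm slice).  Each
compartment follows mono-exponential wash-in/wash-out kinetics

    S(t) = S0                                              pre stage
    S(t) = S0 (1 + A (1 − e^{−(t − t_on)/τ_in}))           oxygen stage
    S(t) = S0 (1 + A_end e^{−(t − t_off)/τ_out})           post stage

with `A_end = A (1 − e^{−D_oxy/τ_in})`, so the noise-free true PSIC of
a compartment is exactly `100·A·(1 − e^{−D_oxy/τ_in})`.

**Frame-readout convention.**  Frame timestamps mark acquisition onset;
the simulated SI of a frame is the kinetic model at the frame's readout,
i.e. the end of its window.  The last oxygen-stage frame therefore
carries exactly the full oxygen exposure `D_oxy`, and a raw-maximum
PSIC map on a noise-free phantom reproduces the closed form to machine
precision — the property the oracle tests rely on.  Stage membership of
a frame uses half-open intervals `[start, end)` on timestamps (the final
interval closed at its end).

**Default kinetic parameters** (chosen once to emulate the enhancement
levels of the modelled experiment; all compartments share S0 = 1000 SI
units, τ_in = 60 s, τ_out = 90 s):

| compartment   | A      | true PSIC | pO2 baseline | pO2 amplitude |
|---------------|--------|-----------|--------------|---------------|
| necrotic core | 0.010  | 1.0%      | 2 mmHg       | 2 mmHg        |
| penumbra      | 0.068  | 6.8%      | 5 mmHg       | 11.4 mmHg     |
| active tumor  | 0.156  | 15.5%     | 20 mmHg      | 43.4 mmHg     |
| normal tissue | 0.040  | 4.0%      | 35 mmHg      | 25 mmHg       |

The pO2 amplitudes are calibrated so the oxygen-stage mean elevation
(the delta-pO2 definition above applied to the wash-in curve) is
≈34.8 mmHg in active tumor and ≈9.1 mmHg in penumbra.  With the default
geometry, core+penumbra occupy 25% of the tumor disk — the pooled
low-PSIC area proportion of the modelled study.  The dynamic frame rate
is not specified by the protocol being modelled; 15 s per frame
(60 frames over 15 min) is a declared default, configurable.

Noise is additive Gaussian by default (standard deviation in SI units;
SNR 20 means sigma = S0/20); Rician magnitude noise is available by
flag, since magnitude-MRI noise is Rician (the two coincide at high
SNR).  A seed fully determines every generated object.

**What the phantom does not emulate:** motion, coil-sensitivity
inhomogeneity, physiological drift, partial-volume mixing at
compartment boundaries (labels are crisp), spatially correlated noise,
and any pulse-sequence physics (the simulator works at the
signal-intensity level).  Tests passing on the phantom therefore
validate the estimator chain, not robustness to those real-data
effects.

## Numerical choices in the mapping

- **Peak smoothing.**  The raw per-voxel oxygen-stage maximum is
  upward-biased by noise (max of ~20 noisy samples); the bias is worst
  for near-flat time courses, where every frame is a candidate peak.
  A centred moving average (odd window, edges replicated) is applied
  before the peak search.  The default window is 13 frames (195 s): at
  SNR 20 it holds the per-compartment mean PSIC bias to ≤1.4 percentage
  points (necrotic core, the worst case; penumbra +0.6, active tumor
  −0.1) while a 3-frame window would leave ~4 points of bias and break
  hypoxic-fraction recovery.  Window 1 reproduces the literal raw
  maximum and is what the noise-free closed-form checks use.
- **Baseline guard.**  Voxels whose baseline is at or below
  `epsilon_baseline` (default 1e−6 × the series median SI) are flagged
  invalid and excluded — not clamped — and the area-fraction denominator
  counts valid tumor voxels only.
- **Threshold tie.**  PSIC exactly at the threshold classifies as low
  (conservative toward calling hypoxia); the threshold is configurable.
- **Grouping boundaries.**  Low-PSIC-fraction groups use cuts
  (0.20, 0.30) with the closed interval [0.20, 0.30] assigned to the
  medium group.
- **ROI placement.**  A circular ROI of a given physical volume (default
  0.98 mm³ over a 2-mm slice) takes the n pixels nearest its centre,
  n = round(target area / pixel area), ties broken by row then column —
  deterministic; at the default geometry n = 1.
- **Coordinates.**  Pixel indices are 0-based (row, col); geometry in mm
  uses pixel centres.

## Statistics

Spearman rank correlation (average ranks for ties; two-sided p from the
t approximation with n−2 df, delegated to scipy) with an in-package
exact-permutation p-value for n ≤ 9 (full n! enumeration); paired
Student t-tests (identical samples return t = 0, p = 1; constant
nonzero differences are a signalled error since the statistic is
undefined); Kaplan–Meier product-limit curves with right-censoring
(median = earliest event time with survival ≤ 0.5, undefined if never
reached); and the standard k-group log-rank test (hypergeometric
observed-vs-expected at each distinct event time, ties pooled, χ² with
k−1 df).  KM and log-rank are delegated to lifelines; the test suite
checks both against hand-worked product-limit and observed/expected
tables and against brute-force rank enumeration.  Two-sided p-values
throughout; no multiple-testing correction.

**Finite-sample calibration of the log-rank test.**  With 3 groups of
15 subjects and all events observed, the asymptotic χ² reference is
slightly anticonservative: the true null rejection rate at α = 0.05 is
≈0.066 (measured at 5000 replicates with R `survival::survdiff`, which
agrees with this package's statistic to seven digits; mean χ² ≈ 2.20
against a nominal 2).  The inflation disappears by ~200 per group
(measured 0.048).  Monte-Carlo calibration checks at the small group
size should expect a rate near 0.06, not 0.05.

## Synthetic cohort design (`run-all` defaults)

- **Imaging cohort:** 9 subjects whose enhancement amplitudes scale over
  0.75–1.30 and whose penumbra outer radius spans 4.5–8.5 mm, giving
  low-PSIC fractions ≈0.14–0.50; SNR 20.
- **pO2 cohort:** 5 subjects (the first five imaging subjects), one
  trace per site (active tumor, penumbra), probe noise 1 mmHg, sampled
  at 1 Hz.
- **Histology surrogates:** per-ROI vessel counts with mean
  max(0, −0.4 + 0.35·PSIC) — ≈2 vessels at PSIC 6.8%, ≈5 at 15.6% — and
  CV² = 0.15 (rounded-Gamma count model, whose zero-dispersion limit is
  the deterministic rounded mean); GLUT-1 fractions decreasing in PSIC,
  clipped to [0, 1].  Subject-level section fractions
  (GLUT-1-positive + necrotic area) follow 0.1 + 0.8·low_fraction with
  0.04 noise.
- **Survival cohort:** 90 subjects in three latent severity classes
  (low-PSIC fractions ~N(0.10/0.25/0.40, 0.025)), exponential
  proportional hazards h = 0.00292·e^{9·fraction} per day (median 25
  days at fraction 0.25), right-censoring at 150 days.  This separation
  is deliberately stronger, and the cohort larger, than an 11-animal
  in-vivo study: with realistic in-vivo effect sizes the sample medians
  of three ~4-animal groups are too noisy for their ordering to be a
  stable property, so the default is sized for a reproducible ordering
  (ordered medians in ≈99% of seeded runs) while keeping the same
  qualitative design.

Problem sizes used by the test suite and the acceptance script — one
96×192×60 phantom per seed (10 seeds for fraction recovery), 2000
log-rank null replicates, 100 survival-cohort replicates, the 9-subject
default pipeline run twice for byte-level determinism — were chosen so
the whole validation runs in a couple of minutes on one CPU.

## Known limitations

- The classification threshold (10%) is treated as given, not
  estimated; no uncertainty is attached to the low-PSIC fraction.
- PSIC is offset-sensitive: any additive signal drift between stages
  biases the map (the algebra is tested, not corrected).
- The exact-permutation Spearman p is limited to n ≤ 9 by cost.
- Histology enters as tabulated counts/fractions; no image segmentation
  is performed.
- No Cox regression or hazard-ratio estimation; the survival layer is
  KM + log-rank only.
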