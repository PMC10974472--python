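# Methods

This note records the models, conventions, parameter choices and
limitations behind `gipca`.  It is written for a reader who wants to judge
what the package's tests do — and do not — demonstrate about real
gait-initiation (GI) data.

## Coordinate and signal conventions

Force-plate axes: `x` = mediolateral (ML), `y` = anteroposterior (AP),
`z` = vertical up; the plate origin lies in its surface, so
`COP_x = -My/Fz` and `COP_y = Mx/Fz`.  COP samples with `|Fz| < 10 N` are
flagged invalid and excluded from extrema.  All channels are filtered with
a zero-phase (forward–backward) 2nd-order Butterworth low-pass at 10 Hz
(default sampling rate 500 Hz).  Zero-phase application was chosen because
a causal filter's group delay would bias every event time; the cost is
that the single-pass −3 dB point becomes −6 dB, which the tests account
for explicitly.

## Event detection

The four landmarks are found on the filtered traces:

* **t0** (GI onset): first sustained (≥ 50 ms) excursion of either COP
  axis beyond `max(2.5 × baseline SD, 0.1 mm)` from the quiet-standing
  baseline mean (first 0.5 s).  The crossing is then refined by walking
  back on the *unfiltered* COP to the last sample inside the raw baseline
  band: the raw signal carries no acausal filter leakage, which makes the
  noiseless onset exact to one sample.  Onsets are detected per axis; the
  earlier one defines `t0`, and the per-axis onsets give the two APA
  durations (`APA_ap = HO − onset_ap`, likewise ML) — the reading adopted
  for "ML/AP APA in seconds".
* The **execution phase** is anchored by the first vertical-force drop
  more than 25% below body weight (the plate unloads as weight transfers
  onto the stepping foot ahead of it).
* **HC**: the foot-strike force peak — the Fz maximum after that drop.
  An alternative convention places HC at the onset of the rise toward the
  peak; the peak itself was chosen because it is a locally symmetric
  landmark, hence unbiased under zero-phase filtering, whereas a rise
  onset is smeared backward by the filter.
* **TO**: the push-off Fz maximum between `t0` and the execution drop.
* **HO**: the argmin of the first Fz unloading dip before TO exceeding 5%
  of body weight.

All thresholds are configuration keys (`events.k_sigma`,
`events.min_sustain_ms`, `events.baseline_s`, etc.).  The acceptance tests
require noiseless recovery within one sample (2 ms) and a pooled median
error ≤ 10 ms at realistic noise; measured values are 0 ms (noiseless) and
~0–6 ms per landmark (noisy), the GI onset being the slowest because a
threshold crossing on a smooth ramp is intrinsically biased late.

## Feature set

The 11-variable registry (`gipca.registry.FEATURES`) holds the two APA
durations, the two COP shifts (maximal absolute filtered-COP displacement
from baseline inside `[t0, HO]`), AP COM velocity at HO/TO/HC, ML COM
velocity at HO/TO, the foot-lift time `TO − HO`, and the Fz peak in a
±150 ms window around HC.  The literal enumeration "AP/ML COM velocity at
HO, TO and HC" would give twelve variables; the ML velocity at heel
contact is the one omitted to keep the registry at eleven, since the
downstream component structure involves only the AP velocities.  COM
velocities integrate the filtered, baseline-corrected horizontal forces
from `t0` (quiet standing precedes `t0`, so `v(t0) = 0`).

## Synthetic cohorts

`simulate_cohort` draws two groups from multivariate normal populations
with a shared covariance `D R D`:

* per-variable SDs `D` chosen at physiologically plausible magnitudes
  (e.g. 0.06 s on APA durations, 8–10 mm on COP shifts, 0.03–0.12 m/s on
  velocities, 60 N on the force peak);
* correlation `R = LLᵀ + 0.001·I`, a three-factor model (loading/impact,
  APA/postural, propulsion-velocity factors) with row-normalized loadings.
  Three latent factors with small uniqueness reproduce the empirically
  observed situation in which three principal components carry ~99% of
  the cohort variance; at n = 20 the sample estimate of that cumulative
  fraction is ~98.9–99.5%.
* The control-minus-PD mean shift (in SD units: 1.4 on the force peak,
  1.2 on AP velocities, 1.0 on APA durations, 0.8 on COP shifts, 0.6 on
  ML velocities, −0.5 on foot lift) concentrates the group difference on
  the loading, propulsion and APA variables, scaled by a single
  `effect_scale` knob (1.0 = full profile, 0 = identical populations).

No public per-variable cohort statistics exist for this population, so
the magnitudes are design choices, fixed once; analyses that depend on an
absolute separation level instead *tune* `effect_scale` per cohort so the
realized bootstrapped-cloud overlap matches a stated target (see below).

## Synthetic trials

`simulate_trial` builds six-channel waveforms from piecewise raised-cosine
primitives, band-limited below the 10 Hz analysis filter: quiet standing
(`Fz = mg`, COP at its origin), per-axis raised-cosine COP ramps from the
axis onset to HO, a symmetric swing-leg unloading dip centred at HO, a
push-off overshoot at TO, a step down to the execution-phase load level,
a symmetric foot-strike bump peaking at HC, and a final step off the
plate.  Horizontal forces follow a C¹ PCHIP COM-velocity profile through
the configured landmark velocities, so the stored ground-truth features
are exact by construction.  Moments are generated from the COP trajectory
(`Mx = COP_y·Fz`, `My = −COP_x·Fz`), which makes the COP round trip exact
to machine precision at zero noise.  Dip/overshoot/peak amplitudes are
pre-compensated for the measured attenuation of the analysis filter at
each bump's width (boost capped at 3×), so configured depths and peaks
refer to the filtered domain in which landmarks and features are defined.
Measurement noise is white Gaussian (default 0.3 N on forces, 0.09 N·m on
moments — sub-millimetre COP noise, typical of commercial plates).

What the trial model does **not** emulate: forward dynamics, double-plate
protocols, trial-to-trial waveform variability beyond additive noise, soft
tissue artefacts, or any coupling between the vertical and horizontal
channels.  Passing recovery tests therefore show the extraction chain is
correct for waveforms with the canonical GI phasing, not that it is robust
to every pathology of real recordings.

## PCA, bootstrap, overlap, mixture

* PCA standardizes columns (the 11 variables mix s, m, m/s, N; raw
  covariance would be meaningless) and takes the SVD of the centred
  z-scored matrix — stable also when n < p.  Loadings carry a
  deterministic sign (largest-magnitude coefficient positive).  The PCA is
  fitted once on the pooled two-group table; bootstrap replicates re-use
  the fixed loadings.
* The bootstrap resamples participants (not trials) with replacement,
  B = 10,000 by default, with independent seeded streams per group derived
  from the global seed.
* Confidence ellipses use the cloud mean and covariance with the
  chi-square radius `χ²_d(level)`, level 0.95 by default.
* The Jaccard coefficient is defined for finite sets; for point clouds the
  membership rule discretises it: every pooled cloud point is an element,
  "in A" means inside A's 95% ellipse, `J = |in both|/|in either|`.  A
  Monte-Carlo ellipse-*area* variant (`jaccard.method = area_mc`) is
  available; the membership rule is the default because it uses only
  objects the analysis already constructs.
* The Gaussian mixture is fitted by EM with full covariances,
  k-means++-style mean seeding, uniform initial weights, pooled initial
  covariance, an eigenvalue floor of 1e-8 (bootstrap clouds can be nearly
  degenerate), tolerance 1e-8, up to 500 iterations, best of 10 seeded
  restarts.  Collapsed components are re-seeded (with a warning) and
  repeated collapse is an error.  Cluster-to-group naming is by optimal
  assignment on the contingency table.  Mixtures are fitted independently
  per 2-D subspace (PC1/PC2 and PC2/PC3 by default).

## Study-scale analyses and problem sizes

The acceptance-level analyses use 10+10 cohorts, B = 10,000 bootstrap
replicates for headline numbers (4,000 inside the Monte-Carlo test loop,
2,500 inside calibration loops, with 3–4 mixture restarts there), 20
cohort seeds in Monte-Carlo aggregates, and 100,000 points for ellipse
coverage — sizes chosen so the full suite runs in a few minutes on one
core while keeping Monte-Carlo error well inside the asserted margins.

For analyses "at a given separation", the overlap itself is the
conditioning variable: `tune_effect_scale` bisects `effect_scale` on the
decreasing branch of J(scale) until the realized overlap of the two
bootstrapped clouds reaches the target (0.10).  With 10 participants per
group the realized overlap is strongly cohort-dependent — a sizeable
minority of cohorts cannot reach J ≈ 0.10 at any plausible effect size
because their group sample means happen to lie close in the PC2/PC3 plane
— so aggregate accuracy statements are made over (or summarized by medians
of) cohorts that realize the target overlap.  Note also that J(scale) is
not monotone globally: at very large separations the pooled PCA aligns
PC1 with the group difference and the PC2/PC3 clouds *coincide*, a
structural property of a rank-one mean shift, not an implementation
artefact.

## Known limitations

* **Resampled-mean classification is optimistic under the null.**  Each
  group's bootstrapped-mean cloud centres on that group's *sample* mean.
  Two samples from the *same* population still have sample means
  ~√2·SE apart while each cloud's SD is ~SE, so the unsupervised mixture
  separates the clouds well above chance (measured ~80% per-group accuracy
  at zero effect).  Chance-level behaviour under the null is recovered at
  the participant level (classifying the 20 raw score vectors: ~57%).
  Accuracy figures for bootstrapped clouds should therefore never be read
  as participant-level classification performance without a null
  comparison.
* The bootstrapped-mean cloud is only approximately Gaussian: it inherits
  the sample's own skewness (O(1/√n)), which a normality test will detect
  at B = 10,000; the package's Gaussianity check uses a 500-replicate
  subsample, the resolution relevant for ellipse construction.
* Feature recovery tolerances are limited by the 10 Hz filter: sharp
  velocity transients (e.g. a short foot-lift) are attenuated by up to
  ~0.02 m/s, and narrow force bumps are widened; the simulator compensates
  amplitudes but not shapes.
* The generator's population parameters are plausible, not estimated from
  data; absolute accuracies and overlaps transfer to real cohorts only in
  so far as the three-factor, common-covariance MVN structure holds.
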