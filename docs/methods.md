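# Methods

This note documents the models, conventions and numerical choices behind
`gammamap`, in the order the pipeline applies them, followed by the
synthetic-data model and the validation-study designs.

## Signal chain

**Sampling rates.** Acquisition-style recordings are 10 kHz; analysis
runs at 2 kHz (`downsample`). Integer ratios use an 8th-order
Chebyshev-I anti-alias low-pass with cutoff at 0.8× the target Nyquist
(scipy's IIR decimator) applied forward–backward; non-integer ratios
fall back to polyphase resampling. The analysis rate must exceed twice
the highest band edge (500 Hz floor for the 70–250 Hz high-gamma band).

**Bipolar re-referencing.** Contacts are ordered by `contact_index`
within each strip; derived channel *i* is contact *i* minus contact
*i+1* and carries contact *i*'s coordinates; the last contact's location
is discarded. A layout of C localized contacts on S strips yields C − S
channels (79 contacts on 20 strips → 59). Strips with fewer than two
localized contacts are dropped with a warning. Any signal common to a
strip — scalp-reference leakage, common-mode theatre artifact — cancels
exactly; this identity is tested to machine precision.

**Filters.** The notch at each 50 Hz and 79 Hz harmonic below Nyquist
is a 2nd-order IIR notch of 1 Hz bandwidth applied forward–backward;
band-passes are 4th-order Butterworth applied forward–backward
(zero-phase, so band power is not lagged against trial markers). Orders
and bandwidths are conventions, not physiological constants: the source
protocol specifies the filter placements but not their shapes, so the
defaults are standard, stable choices and all are exposed as arguments.
Measured attenuation at every configured harmonic exceeds 20 dB and
broadband power outside the notch bands changes by < 5%.

**Instantaneous power** is the squared magnitude of the analytic signal
(Hilbert transform), computed over the whole contiguous recording rather
than per trial so trial edges carry no transform artifacts. The first
and last second of a recording can carry filter edge effects; every
trial-segmentation rule removes at least 1 s, so flagged samples never
reach statistics.

## Trial segmentation and condition power

Trial markers are placed by hand during surgery, so each trial is
trimmed before averaging: rest keeps `[onset+2 s, offset−2 s)`, count
keeps `[onset+1 s, offset−1 s)`, switch additionally loses 3 s at the
start (the easy initial phase of the alternation). The 1 s task
exclusion is read as applying to both trial ends, parallel to the rest
rule; a `task_edge_end_s` override supports the single-ended reading,
since the phrasing is genuinely ambiguous. Windows are half-open sample
intervals with boundaries rounded to the nearest sample (manual markers
carry hundreds of milliseconds of error, so sub-sample fidelity is
moot); segmentation is verified exactly against a per-sample
centre-of-sample mask oracle.

Each condition reduces to the time-point mean over the concatenation of
its retained trials (a duration-weighted trial mean), and condition
pairs to the percent change `(P₁/P₂ − 1) × 100`. The formula is used
exactly as stated; it is not antisymmetric under swapping its arguments
and no such property is claimed. PSD contrasts use Welch estimates (1 s
Hann windows, 50% overlap) per retained trial, averaged within
condition — standard defaults where the protocol is silent.

## Rotation surrogate test

The retained power samples of the two contrasted conditions' trials are
concatenated in performed order into a closed loop. Each surrogate
shifts every marker by one shared uniform-integer jitter in
`[1, L−1]` (jitter 0 reproduces the observed statistic and is
excluded); windows wrapping the loop end read circularly. This
preserves trial count, per-trial lengths, condition labels and the
power series' autocorrelation. The statistic is the ratio of condition
mean powers; significance is two-tailed at the 2.5th/97.5th percentile
ranks of the surrogate distribution, with the empirical
`p = 2·min(r, 1−r)` from the observed ratio's fractional rank. The
percentile thresholds use a nearest-rank convention chosen so the
percentile decision and the `p < .05` decision coincide exactly on the
same surrogate set (absent ties). The observed statistic is not added
to the surrogate set by default; an add-one flag provides the
conservative convention. A constant loop yields a degenerate surrogate
distribution and is reported non-significant. Rotation operates on the
power series, not the raw voltage, so concatenation points introduce no
spurious power transients. For the count>rest contrast the loop is
built from the count and rest trials in performed order, with the rest
period entering as a single long trial.

The default `n_perm` is 100 000; simulation studies and tests use 300 –
1000, which bounds the Monte-Carlo standard error of the thresholds at
the cost of coarser p-value granularity (the calibration study's level
is unaffected because significance is a rank comparison).

## Network assignment

Each electrode collects all nonzero-label voxels whose **centre** lies
within 5 mm (inclusive) of the electrode in millimetre space and takes
the modal label; ties break to the smallest label id (deterministic);
an empty candidate set yields `unassigned`. Background (label 0) never
votes. Voxel-centre distance and the inclusive boundary are conventions
— the alternative readings differ only at exact-boundary geometry — and
the radius is configurable. The module is parcellation-agnostic: any
integer label volume plus name table works, so comparing parcellation
schemes is a configuration matter. Brain-shift compensation by
back-projection along the cortical surface normal is out of scope; a
documented simplification (`snap_to_surface`, nearest point of a
supplied surface cloud) stands in for it and records displacements.

## Group statistics

Percent changes are compared between networks with a linear mixed
model: fixed network effect, random intercept per subject, REML.
Degrees of freedom follow the residual convention `n_observations −
n_fixed_params` (59 electrodes and a 2-level fixed effect → 57; a
5-level network model → 54). One-tailed p-values correspond to the
directional prediction that the control network's increase is larger.
When the between-subject variance estimate collapses to the boundary
(singular fit), the model degenerates to pooled ordinary least squares,
which is then used with a warning — on such fixtures the t-statistic
agrees with the closed-form two-sample t-test to 1e-6. Per-network
contrasts are reported uncorrected by default; a Benjamini–Hochberg
layer is available but off.

Spatial focality is compared via all pairwise Euclidean distances among
each band's significant electrodes and an unpaired two-sample t-test
between bands' distance sets (with a motor-exclusion variant). The
anterior–posterior shift between contrasts compares MNI y-coordinates of
the two significant-electrode sets; the default is the unpaired
Wilcoxon rank-sum test, because the two sets are generally of different
sizes and unpaired — a paired signed-rank variant is provided for the
case where the sets coincide electrode-for-electrode, since published
descriptions of this comparison name a signed-rank test without stating
the pairing.

## Synthetic sessions

Each contact channel is a sum of independent components, in microvolts:

* **1/f background** — white noise spectrally shaped to a power-spectrum
  exponent of 2.0 (typical for cortical LFP), flattened below 1 Hz,
  std 15 µV, independent per contact.
* **Band components** — filtered white noise confined to each of the six
  bands (not pure tones, so Hilbert envelopes fluctuate like
  physiological broadband activity), baseline stds 8/6/5/4/4/8 µV for
  δ/θ/α/β/LG/HG, independent per contact. Within each trial the
  component's variance is multiplied by the effect specification's gain
  for that contact's network, the band, and the trial's condition
  (default 1 = no modulation). The HG baseline is deliberately large
  relative to the 1/f background's power above 70 Hz so that an
  injected power ratio survives as an observable total-band-power ratio
  (the background dilutes a ×1.5 injection to ≈×1.45).
* **Shared tones** — 50 Hz line noise (8 µV, 4 harmonics with 1/h
  amplitude decay) and a 79 Hz theatre-equipment tone (6 µV, 3
  harmonics), identical across channels; the 79 Hz tone is the largest
  spectral peak in 70–90 Hz before notching.
* **Common mode** — one 1/f signal per strip (20 µV), identical on its
  four contacts, cancelled exactly by bipolar re-referencing.
* **Acquisition filter** — optional (default on) order-4 Butterworth
  1 Hz high-pass and 1500 Hz low-pass, emulating the online chain; the
  low-pass leg is skipped when it sits at or above Nyquist.

The schedule places one rest period (uniform 120–180 s), then count and
switch trials (truncated normal, 20.1 ± 7.4 s and 29.4 ± 9.4 s, four
each by default — the protocol median) in strict alternation broken
with probability 0.1, separated by 2–5 s gaps. Duration floors (6 s
count, 10 s switch/rest) guarantee every trial retains analyzable
samples after edge exclusions. Identical seeds yield bit-identical
sessions; every random draw descends from the master seed through named
substreams.

**What the generator does not emulate** — and hence what passing tests
do not show about patient data: behavioural errors and excluded trials,
non-stationary arousal or anaesthesia after-effects, spatially
correlated physiological noise across strips, electrode impedance
drift, tissue heterogeneity near tumors, and real cortical geometry
(blob parcellations and random strip orientations stand in for both).
The validation studies demonstrate that the *analysis* is calibrated
and sensitive under the protocol's design structure, not that any
particular physiological effect size holds.

## Validation-study sizes

Chosen as the smallest designs that make the target properties sharp:

* **Null calibration** — 5 sessions × 5 strips (15 bipolar channels) ×
  6 bands = 450 electrode-band rotation tests at `n_perm = 1000`,
  4 count + 4 switch trials each, no injected modulation; the rejection
  rate is compared to 0.05 within its binomial 95% interval.
* **Effect recovery** — 8 sessions × 5 strips (2 on the FPN blob, 3 on
  the DMN blob): 48 affected and 72 unaffected HG channels, ×1.5
  switch/count HG gain; ≥90% of affected channels must be flagged as
  significant increases and ≤10% of unaffected channels flagged at all.
* **Mixed model** — 200 replicates of 13 subjects × 5 electrodes,
  group effect 30 points, between-subject sd 10, residual sd 20;
  coverage of the 95% interval must be ≥90%, and one-tailed p-values
  under permuted labels must pass a Kolmogorov–Smirnov uniformity check.
* **Oracles** — 100 randomized event tables (segmentation) and 100
  randomized label volumes (assignment), exact match required.
* **Determinism** — two full pipeline runs (2 subjects, `n_perm = 300`,
  shortened rest) compared byte-for-byte across all output tables.

## Known limitations

* The rotation test assumes (circular) stationarity of the power series
  under the null; slow drifts spanning a session can inflate false
  positives on real data (the generator's background is stationary).
* The mixed model's residual-dof convention is a documented choice;
  small-sample dof corrections (Satterthwaite, Kenward-Roger) are not
  implemented.
* `snap_to_surface` is a nearest-point simplification of norm-vector
  brain-shift back-projection and can move electrodes tangentially.
* The count>rest loop treats the single rest period as one trial; with
  one long and several short trials the surrogate distribution is
  coarser than for switch>count.
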