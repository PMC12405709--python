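# Methods

This note documents the models, conventions and design choices behind
`septrial`, in the spirit of a methods appendix: what is computed, under
which assumptions, and where the genuinely open choices were made.

## Signal model and montage

Recordings are 19-channel scalp EEG on the 10-20 layout at 300 Hz, in
microvolts, with stimulus onsets as an event list of sample indices.
Modern channel names (T7/T8/P7/P8) are canonical; the legacy aliases
T3/T4/T5/T6 are accepted on read and normalized. Electrode positions are
azimuthal-equidistant projections onto the unit disk (Cz at the origin,
the 10% ring at radius 0.8, intermediate electrodes midway between their
ring and midline neighbors). Neighborhoods for the surface Laplacian are
Hjorth-style: channels within a projected distance of 0.50, which gives
Cz exactly {C3, C4, Fz, Pz}, four neighbors for interior channels and at
least two everywhere. Spline Laplacians were deliberately avoided: with
19 dry electrodes a nearest-neighbor Laplacian is more robust than a
spherical-spline fit.

Sample mapping uses round-half-up of ms·rate/1000, so the ±25 ms feature
window at 300 Hz is ±8 samples (17 samples total). The pre-stimulus
"rest" window is defined as the 17 samples ending at stimulus onset
(−53.3..0 ms at 300 Hz): the nominal −50..0 ms window maps to 15 samples,
and equal epoch lengths across classes are worth 3 ms of nominal window.

Two file formats are supported: a lossless container (float samples plus
JSON metadata in an `.npz`) and 16-bit EDF for interchange, with events
in a CSV sidecar (`sample_index,label`) and the exact sample count in a
JSON sidecar (EDF pads to whole 1 s records). The EDF writer is minimal
but standard-conformant; the test suite cross-reads its output with mne.

## Synthetic runs

The generator produces the statistical structure the analysis assumes,
not a biophysical forward model:

- **Background**: per-channel Gaussian 1/f (power exponent 1) noise,
  mixed across channels by the Cholesky factor of a distance-decaying
  correlation matrix exp(−d/0.6); an 8–12 Hz narrowband rhythm weighted
  toward the occiput (amplitude 0.5 of background RMS at O1/O2); white
  sensor noise at 0.1 of background RMS.
- **Evoked response**: Gaussian components P40 (+6 µV, 40 ms, FWHM
  22 ms), N70 (−12 µV, 90 ms, FWHM 30 ms) and P200 (+8 µV, 200 ms, FWHM
  80 ms), projected through a Cz-peaked topography exp(−d²/2·0.35²).
  The 90 ms default N70 latency sits inside the 87–99 ms range typical
  for tibial-nerve SEPs. Per-trial variability: amplitude scale
  ~N(1, 0.3²) truncated at 0, latency jitter ~N(0, 5 ms²).
- **Gating**: SEP amplitude is multiplied by 1.0 / 0.85 / 0.7 at 0.2 /
  1 / 2 Hz — evoked responses attenuate at faster stimulation rates; the
  specific gains are calibration knobs, not claims.
- **ISIs** are uniform in base·(1 ± 0.2): 5 ± 1 s, 1 ± 0.2 s,
  0.5 ± 0.1 s at the three rates; 75 trials per run by default.
- **SNR**: the `snr` parameter is |N70| / background RMS per channel.
  The default (1.8) was calibrated once so that the Cz N70 r² at 0.2 Hz
  lands near 0.4, the signal-to-noise regime the analysis targets, and
  was not revisited afterwards.
- **Artifacts** (on by default — recordings in this paradigm are not
  clean): blinks as 0.5–2 s biphasic ~100 µV frontal deflections at
  6/min, and broadband 20–40 Hz movement bursts 0–300 ms post-stimulus
  on posterior channels in 5% of trials. Ground truth (per-trial scales
  and shifts, artifact-free traces, affected trial indices) is returned
  alongside every run.

What the simulator does **not** emulate: volume-conducted source
geometry, electrode drift or impedance changes across a session,
habituation, or any between-run nonstationarity — two runs from the same
configuration are draws from the same distribution. Passing tests
therefore show that the pipeline recovers what it assumes under realistic
noise, jitter and artifacts; they do not quantify robustness to the
session-to-session drift real recordings have.

## Preprocessing

The band-pass is a 0.2–40 Hz Butterworth of order 2, applied
forward–backward offline (zero phase, effective order 4) with reflective
padding over three time constants of the 0.2 Hz corner, or forward-only
in the online/streaming path (its passband group delay is logged).

Bad channels are those with peak-to-peak below 0.5 µV (flat) or with a
robust z-score of the *median per-1 s-segment* log-variance above 6.
Using the median over segments makes the detector respond to channels
that are broken throughout the run while ignoring transient artifacts
and the evoked response itself; the z threshold of 6 sits far below a
genuinely broken channel (a 50× noise channel scores z ≈ 54) and above
the physiological spread (alpha-loaded occipital channels reach z ≈ 4).
Flagged channels are removed before spatial filtering; a Laplacian
channel whose surviving neighborhood drops below two raises an error.

Artifact-trial rejection (calibration data only, never online) flags
trials whose peak-to-peak or variance robust z-score across trials
exceeds 4. Ocular cleanup (calibration only) delegates decomposition to
FastICA and removes up to `n_components` components that correlate
(|r| > 0.6) with a 0.5–4 Hz frontal blink proxy *and* load predominantly
on Fp1/Fp2; on decomposition failure the recording is returned unchanged
with a warning. Every step appends itself to a stage audit log in the
recording metadata; the pseudo-online path asserts that nothing beyond
band-pass and spatial filtering ever touched its input.

## Calibration

The N70 latency is the most negative deflection of the stimulus-locked
trial average at the candidate electrode (Cz) within 60–120 ms, with
ties broken toward earlier latencies. The deflection must fall below 4
standard errors of the trial average (median per-sample across-trial SD
divided by √n); otherwise "N70 not detected" is raised — the intended
fallback is reusing a latency calibrated at another stimulation rate.

Per-electrode r² is the squared Pearson correlation between the ±1 class
label and the signed amplitude at the epoch center sample (a windowed-RMS
variant is available); p-values come from the exact F(1, n−2) tail and
are Bonferroni-corrected across electrodes for the −log₁₀(p) maps.
Electrode selection is the fixed centro-parietal set (C3, P3, Cz, Pz,
P4, C4) in multivariate mode and the r²-argmax (ties to Cz) in
univariate mode.

The rLDA uses the pooled within-class covariance (denominator n−2) and
the shrinkage target (tr Σ/d)·I. The shrinkage grid is
{0, 0.001, 0.01, 0.05, 0.1, 0.2, 0.5, 1}; each cross-validation fold
tunes λ on a stratified 20% holdout of its *training* portion (the
natural reading of tuning "within the fold"), ties going to the smallest
λ. Cross-validation is stratified 5-fold with a logged seed; the summary
statistic is the median fold AUC. Degenerate cases are defined rather
than fatal: zero within-class variance falls back to w = μ₊ − μ₋; a
singular covariance at λ = 0 raises with advice to regularize. A P40
variant of the latency estimator (positive-peak search at 30–60 ms) is
available behind the `component` flag; N70 is the supported default.

## Pseudo-online evaluation and streaming

The frozen model is applied to an unseen run with minimal preprocessing:
band-pass plus the spatial filter fixed at calibration. Scores over the
balanced SEP/rest windows give the online AUC;
degradation% = 100·(offline median − online)/offline median. Offline
replay defaults to the zero-phase filter (matching the offline analysis
it is compared against); the streaming emulator is strictly causal.

The streaming replay processes the recording in chunks of any size
through a stateful forward Butterworth filter and epochs each stimulus
once its response window has fully streamed; per-trial scores are
bit-identical across chunk sizes and match batch causal scoring. The
gauge output is max(0, score) scaled by the calibration-score
interquartile range. Wall-clock deadlines (the ~200 ms feedback target)
are recorded per trial — measured both from stimulus onset and from
window end, since the two conventions differ — but are never part of
automated checks: they are hardware properties. A background gate
(`trigger_ready`) reports whether the running RMS of a monitored channel
stayed below threshold for a hold window, emulating
quiet-background-gated stimulation.

Note one structural consequence of matched simulated runs: the offline
median CV AUC is estimated from models trained on 4/5 of the calibration
trials, while the frozen model uses all of them, so on identically
distributed runs the expected offline−online difference is only weakly
positive (selection optimism and the artifact asymmetry — rejection
offline, none online — minus the CV data-size bias). Real sessions add
drift on top; simulated degradation percentages are therefore smaller
than what sessions apart in time produce.

## Statistics

AUC is the rank-based Mann–Whitney statistic with average ranks on ties.
The Friedman χ² uses within-subject average ranks and the standard
tie-corrected denominator; all-tied data returns χ² = 0, p = 1. Kendall's
w = χ²/(n(k−1)) clipped to [0, 1], with Cohen-style bands (≥0.1 small,
≥0.3 moderate, ≥0.5 large). Post-hoc comparisons refer
|mean-rank difference| / √(k(k+1)/12n) to the studentized-range
distribution with infinite degrees of freedom. The χ² reference is an
approximation: at n = 6 it deviates from the exact permutation null by
up to ~0.06 in p, which the test suite bounds explicitly; at n = 10 the
nominal 5% level is accurate to within ~1%. The pipeline is
nonparametric throughout — no normality pre-screening is performed, the
rank-based path is simply always used.

## Problem sizes

Simulation-backed checks use 75-trial runs: 10 run-pairs at 0.2 Hz for
parameter recovery and generalization (20 pairs in the test suite), 20
null runs at 1 Hz for chance-level calibration, and 2000 replicates for
the Friedman type-I rate. These sizes give Monte-Carlo standard errors
comfortably inside the asserted bands while keeping a full suite run in
a few minutes on one core.

## Known limitations

- The Laplacian is nearest-neighbor with equal weights, not a spherical
  spline; absolute µV scales after spatial filtering are therefore
  montage-dependent ("µV per unit²" in Laplacian-referenced units).
- The ocular-removal contract is statistical (blink-band variance down
  ≥70% at Fp1/Fp2, Cz evoked average changed <10% RMS), not a guarantee
  per component; pathological mixing can defeat the frontal-dominance
  gate.
- The bipolar montage defaults to Cz − Fz and is configurable; no claim
  is made that this is the optimal pair.
- Univariate decoding with a single RMS feature is scale-invariant under
  AUC, so shrinkage tuning is inert there (λ affects only multivariate
  models).
- EDF export quantizes to 16 bits over the per-channel data range; use
  the container format for lossless round trips.
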