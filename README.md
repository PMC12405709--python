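# septrial

Single-trial somatosensory evoked potential (SEP) decoding for
non-invasive brain–computer interfaces: simulation, calibration,
pseudo-online evaluation, and streaming replay — in one tested Python
package.

## The problem

Operant conditioning of cortical evoked responses needs feedback after
*every* stimulus, in real time. Scalp SEPs elicited by tibial nerve
stimulation are small (tens of µV) and buried in ongoing EEG, so they are
traditionally averaged over hundreds of trials. This package implements a
pipeline that decides, trial by trial, whether the 50 ms EEG window around
the subject-specific **N70** component (the negative mid-latency SEP
deflection, ~70–100 ms after stimulation) looks like an evoked response or
like pre-stimulus background.

The decoder is a shrinkage-regularized linear discriminant (rLDA). With
class means μ₊, μ₋ and pooled within-class covariance Σ,

    Σ_λ = (1 − λ) Σ + λ (tr Σ / d) I,
    w = Σ_λ⁻¹ (μ₊ − μ₋),   b = −wᵀ(μ₊ + μ₋)/2,

scores s(x) = wᵀx + b are positive for SEP-like windows. Features are the
RMS of the band-passed (0.2–40 Hz, Butterworth order 2), spatially
filtered (surface Laplacian / CAR / linked-ears / bipolar) signal in a
−25..+25 ms window around the calibrated N70 latency (class +1) and an
equal-length pre-stimulus window (class −1). Performance is the rank-based
ROC AUC; condition comparisons use the Friedman test with Kendall's
w = χ²/(n(k−1)) and Tukey-style post-hoc rank tests; electrode-wise SNR is
the label-vs-amplitude r² with Bonferroni-corrected −log₁₀(p) maps.

Because no public single-trial SEP corpus exists, the package ships a
first-class synthetic-data module: 1/f background EEG with
distance-decaying channel correlation, an occipital alpha rhythm, a
Cz-peaked SEP topography with per-trial amplitude/latency jitter,
stimulation-rate-dependent gating, and ocular/movement/bad-channel
artifacts — all with recorded ground truth.

## Worked example

```python
from septrial import (SimConfig, SpatialFilterSpec, build_1020_montage,
                      calibrate_decoder, generate_run, pseudo_online_eval)

montage = build_1020_montage()
run1, _ = generate_run(SimConfig(seed=10, stim_freq_hz=0.2), montage)
run2, _ = generate_run(SimConfig(seed=11, stim_freq_hz=0.2), montage)

res = calibrate_decoder(run1, montage, mode="univariate", seed=0)
bundle = pseudo_online_eval(res.model, run2, montage,
                            SpatialFilterSpec("laplacian"),
                            offline_median=res.bundle.median_auc)
print(res.latency_ms, res.bundle.median_auc, bundle.online_auc,
      bundle.degradation_pct)
```

prints

```
90.0 0.765 0.720 5.97
```

meaning: the N70 latency was recovered at 90.0 ms (the simulated truth),
the offline 5-fold cross-validated median AUC on the calibration run was
0.765, the frozen decoder scored 0.720 on a never-seen run under online
constraints (band-pass + Laplacian only — no ICA, no trial rejection), a
5.97% generalization drop. An AUC of 0.5 is chance; 1.0 is perfect
separation of SEP windows from background.

The `examples/` directory has one short narrative script per capability
(simulation, calibration, pseudo-online evaluation, streaming replay with
gauge feedback and background-gated triggering, repeated-measures
statistics). A thin CLI mirrors the same stages:

```bash
septrial simulate --freq 1 --trials 75 --seed 1 --out run1.npz
septrial calibrate --input run1.npz --seed 0 --out model.json
septrial evaluate --model model.json --input run2.npz
septrial pipeline --seed 0 --out results/
```

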