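"""Pseudo-online generalization: frozen decoder on an unseen run.

The decoder calibrated on the first run is applied to a second,
never-seen run under online constraints: only band-pass and the spatial
filter fixed at calibration, no ICA, no trial rejection.  The drop from
the offline median CV AUC to the online AUC is the generalization cost.
"""

from septrial import (SimConfig, SpatialFilterSpec, build_1020_montage,
                      calibrate_decoder, generate_run, pseudo_online_eval)

montage = build_1020_montage()
run1, _ = generate_run(SimConfig(seed=10, stim_freq_hz=0.2), montage)
run2, _ = generate_run(SimConfig(seed=11, stim_freq_hz=0.2), montage)

res = calibrate_decoder(run1, montage, seed=0)
bundle = pseudo_online_eval(res.model, run2, montage,
                            SpatialFilterSpec("laplacian"),
                            offline_median=res.bundle.median_auc)
print(f"offline median CV AUC (run 1): {bundle.median_auc:.3f}")
print(f"pseudo-online AUC (unseen run 2): {bundle.online_auc:.3f}")
print(f"degradation: {bundle.degradation_pct:.2f}%  "
      f"(positive = the decoder lost accuracy on unseen data)")
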