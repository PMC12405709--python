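"""Pseudo-online evaluation and streaming emulation.

The frozen calibrated decoder is applied to an unseen run under online
constraints: bandpass plus the spatial filter fixed at calibration,
no ICA, no trial rejection, labels untouched until the final AUC.
A chunked streaming replay emulates the real-time feedback loop
(background-gated triggering, per-trial gauge output).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal

from .core_io import Montage, Recording, ResultBundle, ms_to_samples
from .calibration import RLDAModel, build_balanced_epochs, extract_features
from .preprocess import FilterSpec, SpatialFilterSpec, bandpass, spatial_filter
from .stats import auc

_FORBIDDEN_ONLINE = {"ica", "reject_trials"}


def relative_difference(value: float, reference: float) -> float:
    """Percent drop of ``value`` relative to ``reference``, 2 decimals.

    relative_difference(0.68, 0.81) = 16.05: the pseudo-online AUC of
    0.68 is 16.05% below the offline median of 0.81.
    """
    if reference == 0:
        raise ZeroDivisionError("reference must be nonzero")
    return round(100.0 * (reference - value) / reference, 2)


def _check_online_input(rec: Recording) -> None:
    stages = {s["stage"] for s in rec.meta.get("stages", [])}
    bad = stages & _FORBIDDEN_ONLINE
    if bad:
        raise ValueError(
            f"pseudo-online input already passed calibration-only stages "
            f"{sorted(bad)}")


def score_run(model: RLDAModel, rec: Recording, montage: Montage,
              spatial: SpatialFilterSpec,
              filter_mode: str = "zero_phase"):
    """Minimal-preprocessing per-trial scores on a run.

    Applies only the bandpass (zero-phase offline replay, or causal to
    match a real-time system) and the calibration spatial filter, then
    scores SEP and rest features with the frozen model.  Returns
    (scores, labels) over the balanced trial set.
    """
    _check_online_input(rec)
    proc = bandpass(rec, FilterSpec(mode=filter_mode))
    sp = spatial_filter(proc, spatial, montage)
    missing = [e for e in model.feature_spec.electrodes
               if e not in sp.channel_names]
    if missing:
        raise ValueError(f"montage mismatch with calibration: {missing}")
    stages = [s["stage"] for s in sp.meta.get("stages", [])]
    assert set(stages) <= {"bandpass", "spatial"}, \
        "online path touched a calibration-only stage"
    epochs = build_balanced_epochs(sp, model.feature_spec)
    X, y = extract_features(epochs, model.feature_spec.electrodes)
    return model.score(X), y


def pseudo_online_eval(model: RLDAModel, rec: Recording, montage: Montage,
                       spatial: SpatialFilterSpec,
                       offline_median: float | None = None,
                       filter_mode: str = "zero_phase") -> ResultBundle:
    """Generalization AUC of a frozen model on an unseen run.

    degradation_pct = 100 (offline_median - online) / offline_median when
    the offline median is supplied.
    """
    scores, y = score_run(model, rec, montage, spatial, filter_mode)
    bundle = ResultBundle(online_auc=float(auc(scores, y)),
                          median_auc=offline_median)
    return bundle.finalize()


def trigger_ready(buffer: np.ndarray, level_uv: float, hold_ms: float,
                  rate: float = 300.0, rms_window_ms: float = 100.0) -> bool:
    """Background gate: ready iff the running RMS of the monitored channel
    stayed at or below ``level_uv`` for the whole hold window."""
    buffer = np.asarray(buffer, dtype=float)
    hold = ms_to_samples(hold_ms, rate)
    if len(buffer) < hold:
        raise ValueError("buffer shorter than the hold window")
    win = max(1, ms_to_samples(rms_window_ms, rate))
    seg = buffer[-hold:]
    sq = np.convolve(seg ** 2, np.ones(win) / win, mode="valid")
    return bool(np.all(np.sqrt(sq) <= level_uv))


@dataclass
class TrialOutput:
    """Per-stimulus streaming result."""

    event: int
    score: float
    gauge: float
    deadline_from_onset_ms: float
    deadline_from_window_end_ms: float


@dataclass
class StreamState:
    """Causal per-channel filter state plus the emitted trial outputs."""

    zi: np.ndarray
    n_seen: int = 0
    outputs: list = field(default_factory=list)


def stream_simulate(rec: Recording, model: RLDAModel, montage: Montage,
                    spatial: SpatialFilterSpec,
                    chunk_samples: int = 30,
                    gauge_range: float | None = None) -> list[TrialOutput]:
    """Replay a run chunk-by-chunk through the causal online pipeline.

    Each chunk passes through a stateful forward Butterworth filter; once
    the response window of a stimulus is fully available, the trial is
    epoched, scored with the frozen model, and a non-negative gauge
    magnitude (score scaled to [0, 1] by ``gauge_range``, default the
    calibration-score IQR) is emitted.  Output is invariant to
    ``chunk_samples``, and matches batch causal scoring to float
    precision.
    """
    if chunk_samples < 1:
        raise ValueError("chunk_samples must be >= 1")
    _check_online_input(rec)
    fspec = FilterSpec(mode="causal")
    sos = fspec.sos(rec.rate)
    zi = np.zeros(signal.sosfilt_zi(sos).shape[:1] + (rec.n_channels, 2))
    state = StreamState(zi=zi)
    if gauge_range is None:
        gauge_range = float(model.metadata.get("score_iqr", 1.0)) or 1.0

    lat = ms_to_samples(model.feature_spec.center_latency_ms, rec.rate)
    half = ms_to_samples(
        (model.feature_spec.response_window_ms[1]
         - model.feature_spec.response_window_ms[0]) / 2.0, rec.rate)
    ready_at = rec.events + lat + half + 1   # window fully streamed
    too_early = rec.events + lat - half < 0
    el_idx = None

    filtered = np.empty_like(rec.samples)
    pending = list(np.nonzero(~too_early)[0])
    if too_early.any():
        raise ValueError("event closer than the response window to the "
                         "stream start")
    pos = 0
    while pos < rec.n_samples:
        stop = min(pos + chunk_samples, rec.n_samples)
        chunk = rec.samples[:, pos:stop]
        filtered[:, pos:stop], state.zi = signal.sosfilt(
            sos, chunk, axis=1, zi=state.zi)
        state.n_seen = stop
        while pending and ready_at[pending[0]] <= stop:
            i = pending.pop(0)
            ev = rec.events[i]
            # spatial filtering is stateless per sample, so only the
            # response window needs it
            win_rec = Recording(
                filtered[:, ev + lat - half:ev + lat + half + 1],
                rec.rate, rec.channel_names)
            spat = spatial_filter(win_rec, spatial, montage)
            if el_idx is None:
                el_idx = [spat.channel_names.index(e)
                          for e in model.feature_spec.electrodes]
            win = spat.samples[el_idx]
            feats = np.sqrt((win ** 2).mean(axis=1))
            score = float(model.score(feats)[0])
            gauge = float(np.clip(max(0.0, score) / gauge_range, 0.0, 1.0))
            state.outputs.append(TrialOutput(
                int(ev), score, gauge,
                (lat + half + 1) / rec.rate * 1000.0,
                1 * 1000.0 / rec.rate))
        pos = stop
    return state.outputs
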