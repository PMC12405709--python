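"""Temporal filtering, bad-channel handling, spatial filtering, artifact
rejection and ocular cleanup.

A strict split is maintained between calibration-only denoising (ICA,
trial-statistics rejection) and the minimal path permitted online
(bandpass + spatial filter).  Every step appends itself to the
recording's ``meta['stages']`` audit log so the online path can be
verified label-blind and minimal.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import signal

from .core_io import EpochSet, Montage, Recording


@dataclass(frozen=True)
class FilterSpec:
    """Band-pass specification: 0.2-40 Hz Butterworth of order 2.

    ``zero_phase`` applies the filter forward-backward (effective order 4,
    no group delay); ``causal`` applies it forward only, as a real-time
    system must, and reports its passband group delay.
    """

    band_hz: tuple[float, float] = (0.2, 40.0)
    order: int = 2
    mode: str = "zero_phase"       # or "causal"

    def sos(self, rate: float) -> np.ndarray:
        low, high = self.band_hz
        if not (0 < low < high < rate / 2):
            raise ValueError("band must satisfy 0 < low < high < Nyquist")
        return signal.butter(self.order, self.band_hz, btype="bandpass",
                             fs=rate, output="sos")


@dataclass(frozen=True)
class SpatialFilterSpec:
    """Spatial filter: surface Laplacian, CAR, linked ears, or bipolar."""

    kind: str = "laplacian"        # laplacian | car | linked_ears | bipolar
    target: str = "Cz"             # bipolar only
    reference: str = "Fz"          # bipolar only

    def __post_init__(self):
        if self.kind == "bipolar" and self.target == self.reference:
            raise ValueError("bipolar reference must differ from target")


def _log_stage(rec: Recording, stage: str, **params) -> Recording:
    meta = dict(rec.meta)
    meta["stages"] = list(meta.get("stages", [])) + [
        {"stage": stage, **params}]
    return rec.copy_with(meta=meta)


def bandpass(rec: Recording, spec: FilterSpec = FilterSpec()) -> Recording:
    """Band-pass filter every channel.

    Zero-phase mode pads with reflected data over ~3 time constants of the
    high-pass corner to suppress edge transients.
    """
    sos = spec.sos(rec.rate)
    if spec.mode == "zero_phase":
        padlen = min(rec.n_samples - 1,
                     int(3 * rec.rate / (2 * np.pi * spec.band_hz[0])))
        out = signal.sosfiltfilt(sos, rec.samples, axis=1, padlen=padlen)
        extra = {}
    elif spec.mode == "causal":
        out = signal.sosfilt(sos, rec.samples, axis=1)
        w, gd = signal.group_delay(
            signal.sos2tf(sos), w=[np.sqrt(spec.band_hz[0] * spec.band_hz[1])],
            fs=rec.rate)
        extra = {"group_delay_samples": float(gd[0])}
    else:
        raise ValueError(f"unknown filter mode {spec.mode!r}")
    return _log_stage(rec.copy_with(samples=out), "bandpass",
                      band=list(spec.band_hz), order=spec.order,
                      mode=spec.mode, **extra)


def _robust_z(values: np.ndarray) -> np.ndarray:
    dev = values - np.median(values)
    scale = 1.4826 * np.median(np.abs(dev))
    if scale == 0:
        scale = values.std()
    if scale == 0:
        return np.zeros_like(values)
    return dev / scale


def detect_bad_channels(rec: Recording, flat_uv: float = 0.5,
                        z_var: float = 6.0,
                        segment_s: float = 1.0) -> list[str]:
    """Flag flat channels (peak-to-peak < flat_uv) and persistently noisy
    channels (robust z-score of the median per-segment log-variance
    > z_var).

    Using the median over short-segment variances makes the detector
    sensitive to channels that are broken throughout the run while
    ignoring transient artifacts (blinks, movement bursts) and the
    evoked response itself.
    """
    if rec.n_channels < 4:
        raise ValueError("bad-channel detection needs >= 4 channels")
    p2p = rec.samples.max(axis=1) - rec.samples.min(axis=1)
    flat = p2p < flat_uv
    seg = max(1, int(segment_s * rec.rate))
    n_seg = max(1, rec.n_samples // seg)
    segs = rec.samples[:, :n_seg * seg].reshape(rec.n_channels, n_seg, seg)
    med_var = np.median(segs.var(axis=2), axis=1)
    logv = np.log(np.maximum(med_var, 1e-30))
    noisy = _robust_z(logv) > z_var
    return [ch for ch, f, nz in zip(rec.channel_names, flat, noisy)
            if f or nz]


def spatial_filter(rec: Recording, spec: SpatialFilterSpec,
                   montage: Montage, exclude: tuple[str, ...] = ()) -> Recording:
    """Apply a spatial filter.

    Channels in ``exclude`` (e.g. detected bad channels) are removed: they
    are dropped from the output and from every neighborhood/average.
    laplacian: x_c - mean(surviving neighbors of c), with an error if
    fewer than 2 neighbors survive.  car: subtract the mean of all
    surviving channels.  linked_ears: identity (the recording reference
    is retained).  bipolar: target - reference, single channel out.
    """
    names = rec.channel_names
    excl = {montage.channel_names[montage.index(e)] for e in exclude}
    keep = [i for i, ch in enumerate(names) if ch not in excl]
    kept_names = tuple(names[i] for i in keep)
    if spec.kind == "linked_ears":
        out = rec.copy_with(samples=rec.samples[keep].copy(),
                            channel_names=kept_names)
    elif spec.kind == "car":
        mean = rec.samples[keep].mean(axis=0)
        out = rec.copy_with(samples=rec.samples[keep] - mean[None, :],
                            channel_names=kept_names)
    elif spec.kind == "laplacian":
        filtered = np.empty((len(keep), rec.n_samples))
        for row, i in enumerate(keep):
            ch = names[i]
            nbrs = [nb for nb in montage.adjacency[ch]
                    if nb in kept_names]
            if len(nbrs) < 2:
                raise ValueError(
                    f"channel {ch}: fewer than 2 neighbors survive "
                    f"bad-channel removal")
            idx = [names.index(nb) for nb in nbrs]
            filtered[row] = rec.samples[i] - rec.samples[idx].mean(axis=0)
        out = rec.copy_with(samples=filtered, channel_names=kept_names)
    elif spec.kind == "bipolar":
        if {spec.target, spec.reference} & excl:
            raise ValueError("bipolar target/reference flagged bad")
        tgt = rec.channel(spec.target)
        ref = rec.channel(spec.reference)
        out = rec.copy_with(samples=(tgt - ref)[None, :],
                            channel_names=(spec.target,))
    else:
        raise ValueError(f"unknown spatial filter {spec.kind!r}")
    return _log_stage(out, "spatial", kind=spec.kind,
                      excluded=sorted(excl))


def reject_artifact_trials(epochs: EpochSet, z_p2p: float = 4.0,
                           z_var: float = 4.0) -> np.ndarray:
    """Keep-mask over trials, rejecting outliers in peak-to-peak or variance.

    Trial statistics are compared across trials with robust z-scores.
    Calibration data only; the pseudo-online path never calls this.
    """
    if epochs.n_trials < 5:
        raise ValueError("trial rejection needs >= 5 trials")
    p2p = (epochs.data.max(axis=2) - epochs.data.min(axis=2)).max(axis=1)
    var = epochs.data.var(axis=2).mean(axis=1)
    keep = (_robust_z(p2p) <= z_p2p) & (_robust_z(var) <= z_var)
    return keep


def remove_ocular(rec: Recording, n_components: int = 3,
                  corr_threshold: float = 0.6) -> Recording:
    """Remove ocular components via ICA (calibration data only).

    Decomposition is delegated to FastICA; components are flagged as ocular
    when their time course correlates with a frontal 0.5-4 Hz blink proxy
    (|r| > corr_threshold) and their scalp loading is frontal-dominant.  At
    most ``n_components`` components are removed.  On decomposition failure
    the recording is returned unchanged with a warning.
    """
    if n_components == 0:
        return _log_stage(rec, "ica", removed=0)
    if rec.duration < 60.0:
        raise ValueError("ocular removal needs >= 60 s of data")
    from sklearn.decomposition import FastICA

    sos = signal.butter(2, [0.5, 4.0], btype="bandpass", fs=rec.rate,
                        output="sos")
    frontal = [i for i, ch in enumerate(rec.channel_names)
               if ch in ("Fp1", "Fp2")]
    proxy = signal.sosfiltfilt(sos, rec.samples[frontal].mean(axis=0))

    try:
        ica = FastICA(n_components=rec.n_channels, random_state=0,
                      max_iter=500, tol=1e-3)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            sources = ica.fit_transform(rec.samples.T)
    except Exception as exc:            # decomposition failure contract
        warnings.warn(f"ICA failed ({exc}); recording returned unchanged")
        return _log_stage(rec, "ica", removed=0, failed=True)

    mixing = ica.mixing_                           # channels x components
    others = [i for i in range(rec.n_channels) if i not in frontal]
    scores = []
    for j in range(sources.shape[1]):
        r = np.corrcoef(sources[:, j], proxy)[0, 1]
        front_load = np.abs(mixing[frontal, j]).mean()
        other_load = np.abs(mixing[others, j]).mean()
        frontal_dom = front_load > 1.5 * max(other_load, 1e-30)
        scores.append((abs(r), frontal_dom, j))
    remove = [j for r, dom, j in sorted(scores, reverse=True)
              if r > corr_threshold and dom][:n_components]

    keep = [j for j in range(sources.shape[1]) if j not in remove]
    clean = (sources[:, keep] @ mixing[:, keep].T + ica.mean_).T
    return _log_stage(rec.copy_with(samples=clean), "ica",
                      removed=len(remove))
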