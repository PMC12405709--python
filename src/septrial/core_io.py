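"""Domain containers and file I/O for single-trial SEP analysis.

The package works on 19-channel scalp EEG laid out on the international
10-20 system, sampled at 300 Hz, with stimulus onsets carried as an event
list of sample indices.  Two on-disk formats are supported: a lossless
container (float samples + JSON-encoded metadata inside an ``.npz``) and
16-bit EDF for interchange, with events stored in a CSV sidecar.
"""

from __future__ import annotations

import io
import json
import math
import os
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

#: canonical 10-20 channel order used throughout the package
CHANNELS_1020 = (
    "Fp1", "Fp2", "Fz", "F3", "F4", "F7", "F8", "Cz", "C3", "C4",
    "T7", "T8", "Pz", "P3", "P4", "P7", "P8", "O1", "O2",
)

#: legacy 10-20 names accepted on read and normalised to modern labels
LEGACY_ALIASES = {"T3": "T7", "T4": "T8", "T5": "P7", "T6": "P8"}

DEFAULT_RATE = 300.0


def normalize_channel(name: str) -> str:
    """Map a legacy 10-20 label (T3/T4/T5/T6) to its modern equivalent."""
    name = name.strip()
    return LEGACY_ALIASES.get(name, name)


def round_half_up(x: float) -> int:
    """Round with halves going up (7.5 -> 8, -7.5 -> -7)."""
    return int(math.floor(x + 0.5))


def ms_to_samples(ms: float, rate: float) -> int:
    """Convert a time offset in milliseconds to samples (round-half-up)."""
    return round_half_up(ms * rate / 1000.0)


@dataclass(frozen=True)
class Montage:
    """A 10-20 electrode layout with 2-D positions and neighbor adjacency.

    Positions are azimuthal-equidistant projections onto the unit disk
    (vertex Cz at the origin, outer 10% ring at radius 0.8).  Adjacency is
    Hjorth-style: two channels are neighbors when their projected distance
    is below a fixed threshold chosen so interior channels have four
    neighbors.
    """

    channel_names: tuple[str, ...]
    positions: np.ndarray          # (n_channels, 2)
    adjacency: dict[str, frozenset[str]]

    def __post_init__(self):
        if len(set(self.channel_names)) != len(self.channel_names):
            raise ValueError("duplicate channel labels in montage")
        for ch, nbrs in self.adjacency.items():
            for nb in nbrs:
                if ch not in self.adjacency[nb]:
                    raise ValueError("adjacency is not symmetric")

    def index(self, name: str) -> int:
        return self.channel_names.index(normalize_channel(name))

    def position(self, name: str) -> np.ndarray:
        return self.positions[self.index(name)]

    def distance(self, a: str, b: str) -> float:
        return float(np.linalg.norm(self.position(a) - self.position(b)))


_NEIGHBOR_THRESHOLD = 0.50


def build_1020_montage() -> Montage:
    """Construct the 19-channel 10-20 montage used by the analysis.

    Deterministic: repeated calls return identical positions/adjacency.
    """
    ring = {  # azimuth (deg, clockwise from anterior midline) at radius 0.8
        "Fp1": -18, "Fp2": 18, "F7": -54, "F8": 54, "T7": -90, "T8": 90,
        "P7": -126, "P8": 126, "O1": -162, "O2": 162,
    }
    pos: dict[str, np.ndarray] = {}
    for ch, az in ring.items():
        a = math.radians(az)
        pos[ch] = 0.8 * np.array([math.sin(a), math.cos(a)])
    pos["Cz"] = np.zeros(2)
    for ch, az in (("Fz", 0), ("C4", 90), ("Pz", 180), ("C3", -90)):
        a = math.radians(az)
        pos[ch] = 0.4 * np.array([math.sin(a), math.cos(a)])
    # intermediate electrodes sit midway between their ring and midline peers
    pos["F3"] = (pos["F7"] + pos["Fz"]) / 2
    pos["F4"] = (pos["F8"] + pos["Fz"]) / 2
    pos["P3"] = (pos["P7"] + pos["Pz"]) / 2
    pos["P4"] = (pos["P8"] + pos["Pz"]) / 2

    positions = np.array([pos[ch] for ch in CHANNELS_1020])
    adjacency: dict[str, frozenset[str]] = {}
    for i, ch in enumerate(CHANNELS_1020):
        d = np.linalg.norm(positions - positions[i], axis=1)
        nbrs = [c for j, c in enumerate(CHANNELS_1020)
                if j != i and d[j] < _NEIGHBOR_THRESHOLD]
        adjacency[ch] = frozenset(nbrs)
    return Montage(CHANNELS_1020, positions, adjacency)


@dataclass
class Recording:
    """A multichannel EEG run: channels x time samples in microvolts."""

    samples: np.ndarray            # (n_channels, n_samples), µV
    rate: float = DEFAULT_RATE
    channel_names: tuple[str, ...] = CHANNELS_1020
    events: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=int))
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.samples = np.asarray(self.samples, dtype=float)
        self.events = np.asarray(self.events, dtype=int)
        self.channel_names = tuple(normalize_channel(c)
                                   for c in self.channel_names)
        if self.rate <= 0:
            raise ValueError("sampling rate must be positive")
        if self.samples.ndim != 2:
            raise ValueError("samples must be channels x time")
        if self.samples.shape[0] != len(self.channel_names):
            raise ValueError("channel count does not match channel labels")
        if self.events.size:
            if np.any(np.diff(self.events) <= 0):
                raise ValueError("events must be strictly increasing")
            if self.events[0] < 0 or self.events[-1] >= self.n_samples:
                raise ValueError("event outside recording bounds")

    @property
    def n_channels(self) -> int:
        return self.samples.shape[0]

    @property
    def n_samples(self) -> int:
        return self.samples.shape[1]

    @property
    def duration(self) -> float:
        return self.n_samples / self.rate

    def channel(self, name: str) -> np.ndarray:
        return self.samples[self.channel_names.index(normalize_channel(name))]

    def copy_with(self, **kw) -> "Recording":
        return replace(self, **kw)


@dataclass
class EpochSet:
    """Trials x channels x samples, with class labels (+1 SEP, -1 rest)."""

    data: np.ndarray               # (n_trials, n_channels, n_samples)
    window_ms: tuple[float, float]
    labels: np.ndarray             # ±1 per trial
    alignment: str                 # "stimulus+latency" or "pre-stimulus"
    channel_names: tuple[str, ...] = CHANNELS_1020

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=float)
        self.labels = np.asarray(self.labels, dtype=int)
        if self.data.ndim != 3:
            raise ValueError("epoch data must be trials x channels x samples")
        if not np.all(np.isin(self.labels, (-1, 1))):
            raise ValueError("labels must be -1 or +1")
        if len(self.labels) != self.data.shape[0]:
            raise ValueError("one label per trial required")

    @property
    def n_trials(self) -> int:
        return self.data.shape[0]

    def concat(self, other: "EpochSet") -> "EpochSet":
        if self.data.shape[1:] != other.data.shape[1:]:
            raise ValueError("epoch shapes differ")
        return EpochSet(
            np.concatenate([self.data, other.data]),
            self.window_ms,
            np.concatenate([self.labels, other.labels]),
            "mixed" if self.alignment != other.alignment else self.alignment,
            self.channel_names,
        )


@dataclass
class ResultBundle:
    """Offline CV and pseudo-online decoding performance summary."""

    cv_aucs: list[float] = field(default_factory=list)
    median_auc: float | None = None
    chosen_lambdas: list[float] = field(default_factory=list)
    online_auc: float | None = None
    degradation_pct: float | None = None

    def finalize(self) -> "ResultBundle":
        if self.cv_aucs and self.median_auc is None:
            self.median_auc = float(np.median(self.cv_aucs))
        if self.median_auc and self.online_auc is not None:
            self.degradation_pct = round(
                100.0 * (self.median_auc - self.online_auc) / self.median_auc, 2)
        return self

    def to_dict(self) -> dict:
        return {
            "cv_aucs": [float(a) for a in self.cv_aucs],
            "median_auc": self.median_auc,
            "chosen_lambdas": [float(x) for x in self.chosen_lambdas],
            "online_auc": self.online_auc,
            "degradation_pct": self.degradation_pct,
        }


# ---------------------------------------------------------------------------
# container format (lossless): npz with float samples + JSON metadata
# ---------------------------------------------------------------------------

def _write_container(rec: Recording, path: str) -> str:
    if not path.endswith(".npz"):
        path += ".npz"
    header = json.dumps({
        "rate": rec.rate,
        "channel_names": list(rec.channel_names),
        "meta": rec.meta,
    })
    np.savez(path, samples=rec.samples, events=rec.events,
             header=np.frombuffer(header.encode(), dtype=np.uint8))
    return path


def _read_container(path: str) -> Recording:
    with np.load(path) as z:
        header = json.loads(bytes(z["header"]).decode())
        return Recording(z["samples"], header["rate"],
                         tuple(header["channel_names"]),
                         z["events"], header["meta"])


# ---------------------------------------------------------------------------
# EDF (16-bit interchange) + events CSV sidecar
# ---------------------------------------------------------------------------

def _edf_field(value, width: int) -> bytes:
    s = str(value)[:width]
    return s.ljust(width).encode("ascii")


def _sidecar_paths(path: str) -> tuple[str, str]:
    stem = path[:-4] if path.endswith(".edf") else path
    return stem + ".events.csv", stem + ".meta.json"


def _write_edf(rec: Recording, path: str) -> str:
    """Write a plain 16-bit EDF (1 s records, physical dimension uV).

    The stimulus event list goes to ``<stem>.events.csv`` and the exact
    sample count (EDF records are padded to whole seconds) to
    ``<stem>.meta.json``.
    """
    if not path.endswith(".edf"):
        path += ".edf"
    spr = int(round(rec.rate))            # samples per 1 s record
    if abs(spr - rec.rate) > 1e-9:
        raise ValueError("EDF export requires an integer sampling rate")
    n_rec = int(math.ceil(rec.n_samples / spr))
    padded = np.zeros((rec.n_channels, n_rec * spr))
    padded[:, :rec.n_samples] = rec.samples

    pmin = padded.min(axis=1)
    pmax = padded.max(axis=1)
    flat = pmax - pmin < 1e-12
    pmax[flat] = pmin[flat] + 1.0
    dmin, dmax = -32768, 32767

    buf = io.BytesIO()
    ns = rec.n_channels
    buf.write(_edf_field("0", 8))
    buf.write(_edf_field("X", 80))
    buf.write(_edf_field("Startdate X", 80))
    buf.write(_edf_field("01.01.00", 8))
    buf.write(_edf_field("00.00.00", 8))
    buf.write(_edf_field(256 * (ns + 1), 8))
    buf.write(_edf_field("", 44))
    buf.write(_edf_field(n_rec, 8))
    buf.write(_edf_field(1, 8))
    buf.write(_edf_field(ns, 4))
    for ch in rec.channel_names:
        buf.write(_edf_field(f"EEG {ch}", 16))
    for _ in range(ns):
        buf.write(_edf_field("", 80))
    for _ in range(ns):
        buf.write(_edf_field("uV", 8))
    for v in pmin:
        buf.write(_edf_field(f"{v:.6g}"[:8], 8))
    for v in pmax:
        buf.write(_edf_field(f"{v:.6g}"[:8], 8))
    for _ in range(ns):
        buf.write(_edf_field(dmin, 8))
    for _ in range(ns):
        buf.write(_edf_field(dmax, 8))
    for _ in range(ns):
        buf.write(_edf_field("", 80))
    for _ in range(ns):
        buf.write(_edf_field(spr, 8))
    for _ in range(ns):
        buf.write(_edf_field("", 32))

    # re-read physical min/max exactly as stored (ASCII-rounded) so that the
    # writer and any conformant reader use the same scaling
    pmin_s = np.array([float(f"{v:.6g}"[:8]) for v in pmin])
    pmax_s = np.array([float(f"{v:.6g}"[:8]) for v in pmax])
    scale = (pmax_s - pmin_s) / (dmax - dmin)
    digital = np.round((padded - pmin_s[:, None]) / scale[:, None] + dmin)
    digital = np.clip(digital, dmin, dmax).astype("<i2")
    for r in range(n_rec):
        block = digital[:, r * spr:(r + 1) * spr]
        buf.write(block.tobytes())          # channel-major within each record

    with open(path, "wb") as fh:
        fh.write(buf.getvalue())
    ev_path, meta_path = _sidecar_paths(path)
    pd.DataFrame({"sample_index": rec.events,
                  "label": ["stim"] * len(rec.events)}).to_csv(
        ev_path, sep=",", index=False)
    with open(meta_path, "w") as fh:
        json.dump({"n_samples": rec.n_samples, "rate": rec.rate,
                   "meta": rec.meta}, fh)
    return path


def _read_edf(path: str) -> Recording:
    with open(path, "rb") as fh:
        raw = fh.read()
    ns = int(raw[252:256])
    n_rec = int(raw[236:244])
    off = 256
    labels = [raw[off + 16 * i:off + 16 * (i + 1)].decode().strip()
              for i in range(ns)]
    labels = [lb[4:] if lb.startswith("EEG ") else lb for lb in labels]
    off += 16 * ns + 80 * ns + 8 * ns
    pmin = np.array([float(raw[off + 8 * i:off + 8 * (i + 1)])
                     for i in range(ns)])
    off += 8 * ns
    pmax = np.array([float(raw[off + 8 * i:off + 8 * (i + 1)])
                     for i in range(ns)])
    off += 8 * ns
    dmin = np.array([float(raw[off + 8 * i:off + 8 * (i + 1)])
                     for i in range(ns)])
    off += 8 * ns
    dmax = np.array([float(raw[off + 8 * i:off + 8 * (i + 1)])
                     for i in range(ns)])
    off += 8 * ns + 80 * ns
    spr = np.array([int(raw[off + 8 * i:off + 8 * (i + 1)])
                    for i in range(ns)])
    if len(set(spr)) != 1:
        raise ValueError("heterogeneous samples-per-record not supported")
    spr = int(spr[0])
    data = np.frombuffer(raw[256 * (ns + 1):], dtype="<i2")
    data = data.reshape(n_rec, ns, spr).transpose(1, 0, 2).reshape(ns, -1)
    scale = (pmax - pmin) / (dmax - dmin)
    samples = (data - dmin[:, None]) * scale[:, None] + pmin[:, None]

    ev_path, meta_path = _sidecar_paths(path)
    events = np.empty(0, dtype=int)
    meta: dict = {}
    rate = float(spr)
    if os.path.exists(meta_path):
        with open(meta_path) as fh:
            m = json.load(fh)
        samples = samples[:, :m["n_samples"]]
        rate = m["rate"]
        meta = m.get("meta", {})
    if os.path.exists(ev_path):
        events = pd.read_csv(ev_path)["sample_index"].to_numpy(dtype=int)
    return Recording(samples, rate, tuple(labels), events, meta)


def write_recording(rec: Recording, path: str, format: str = "container") -> str:
    """Write a recording; format is 'container' (lossless) or 'edf' (16-bit)."""
    if format == "container":
        return _write_container(rec, path)
    if format == "edf":
        return _write_edf(rec, path)
    raise ValueError(f"unknown format {format!r}")


def read_recording(path: str, format: str | None = None) -> Recording:
    """Read a recording written by :func:`write_recording`.

    Raises on a missing file, non-monotonic events, or a channel-count
    mismatch (via Recording validation).
    """
    if not os.path.exists(path):
        raise FileNotFoundError(path)
    if format is None:
        format = "edf" if path.endswith(".edf") else "container"
    if format == "container":
        return _read_container(path)
    if format == "edf":
        return _read_edf(path)
    raise ValueError(f"unknown format {format!r}")
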