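"""Offline decoder calibration.

Epoching around the subject-specific N70 latency, r-squared based
spatio-temporal feature assessment, RMS feature extraction, shrinkage
regularized LDA (rLDA), per-fold shrinkage tuning on a 20% holdout, and
5-fold cross-validated AUC with the median across folds as the summary.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sps
from sklearn.model_selection import StratifiedKFold, train_test_split

from .core_io import (EpochSet, Montage, Recording, ResultBundle,
                      ms_to_samples)
from .preprocess import (FilterSpec, SpatialFilterSpec, bandpass,
                         detect_bad_channels, reject_artifact_trials,
                         remove_ocular, spatial_filter)
from .stats import auc

#: shrinkage grid searched during hyperparameter optimization
LAMBDA_GRID = (0.0, 0.001, 0.01, 0.05, 0.1, 0.2, 0.5, 1.0)

#: fixed centro-parietal electrode set for multivariate decoding
MULTIVARIATE_SET = ("C3", "P3", "Cz", "Pz", "P4", "C4")


def _as_seed(rng) -> int:
    if isinstance(rng, np.random.Generator):
        return int(rng.integers(0, 2 ** 31 - 1))
    return int(rng)


@dataclass(frozen=True)
class FeatureSpec:
    """Where and when features are taken.

    The response window is -25..+25 ms around the subject-specific N70
    (or P40) latency; the rest window is the equal-duration pre-stimulus
    segment ending at trial onset.
    """

    electrodes: tuple[str, ...]
    center_latency_ms: float
    response_window_ms: tuple[float, float] = (-25.0, 25.0)
    rest_window_ms: tuple[float, float] = (-50.0, 0.0)

    def __post_init__(self):
        dur_resp = self.response_window_ms[1] - self.response_window_ms[0]
        dur_rest = self.rest_window_ms[1] - self.rest_window_ms[0]
        if abs(dur_resp - dur_rest) > 1e-9:
            raise ValueError("response and rest windows must be equal length")


@dataclass
class RSquaredMap:
    """Per-electrode r-squared between class label and signal feature.

    r2 is the squared Pearson correlation between the -1/+1 label and the
    per-trial feature value; p comes from the exact F(1, n-2) tail;
    neglogp_bonf is -log10(min(1, p * n_electrodes)).
    """

    electrodes: tuple[str, ...]
    r2: np.ndarray
    p: np.ndarray
    neglogp_bonf: np.ndarray
    n: int

    def at(self, electrode: str) -> float:
        return float(self.r2[self.electrodes.index(electrode)])


@dataclass
class RLDAModel:
    """Trained shrinkage-LDA decoder; score(x) = w.x + b, positive => SEP."""

    w: np.ndarray
    b: float
    lam: float
    feature_spec: FeatureSpec
    metadata: dict = field(default_factory=dict)

    def score(self, X: np.ndarray) -> np.ndarray:
        return np.atleast_2d(X) @ self.w + self.b

    def to_dict(self) -> dict:
        return {"w": self.w.tolist(), "b": self.b, "lambda": self.lam,
                "electrodes": list(self.feature_spec.electrodes),
                "center_latency_ms": self.feature_spec.center_latency_ms,
                "metadata": self.metadata}


def epoch(rec: Recording, events, window_ms, alignment: str,
          center_latency_ms: float = 0.0, label: int = 1,
          channel_names=None) -> EpochSet:
    """Cut equal-length epochs around each event.

    ``stimulus+latency`` alignment centers the window at
    event + center_latency; ``pre-stimulus`` takes the equal-length
    segment ending at the event.  The window is mapped to samples with
    round-half-up, so +/-25 ms at 300 Hz becomes +/-8 samples (17 total).
    Events too close to the recording edge are dropped.
    """
    events = np.asarray(events, dtype=int)
    half = ms_to_samples((window_ms[1] - window_ms[0]) / 2.0, rec.rate)
    length = 2 * half + 1
    if alignment == "stimulus+latency":
        centers = events + ms_to_samples(center_latency_ms, rec.rate)
        starts = centers - half
    elif alignment == "pre-stimulus":
        starts = events - (length - 1)
    else:
        raise ValueError(f"unknown alignment {alignment!r}")
    keep = (starts >= 0) & (starts + length <= rec.n_samples)
    data = np.stack([rec.samples[:, s:s + length] for s in starts[keep]]) \
        if keep.any() else np.empty((0, rec.n_channels, length))
    return EpochSet(data, tuple(window_ms),
                    np.full(int(keep.sum()), label, dtype=int), alignment,
                    channel_names or rec.channel_names)


def build_balanced_epochs(rec: Recording, spec: FeatureSpec) -> EpochSet:
    """One SEP epoch (+1) and one pre-stimulus rest epoch (-1) per event."""
    sep = epoch(rec, rec.events, spec.response_window_ms, "stimulus+latency",
                spec.center_latency_ms, label=1)
    rest = epoch(rec, rec.events, spec.rest_window_ms, "pre-stimulus",
                 label=-1)
    m = min(sep.n_trials, rest.n_trials)   # balance if edges dropped trials
    sep.data, sep.labels = sep.data[:m], sep.labels[:m]
    rest.data, rest.labels = rest.data[-m:], rest.labels[-m:]
    return sep.concat(rest)


def _label_correlation_r2(values: np.ndarray, labels: np.ndarray):
    n = len(labels)
    v = values - values.mean()
    l = labels - labels.mean()
    denom = np.sqrt((v ** 2).sum() * (l ** 2).sum())
    if denom == 0:
        return 0.0, 1.0
    r = float((v * l).sum() / denom)
    r2 = min(r * r, 1.0)
    if n <= 2 or r2 >= 1.0:
        return r2, 0.0 if r2 >= 1.0 else 1.0
    f = r2 * (n - 2) / (1 - r2)
    return r2, float(sps.f.sf(f, 1, n - 2))


def rsquared_map(epochs: EpochSet, feature: str = "amplitude") -> RSquaredMap:
    """Label-vs-signal r-squared per electrode.

    ``amplitude``: signed value at the epoch center sample (the N70
    latency sample for response epochs).  ``rms``: root-mean-square over
    the whole epoch window.
    """
    if len(np.unique(epochs.labels)) < 2:
        raise ValueError("both classes required")
    if epochs.n_trials < 8:
        raise ValueError("need at least 8 trials")
    if feature == "amplitude":
        values = epochs.data[:, :, epochs.data.shape[2] // 2]
    elif feature == "rms":
        values = np.sqrt((epochs.data ** 2).mean(axis=2))
    else:
        raise ValueError(f"unknown feature {feature!r}")
    m = values.shape[1]
    r2 = np.empty(m)
    p = np.empty(m)
    for c in range(m):
        r2[c], p[c] = _label_correlation_r2(values[:, c], epochs.labels)
    neglog = -np.log10(np.minimum(1.0, np.maximum(p * m, 1e-300)))
    return RSquaredMap(tuple(epochs.channel_names), r2, p, neglog,
                       epochs.n_trials)


def estimate_n70_latency(rec: Recording, electrode: str = "Cz",
                         search_window_ms=(60.0, 120.0),
                         min_trials: int = 20,
                         z_floor: float = 4.0,
                         component: str = "N70") -> float:
    """Latency of the subject-specific SEP component peak.

    Operates on spatially filtered calibration data.  The candidate
    electrode's trial average is searched within the window for the most
    negative deflection (``component='N70'``, default) or the most
    positive one (``component='P40'``, with a 30-60 ms window unless one
    is given).  The peak must exceed z_floor times the standard error of
    the trial average, otherwise '<component> not detected' is raised
    (the univariate fallback is to reuse a latency calibrated at another
    stimulation frequency).  Ties break toward the earlier latency.
    """
    if component not in ("N70", "P40"):
        raise ValueError("component must be 'N70' or 'P40'")
    if component == "P40" and search_window_ms == (60.0, 120.0):
        search_window_ms = (30.0, 60.0)
    if len(rec.events) < min_trials:
        raise ValueError(f"need >= {min_trials} accepted trials")
    ch = rec.channel(electrode)
    lo = ms_to_samples(search_window_ms[0], rec.rate)
    hi = ms_to_samples(search_window_ms[1], rec.rate)
    segs = [ch[ev + lo:ev + hi + 1] for ev in rec.events
            if ev + lo >= 0 and ev + hi < rec.n_samples]
    segs = np.asarray(segs)
    avg = segs.mean(axis=0)
    sign = -1.0 if component == "N70" else 1.0
    # significance floor: standard error of the trial average
    sem = float(np.median(segs.std(axis=0, ddof=1))) / np.sqrt(len(segs))
    idx = int(np.argmax(sign * avg))       # argmax takes the earliest tie
    if sign * avg[idx] <= z_floor * sem:
        raise ValueError(f"{component} not detected")
    return (lo + idx) / rec.rate * 1000.0


def select_electrodes(rsq: RSquaredMap, mode: str,
                      bad: tuple[str, ...] = ()) -> tuple[str, ...]:
    """Pick decoding electrodes.

    multivariate: the fixed centro-parietal set C3, P3, Cz, Pz, P4, C4.
    univariate: the electrode maximizing r2 (ties resolve to Cz when Cz is
    tied, else alphabetically).
    """
    if mode == "multivariate":
        chosen = MULTIVARIATE_SET
    elif mode == "univariate":
        best = np.max(rsq.r2)
        tied = [e for e, v in zip(rsq.electrodes, rsq.r2)
                if np.isclose(v, best)]
        chosen = ("Cz",) if "Cz" in tied else (sorted(tied)[0],)
    else:
        raise ValueError(f"unknown mode {mode!r}")
    flagged = [e for e in chosen if e in bad]
    if flagged:
        alternatives = [e for e in rsq.electrodes
                        if e not in bad and e not in chosen]
        raise ValueError(
            f"selected electrode(s) {flagged} flagged bad; "
            f"alternatives: {alternatives}")
    return tuple(chosen)


def extract_features(epochs: EpochSet,
                     electrodes: tuple[str, ...]) -> tuple[np.ndarray, np.ndarray]:
    """RMS of each epoch at the selected electrodes -> (features, labels)."""
    if epochs.data.shape[2] == 0:
        raise ValueError("empty epoch window")
    idx = [epochs.channel_names.index(e) for e in electrodes]
    X = np.sqrt((epochs.data[:, idx, :] ** 2).mean(axis=2))
    return X, epochs.labels.copy()


def train_rlda(X: np.ndarray, y: np.ndarray, lam: float,
               feature_spec: FeatureSpec | None = None) -> RLDAModel:
    """Fit shrinkage-regularized LDA.

    Sigma_reg = (1 - lambda) Sigma_pooled + lambda (tr Sigma_pooled / d) I;
    w = Sigma_reg^-1 (mu+ - mu-); b places the boundary at the class-mean
    midpoint.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    y = np.asarray(y)
    pos, neg = X[y == 1], X[y == -1]
    if len(pos) < 2 or len(neg) < 2:
        raise ValueError("need >= 2 samples per class")
    mu_p, mu_n = pos.mean(axis=0), neg.mean(axis=0)
    d = X.shape[1]
    cov = (np.cov(pos, rowvar=False, ddof=1) * (len(pos) - 1)
           + np.cov(neg, rowvar=False, ddof=1) * (len(neg) - 1)) \
        / (len(pos) + len(neg) - 2)
    cov = np.atleast_2d(cov)
    if np.trace(cov) == 0:
        # degenerate: no within-class variance at all; any projection on
        # the mean difference separates the classes
        w = mu_p - mu_n
        b = float(-w @ (mu_p + mu_n) / 2.0)
        return RLDAModel(w, b, float(lam),
                         feature_spec
                         or FeatureSpec(tuple(f"f{i}" for i in range(d)),
                                        0.0))
    reg = (1 - lam) * cov + lam * (np.trace(cov) / d) * np.eye(d)
    try:
        w = np.linalg.solve(reg, mu_p - mu_n)
    except np.linalg.LinAlgError as exc:
        raise np.linalg.LinAlgError(
            f"regularized covariance is singular ({exc}); "
            "use lambda > 0 for collinear features") from exc
    b = float(-w @ (mu_p + mu_n) / 2.0)
    return RLDAModel(w, b, float(lam),
                     feature_spec
                     or FeatureSpec(tuple(f"f{i}" for i in range(d)), 0.0))


def optimize_lambda(X: np.ndarray, y: np.ndarray,
                    grid=LAMBDA_GRID, holdout_frac: float = 0.2,
                    rng=0) -> float:
    """Select shrinkage by holdout AUC.

    A stratified holdout of ``holdout_frac`` of the data is scored for
    every lambda on the grid; argmax wins, ties go to the smallest
    lambda.  If a split lacks a class it is redrawn (max 5 attempts).
    """
    if len(grid) == 0:
        raise ValueError("empty lambda grid")
    if len(grid) == 1:
        return float(grid[0])
    seed = _as_seed(rng)
    for attempt in range(5):
        try:
            Xt, Xh, yt, yh = train_test_split(
                X, y, test_size=holdout_frac, stratify=y,
                random_state=seed + attempt)
            best_lam, best_auc = None, -np.inf
            for lam in sorted(grid):
                try:
                    model = train_rlda(Xt, yt, lam)
                except np.linalg.LinAlgError:
                    continue
                a = auc(model.score(Xh), yh)
                if a > best_auc:
                    best_lam, best_auc = float(lam), a
            if best_lam is None:
                raise ValueError("no lambda on the grid was trainable")
            return best_lam
        except ValueError as exc:
            if "least populated" in str(exc) or "class" in str(exc):
                continue
            raise
    raise ValueError("could not form a stratified holdout in 5 attempts")


def crossvalidate(X: np.ndarray, y: np.ndarray, k: int = 5,
                  lambda_grid=LAMBDA_GRID, rng=0) -> ResultBundle:
    """Stratified k-fold CV with per-fold shrinkage tuning.

    Each fold tunes lambda on a 20% holdout of its training portion,
    trains on the full training portion, and scores the held-out fold;
    the summary AUC is the median across folds.
    """
    y = np.asarray(y)
    if len(y) < 2 * k:
        raise ValueError("need at least 2 samples per fold")
    seed = _as_seed(rng)
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    aucs, lams = [], []
    for f, (tr, te) in enumerate(skf.split(X, y)):
        if len(np.unique(y[te])) < 2:
            raise ValueError("a fold lost one of the classes")
        lam = optimize_lambda(X[tr], y[tr], lambda_grid, rng=seed + 1000 + f)
        model = train_rlda(X[tr], y[tr], lam)
        aucs.append(auc(model.score(X[te]), y[te]))
        lams.append(lam)
    return ResultBundle(cv_aucs=aucs, chosen_lambdas=lams).finalize()


@dataclass
class CalibrationResult:
    model: RLDAModel
    bundle: ResultBundle
    rsq: RSquaredMap
    latency_ms: float
    bad_channels: list[str]
    kept_trials: int


def calibrate_decoder(rec: Recording, montage: Montage,
                      mode: str = "univariate",
                      spatial: SpatialFilterSpec = SpatialFilterSpec(),
                      seed: int = 0,
                      lambda_grid=LAMBDA_GRID,
                      reject: bool = True,
                      ica: bool = False,
                      center_latency_ms: float | None = None,
                      filter_spec: FilterSpec = FilterSpec()) -> CalibrationResult:
    """Full offline calibration on one run.

    Denoise (bandpass, bad channels, optional ICA), spatially filter,
    estimate the N70 latency from the trial average, build a balanced
    epoch set, reject artifact trials, assess per-electrode r-squared,
    select electrodes, extract RMS features and cross-validate an rLDA.
    ``center_latency_ms`` overrides latency estimation (e.g. the
    univariate fallback of reusing another frequency's calibration).
    """
    proc = bandpass(rec, filter_spec)
    bad = detect_bad_channels(proc)
    if ica:
        proc = remove_ocular(proc)
    sp = spatial_filter(proc, spatial, montage, exclude=tuple(bad))
    if center_latency_ms is None:
        candidate = "Cz" if spatial.kind != "bipolar" else spatial.target
        center_latency_ms = estimate_n70_latency(sp, candidate)
    fspec = FeatureSpec(("Cz",), center_latency_ms)
    epochs = build_balanced_epochs(sp, fspec)

    if reject:
        half = epochs.n_trials // 2
        sep_keep = reject_artifact_trials(
            EpochSet(epochs.data[:half], epochs.window_ms,
                     epochs.labels[:half], "stimulus+latency",
                     epochs.channel_names))
        rest_keep = reject_artifact_trials(
            EpochSet(epochs.data[half:], epochs.window_ms,
                     epochs.labels[half:], "pre-stimulus",
                     epochs.channel_names))
        pair_keep = sep_keep & rest_keep
        mask = np.concatenate([pair_keep, pair_keep])
        epochs = EpochSet(epochs.data[mask], epochs.window_ms,
                          epochs.labels[mask], epochs.alignment,
                          epochs.channel_names)

    rsq = rsquared_map(epochs)
    electrodes = select_electrodes(rsq, mode, bad=tuple(bad))
    fspec = FeatureSpec(electrodes, center_latency_ms)
    X, y = extract_features(epochs, electrodes)
    bundle = crossvalidate(X, y, lambda_grid=lambda_grid, rng=seed)
    lam = optimize_lambda(X, y, lambda_grid, rng=seed + 1)
    model = train_rlda(X, y, lam, fspec)
    train_scores = model.score(X)
    model.metadata.update({
        "mode": mode, "spatial": spatial.kind, "seed": seed,
        "cv_aucs": [float(a) for a in bundle.cv_aucs],
        "score_iqr": float(np.subtract(*np.percentile(train_scores,
                                                      [75, 25]))),
    })
    return CalibrationResult(model, bundle, rsq, center_latency_ms, bad,
                             epochs.n_trials // 2)
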