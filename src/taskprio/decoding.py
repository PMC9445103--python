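"""Time-resolved decoding of classification type with trial-group averaging.

At every (20 Hz) time point a linear support vector machine is trained and
tested on averages of small random groups of trials rather than single
trials, to boost signal-to-noise: each of 10 iterations randomly assigns
the trials of each class to 15 equal-size groups (surplus trials randomly
excluded), and a 15-fold cross-validation trains on the 28 group averages
(14 per class) and classifies the 2 held-out averages.  Each class thus
receives 10 x 15 = 150 predictions per time point; accuracy is the number
of correct predictions divided by the number made.  Curves are smoothed
with a 5-point (+/- 100 ms) edge-truncated moving average.

Features are either broadband voltage (64 channels) or raw, non-baselined
alpha power at 8-12 Hz (64 x 5 = 320 features), both downsampled to 20 Hz
by non-overlapping bin averaging.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.svm import SVC

from ._utils import bin_downsample, moving_average, window_mask
from .containers import EpochSet, TFRSet

try:  # low-level libsvm binding: identical solver, ~20x less call overhead
    from sklearn.svm import _libsvm

    _libsvm.set_verbosity_wrap(0)
except ImportError:  # pragma: no cover - fallback for changed sklearn internals
    _libsvm = None


def _fit_predict_linear_svm(x_train, y_train, x_test, c):
    """Train a linear SVM and predict labels for ``x_test``.

    Uses the raw libsvm binding when available (bit-identical to
    ``SVC(kernel='linear')`` on these inputs, verified in the test suite);
    falls back to the public estimator otherwise.
    """
    if _libsvm is None:  # pragma: no cover
        svm = SVC(kernel="linear", C=c)
        return svm.fit(x_train, y_train.astype(int)).predict(x_test)
    model = _libsvm.fit(x_train, y_train, svm_type=0, kernel="linear", C=c)
    sv_coef, intercept = model[3], model[4]
    w = sv_coef[0] @ model[1]
    decision = x_test @ w + intercept[0]
    # libsvm's positive side is the first training label (here 0)
    return np.where(decision > 0, y_train[0], y_train[-1])


@dataclass
class DecodingConfig:
    feature_kind: str = "broadband_erp"  # or "alpha_power"
    alpha_freqs_hz: tuple = (8.0, 9.0, 10.0, 11.0, 12.0)
    n_groups: int = 15
    n_iterations: int = 10
    decode_sfreq: float = 20.0
    smoothing_points: int = 5
    time_range_ms: tuple = (0.0, 11800.0)
    svm_c: float = 1.0

    def __post_init__(self):
        if self.feature_kind not in ("broadband_erp", "alpha_power"):
            raise ValueError(f"unknown feature_kind {self.feature_kind!r}")
        if self.n_groups < 3:
            raise ValueError("need at least 3 groups")
        if self.smoothing_points % 2 != 1:
            raise ValueError("smoothing_points must be odd")


def prepare_features(
    source: EpochSet | TFRSet, config: DecodingConfig
) -> tuple[np.ndarray, np.ndarray]:
    """Feature tensor (trials x features x decode-time) and its time axis.

    Broadband features come from an :class:`EpochSet` (one feature per
    channel); alpha features from a raw :class:`TFRSet` (channel x frequency,
    flattened).  The time axis is cropped to the decode range and bin-averaged
    down to ``decode_sfreq``.
    """
    if config.feature_kind == "broadband_erp":
        if not isinstance(source, EpochSet):
            raise TypeError("broadband decoding needs an EpochSet")
        x = source.data.astype(np.float64)  # trials x ch x t
        times, sfreq = source.times_ms, source.sfreq
    else:
        if not isinstance(source, TFRSet):
            raise TypeError("alpha-power decoding needs a TFRSet")
        if source.is_db:
            raise ValueError("alpha decoding uses raw (not baseline-corrected) power")
        fidx = []
        for f in config.alpha_freqs_hz:
            hits = np.flatnonzero(np.isclose(source.freqs_hz, f))
            if hits.size == 0:
                raise ValueError(f"frequency {f} Hz not in TFR")
            fidx.append(hits[0])
        x = source.power[:, :, fidx]  # trials x ch x 5 x t
        x = x.reshape(x.shape[0], -1, x.shape[-1]).astype(np.float64)
        times, sfreq = source.times_ms, source.sfreq

    tmask = window_mask(times, config.time_range_ms)
    x, times = x[..., tmask], times[tmask]
    factor = int(round(sfreq / config.decode_sfreq))
    if factor < 1 or not np.isclose(sfreq / factor, config.decode_sfreq):
        raise ValueError(f"decode_sfreq {config.decode_sfreq} does not divide {sfreq}")
    return bin_downsample(x, factor, axis=-1), bin_downsample(times, factor)


@dataclass
class DecodingResult:
    """Accuracy time series plus confusion bookkeeping for one analysis."""

    accuracy: np.ndarray            # raw accuracy per time point
    accuracy_smoothed: np.ndarray
    times_ms: np.ndarray
    classes: list
    correct_by_class: np.ndarray    # (2, n_times)
    count_by_class: np.ndarray      # (2, n_times)
    group_sizes: dict
    n_predictions_per_class: int
    config: DecodingConfig = field(repr=False, default=None)
    seed: int | None = None

    def summary(self) -> str:
        return (
            f"group-averaged SVM decoding of {self.classes[0]} vs {self.classes[1]}: "
            f"{self.n_predictions_per_class} predictions/class/time point, group sizes "
            f"{self.group_sizes}, mean accuracy {self.accuracy.mean():.3f}, "
            f"peak {self.accuracy_smoothed.max():.3f} at "
            f"{self.times_ms[self.accuracy_smoothed.argmax()]:.0f} ms"
        )


def decode_timecourse(
    features: np.ndarray,
    labels: np.ndarray,
    config: DecodingConfig | None = None,
    seed: int | None = None,
) -> DecodingResult:
    """Run the full group-averaged cross-validation over time.

    ``features`` is (trials x features x time) at the decode rate (from
    :func:`prepare_features`); ``labels`` assigns each trial to one of two
    classes.  Reproducible from ``seed``.
    """
    config = config or DecodingConfig()
    labels = np.asarray(labels)
    classes = sorted(np.unique(labels).tolist())
    if len(classes) != 2:
        raise ValueError(f"need exactly 2 classes, got {classes}")
    n_groups, n_iter = config.n_groups, config.n_iterations
    cls_trials = {c: np.flatnonzero(labels == c) for c in classes}
    group_sizes = {}
    for c, tr in cls_trials.items():
        if len(tr) < n_groups:
            raise ValueError(
                f"class {c!r} has {len(tr)} trials; needs >= {n_groups}")
        group_sizes[c] = len(tr) // n_groups

    n_times = features.shape[-1]
    n_feat = features.shape[1]
    rng = np.random.default_rng(seed)
    correct = np.zeros((2, n_times), dtype=int)
    total = np.zeros((2, n_times), dtype=int)
    y_train = np.repeat([0.0, 1.0], n_groups - 1)
    x_train = np.empty((2 * (n_groups - 1), n_feat), dtype=np.float64, order="C")

    for _ in range(n_iter):
        # per-class group averages: (2, n_groups, n_features, n_times)
        avgs = []
        for c in classes:
            perm = rng.permutation(cls_trials[c])
            gs = group_sizes[c]
            kept = perm[: n_groups * gs]  # surplus trials randomly excluded
            grp = features[kept].reshape(n_groups, gs, *features.shape[1:]).mean(1)
            avgs.append(grp)
        avgs = np.stack(avgs)
        for ti in range(n_times):
            x = avgs[..., ti]  # (2, n_groups, n_features)
            for fold in range(n_groups):
                train_idx = np.delete(np.arange(n_groups), fold)
                x_train[: n_groups - 1] = x[0, train_idx]
                x_train[n_groups - 1:] = x[1, train_idx]
                pred = _fit_predict_linear_svm(x_train, y_train, x[:, fold], config.svm_c)
                correct[0, ti] += pred[0] == 0
                correct[1, ti] += pred[1] == 1
                total[:, ti] += 1

    accuracy = correct.sum(0) / total.sum(0)
    return DecodingResult(
        accuracy=accuracy,
        accuracy_smoothed=moving_average(accuracy, config.smoothing_points),
        times_ms=None,  # attached by GroupAverageDecoder / caller if known
        classes=classes,
        correct_by_class=correct,
        count_by_class=total,
        group_sizes=group_sizes,
        n_predictions_per_class=int(total[0, 0]),
        config=config,
        seed=seed,
    )


def confusion_summary(
    result: DecodingResult, window_ms: tuple[float, float] | None = None
) -> dict:
    """Per-class accuracy over a time window (whole range by default)."""
    if result.times_ms is None or window_ms is None:
        sel = slice(None)
    else:
        sel = window_mask(result.times_ms, window_ms)
    corr = result.correct_by_class[:, sel].sum(1)
    tot = result.count_by_class[:, sel].sum(1)
    if (tot == 0).any():
        raise ValueError("empty window")
    return {c: float(corr[i] / tot[i]) for i, c in enumerate(result.classes)}


class GroupAverageDecoder:
    """Model-style front end: features + labels in, ``fit`` runs the
    group-averaged SVM cross-validation and returns a
    :class:`DecodingResult` with the decode-time axis attached."""

    def __init__(self, source, labels, config: DecodingConfig | None = None):
        self.config = config or DecodingConfig()
        if isinstance(source, (EpochSet, TFRSet)):
            self.features, self.times_ms = prepare_features(source, self.config)
        else:
            self.features, self.times_ms = np.asarray(source), None
        self.labels = np.asarray(labels)

    def fit(self, seed: int | None = None) -> DecodingResult:
        result = decode_timecourse(self.features, self.labels, self.config, seed)
        result.times_ms = self.times_ms
        return result
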