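"""Feature preparation and the trial-group-averaged SVM scheme."""

import numpy as np
import pandas as pd
import pytest
from sklearn.model_selection import cross_val_score
from sklearn.svm import SVC

from taskprio import tfr as tfrm
from taskprio.decoding import (
    DecodingConfig,
    GroupAverageDecoder,
    confusion_summary,
    decode_timecourse,
    prepare_features,
)

LABELS2 = ("odd_even", "smaller_bigger")


def make_features(n_per_class=30, n_feat=8, n_times=12, signal=0.0,
                  signal_times=None, seed=0):
    """Gaussian features; optional class-separable mean shift."""
    rng = np.random.default_rng(seed)
    n = 2 * n_per_class
    x = rng.normal(size=(n, n_feat, n_times))
    labels = np.repeat(LABELS2, n_per_class)
    if signal:
        pattern = rng.normal(size=n_feat)
        pattern /= np.linalg.norm(pattern)
        tsel = slice(None) if signal_times is None else signal_times
        x[:n_per_class, :, tsel] += signal * pattern[:, None]
        x[n_per_class:, :, tsel] -= signal * pattern[:, None]
    return x, labels


class TestPrepareFeatures:
    def test_broadband_dimension_is_64(self, small_epochs):
        cfg = DecodingConfig(feature_kind="broadband_erp")
        feats, times = prepare_features(small_epochs, cfg)
        assert feats.shape[1] == 64
        assert feats.shape[0] == small_epochs.n_trials
        # 20 Hz axis inside 0..11800 ms
        assert len(times) == feats.shape[-1]
        assert np.allclose(np.diff(times), 50.0)
        assert times[0] >= 0.0 and times[-1] <= 11800.0

    def test_alpha_dimension_is_320(self, small_epochs):
        bank = tfrm.build_wavelets(200.0, np.array([8.0, 9.0, 10.0, 11.0, 12.0]))
        raw = tfrm.decompose(small_epochs, bank)
        cfg = DecodingConfig(feature_kind="alpha_power")
        feats, _ = prepare_features(raw, cfg)
        assert feats.shape[1] == 64 * 5

    def test_constant_input_gives_constant_features(self, small_epochs):
        from taskprio.containers import EpochSet

        ep = EpochSet(np.full_like(small_epochs.data, 3.0), small_epochs.sfreq,
                      small_epochs.times_ms, small_epochs.channel_names,
                      small_epochs.metadata)
        feats, _ = prepare_features(ep, DecodingConfig())
        assert np.allclose(feats, 3.0)

    def test_db_power_rejected(self, small_epochs):
        bank = tfrm.build_wavelets(200.0, np.array([8.0, 9.0, 10.0, 11.0, 12.0]))
        db = tfrm.db_baseline(tfrm.decompose(small_epochs, bank))
        with pytest.raises(ValueError, match="raw"):
            prepare_features(db, DecodingConfig(feature_kind="alpha_power"))


class TestDecodeTimecourse:
    def test_null_labels_near_chance(self):
        x, labels = make_features(n_per_class=45, n_times=30, seed=1)
        res = decode_timecourse(x, labels, DecodingConfig(n_iterations=4), seed=2)
        assert res.accuracy.mean() == pytest.approx(0.5, abs=0.04)

    def test_planted_signal_recovered_inside_window(self):
        x, labels = make_features(n_per_class=30, n_times=20, signal=1.5,
                                  signal_times=slice(5, 12), seed=3)
        res = decode_timecourse(x, labels, DecodingConfig(n_iterations=3), seed=4)
        assert res.accuracy[6:11].mean() > 0.9
        assert abs(res.accuracy[15:].mean() - 0.5) < 0.1

    def test_identical_class_distributions_are_chance(self):
        rng = np.random.default_rng(5)
        x = rng.normal(size=(60, 6, 10))  # both classes iid from one distribution
        labels = np.repeat(LABELS2, 30)
        res = decode_timecourse(x, labels, DecodingConfig(n_iterations=4), seed=6)
        assert res.accuracy.mean() == pytest.approx(0.5, abs=0.06)

    def test_exact_duplication_never_above_chance(self):
        """Copying one class's trials verbatim into the other must not create
        spurious decodability.  (It actually drives accuracy *below* chance:
        each held-out average shares trials with the opposite class's
        training averages, an anti-learning leakage inherent to group
        averaging over duplicated data.)"""
        rng = np.random.default_rng(7)
        half = rng.normal(size=(30, 6, 10))
        x = np.concatenate([half, half.copy()])
        labels = np.repeat(LABELS2, 30)
        res = decode_timecourse(x, labels, DecodingConfig(n_iterations=4), seed=8)
        assert res.accuracy.mean() <= 0.52

    def test_prediction_counts_and_balance(self):
        x, labels = make_features(n_per_class=31, n_times=5, seed=7)
        res = decode_timecourse(x, labels, DecodingConfig(), seed=8)
        # 10 iterations x 15 folds per class, surplus (31 - 2*15) excluded
        assert res.n_predictions_per_class == 150
        assert (res.count_by_class == 150).all()
        assert res.group_sizes == {c: 2 for c in LABELS2}

    def test_insufficient_trials_error(self):
        x, labels = make_features(n_per_class=10, n_times=3)
        with pytest.raises(ValueError, match="needs >="):
            decode_timecourse(x, labels, DecodingConfig(n_groups=15), seed=0)

    def test_single_class_error(self):
        x, _ = make_features(n_per_class=20, n_times=3)
        with pytest.raises(ValueError, match="2 classes"):
            decode_timecourse(x, np.repeat("odd_even", 40), DecodingConfig(), seed=0)

    def test_seed_determinism(self):
        x, labels = make_features(n_per_class=20, n_times=8, seed=9)
        cfg = DecodingConfig(n_groups=10, n_iterations=2)
        a = decode_timecourse(x, labels, cfg, seed=10)
        b = decode_timecourse(x, labels, cfg, seed=10)
        assert (a.accuracy == b.accuracy).all()
        c = decode_timecourse(x, labels, cfg, seed=11)
        assert not (a.accuracy == c.accuracy).all()

    def test_smoothing_is_edge_truncated_moving_average(self):
        x, labels = make_features(n_per_class=16, n_times=7, seed=12)
        cfg = DecodingConfig(n_groups=8, n_iterations=2)
        res = decode_timecourse(x, labels, cfg, seed=13)
        acc = res.accuracy
        assert res.accuracy_smoothed[0] == pytest.approx(acc[:3].mean())
        assert res.accuracy_smoothed[3] == pytest.approx(acc[1:6].mean())

    def test_group_averaging_beats_single_trials(self):
        """The scheme's rationale: averaging trials into groups raises SNR,
        so group-averaged decoding should not do worse than a single-trial
        SVM cross-validation on the same noisy planted signal."""
        x, labels = make_features(n_per_class=45, n_feat=16, n_times=1,
                                  signal=0.35, seed=14)
        res = decode_timecourse(x, labels, DecodingConfig(n_iterations=4), seed=15)
        single = cross_val_score(SVC(kernel="linear", C=1.0), x[..., 0],
                                 labels, cv=15).mean()
        assert res.accuracy[0] >= single - 0.02


class TestConfusion:
    def test_null_confusion_symmetric(self):
        x, labels = make_features(n_per_class=30, n_times=10, seed=16)
        res = decode_timecourse(x, labels, DecodingConfig(n_iterations=4), seed=17)
        acc = confusion_summary(res)
        assert set(acc) == set(LABELS2)
        for v in acc.values():
            assert v == pytest.approx(0.5, abs=0.08)

    def test_planted_signal_confusion_balanced(self):
        x, labels = make_features(n_per_class=30, n_times=6, signal=1.0, seed=18)
        res = decode_timecourse(x, labels, DecodingConfig(n_iterations=4), seed=19)
        acc = confusion_summary(res)
        assert abs(acc[LABELS2[0]] - acc[LABELS2[1]]) < 0.05


class TestModelInterface:
    def test_decoder_from_epochs(self, small_epochs):
        meta = small_epochs.metadata
        cfg = DecodingConfig(n_groups=4, n_iterations=2,
                             time_range_ms=(5000.0, 7000.0))
        model = GroupAverageDecoder(
            small_epochs, meta["classification_type"].to_numpy(), cfg)
        res = model.fit(seed=20)
        assert res.times_ms is not None
        assert len(res.accuracy) == len(res.times_ms)
        assert "decoding" in res.summary()
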