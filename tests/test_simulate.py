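"""Schedule balance, feedback formulas, behavior and EEG generation."""

import numpy as np
import pandas as pd
import pytest

from taskprio import simulate as sim

FACTORS = ["important_task", "retrocue_side", "classification_type"]


class TestSchedule:
    def test_paper_scale_schedule(self):
        sch = sim.make_schedule(10, 60, seed=1)
        assert len(sch) == 600
        assert sch.groupby("important_task").size().tolist() == [300, 300]
        # per-block single-factor and pairwise balance is exact
        for f in FACTORS:
            assert (sch.groupby(["block", f]).size() == 30).all()
        for a, b in [(0, 1), (0, 2), (1, 2)]:
            counts = sch.groupby(["block", FACTORS[a], FACTORS[b]]).size()
            assert (counts == 15).all()
        # triple cells differ by at most one (60 not divisible by 8)
        triple = sch.groupby(["block"] + FACTORS).size()
        assert set(triple.unique()) == {7, 8}

    def test_minimal_balanced_design(self):
        sch = sim.make_schedule(1, 8, seed=2)
        assert (sch.groupby(FACTORS).size() == 1).all()

    def test_indivisible_block_errors(self):
        with pytest.raises(ValueError, match="divisible"):
            sim.make_schedule(1, 7, seed=3)

    def test_reproducible_and_shuffled(self):
        a = sim.make_schedule(2, 16, seed=4)
        b = sim.make_schedule(2, 16, seed=4)
        pd.testing.assert_frame_equal(a, b)
        c = sim.make_schedule(2, 16, seed=5)
        assert not a.equals(c)

    def test_event_onsets(self):
        sch = sim.make_schedule(1, 8, seed=0)
        onsets = sch.attrs["event_onsets_ms"]
        assert onsets["relevance_cue"] == 0
        assert onsets["memory_items"] == 3000
        assert onsets["classification_cue"] == 5600
        assert onsets["classification_digit"] == 6800
        assert onsets["retro_cue"] == 9600
        assert onsets["wm_target"] == 10800


class TestFeedback:
    @pytest.mark.parametrize("rt,correct,cued,expected", [
        (300.0, True, True, 75.0),    # fastest band gives the maximum
        (400.0, True, True, 75.0),
        (1800.0, True, True, 0.0),    # formula endpoint
        (1100.0, True, False, 12.5),  # un-cued maximum is 25
        (900.0, False, True, 0.0),    # incorrect always zero
        (None, True, True, 0.0),      # missing always zero
    ])
    def test_nct_scores(self, rt, correct, cued, expected):
        assert sim.feedback_nct(rt, correct, cued) == pytest.approx(expected)

    @pytest.mark.parametrize("dev,cued,expected", [
        (0.0, True, 75.0),
        (45.0, True, 0.0),
        (60.0, True, 0.0),     # beyond 45 degrees stays zero
        (22.5, True, 37.5),
        (22.5, False, 12.5),
        (None, True, 0.0),
    ])
    def test_wmt_scores(self, dev, cued, expected):
        assert sim.feedback_wmt(dev, cued) == pytest.approx(expected)

    def test_contract_violations(self):
        with pytest.raises(ValueError):
            sim.feedback_nct(150.0, True, True)
        with pytest.raises(ValueError):
            sim.feedback_wmt(-1.0, True)

    def test_total_bounded_by_100(self):
        sch = sim.make_schedule(2, 16, seed=6)
        beh = sim.simulate_behavior(sch, seed=7)
        assert (beh["fp_total"] >= 0).all() and (beh["fp_total"] <= 100).all()
        assert np.allclose(beh["fp_total"], beh["fp_nct"] + beh["fp_wmt"])


class TestBehavior:
    def test_condition_means_recovered(self):
        sch = sim.make_schedule(20, 60, seed=8)  # 600 trials per condition
        beh = sim.simulate_behavior(sch, seed=9)
        task = sch["important_task"]
        p = sim.BehaviorParams()
        for cond in ("NCT", "WMT"):
            rts = beh.loc[task == cond, "rt_nct_ms"]
            se = p.nct_rt_sd_ms[cond] / np.sqrt(len(rts))
            assert abs(rts.mean() - p.nct_rt_mean_ms[cond]) < 4 * se
        # the configured importance gap survives sampling
        gap = (beh.loc[task == "WMT", "rt_nct_ms"].mean()
               - beh.loc[task == "NCT", "rt_nct_ms"].mean())
        assert gap == pytest.approx(562.86 - 537.00, abs=20.0)

    def test_zero_variance_params(self):
        sch = sim.make_schedule(1, 8, seed=10)
        params = sim.BehaviorParams(
            nct_rt_sd_ms={"NCT": 0.0, "WMT": 0.0},
            wmt_rt_sd_ms={"NCT": 0.0, "WMT": 0.0},
            deviation_sd_deg={"NCT": 0.0, "WMT": 0.0},
        )
        beh = sim.simulate_behavior(sch, params, seed=11)
        task = sch["important_task"]
        for cond in ("NCT", "WMT"):
            assert (beh.loc[task == cond, "rt_nct_ms"]
                    == params.nct_rt_mean_ms[cond]).all()

    def test_seeded_reproducibility(self):
        sch = sim.make_schedule(1, 16, seed=12)
        a = sim.simulate_behavior(sch, seed=13)
        b = sim.simulate_behavior(sch, seed=13)
        pd.testing.assert_frame_equal(a, b)

    def test_rts_within_registration_window(self):
        sch = sim.make_schedule(4, 60, seed=14)
        beh = sim.simulate_behavior(sch, seed=15)
        assert beh["rt_nct_ms"].between(*sim.NCT_RT_WINDOW_MS).all()
        assert (beh["deviation_deg"] >= 0).all()


class TestEpochs:
    def test_shape_axes_and_metadata(self, small_epochs):
        ep = small_epochs
        assert ep.data.shape == (16, 64, 3481)
        assert ep.times_ms[0] == -3700.0 and ep.times_ms[-1] == 13700.0
        assert np.allclose(np.diff(ep.times_ms), 5.0)
        assert len(ep.metadata) == ep.n_trials

    def test_seed_determinism(self):
        sch = sim.make_schedule(1, 8, seed=16)
        spec = sim.default_effect_spec(seed=17)
        a = sim.simulate_epochs(sch, spec)
        b = sim.simulate_epochs(sch, spec)
        assert (a.data == b.data).all()
        c = sim.simulate_epochs(sch, sim.default_effect_spec(seed=18))
        assert not (a.data == c.data).all()

    def test_unknown_channel_label_errors(self):
        sch = sim.make_schedule(1, 8, seed=19)
        spec = sim.EffectSpec(
            band_effects=[sim.BandEffect(5.0, (0.0, 1000.0), 1.0,
                                         channels=["NOPE"])])
        with pytest.raises(KeyError, match="NOPE"):
            sim.simulate_epochs(sch, spec)

    def test_effect_window_outside_epoch_errors(self):
        sch = sim.make_schedule(1, 8, seed=20)
        spec = sim.EffectSpec(
            band_effects=[sim.BandEffect(5.0, (13000.0, 15000.0), 1.0)])
        with pytest.raises(ValueError, match="outside epoch"):
            sim.simulate_epochs(sch, spec)

    def test_planted_burst_raises_band_power(self):
        """A strong 5 Hz burst must raise 5 Hz power inside its window for
        the targeted condition only."""
        from taskprio import tfr as tfrm

        sch = sim.make_schedule(1, 16, seed=21)
        spec = sim.EffectSpec(
            band_effects=[sim.BandEffect(5.0, (3000.0, 5600.0), 8.0,
                                         condition=("important_task", "NCT"))],
            seed=22)
        ep = sim.simulate_epochs(sch, spec)
        tfr = tfrm.decompose(ep, tfrm.build_wavelets(ep.sfreq, np.array([5.0])))
        win = (tfr.times_ms >= 3400) & (tfr.times_ms <= 5200)
        out = (tfr.times_ms >= 7000) & (tfr.times_ms <= 9000)
        nct = (sch["important_task"] == "NCT").to_numpy()
        p_nct = tfr.power[nct][..., win].mean()
        p_wmt = tfr.power[~nct][..., win].mean()
        p_out = tfr.power[nct][..., out].mean()
        assert p_nct > 3 * p_wmt
        assert p_nct > 3 * p_out

    def test_roundtrip_io(self, small_epochs, tmp_path):
        from taskprio.containers import EpochSet

        small_epochs.save(tmp_path / "ep")
        back = EpochSet.load(tmp_path / "ep")
        assert np.allclose(back.data, small_epochs.data, atol=1e-6)
        assert back.channel_names == small_epochs.channel_names
        assert len(back.metadata) == len(small_epochs.metadata)
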