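"""Contract tests of filtering, artifact rejection, epoching, RP and LRP."""

import numpy as np
import pandas as pd
import pytest

from driftrace.erp_pipeline import (
    Epochs,
    Recording,
    apply_filters,
    average_reference,
    compute_lrp,
    compute_rp,
    epoch,
    exclude_trials,
    reject_artifacts,
)
from driftrace.synthetic_data import GeneratorConfig, generate_behavior, generate_eeg

RATE = 512.0


def make_recording(data, events=None):
    data = np.atleast_2d(data)
    labels = [f"ch{i}" for i in range(data.shape[0])]
    ev = events if events is not None else pd.DataFrame({"sample": [], "kind": []})
    return Recording(data=data, rate=RATE, labels=labels, events=ev)


class TestApplyFilters:
    def test_notch_attenuates_60_hz(self):
        t = np.arange(int(90 * RATE)) / RATE
        rec = make_recording(20 * np.sin(2 * np.pi * 60 * t))
        out = apply_filters(rec, highpass_hz=None, notch_band=(59, 61))
        mid = slice(int(10 * RATE), int(80 * RATE))
        assert out.data[0, mid].std() < 0.1 * rec.data[0, mid].std()

    def test_highpass_removes_dc_offset(self):
        rec = make_recording(np.full(int(90 * RATE), 50.0))
        out = apply_filters(rec, highpass_hz=0.1, notch_band=None)
        mid = slice(int(40 * RATE), int(50 * RATE))
        assert np.abs(out.data[0, mid]).max() < 1.0

    def test_passband_signal_preserved(self):
        t = np.arange(int(90 * RATE)) / RATE
        rec = make_recording(10 * np.sin(2 * np.pi * 5 * t))
        out = apply_filters(rec, highpass_hz=0.1, notch_band=(59, 61))
        mid = slice(int(10 * RATE), int(80 * RATE))
        ratio = out.data[0, mid].std() / rec.data[0, mid].std()
        assert ratio == pytest.approx(1.0, abs=0.05)

    def test_corner_at_or_above_nyquist_rejected(self):
        rec = make_recording(np.zeros(int(5 * RATE)))
        with pytest.raises(ValueError, match="Nyquist"):
            apply_filters(rec, highpass_hz=None, notch_band=None, lowpass_hz=256.0)
        with pytest.raises(ValueError, match="Nyquist"):
            apply_filters(rec, highpass_hz=None, notch_band=(255, 257))


def test_average_reference_subtracts_scalp_mean():
    data = np.vstack([np.full(100, 3.0), np.full(100, 1.0), np.full(100, 50.0)])
    rec = Recording(
        data=data, rate=RATE, labels=["a", "b", "EOG1"],
        events=pd.DataFrame({"sample": [], "kind": []}),
    )
    out = average_reference(rec, exclude=("EOG1",))
    assert np.allclose(out.data[0], 1.0)
    assert np.allclose(out.data[1], -1.0)
    assert np.allclose(out.data[2], 48.0)  # reference applied to all rows


class TestRejectArtifacts:
    def background(self, n_s=20.0):
        t = np.arange(int(n_s * RATE)) / RATE
        return 30 * np.sin(2 * np.pi * 5 * t)

    def test_clean_recording_has_empty_mask(self):
        mask = reject_artifacts(make_recording(self.background()))
        assert not mask.any()

    def test_amplitude_spike_masks_guarded_interval(self):
        x = self.background()
        t0 = int(10 * RATE)
        x[t0] = 120.0
        mask = reject_artifacts(make_recording(x))
        guard = int(0.15 * RATE)
        assert mask[t0 - guard : t0 + guard + 1].all()
        assert not mask[: t0 - int(0.5 * RATE)].any()

    def test_flatline_masked(self):
        x = self.background()
        a = int(10 * RATE)
        x[a : a + int(0.2 * RATE)] = 0.0
        mask = reject_artifacts(make_recording(x))
        assert mask[a + int(0.05 * RATE) : a + int(0.15 * RATE)].any()

    def test_step_rule_catches_fast_jump(self):
        x = self.background()
        a = int(10 * RATE)
        x[a : a + int(0.05 * RATE)] += 90.0  # |x| stays < 100, jump > 100/200ms
        mask = reject_artifacts(make_recording(x))
        assert mask[a] or mask[a + 1]


class TestExcludeTrials:
    def test_bound_rules(self):
        df = pd.DataFrame({"rt": [0.15, 11.0, 1.0, 1.1], "subject": 0})
        out = exclude_trials(df)
        assert list(out["reason"][:2]) == ["too_fast", "too_slow"]
        assert out["kept"].tolist() == [False, False, True, True]

    def test_wrong_key_rule(self):
        df = pd.DataFrame({"rt": [1.0, 1.0], "wrong_key": [True, False]})
        out = exclude_trials(df)
        assert out["reason"].tolist() == ["wrong_key", ""]

    def test_three_sd_rule_from_direct_computation(self, rng):
        rts = np.concatenate([rng.normal(1.0, 0.05, 99), [1.3]])
        df = pd.DataFrame({"rt": rts, "subject": 0, "decision_type": "a", "difficulty": "e"})
        out = exclude_trials(df)
        surv = rts  # no trial hits the bound rules
        assert 1.3 > surv.mean() + 3 * surv.std(ddof=1)  # oracle premise
        assert not out["kept"].iloc[-1]
        assert out["reason"].iloc[-1] == "rt_outlier"
        assert out["kept"][:-1].all()

    def test_conservation_of_counts(self, rng):
        df = pd.DataFrame({"rt": rng.gamma(4, 0.5, 200), "subject": 0})
        out = exclude_trials(df)
        assert out["kept"].sum() + (out["reason"] != "").sum() == len(df)


def trials_frame(stim_s, resp_s):
    return pd.DataFrame(
        {
            "stimulus_sample": np.asarray(stim_s, dtype=int),
            "response_sample": np.asarray(resp_s, dtype=int),
            "subject": 0,
            "decision_type": "arbitrary",
            "difficulty": "easy",
            "hand": "left",
        }
    )


class TestEpoch:
    def test_constant_channel_zeroed_by_baseline(self):
        rec = make_recording(np.full(int(10 * RATE), 7.0))
        tr = trials_frame([int(3 * RATE)], [int(5 * RATE)])
        ep = epoch(rec, tr, lock="response")
        assert np.allclose(ep.data, 0.0)

    def test_window_sample_count_half_open(self):
        rec = make_recording(np.zeros(int(10 * RATE)))
        tr = trials_frame([int(3 * RATE)], [int(5 * RATE)])
        ep = epoch(rec, tr, lock="response", window=(-2.0, 0.2))
        assert ep.data.shape[2] == 1126

    def test_linear_drift_oracle(self):
        # 1 µV/s drift, stimulus at 1 s, response at 3 s, stimulus-locked
        # baseline [-1, -0.5) s covers absolute time [0, 0.5) s with mean
        # 0.25 µV -> epoch values equal t - 0.25
        t = np.arange(int(10 * RATE)) / RATE
        rec = make_recording(t.copy())
        tr = trials_frame([int(1 * RATE)], [int(3 * RATE)])
        ep = epoch(rec, tr, lock="response", window=(-2.0, 0.2))
        baseline_mean = t[0:256].mean()  # samples of [-1, -0.5) before stimulus
        expected = ep.times + 3.0 - baseline_mean
        assert np.allclose(ep.data[0, 0], expected, atol=1e-9)

    def test_baseline_subtraction_idempotent(self):
        rng = np.random.default_rng(0)
        rec = make_recording(rng.normal(0, 10, int(10 * RATE)))
        tr = trials_frame([int(4 * RATE)], [int(6 * RATE)])
        ep = epoch(
            rec, tr, lock="stimulus", window=(-1.5, 0.5),
            baseline=(-1.0, -0.5, "stimulus"),
        )
        # re-baselining the already-baselined epoch changes nothing
        sel = (ep.times >= -1.0) & (ep.times < -0.5)
        assert ep.data[0, 0, sel].mean() == pytest.approx(0.0, abs=1e-12)

    def test_out_of_bounds_trial_dropped_with_reason(self):
        rec = make_recording(np.zeros(int(4 * RATE)))
        tr = trials_frame(
            [int(0.3 * RATE), int(0.5 * RATE), int(3.0 * RATE)],
            [int(1.0 * RATE), int(2.6 * RATE), int(3.9 * RATE)],
        )
        ep = epoch(rec, tr, lock="response")
        assert ep.meta["reason"].tolist() == [
            "out_of_bounds",  # epoch starts before the recording
            "baseline_out_of_bounds",  # stimulus too close to the start
            "out_of_bounds",  # epoch runs past the end
        ]
        assert ep.data.shape[0] == 0

    def test_artifact_overlap_dropped(self):
        rec = make_recording(np.zeros(int(10 * RATE)))
        mask = np.zeros(rec.n_samples, dtype=bool)
        mask[int(4.9 * RATE)] = True
        tr = trials_frame([int(3 * RATE)], [int(5 * RATE)])
        ep = epoch(rec, tr, lock="response", bad_mask=mask)
        assert ep.meta["reason"].tolist() == ["artifact"]


def noiseless_cfg(**kw):
    defaults = dict(
        n_subjects=1, trials_per_condition=12, noise_amplitude_uv=0.0,
        saccade_rate_hz=1e-9, blink_rate_hz=1e-9, artifact_rate_hz=1e-9,
    )
    defaults.update(kw)
    return GeneratorConfig(**defaults)


def epoch_noiseless(cfg, seed=3):
    beh = generate_behavior(cfg, seed)
    rec, trials = generate_eeg(beh, cfg, seed + 1)
    return epoch(rec, trials, lock="response")


class TestComputeRp:
    def test_ramp_stat_window_mean_matches_analytic_value(self):
        # linear ramp 0 -> -2.5 µV over 1.2 s: mean over [-0.5, 0) is
        # -2.5 * 0.95 / 1.2 = -1.979 µV (direct integration)
        ep = epoch_noiseless(noiseless_cfg(lrp_peak_uv=0.0))
        table, grand = compute_rp(ep, min_trials=1)
        arb = table[table["decision_type"] == "arbitrary"]
        dlb = table[table["decision_type"] == "deliberate"]
        assert arb["mean_amplitude_uv"].to_numpy() == pytest.approx(-1.979, abs=0.02)
        assert dlb["mean_amplitude_uv"].to_numpy() == pytest.approx(0.0, abs=1e-9)

    def test_rp_is_linear_in_the_data(self):
        ep = epoch_noiseless(noiseless_cfg(lrp_peak_uv=0.0))
        t1, _ = compute_rp(ep, min_trials=1)
        ep.data = 2.0 * ep.data
        t2, _ = compute_rp(ep, min_trials=1)
        assert np.allclose(
            t2["mean_amplitude_uv"], 2.0 * t1["mean_amplitude_uv"]
        )

    def test_low_trial_subjects_flagged(self):
        ep = epoch_noiseless(noiseless_cfg())
        table, _ = compute_rp(ep, min_trials=30)
        assert table["flagged_low_n"].all()  # only 12 trials per condition


class TestComputeLrp:
    def test_equal_channels_give_zero_lrp(self, rng):
        data = np.zeros((3, 2, 100))
        data[:, 0, :] = data[:, 1, :] = rng.normal(size=(3, 100))
        ep = Epochs(
            data=data, rate=RATE, labels=["C3", "C4"], lock="response",
            window=(0.0, 100 / RATE), baseline=None,
            meta=pd.DataFrame(
                {"subject": 0, "hand": ["left", "right", "left"],
                 "kept": True, "epoch_index": [0, 1, 2]}
            ),
        )
        table, waves = compute_lrp(ep, stat_window=(0.0, 100 / RATE))
        assert np.allclose(waves, 0.0)

    def test_injected_template_recovered_and_antisymmetric(self):
        # with the contralateral mapping (left hand -> C4), a -x template
        # gives LRP = mean_left(C3-C4) - mean_right(C3-C4) = +2x over its span
        cfg = noiseless_cfg(rp_peak_uv=0.0, lrp_peak_uv=-1.0)
        ep = epoch_noiseless(cfg)
        table, waves = compute_lrp(ep)
        sel = (ep.times >= -0.3) & (ep.times < 0.0)
        span_mean = waves[0, sel].mean()
        # template ramps 0 -> -1 over 0.3 s: mean |value| = 0.5 -> LRP = +1.0
        assert span_mean == pytest.approx(1.0, abs=0.05)

        flipped = ep.meta.copy()
        flipped["hand"] = flipped["hand"].map({"left": "right", "right": "left"})
        ep2 = Epochs(
            data=ep.data, rate=ep.rate, labels=ep.labels, lock=ep.lock,
            window=ep.window, baseline=ep.baseline, meta=flipped,
        )
        _, waves2 = compute_lrp(ep2)
        assert np.allclose(waves2, -waves)

    def test_missing_hand_rejected(self):
        cfg = noiseless_cfg()
        ep = epoch_noiseless(cfg)
        ep.meta["hand"] = "left"
        with pytest.raises(ValueError, match="hand"):
            compute_lrp(ep)
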