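"""Unit and property tests of the accumulator/race simulation core."""

import dataclasses
import math

import numpy as np
import pytest
from scipy import stats

from driftrace import ddm_core
from driftrace.ddm_core import (
    AccumulatorParams,
    UNBOUNDED,
    best_fit_condition,
    condition_from_entry,
    load_parameter_table,
    noiseless_crossing_time,
    parameter_table,
    run_race,
    run_trial,
    save_parameter_table,
    simulate_accumulator,
    simulate_condition,
)


def noiseless(I, k, threshold=0.3, **kw):
    return AccumulatorParams(drift=I, leak=k, noise_scale=0.0, threshold=threshold, **kw)


class TestSimulateAccumulator:
    def test_zero_drive_stays_at_zero(self):
        trace, idx = simulate_accumulator(noiseless(0.0, 0.4), seed=0)
        assert idx is None
        assert np.all(trace == 0.0)

    def test_linear_ramp_crosses_at_expected_sample(self):
        # I*dt = 3e-4 per step -> reaches 0.3 at sample 1000
        trace, idx = simulate_accumulator(noiseless(0.3, 0.0), seed=0)
        assert idx == 1000
        assert trace.size == idx + 1
        assert trace[-1] >= 0.3 > trace[-2]

    @pytest.mark.parametrize(
        "I,k,theta",
        [(0.23, 0.52, 0.3), (0.18, 0.3, 0.3), (0.4, 0.55, 0.3), (0.3, 0.2, 0.25)],
    )
    def test_noiseless_crossing_matches_closed_form(self, I, k, theta):
        p = noiseless(I, k, threshold=theta)
        trace, idx = simulate_accumulator(p, seed=0)
        t_star = noiseless_crossing_time(I, k, theta)
        assert idx is not None
        assert abs(idx * p.dt - t_star) <= 2 * p.dt

    def test_subthreshold_asymptote_never_crosses(self):
        # asymptote I/k = 0.1 below threshold 0.3
        trace, idx = simulate_accumulator(noiseless(0.05, 0.5), seed=0)
        assert idx is None
        assert trace.max() < 0.11

    def test_unbounded_threshold_never_reports_crossing(self):
        p = AccumulatorParams(drift=0.5, leak=0.0, noise_scale=0.1, threshold=UNBOUNDED)
        trace, idx = simulate_accumulator(p, seed=1)
        assert idx is None
        assert trace.size == p.n_steps + 1

    def test_mean_trace_converges_to_noiseless_solution(self, rng):
        # law of large numbers: mean over runs ~ deterministic leaky curve
        p = AccumulatorParams(drift=0.24, leak=0.53, noise_scale=0.22, t_max=2.0)
        noise = rng.standard_normal((5000, p.n_steps))
        mean_trace = ddm_core._integrate_batch(p, noise).mean(axis=0)
        t = np.arange(1, p.n_steps + 1) * p.dt
        expected = p.drift / p.leak * (1 - np.exp(-p.leak * t))
        assert np.max(np.abs(mean_trace - expected)) < 0.02

    @pytest.mark.parametrize(
        "kw",
        [
            {"drift": math.nan},
            {"dt": 0.0},
            {"t_max": -1.0},
            {"leak": -0.1},
            {"noise_scale": -0.2},
            {"threshold": 0.0},
        ],
    )
    def test_invalid_parameters_rejected(self, kw):
        base = dict(drift=0.2, leak=0.5, noise_scale=0.1)
        base.update(kw)
        with pytest.raises(ValueError):
            AccumulatorParams(**base)


class TestRunRace:
    def test_noiseless_ramp_beats_flat(self):
        res = run_race(noiseless(0.3, 0.0), noiseless(0.0, 0.0), seed=0)
        assert res.winner == "congruent"
        assert res.rt == pytest.approx(1.0)
        # loser trace truncated at the winner's crossing
        assert len(res.traces[0]) == len(res.traces[1]) == res.crossing_index + 1

    def test_equal_parameters_win_fraction_is_half(self, arbitrary_easy):
        p = dataclasses.replace(arbitrary_easy.congruent)
        sim = simulate_condition(
            condition_from_entry("arbitrary", "easy", p.drift, p.drift, p.leak, p.noise_scale),
            10_000,
            seed=7,
            keep_traces=False,
        )
        # 3-sigma binomial band around 0.5 at n = 10,000
        assert abs(sim.consistency - 0.5) < 3 * 0.5 / math.sqrt(10_000)

    def test_swapping_roles_swaps_win_fraction(self):
        a = condition_from_entry("arbitrary", "easy", 0.24, 0.18, 0.5, 0.2)
        b = condition_from_entry("arbitrary", "easy", 0.18, 0.24, 0.5, 0.2)
        fa = simulate_condition(a, 4000, seed=3, keep_traces=False).consistency
        fb = simulate_condition(b, 4000, seed=4, keep_traces=False).consistency
        se = math.sqrt(0.25 / 4000)
        assert abs(fa - (1 - fb)) < 5 * se

    def test_mismatched_time_base_rejected(self):
        with pytest.raises(ValueError):
            run_race(noiseless(0.3, 0.0), noiseless(0.3, 0.0, dt=0.002), seed=0)


class TestRunTrial:
    def test_noiseless_deliberate_trial(self, deliberate_easy):
        cond = condition_from_entry("deliberate", "easy", 0.23, 0.06, 0.52, 0.0)
        tr = run_trial(cond, seed=0)
        assert tr.winner == "congruent"
        # SMA integrates thresholdless with drift / 1.45, cut at the crossing
        assert len(tr.sma_traces[0]) == tr.crossing_index + 1
        t = np.arange(len(tr.sma_traces[0])) * cond.congruent.dt
        I, k = 0.23 / 1.45, 0.52
        expected = I / k * (1 - np.exp(-k * t))
        assert np.max(np.abs(tr.sma_traces[0] - expected)) < 0.01

    def test_sma_drift_scaling_is_exact(self, deliberate_easy):
        sma_c, sma_i = deliberate_easy.sma_pair()
        assert sma_c.drift == pytest.approx(deliberate_easy.congruent.drift / 1.45)
        assert sma_i.drift == pytest.approx(deliberate_easy.incongruent.drift / 1.45)
        assert math.isinf(sma_c.threshold) and math.isinf(sma_i.threshold)
        assert sma_c.leak == deliberate_easy.congruent.leak
        assert sma_c.noise_scale == deliberate_easy.congruent.noise_scale

    def test_arbitrary_trial_sma_is_deciding_pair(self, arbitrary_easy):
        tr = run_trial(arbitrary_easy, seed=5)
        assert tr.decided
        assert tr.sma_traces[0] is tr.deciding_traces[0]

    def test_undecided_trial_flagged(self):
        cond = condition_from_entry("arbitrary", "easy", 0.01, 0.01, 0.5, 0.0, t_max=2.0)
        tr = run_trial(cond, seed=0)
        assert tr.winner == "none"
        assert math.isnan(tr.rt)
        assert tr.crossing_index is None


class TestSimulateCondition:
    def test_single_run_reduces_to_run_trial(self, arbitrary_easy):
        tr = run_trial(arbitrary_easy, seed=11)
        sim = simulate_condition(arbitrary_easy, 1, seed=11)
        assert sim.winners[0] == tr.winner
        assert sim.rts[0] == pytest.approx(tr.rt)

    def test_all_undecided_raises_on_consistency(self):
        cond = condition_from_entry("arbitrary", "easy", 0.01, 0.01, 0.5, 0.0, t_max=1.0)
        sim = simulate_condition(cond, 10, seed=0, keep_traces=False)
        assert sim.n_undecided == 10
        with pytest.raises(ValueError):
            sim.consistency

    def test_seed_reproducibility(self, arbitrary_easy):
        a = simulate_condition(arbitrary_easy, 200, seed=9, keep_traces=False)
        b = simulate_condition(arbitrary_easy, 200, seed=9, keep_traces=False)
        assert np.array_equal(a.rts, b.rts, equal_nan=True)
        assert np.array_equal(a.winners, b.winners)

    def test_rt_distribution_invariant_across_seed_blocks(self, arbitrary_easy):
        a = simulate_condition(arbitrary_easy, 1500, seed=101, keep_traces=False)
        b = simulate_condition(arbitrary_easy, 1500, seed=201, keep_traces=False)
        ks = stats.ks_2samp(a.rts[np.isfinite(a.rts)], b.rts[np.isfinite(b.rts)])
        assert ks.pvalue > 0.01

    def test_traces_consistent_with_rt(self, deliberate_easy):
        sim = simulate_condition(deliberate_easy, 20, seed=2, keep_traces=True)
        for i in range(20):
            ci = sim.crossing_indices[i]
            assert ci >= 0
            assert sim.rts[i] == pytest.approx(ci * deliberate_easy.congruent.dt)
            assert len(sim.sma_traces[i][0]) == ci + 1


def test_parameter_table_roundtrip(tmp_path):
    conds = [best_fit_condition(d, e) for d, e in ddm_core.CONDITIONS]
    path = tmp_path / "params.csv"
    save_parameter_table(conds, path)
    loaded = load_parameter_table(path)
    assert [c.congruent.drift for c in loaded] == [c.congruent.drift for c in conds]
    assert parameter_table(loaded).equals(parameter_table(conds))


def test_load_parameter_table_missing_columns(tmp_path):
    path = tmp_path / "bad.csv"
    path.write_text("decision_type,difficulty\ndeliberate,easy\n")
    with pytest.raises(ValueError, match="missing columns"):
        load_parameter_table(path)
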