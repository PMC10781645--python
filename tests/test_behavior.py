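import numpy as np
import pytest

from ultraseq.behavior import (LAP_LENGTH_CM, bouts_from_state,
                               coactivity_and_synchrony, count_laps,
                               derive_speed, immobility_sequence_fraction,
                               onset_speed_analysis,
                               sequence_probability_by_state)
from ultraseq.sequences import SequenceSet
from ultraseq.session import BehaviorTrace, EventMatrix


def _trace(speed_cm_s, duration_s=60.0, rate=40.0):
    n = int(duration_s * rate)
    position = np.cumsum(np.full(n, speed_cm_s / rate))
    return BehaviorTrace(position=position, native_rate=rate)


class TestDeriveSpeed:
    def test_constant_position_is_one_immobility_bout(self):
        beh = BehaviorTrace(position=np.full(2400, 5.0), native_rate=40.0)
        out = derive_speed(beh, bin_size=0.129, n_bins=465)
        assert np.all(out.speed == 0)
        bouts = bouts_from_state(out.state)
        assert len(bouts) == 1 and not bouts[0][2]

    def test_constant_running_speed_recovered(self):
        out = derive_speed(_trace(10.0), bin_size=0.129, n_bins=465)
        interior = out.speed[50:-50]
        np.testing.assert_allclose(interior, 10.0, rtol=1e-6)
        assert np.all(out.state[50:-50])

    def test_subthreshold_speed_zeroed(self):
        out = derive_speed(_trace(1.0), bin_size=0.129, n_bins=465)
        assert np.all(out.speed == 0)
        assert not out.state.any()

    def test_bout_boundaries_recovered(self):
        rate, bin_size = 40.0, 0.129
        speed = np.concatenate([np.zeros(int(20 * rate)),
                                np.full(int(30 * rate), 8.0),
                                np.zeros(int(20 * rate))])
        position = np.cumsum(speed / rate)
        beh = BehaviorTrace(position=position, native_rate=rate)
        n_bins = int(70 / bin_size)
        out = derive_speed(beh, bin_size=bin_size, n_bins=n_bins)
        bouts = bouts_from_state(out.state)
        run = [b for b in bouts if b[2]]
        assert len(run) == 1
        start_s = run[0][0] * bin_size
        end_s = run[0][1] * bin_size
        assert start_s == pytest.approx(20.0, abs=1.5)
        assert end_s == pytest.approx(50.0, abs=1.5)


class TestLaps:
    def test_perimeter_distance_is_one_lap(self):
        beh = _trace(53.66 / 10.0, duration_s=10.0)
        assert count_laps(beh, (0.0, 10.0)) == pytest.approx(1.0, abs=0.01)

    def test_zero_distance(self):
        beh = BehaviorTrace(position=np.zeros(400), native_rate=40.0)
        assert count_laps(beh, (0.0, 10.0)) == 0.0

    def test_ten_laps(self):
        beh = _trace(53.7, duration_s=10.0)
        assert count_laps(beh, (0.0, 10.0)) == pytest.approx(10.0, abs=0.05)

    def test_lap_length_constant(self):
        assert LAP_LENGTH_CM == pytest.approx(53.66, abs=0.01)


class TestSequenceStateConditioning:
    def test_full_coverage_gives_unit_probabilities(self):
        seqs = SequenceSet(intervals=[(0, 100)], partial_segments=[],
                           bin_size=0.129, n_bins=100)
        state = np.zeros(100, dtype=bool)
        state[:50] = True
        res = sequence_probability_by_state(seqs, state)
        assert res["p_osc_given_running"] == 1.0
        assert res["p_osc_given_immobile"] == 1.0

    def test_running_only_sequences(self):
        seqs = SequenceSet(intervals=[(0, 50)], partial_segments=[],
                           bin_size=0.129, n_bins=100)
        state = np.zeros(100, dtype=bool)
        state[:50] = True
        res = sequence_probability_by_state(seqs, state)
        assert res["p_osc_given_running"] == 1.0
        assert res["p_osc_given_immobile"] == 0.0

    def test_coupling_recovered_from_generated_session(self, clean_run):
        session = clean_run["session"]
        truth = clean_run["truth"]
        seqs = clean_run["seqs"]
        state = derive_speed(session.behavior, session.bin_size,
                             session.events.n_bins).state
        rec = sequence_probability_by_state(seqs, state)
        true_mask = np.zeros(session.events.n_bins, dtype=bool)
        for a, b in truth.sequence_intervals:
            true_mask[a:b] = True
        ref_run = true_mask[state].mean()
        ref_imm = true_mask[~state].mean()
        assert rec["p_osc_given_running"] == pytest.approx(ref_run, abs=0.05)
        assert rec["p_osc_given_immobile"] == pytest.approx(ref_imm, abs=0.05)


class TestImmobilityCoverage:
    def test_full_session_sequences_cover_everything(self, rng):
        n = 4000
        seqs = SequenceSet(intervals=[(0, n)], partial_segments=[],
                           bin_size=0.129, n_bins=n)
        state = rng.random(n) < 0.5
        res = immobility_sequence_fraction(state, seqs, 0.129,
                                           n_shuffles=20, rng=rng)
        occupied = ~np.isnan(res["observed"])
        assert np.all(res["observed"][occupied] == 1.0)

    def test_no_sequences_give_zero(self, rng):
        n = 4000
        seqs = SequenceSet(intervals=[], partial_segments=[],
                           bin_size=0.129, n_bins=n)
        state = rng.random(n) < 0.5
        res = immobility_sequence_fraction(state, seqs, 0.129,
                                           n_shuffles=20, rng=rng)
        occupied = ~np.isnan(res["observed"])
        assert np.all(res["observed"][occupied] == 0.0)


class TestOnsets:
    def test_constant_speed_pre_equals_post(self):
        n = 4000
        seqs = SequenceSet(intervals=[(1000, 1900), (1900, 2800)],
                           partial_segments=[], bin_size=0.129, n_bins=n)
        speed = np.full(n, 7.0)
        state = np.ones(n, dtype=bool)
        res = onset_speed_analysis(seqs, speed, state, 0.129)
        np.testing.assert_allclose(res["pre_speeds"], res["post_speeds"])

    def test_running_only_onsets(self):
        n = 8000
        seqs = SequenceSet(intervals=[(1000, 1800), (4000, 4800)],
                           partial_segments=[], bin_size=0.129, n_bins=n)
        state = np.zeros(n, dtype=bool)
        state[500:2500] = True
        state[3500:5500] = True
        speed = np.where(state, 8.0, 0.0)
        res = onset_speed_analysis(seqs, speed, state, 0.129)
        assert res["onsets_in_immobility_bouts"] == 0
        assert res["onsets_in_running_bouts"] == 2

    def test_two_second_window_keeps_equality(self):
        n = 4000
        seqs = SequenceSet(intervals=[(1000, 1900)], partial_segments=[],
                           bin_size=0.129, n_bins=n)
        speed = np.full(n, 7.0)
        res = onset_speed_analysis(seqs, speed, np.ones(n, bool), 0.129,
                                   window_s=2.0)
        np.testing.assert_allclose(res["pre_speeds"], res["post_speeds"])


class TestCoactivitySynchrony:
    def test_identical_cells_fully_synchronous(self, rng):
        row = (rng.random(500) < 0.2).astype(int)
        events = EventMatrix(np.vstack([row, row]), 0.129)
        res = coactivity_and_synchrony(events)
        assert res["synchrony"][0] == pytest.approx(1.0)

    def test_all_cells_active_in_one_bin(self):
        values = np.zeros((5, 50), dtype=int)
        values[:, 10] = 1
        res = coactivity_and_synchrony(EventMatrix(values, 0.129))
        assert res["coactivity"][10] == 1.0
        assert res["coactivity"].max() == 1.0

    def test_independent_cells_mean_coactivity(self, rng):
        p = 0.1
        values = (rng.random((40, 20000)) < p).astype(int)
        res = coactivity_and_synchrony(EventMatrix(values, 0.129))
        assert res["coactivity"].mean() == pytest.approx(p, rel=0.05)
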