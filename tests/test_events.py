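"""Event extraction: lifts, first passages, upcrossings, intervals."""

import numpy as np
import pytest

import mrtphase as mp
from mrtphase.events import FirstPassageAccumulator


class TestFirstPassage:
    def test_monotone_lift_counts_levels(self):
        t = np.linspace(0, 10, 1001)
        lift = 4 * np.pi * t / 10
        train = mp.first_passage_events(t, lift)
        assert len(train) == 2
        assert np.allclose(train.times, [5.0, 10.0], atol=1e-9)

    def test_recrossings_do_not_create_events(self):
        # rises through 2*pi, dips below, rises again: exactly one event
        t = np.arange(7, dtype=float)
        lift = np.array([0.0, 4.0, 7.0, 5.0, 6.0, 7.0, 8.0])
        train = mp.first_passage_events(t, lift)
        assert len(train) == 1
        frac = (2 * np.pi - 4.0) / 3.0
        assert train.times[0] == pytest.approx(1 + frac)

    def test_empty_train_allowed(self):
        t = np.linspace(0, 1, 11)
        train = mp.first_passage_events(t, 0.1 * t)
        assert len(train) == 0

    def test_streaming_matches_single_pass(self):
        rng = np.random.default_rng(3)
        t = np.arange(20000) * 0.01
        lift = np.cumsum(rng.normal(0.01, 0.05, t.size))
        one = mp.first_passage_events(t, lift)
        acc = FirstPassageAccumulator()
        for k in range(0, t.size, 1700):
            acc.update(t[k:k + 1700], lift[k:k + 1700])
        assert np.allclose(acc.train().times, one.times, rtol=1e-12)


class TestLiftPhase:
    def test_uniform_rotation_lift_is_linear(self, gsp_spec):
        traj = mp.simulate_gsp(mp.GSPSpec(sigma=0.0), 5.0, 1e-3, seed=0)
        curve = mp.make_counting_curve("spoke")
        lift = mp.lift_phase(traj, curve)
        assert np.allclose(lift, traj.phi_lift)

    def test_wrapped_increment_unwraps_upward(self, alif_spec, alif_cycle):
        # nearest-integer unwrapping: 6.2 -> 0.1 is +0.183, not -6.1
        theta = np.array([6.2, 0.1])
        lift = np.unwrap(theta)
        assert lift[1] - lift[0] == pytest.approx(0.1 + 2 * np.pi - 6.2)

    def test_too_coarse_sampling_raises(self):
        # per-step increments above pi cannot be unwrapped unambiguously
        traj = mp.GSPTrajectory(dt=1.0, t0=0.0, rho=np.ones(4),
                                phi_lift=np.array([0.0, 4.0, 8.0, 12.0]),
                                seed=0)
        with pytest.raises(ValueError, match="too coarse"):
            mp.lift_phase(traj, mp.make_counting_curve("spoke"))


class TestThresholdUpcrossings:
    def test_sine_upcrossings_only(self):
        t = np.linspace(0, 4 * np.pi, 40001)
        train = mp.threshold_upcrossings(t, np.sin(t), 0.0)
        # upcrossings at 0 (excluded: no sample below first) and 2*pi
        assert len(train) == 1
        assert train.times[0] == pytest.approx(2 * np.pi, abs=1e-3)

    def test_subthreshold_series_gives_empty_train(self):
        t = np.linspace(0, 1, 101)
        assert len(mp.threshold_upcrossings(t, np.full(101, -1.0), 0.0)) == 0


class TestIntervals:
    def test_successive_differences(self):
        train = mp.EventTrain(np.array([1.0, 2.0, 4.0]), "x", 0.0, 5.0)
        seq = mp.to_intervals(train)
        assert np.array_equal(seq.intervals, [1.0, 2.0])

    def test_n_events_give_n_minus_one_intervals(self):
        times = np.cumsum(np.abs(np.random.default_rng(0).normal(1, .1, 50)))
        train = mp.EventTrain(times, "x", 0.0, times[-1] + 1)
        assert len(mp.to_intervals(train)) == 49

    def test_single_event_rejected(self):
        train = mp.EventTrain(np.array([1.0]), "x", 0.0, 2.0)
        with pytest.raises(ValueError):
            mp.to_intervals(train)

    def test_alif_threshold_events_are_the_recorded_resets(self, alif_spec):
        traj = mp.simulate_alif(alif_spec, 30.0, 1e-4, seed=5)
        curve = mp.make_counting_curve("alif_threshold")
        train = mp.events_from_trajectory(traj, curve)
        assert np.array_equal(train.times, traj.spike_times)

    def test_interval_csv_round_trip(self, tmp_path):
        seq = mp.IntervalSequence(np.array([0.5, 1.25, 2.0]), label="IPI")
        path = tmp_path / "iv.csv"
        from mrtphase.events import intervals_to_csv, intervals_from_csv
        intervals_to_csv(seq, path)
        back = intervals_from_csv(path)
        assert back.label == "IPI"
        assert np.allclose(back.intervals, seq.intervals, rtol=1e-16)
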