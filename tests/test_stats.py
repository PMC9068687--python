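"""Interval statistics: SCC estimator, Fano factor, renewal checks, tests."""

import numpy as np
import pytest

import mrtphase as mp
from mrtphase.events import EventTrain, IntervalSequence


def brute_force_scc(x, k):
    """Independent oracle: the defining double-loop covariance ratio."""
    xbar = sum(x) / len(x)
    num = sum((x[i] - xbar) * (x[i + k] - xbar) for i in range(len(x) - k))
    den = sum((xi - xbar) ** 2 for xi in x)
    return num / den


class TestSCC:
    def test_lag_zero_is_exactly_one(self):
        x = np.random.default_rng(0).gamma(2, 1, 500)
        assert mp.scc(IntervalSequence(x), 3).rho[0] == 1.0

    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(7)
        for n in (30, 257, 1000):
            x = rng.lognormal(0, 0.5, n)
            est = mp.scc(IntervalSequence(x), 5)
            for k in range(1, 6):
                assert est.rho[k] == pytest.approx(
                    brute_force_scc(list(x), k), abs=1e-12)

    def test_alternating_sequence_is_anticorrelated(self):
        n = 10000
        x = np.tile([1.0, 2.0], n // 2)
        est = mp.scc(IntervalSequence(x), 1)
        assert est.rho[1] == pytest.approx(-(n - 1) / n, abs=1e-12)

    def test_iid_sample_within_null_band(self):
        x = np.random.default_rng(12).random(100_000)
        est = mp.scc(IntervalSequence(x), 5)
        assert np.all(np.abs(est.rho[1:]) < 3 / np.sqrt(x.size))

    def test_degenerate_sequence_rejected(self):
        with pytest.raises(ValueError, match="zero variance"):
            mp.scc(IntervalSequence(np.ones(100)), 2)


class TestSummary:
    def test_constant_sequence_has_zero_cv(self):
        s = mp.interval_summary(IntervalSequence(np.full(50, 2.5)))
        assert s.cv == 0.0 and s.rate * s.mean == pytest.approx(1.0)

    def test_exponential_cv_is_one(self):
        x = np.random.default_rng(3).exponential(2.0, 100_000)
        s = mp.interval_summary(IntervalSequence(x))
        assert s.cv == pytest.approx(1.0, abs=0.02)


class TestFano:
    @staticmethod
    def _renewal_train(intervals):
        times = np.cumsum(intervals)
        return EventTrain(times, "renewal", 0.0, float(times[-1]))

    def test_poisson_fano_is_one(self):
        x = np.random.default_rng(5).exponential(1.0, 200_000)
        fc = mp.fano_curve(self._renewal_train(x), [1, 5, 20, 100, 500])
        assert np.allclose(fc.fano, 1.0, atol=0.15)

    def test_renewal_asymptote_is_cv_squared(self):
        rng = np.random.default_rng(6)
        x = rng.gamma(4.0, 0.25, 200_000)  # CV^2 = 1/4
        fc = mp.fano_curve(self._renewal_train(x), [50, 200, 1000])
        assert fc.asymptote == pytest.approx(0.25, abs=0.05)

    def test_short_train_rejected(self):
        x = np.ones(50)
        with pytest.raises(ValueError, match="too short"):
            mp.fano_curve(self._renewal_train(x), [10.0])

    def test_alif_negative_correlations_reduce_fano_asymptote(self):
        # spike-triggered adaptation: F(inf) < CV^2 for the threshold train
        rep = mp.run_alif(mp.ALIFSpec(), 2000, 1e-4, seed=31,
                          curves=("alif_threshold",))
        train = rep["trains"]["alif_threshold"]
        summ = rep["summary"]["alif_threshold"]
        windows = summ.mean * np.array([5, 10, 20, 50])
        fc = mp.fano_curve(train, windows)
        assert fc.asymptote < summ.cv**2

    def test_markov_renewal_train_matches_conservation_formula(self):
        # lane-chain train: F(inf) = CV^2 (1 + 2 sum rho_k), computed exactly
        chain = mp.LaneRenewalChain(
            mu=np.array([1.0, 2.0]), s2=np.array([0.05, 0.1]),
            Q=np.array([[0.9, 0.1], [0.2, 0.8]]))
        seq = mp.simulate_chain(chain, 300_000, seed=8)
        mean, var, _, _ = mp.exact_interval_moments(chain, 1)
        expected = var / mean**2 * (1 + 2 * mp.exact_scc(chain, 60).sum())
        fc = mp.fano_curve(self._renewal_train(seq.intervals),
                           np.array([200, 500, 1000]) * mean)
        assert fc.asymptote == pytest.approx(expected, rel=0.15)


class TestRenewalRelation:
    def test_renewal_pair_has_zero_residual(self):
        rng = np.random.default_rng(9)
        isi = IntervalSequence(rng.gamma(3, 1, 20_000), "ISI")
        ipi = IntervalSequence(rng.gamma(3, 1, 20_000), "IPI")
        rep = mp.renewal_relation_check(isi, ipi, k_max=10, seed=1)
        assert abs(rep.residual) < 3 * rep.se
        assert rep.lhs == pytest.approx(1 / 3, abs=0.05)


class TestShuffleNull:
    def test_iid_input_is_within_null(self):
        x = np.random.default_rng(10).gamma(2, 1, 5000)
        res = mp.shuffle_null(IntervalSequence(x), n_perm=300, seed=2)
        assert abs(res.z) < 3

    def test_alternating_input_is_far_outside_null(self):
        x = np.tile([1.0, 2.0], 1000) + \
            np.random.default_rng(1).normal(0, 0.01, 2000)
        res = mp.shuffle_null(IntervalSequence(x), n_perm=300, seed=2)
        assert res.z < -10

    def test_short_sequence_rejected(self):
        with pytest.raises(ValueError):
            mp.shuffle_null(IntervalSequence(np.ones(50) + 0.1), n_perm=300)


class TestEnsembleMeanTest:
    def test_zero_mean_sample_accepts(self):
        x = np.random.default_rng(4).normal(0, 1, 400)
        *_, p, decision = mp.ensemble_mean_test(x)
        assert decision == "accept" and p > 0.05

    def test_shifted_sample_rejects(self):
        rng = np.random.default_rng(4)
        x = rng.normal(0, 1, 400)
        x = x + 5 * x.std(ddof=1) / np.sqrt(x.size)
        *_, decision = mp.ensemble_mean_test(x)
        assert decision == "reject"
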