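"""Simulator-level checks: drift fields, resets, reflection, conservation."""

import numpy as np
import pytest
from scipy import stats as sps

import mrtphase as mp
from mrtphase._kernels import _reflect

from conftest import classical_hh_euler


class TestGSPFields:
    @pytest.mark.parametrize("rho, kw, expect_g, expect_f", [
        # on the inner limit cycle the deterministic radial drift vanishes
        (1.0, dict(sigma=0.37), 0.37**2 / 2, None),
        # angular speed: slower on the inner cycle, faster on the outer
        (1.0, dict(sigma=0.37, omega=2.0, gamma=1.0), None, 1.0),
        (3.0, dict(sigma=0.37, omega=2.0, gamma=1.0), None, 3.0),
        (2.0, dict(sigma=0.37, omega=2.0, gamma=1.0), None, 3.0),
    ])
    def test_field_values(self, rho, kw, expect_g, expect_f):
        g, f = mp.gsp_fields(rho, mp.GSPSpec(**kw))
        if expect_g is not None:
            assert g == pytest.approx(expect_g, rel=1e-12)
        if expect_f is not None:
            assert f == pytest.approx(expect_f, rel=1e-12)

    def test_nonpositive_radius_rejected(self):
        with pytest.raises(ValueError):
            mp.gsp_fields(-0.1, mp.GSPSpec())

    def test_spec_invariants(self):
        with pytest.raises(ValueError):
            mp.GSPSpec(c=3.5)
        with pytest.raises(ValueError):
            mp.GSPSpec(rho_minus=1.2)


class TestGSPSimulation:
    def test_deterministic_limit_cycle(self):
        # sigma = 0, start on the cycle: rho stays put, phi advances at f(1)
        spec = mp.GSPSpec(sigma=0.0)
        traj = mp.simulate_gsp(spec, 2.0, 1e-3, seed=0, rho0=1.0)
        assert np.allclose(traj.rho, 1.0, atol=1e-12)
        _, f1 = mp.gsp_fields(1.0, spec)
        assert np.allclose(traj.phi_lift, f1 * traj.t, rtol=1e-10)

    def test_reflection_confines_radius(self, gsp_spec):
        traj = mp.simulate_gsp(gsp_spec, 50.0, 1e-4, seed=4)
        assert traj.rho.min() >= gsp_spec.rho_minus
        assert traj.rho.max() <= gsp_spec.rho_plus

    def test_reflected_brownian_motion_is_uniform(self):
        # mirror reflection must preserve the flat stationary density of
        # driftless Brownian motion on an interval (chi^2 at the 1% level);
        # thinning by 100 steps decorrelates the samples (mixing time of a
        # step-0.25 walk on the unit interval is ~16 steps)
        rng = np.random.default_rng(11)
        x = 0.3
        xs = np.empty(400_000)
        for i, xi in enumerate(rng.standard_normal(xs.size)):
            x = _reflect(x + 0.25 * xi, 0.0, 1.0)
            xs[i] = x
        counts, _ = np.histogram(xs[200::100], bins=10, range=(0, 1))
        assert sps.chisquare(counts).pvalue > 0.01

    def test_bit_reproducibility(self, gsp_spec):
        a = mp.simulate_gsp(gsp_spec, 1.0, 1e-4, seed=9)
        b = mp.simulate_gsp(gsp_spec, 1.0, 1e-4, seed=9)
        assert np.array_equal(a.rho, b.rho)
        assert np.array_equal(a.phi_lift, b.phi_lift)

    def test_coarse_step_rejected(self, gsp_spec):
        with pytest.raises(ValueError):
            mp.simulate_gsp(gsp_spec, 10.0, 5.0, seed=0)


class TestALIF:
    def test_no_adaptation_isi_is_log_two(self):
        # D = 0, delta_a = 0, mu = 2: v' = 2 - v from 0 to 1 takes ln 2
        spec = mp.ALIFSpec(D=0.0, delta_a=0.0)
        traj = mp.simulate_alif(spec, 10.0, 1e-4, seed=0)
        isis = np.diff(traj.spike_times)
        assert np.allclose(isis, np.log(2), atol=2e-4)

    def test_deterministic_period_matches_limit_cycle(self, alif_spec,
                                                      alif_cycle):
        spec = mp.ALIFSpec(D=0.0)
        traj = mp.simulate_alif(spec, 60.0, 1e-4, seed=0)
        isis = np.diff(traj.spike_times)
        assert isis[-1] == pytest.approx(alif_cycle.period, abs=1e-4)

    def test_adaptation_map_contracts_geometrically(self, alif_spec,
                                                    alif_cycle):
        # the post-spike adaptation map is a contraction with ratio
        # exp(-T*/tau_a): reconstruct a+ along the simulated spike train
        spec = mp.ALIFSpec(D=0.0)
        traj = mp.simulate_alif(spec, 80.0, 1e-4, seed=0, a0=2.5)
        a = 2.5
        err = []
        for isi in np.diff(traj.spike_times)[:10]:
            err.append(abs(a - alif_cycle.extras["a_plus"]))
            a = a * np.exp(-isi / spec.tau_a) + spec.delta_a
        err = np.array(err)
        ratios = err[1:] / err[:-1]
        expected = np.exp(-alif_cycle.period / spec.tau_a)
        assert np.allclose(ratios, expected, atol=0.02)

    def test_voltage_never_exceeds_threshold(self, alif_spec):
        traj = mp.simulate_alif(alif_spec, 50.0, 1e-4, seed=3)
        assert traj.v.max() <= alif_spec.v_T

    def test_spike_times_strictly_increasing(self, alif_spec):
        traj = mp.simulate_alif(alif_spec, 50.0, 1e-4, seed=3)
        assert np.all(np.diff(traj.spike_times) > 0)

    def test_mean_driven_required(self):
        with pytest.raises(ValueError):
            mp.ALIFSpec(mu=0.5)


class TestHH:
    def test_generator_and_noise_columns_sum_to_zero(self, hh_spec):
        for V in (-80.0, -40.0, 0.0, 40.0):
            A_Na, A_K, S_Na, S_K = mp.hh_build_matrices(V, hh_spec)
            for mat in (A_Na, A_K, S_Na, S_K):
                assert np.abs(mat.sum(axis=0)).max() < 1e-12
        assert S_Na.shape == (8, 20) and S_K.shape == (5, 8)

    def test_binomial_state_is_stationary_under_clamp(self, hh_spec):
        for V in (-65.0, -30.0, 10.0):
            M, N = mp.hh_binomial_state(*mp.hh_gate_equilibrium(V))
            A_Na, A_K, _, _ = mp.hh_build_matrices(V, hh_spec, M, N)
            assert np.abs(A_Na @ M).max() < 1e-12
            assert np.abs(A_K @ N).max() < 1e-12

    def test_channel_fraction_sums_conserved(self, hh_spec):
        traj = mp.simulate_hh(hh_spec, 100.0, seed=5)
        assert np.abs(traj.M.sum(axis=1) - 1).max() < 1e-10
        assert np.abs(traj.N.sum(axis=1) - 1).max() < 1e-10
        assert traj.M.min() >= 0 and traj.M.max() <= 1
        assert traj.N.min() >= 0 and traj.N.max() <= 1

    def test_deterministic_run_tracks_classical_hh(self, hh_spec):
        # short version of the binomial-manifold invariance check
        dt = 2e-4
        V0 = -65.0
        m, h, n = mp.hh_gate_equilibrium(V0)
        traj = mp.simulate_hh_deterministic(hh_spec, 40.0, dt,
                                            *mp.hh_rest_state(hh_spec, V0))
        V_ref = classical_hh_euler(hh_spec, V0, m, h, n, 40.0, dt)
        assert np.abs(traj.V - V_ref).max() < 0.5

    def test_deterministic_upcrossing_count_matches_period(self, hh_spec,
                                                           hh_cycle):
        duration = 120.0
        traj = mp.simulate_hh_deterministic(hh_spec, duration)
        train = mp.threshold_upcrossings(traj.t, traj.V, hh_spec.V_th)
        expect = duration / hh_cycle.period
        assert abs(len(train) - expect) <= 1.5

    def test_bit_reproducibility(self, hh_spec):
        a = mp.simulate_hh(hh_spec, 5.0, seed=21)
        b = mp.simulate_hh(hh_spec, 5.0, seed=21)
        assert np.array_equal(a.V, b.V)
        assert np.array_equal(a.M, b.M)


class TestSpecIO:
    @pytest.mark.parametrize("ext", ["yaml", "json"])
    def test_spec_round_trip(self, tmp_path, ext):
        spec = mp.ALIFSpec(mu=2.5, D=0.05)
        path = tmp_path / f"spec.{ext}"
        mp.save_spec(spec, path)
        assert mp.load_spec(path) == spec

    def test_trajectory_csv(self, tmp_path, gsp_spec):
        traj = mp.simulate_gsp(gsp_spec, 0.01, 1e-3, seed=0)
        path = tmp_path / "traj.csv"
        mp.trajectory_to_csv(traj, path)
        data = np.loadtxt(path, delimiter=",", skiprows=1)
        assert np.allclose(data[:, 1], traj.rho, rtol=1e-15)

    def test_trajectory_npz(self, tmp_path, alif_spec):
        from mrtphase.models import trajectory_to_npz
        traj = mp.simulate_alif(alif_spec, 1.0, 1e-3, seed=0)
        path = tmp_path / "traj.npz"
        trajectory_to_npz(traj, path)
        data = np.load(path)
        assert np.array_equal(data["v"], traj.v)
        assert data["dt"] == traj.dt
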