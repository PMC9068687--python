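"""Isochron, phase and counting-curve checks."""

import numpy as np
import pytest

import mrtphase as mp
from mrtphase.isochrons import TWO_PI


class TestGSPMeanFrequency:
    def test_constant_angular_speed_factorizes(self, gsp_spec):
        # with f == omega0 the weighted mean is omega0 exactly
        wb = mp.gsp_mean_frequency(gsp_spec, f_override=lambda r: 1.7 + 0 * r)
        assert wb == pytest.approx(1.7, rel=1e-9)

    def test_weighted_mean_bounds(self, gsp_spec):
        wb = mp.gsp_mean_frequency(gsp_spec)
        rho = np.linspace(gsp_spec.rho_minus, gsp_spec.rho_plus, 1001)
        _, f = mp.gsp_fields(rho, gsp_spec)
        assert f.min() <= wb <= f.max()

    def test_deterministic_spec_rejected(self):
        with pytest.raises(ValueError):
            mp.gsp_mean_frequency(mp.GSPSpec(sigma=0.0))


class TestGSPIsochron:
    def test_zero_at_inner_boundary(self, gsp_spec):
        iso = mp.gsp_isochron(gsp_spec)
        assert iso.phi_of_rho[0] == 0.0
        assert np.all(np.isfinite(iso.phi_of_rho))

    def test_spoke_is_isochron_when_speed_is_uniform(self, gsp_spec):
        # f == omega_bar makes the integrand vanish: phi_I == 0 (a spoke)
        wb = mp.gsp_mean_frequency(gsp_spec)
        iso = mp.gsp_isochron(gsp_spec, wb, f_override=lambda r: wb + 0 * r)
        assert np.abs(iso.phi_of_rho).max() < 1e-8

    def test_deterministic_spec_rejected(self, gsp_spec):
        with pytest.raises(ValueError):
            mp.gsp_isochron(mp.GSPSpec(sigma=0.0))

    def test_mean_period_consistent_with_simulation(self, gsp_spec):
        # IPIs are uncorrelated, so the plain standard error applies
        iso = mp.gsp_isochron(gsp_spec)
        rep = mp.run_gsp(gsp_spec, 400, 1e-4, seed=17,
                         curves=("gsp_isochron",))
        s = rep["summary"]["gsp_isochron"]
        se = s.cv * s.mean / np.sqrt(s.n)
        assert abs(s.mean - iso.mean_period) < 3 * se


class TestALIFCycleAndPhase:
    def test_trivial_cycle_without_adaptation(self):
        cyc = mp.alif_limit_cycle(mp.ALIFSpec(delta_a=0.0, D=0.0))
        assert cyc.period == pytest.approx(np.log(2), rel=1e-12)
        assert cyc.extras["a_plus"] == 0.0

    def test_anchor_has_phase_zero(self, alif_spec, alif_cycle):
        th = mp.asymptotic_phase(alif_cycle.anchor, alif_spec, alif_cycle)
        assert min(th, TWO_PI - th) < 1e-5

    def test_uniform_phase_advance_on_cycle(self, alif_spec, alif_cycle):
        # phase advances at rate 2*pi/T* along the cycle
        n = alif_cycle.path.shape[0]
        for frac in (0.25, 0.5, 0.8):
            i = int(frac * n)
            th = mp.asymptotic_phase(alif_cycle.path[i], alif_spec,
                                     alif_cycle)
            assert th == pytest.approx(TWO_PI * i / n, abs=1e-4 * TWO_PI)

    def test_off_cycle_phase_converges(self, alif_spec, alif_cycle):
        loose = mp.asymptotic_phase((0.5, alif_cycle.extras["a_plus"] + 0.3),
                                    alif_spec, alif_cycle, tol=1e-3 * TWO_PI)
        tight = mp.asymptotic_phase((0.5, alif_cycle.extras["a_plus"] + 0.3),
                                    alif_spec, alif_cycle, tol=1e-8 * TWO_PI)
        assert abs(loose - tight) < 1e-3 * TWO_PI
        assert 0 <= tight < TWO_PI

    def test_mesh_interpolation_accuracy(self, alif_spec, alif_cycle,
                                         alif_mesh):
        rng = np.random.default_rng(1)
        v = rng.uniform(-1.5, 0.95, 60)
        a = rng.uniform(0.05, 3.0, 60)
        direct = np.array([mp.asymptotic_phase((vi, ai), alif_spec,
                                               alif_cycle)
                           for vi, ai in zip(v, a)])
        err = np.angle(np.exp(1j * (alif_mesh.phase(v, a) - direct)))
        assert np.abs(err).max() < 1e-3 * TWO_PI


class TestALIFIsochronBranches:
    def test_branch_passes_threshold_point_at_full_phase(self, alif_spec,
                                                         alif_mesh):
        # the 2*pi isochron meets the limit cycle exactly at the threshold
        branches = mp.alif_isochron_branches(alif_spec, TWO_PI - 1e-9,
                                             mesh=alif_mesh)
        pT = np.array([alif_spec.v_T, alif_mesh.cycle.extras["a_threshold"]])
        dmin = min(np.hypot(b[:, 0] - pT[0], b[:, 1] - pT[1]).min()
                   for b in branches)
        assert dmin < 0.05

    def test_reset_pair_has_equal_phase(self, alif_spec, alif_cycle):
        # (v_T, a) with positive inflow and its reset image share the phase
        for a in np.linspace(0.1, 0.9, 10):
            th_T = mp.asymptotic_phase((alif_spec.v_T, a), alif_spec,
                                       alif_cycle)
            th_R = mp.asymptotic_phase((alif_spec.v_R, a + alif_spec.delta_a),
                                       alif_spec, alif_cycle)
            d = np.angle(np.exp(1j * (th_T - th_R)))
            assert abs(d) < 1e-5

    def test_branch_points_have_the_requested_phase(self, alif_spec,
                                                    alif_cycle, alif_mesh):
        theta0 = np.pi / 2
        branches = mp.alif_isochron_branches(alif_spec, theta0,
                                             mesh=alif_mesh)
        assert branches
        pts = np.vstack(branches)[::25]
        direct = np.array([mp.asymptotic_phase(p, alif_spec, alif_cycle)
                           for p in pts])
        err = np.abs(np.angle(np.exp(1j * (direct - theta0))))
        assert np.median(err) < 1e-3 * TWO_PI
        assert np.quantile(err, 0.95) < 1e-2 * TWO_PI


class TestCountingCurves:
    def test_twist_limits_reduce_to_isochron_and_spoke(self, gsp_spec):
        iso = mp.gsp_isochron(gsp_spec)
        traj = mp.simulate_gsp(gsp_spec, 5.0, 1e-3, seed=2)
        spoke = mp.make_counting_curve("spoke")
        iso_curve = mp.make_counting_curve("gsp_isochron", context=iso)
        tw1 = mp.make_counting_curve("gsp_twisted", {"m": 1.0}, iso)
        tw0 = mp.make_counting_curve("gsp_twisted", {"m": 0.0}, iso)
        assert np.array_equal(tw1.lift(traj), iso_curve.lift(traj))
        assert np.array_equal(tw0.lift(traj), spoke.lift(traj))

    def test_horizontal_line_lift_is_continuous_at_spikes(self, alif_spec,
                                                          alif_cycle):
        traj = mp.simulate_alif(alif_spec, 60.0, 1e-4, seed=8)
        curve = mp.make_counting_curve(
            "alif_horizontal_lines", {"delta_a": alif_spec.delta_a},
            alif_cycle)
        lift = mp.lift_phase(traj, curve)
        # the spike_count jump cancels the adaptation kick: no 2*pi jumps
        assert np.abs(np.diff(lift)).max() < 0.1

    def test_unknown_kind_rejected(self):
        with pytest.raises(ValueError):
            mp.make_counting_curve("diagonal")

    def test_missing_context_rejected(self):
        with pytest.raises(ValueError):
            mp.make_counting_curve("gsp_isochron")

    def test_isochron_lift_continuous_across_reset(self, alif_spec,
                                                   alif_mesh):
        traj = mp.simulate_alif(alif_spec, 60.0, 1e-4, seed=8)
        curve = mp.make_counting_curve("alif_deterministic_isochron",
                                       context=alif_mesh)
        lift = mp.lift_phase(traj, curve)
        idx = np.searchsorted(traj.t, traj.spike_times)
        idx = idx[(idx > 0) & (idx < lift.size)]
        jumps = np.abs(lift[idx] - lift[idx - 1])
        # resets advance the lift only by the ordinary phase flow: no
        # 2*pi-scale jumps; jump sizes reflect the local phase gradient,
        # which is large only for near-grazing (v' ~ 0) crossings
        assert np.median(jumps) < 0.05
        assert jumps.max() < 2.0


class TestWindingInvariance:
    def test_event_counts_agree_across_curves(self, gsp_spec):
        # the winding number cannot depend on how rotations are counted
        rep = mp.run_gsp(gsp_spec, 300, 1e-4, seed=23)
        counts = {k: len(t) for k, t in rep["trains"].items()}
        vals = list(counts.values())
        # window counts can differ by the number of turns the counting curve
        # itself winds around the annulus (the twisted curve winds ~16 times)
        span = np.ptp(rep["isochron"].phi_of_rho)
        bound = int(np.ceil(5 * span / (2 * np.pi))) + 1
        assert max(vals) - min(vals) <= bound
        means = [rep["summary"][k].mean for k in counts]
        s = rep["summary"]["gsp_isochron"]
        se = s.cv * s.mean / np.sqrt(s.n)
        assert max(means) - min(means) < 3 * se
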