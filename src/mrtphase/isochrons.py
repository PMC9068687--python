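"""Isochrons, phases and counting curves.

For the GSP oscillator the mean-return-time (MRT) isochron has a closed
quadrature form: with g and f the radial drift and angular speed, the isochron
angle is

    phi_I(rho) = 2 * int_{rho-}^{rho} dq int_{rho-}^{q} du
                 (f(u) - omega_bar) / (sigma^2 u^2)
                 * exp(-2 * int_u^q dv g(v) / (sigma^2 v^2))

and the mean rotation frequency omega_bar is a ratio of two weighted radial
integrals.  Both are evaluated here with an exact antiderivative of
g(v)/(sigma^2 v^2) and running rescaling, so the exponential weight (which
spans many orders of magnitude) never overflows.

For the ALIF and HH neurons the stochastic MRT isochron is approximated by the
deterministic asymptotic-phase isochron of the noiseless system, which is
accurate for weak noise: the phase of a state is obtained by running the
noiseless flow forward and timing its K-th return to the anchor section
(threshold crossing), theta = 2*pi*(K - tau_K / T*) mod 2*pi.

A `CountingCurve` packages any of the counting rules (spoke, isochron,
twisted isochron, voltage threshold, horizontal adaptation lines, ...) as a
map from a trajectory to a continuous lifted rotation-progress series whose
2*pi level passages define the events.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np
from scipy.optimize import brentq

from . import _kernels
from .models import (GSPSpec, ALIFSpec, HHSpec, gsp_fields,
                     simulate_hh_deterministic, hh_rest_state)

TWO_PI = 2.0 * np.pi


# ---------------------------------------------------------------------------
# GSP: mean rotation frequency and MRT isochron (exact quadratures)
# ---------------------------------------------------------------------------


def _gsp_log_weight_antideriv(v: np.ndarray, spec: GSPSpec) -> np.ndarray:
    """H(v) with H'(v) = g(v)/(sigma^2 v^2), in closed form.

    g(v)/(sigma^2 v^2) = [ -v^2 + (c+4) v - (4c+3) + 3c/v ] / sigma^2 + 1/(2v).
    """
    c, s2 = spec.c, spec.sigma**2
    lv = np.log(v)
    return (-(v**3) / 3 + (c + 4) * v**2 / 2 - (4 * c + 3) * v
            + 3 * c * lv) / s2 + 0.5 * lv


def _gsp_f(rho: np.ndarray, spec: GSPSpec,
           f_override: Callable | None) -> np.ndarray:
    if f_override is not None:
        return np.asarray(f_override(rho), dtype=float)
    return gsp_fields(rho, spec)[1]


def gsp_mean_frequency(spec: GSPSpec, rel_tol: float = 1e-6,
                       f_override: Callable | None = None) -> float:
    """Mean rotation frequency omega_bar of the GSP oscillator.

    Ratio of the f-weighted to the unweighted integral of the stationary
    radial weight exp(2H(rho))/(sigma rho)^2 over [rho_minus, rho_plus],
    evaluated by trapezoid quadrature on doubling grids until the relative
    change is below `rel_tol`.  The weight is exponentiated after subtracting
    its maximum (log-space normalisation), so there is no overflow.
    """
    if spec.sigma <= 0:
        raise ValueError("mean-frequency quadrature requires sigma > 0")
    prev = None
    n = 4096
    while n <= 2**20:
        rho = np.linspace(spec.rho_minus, spec.rho_plus, n + 1)
        H = _gsp_log_weight_antideriv(rho, spec)
        logw = 2 * H - 2 * np.log(spec.sigma * rho)
        w = np.exp(logw - logw.max())
        f = _gsp_f(rho, spec, f_override)
        val = np.trapezoid(f * w, rho) / np.trapezoid(w, rho)
        if prev is not None and abs(val - prev) <= rel_tol * abs(val):
            return float(val)
        prev = val
        n *= 2
    raise RuntimeError("omega_bar quadrature did not converge")


@dataclass
class GSPIsochron:
    """The MRT isochron phi_I(rho) of the GSP oscillator on a radius grid."""

    rho_grid: np.ndarray
    phi_of_rho: np.ndarray
    omega_bar: float
    spec: GSPSpec

    @property
    def mean_period(self) -> float:
        return TWO_PI / self.omega_bar

    def phi(self, rho):
        """phi_I at arbitrary radii (linear interpolation on the grid)."""
        return np.interp(rho, self.rho_grid, self.phi_of_rho)


def _gsp_isochron_on_grid(spec: GSPSpec, omega_bar: float, n: int,
                          f_override: Callable | None) -> tuple[np.ndarray, np.ndarray]:
    rho = np.linspace(spec.rho_minus, spec.rho_plus, n + 1)
    dq = rho[1] - rho[0]
    H = _gsp_log_weight_antideriv(rho, spec)
    h = (_gsp_f(rho, spec, f_override) - omega_bar) / (spec.sigma**2 * rho**2)
    # inner integral D(q_j) = int_{rho-}^{q_j} h(u) exp(2(H(u)-H(q_j))) du,
    # evaluated by a rescaled running recurrence (no overflow)
    D = _kernels.scaled_exp_recurrence(H, h, dq)
    phi = np.concatenate(([0.0], np.cumsum(dq * (D[:-1] + D[1:]))))
    return rho, phi


def gsp_isochron(spec: GSPSpec, omega_bar: float | None = None,
                 rel_tol: float = 1e-6,
                 f_override: Callable | None = None) -> GSPIsochron:
    """MRT isochron phi_I on [rho_minus, rho_plus], grid-refinement converged.

    phi_I(rho_minus) = 0 by construction.  Requires sigma > 0 (the quadrature
    expression is for the stochastic system).
    """
    if spec.sigma <= 0:
        raise ValueError("the MRT isochron quadrature requires sigma > 0")
    if omega_bar is None:
        omega_bar = gsp_mean_frequency(spec, rel_tol=rel_tol,
                                       f_override=f_override)
    n = 4096
    rho_prev, phi_prev = _gsp_isochron_on_grid(spec, omega_bar, n, f_override)
    while n <= 2**17:
        n *= 2
        rho, phi = _gsp_isochron_on_grid(spec, omega_bar, n, f_override)
        scale = max(1.0, np.abs(phi).max())
        if np.abs(phi[::2] - phi_prev).max() <= rel_tol * scale:
            return GSPIsochron(rho_grid=rho, phi_of_rho=phi,
                               omega_bar=omega_bar, spec=spec)
        rho_prev, phi_prev = rho, phi
    raise RuntimeError("isochron quadrature did not converge")


def gsp_mrt_passage_times(spec: GSPSpec, iso: GSPIsochron, start_radii,
                          n_samples: int, dt: float, seed: int) -> dict:
    """Monte-Carlo first-passage times from isochron points to the 2pi copy.

    For each start radius r the oscillator is launched at (r, phi_I(r)) and
    run until the isochron lift phi - phi_I(rho) first reaches 2*pi.  Under
    the MRT defining property all conditional means equal the mean rotation
    period 2*pi/omega_bar, irrespective of r.
    """
    # dense uniform grid for O(1) interpolation inside the compiled loop
    ng = 8192
    rg = np.linspace(spec.rho_minus, spec.rho_plus, ng + 1)
    phiI = iso.phi(rg)
    drho = rg[1] - rg[0]
    max_steps = int(200 * iso.mean_period / dt)
    rng = np.random.default_rng(seed)
    out = {}
    for r in start_radii:
        seeds = rng.integers(0, 2**31 - 1, size=n_samples)
        times = np.empty(n_samples)
        phi0 = float(iso.phi(r))
        for i in range(n_samples):
            t = _kernels.gsp_passage_time(
                float(r), phi0, dt, spec.sigma, spec.omega, spec.gamma,
                spec.c, spec.rho_minus, spec.rho_plus, phiI, drho,
                TWO_PI, int(seeds[i]), max_steps)
            if t < 0:
                raise RuntimeError("first-passage run exceeded step budget")
            times[i] = t
        out[float(r)] = times
    return out


# ---------------------------------------------------------------------------
# Deterministic limit cycles
# ---------------------------------------------------------------------------


@dataclass
class LimitCycle:
    """A deterministic limit cycle sampled at uniform phase/time.

    `path` holds one cycle of states ((v, a) for ALIF; (V, M, N) flattened to
    14 columns for HH), `anchor` the state at which the phase is 0 == 2*pi
    (the post-reset point for ALIF, the V_th upcrossing for HH).
    """

    period: float
    path: np.ndarray
    anchor: np.ndarray
    model: str
    extras: dict = field(default_factory=dict)


def _alif_v(t, v0, a0, mu, tau_a):
    """Closed-form deterministic ALIF voltage (handles tau_a == 1)."""
    t = np.asarray(t, dtype=float)
    if tau_a == 1.0:
        return mu + (v0 - mu) * np.exp(-t) - a0 * t * np.exp(-t)
    kap = tau_a / (tau_a - 1.0)
    return (mu - a0 * kap * np.exp(-t / tau_a)
            + (v0 - mu + a0 * kap) * np.exp(-t))


def alif_limit_cycle(spec: ALIFSpec, n_path: int = 512) -> LimitCycle:
    """Deterministic (D = 0) limit cycle of the ALIF model.

    Solves the self-consistency of period and post-reset adaptation:
    a+ = delta_a / (1 - exp(-T*/tau_a)) and v(T*; v_R, a+) = v_T.
    """
    mu, ta, da = spec.mu, spec.tau_a, spec.delta_a
    vT, vR = spec.v_T, spec.v_R

    def a_plus(T):
        if da == 0.0:
            return 0.0
        return da / (1.0 - np.exp(-T / ta))

    def F(T):
        return float(_alif_v(T, vR, a_plus(T), mu, ta)) - vT

    # bracket the period by geometric scan; F < 0 for small T (a+ diverges)
    lo = 1e-6
    if F(lo) >= 0:
        raise RuntimeError("degenerate ALIF regime: immediate threshold hit")
    hi = 0.01
    while F(hi) < 0:
        hi *= 1.5
        if hi > 1e4:
            raise RuntimeError("no repetitive firing found (not mean-driven "
                               "once adaptation equilibrates)")
    T = brentq(F, lo, hi, xtol=1e-14, rtol=8.9e-16)
    ap = a_plus(T)
    ts = np.linspace(0.0, T, n_path, endpoint=False)
    v = _alif_v(ts, vR, ap, mu, ta)
    a = ap * np.exp(-ts / ta)
    path = np.column_stack([v, a])
    return LimitCycle(period=float(T), path=path,
                      anchor=np.array([vR, ap]), model="alif",
                      extras={"a_plus": float(ap),
                              "a_threshold": float(ap * np.exp(-T / ta))})


def hh_limit_cycle(spec: HHSpec, dt: float | None = None,
                   transient: float = 250.0, n_path: int = 512) -> LimitCycle:
    """Deterministic (epsilon = 0) limit cycle of the HH model.

    Integrates past the transient, measures the period between successive
    V_th upcrossings, and stores one cycle resampled to `n_path` points with
    the anchor (phase 0) at the V_th upcrossing.
    """
    if dt is None:
        dt = spec.dt
    warm = simulate_hh_deterministic(spec, transient, dt)
    V0, M0, N0 = warm.V[-1], warm.M[-1], warm.N[-1]
    tail = simulate_hh_deterministic(spec, 80.0, dt, V0=V0, M0=M0, N0=N0)
    up = np.flatnonzero((tail.V[:-1] < spec.V_th) & (tail.V[1:] >= spec.V_th))
    if up.size < 2:
        raise RuntimeError("model is not oscillating at epsilon = 0 "
                           "(no repetitive V_th upcrossings)")
    i0, i1 = up[-2] + 1, up[-1] + 1
    frac0 = (spec.V_th - tail.V[i0 - 1]) / (tail.V[i0] - tail.V[i0 - 1])
    frac1 = (spec.V_th - tail.V[i1 - 1]) / (tail.V[i1] - tail.V[i1 - 1])
    T = ((i1 + frac1) - (i0 + frac0)) * dt
    states = np.column_stack([tail.V[i0:i1], tail.M[i0:i1], tail.N[i0:i1]])
    # resample to n_path uniform-time points over one period
    idx = np.linspace(0, states.shape[0] - 1, n_path)
    lo = np.floor(idx).astype(int)
    hi = np.minimum(lo + 1, states.shape[0] - 1)
    w = (idx - lo)[:, None]
    path = (1 - w) * states[lo] + w * states[hi]
    return LimitCycle(period=float(T), path=path, anchor=path[0].copy(),
                      model="hh", extras={"dt": dt, "v_scale": 0.01})


# ---------------------------------------------------------------------------
# Asymptotic phase (weak-noise stand-in for the MRT phase)
# ---------------------------------------------------------------------------


def asymptotic_phase(state, spec, cycle: LimitCycle,
                     tol: float = 1e-6 * TWO_PI, k_max: int = 60) -> float:
    """Deterministic asymptotic phase of `state`, in [0, 2*pi).

    The noiseless flow is run forward from `state`; after the K-th anchor
    crossing at time tau_K the estimate is theta = 2*pi*(K - tau_K/T*) mod
    2*pi, iterated in K until two successive estimates differ by < tol.
    theta = 0 at the cycle anchor (post-reset point for ALIF, V_th upcrossing
    for HH, where the phase jumps 2*pi -> 0).
    """
    if isinstance(spec, ALIFSpec):
        if spec.tau_a == 1.0:
            raise NotImplementedError("phase evaluation requires tau_a != 1")
        v, a = float(state[0]), float(state[1])
        th = _kernels.alif_asymptotic_phase(
            v, a, spec.mu, spec.tau_a, spec.delta_a, spec.v_T, spec.v_R,
            cycle.period, tol, k_max)
        if np.isnan(th):
            raise RuntimeError("state outside the basin (no threshold "
                               "crossing within the scan budget)")
        return float(th)
    if isinstance(spec, HHSpec):
        state = np.asarray(state, dtype=float)
        return hh_asymptotic_phase(state[0], state[1:9], state[9:14],
                                   spec, cycle, tol=tol,
                                   n_cross=min(k_max, 6))
    raise TypeError(f"no phase evaluation for spec type {type(spec)!r}")


def hh_asymptotic_phase(V, M, N, spec: HHSpec, cycle: LimitCycle,
                        tol: float = 1e-3 * TWO_PI, n_cross: int = 3) -> float:
    """Asymptotic phase of an HH state from timed returns of the eps=0 flow."""
    dt = cycle.extras.get("dt", spec.dt)
    max_steps = int((n_cross + 2) * cycle.period / dt)
    times, found = _kernels.hh_det_crossings(
        float(V), np.asarray(M, float), np.asarray(N, float), dt,
        spec.C, spec.gbar_Na, spec.gbar_K, spec.g_L, spec.V_Na, spec.V_K,
        spec.V_L, spec.I_app, spec.V_th, n_cross, max_steps)
    if found == 0:
        raise RuntimeError("state outside the oscillating basin")
    thetas = [TWO_PI * (k + 1 - times[k] / cycle.period)
              for k in range(found)]
    th = thetas[-1]
    for k in range(1, found):
        if abs(thetas[k] - thetas[k - 1]) < tol:
            th = thetas[k]
            break
    return float(th % TWO_PI)


# ---------------------------------------------------------------------------
# ALIF phase mesh (tabulated asymptotic phase, bilinear interpolation)
# ---------------------------------------------------------------------------


@dataclass
class AlifPhaseMesh:
    """Asymptotic phase tabulated on a rectangular (v, a) mesh.

    Interpolation acts on (cos, sin) of the phase so that the 2*pi branch cut
    is invisible; out-of-range queries are clamped to the mesh edge.
    """

    v_grid: np.ndarray
    a_grid: np.ndarray
    theta: np.ndarray  # (nv, na)
    cycle: LimitCycle
    spec: ALIFSpec
    _cos: np.ndarray = field(init=False, repr=False)
    _sin: np.ndarray = field(init=False, repr=False)

    def __post_init__(self):
        self._cos = np.cos(self.theta)
        self._sin = np.sin(self.theta)

    def phase(self, v, a):
        """Interpolated phase in [0, 2*pi) at the query points."""
        v = np.clip(np.asarray(v, float), self.v_grid[0], self.v_grid[-1])
        a = np.clip(np.asarray(a, float), self.a_grid[0], self.a_grid[-1])
        dv = self.v_grid[1] - self.v_grid[0]
        da = self.a_grid[1] - self.a_grid[0]
        fi = (v - self.v_grid[0]) / dv
        fj = (a - self.a_grid[0]) / da
        i = np.clip(fi.astype(int), 0, self.v_grid.size - 2)
        j = np.clip(fj.astype(int), 0, self.a_grid.size - 2)
        wi = fi - i
        wj = fj - j

        def interp(F):
            return ((1 - wi) * (1 - wj) * F[i, j] + wi * (1 - wj) * F[i + 1, j]
                    + (1 - wi) * wj * F[i, j + 1] + wi * wj * F[i + 1, j + 1])

        th = np.arctan2(interp(self._sin), interp(self._cos))
        return np.where(th < 0, th + TWO_PI, th)


def alif_phase_mesh(spec: ALIFSpec, cycle: LimitCycle | None = None,
                    v_min: float = -2.0, a_max: float = 4.0,
                    n_v: int = 281, n_a: int = 281,
                    tol: float = 1e-6 * TWO_PI) -> AlifPhaseMesh:
    """Tabulate the deterministic asymptotic phase on a (v, a) mesh.

    The mesh spans [v_min, v_T] x [0, a_max]; resolution defaults keep the
    bilinear interpolation error well below 1e-3 * 2*pi for the standard
    parameter regime (checked by the test suite).
    """
    if spec.tau_a == 1.0:
        raise NotImplementedError("phase mesh requires tau_a != 1")
    if cycle is None:
        cycle = alif_limit_cycle(spec)
    v_grid = np.linspace(v_min, spec.v_T, n_v)
    a_grid = np.linspace(0.0, a_max, n_a)
    theta = _kernels.alif_phase_mesh_kernel(
        v_grid, a_grid, spec.mu, spec.tau_a, spec.delta_a, spec.v_T,
        spec.v_R, cycle.period, tol, 60)
    return AlifPhaseMesh(v_grid=v_grid, a_grid=a_grid, theta=theta,
                         cycle=cycle, spec=spec)


def alif_isochron_branches(spec: ALIFSpec, theta0: float,
                           mesh: AlifPhaseMesh | None = None,
                           verify_tol: float = 1e-3 * TWO_PI) -> list[np.ndarray]:
    """Branches of the deterministic isochron {(v, a): phase = theta0}.

    Extracts zero contours of sin(theta - theta0) on the phase mesh, keeps
    the segments where cos(theta - theta0) > 0 (discarding the antiphase
    set), and verifies every retained point by a direct forward-flow phase
    evaluation, dropping points within `verify_tol` of nothing — the phase
    field has genuine discontinuities along the grazing-threshold set, and
    contour cells straddling a jump would otherwise emit spurious points.
    Returns a list of (n, 2) arrays of (v, a) points; several branches per
    phase are expected because of the fire-and-reset rule.
    """
    from skimage import measure

    if mesh is None:
        mesh = alif_phase_mesh(spec)
    cycle = mesh.cycle
    d = mesh.theta - theta0
    sin_f = np.sin(d)
    cos_f = np.cos(d)
    branches = []
    for contour in measure.find_contours(sin_f, 0.0):
        fi, fj = contour[:, 0], contour[:, 1]
        i = np.clip(fi.astype(int), 0, mesh.v_grid.size - 2)
        j = np.clip(fj.astype(int), 0, mesh.a_grid.size - 2)
        wi, wj = fi - i, fj - j
        cval = ((1 - wi) * (1 - wj) * cos_f[i, j]
                + wi * (1 - wj) * cos_f[i + 1, j]
                + (1 - wi) * wj * cos_f[i, j + 1]
                + wi * wj * cos_f[i + 1, j + 1])
        keep = cval > 0.0
        if keep.any():
            dv = mesh.v_grid[1] - mesh.v_grid[0]
            da = mesh.a_grid[1] - mesh.a_grid[0]
            v_all = mesh.v_grid[0] + fi * dv
            a_all = mesh.a_grid[0] + fj * da
            for p in np.flatnonzero(keep):
                th = _kernels.alif_asymptotic_phase(
                    v_all[p], a_all[p], spec.mu, spec.tau_a, spec.delta_a,
                    spec.v_T, spec.v_R, cycle.period, 1e-2 * verify_tol, 60)
                d = np.angle(np.exp(1j * (th - theta0)))
                if not np.abs(d) < verify_tol:
                    keep[p] = False
        # split the contour at discarded stretches
        if not keep.any():
            continue
        edges = np.flatnonzero(np.diff(keep.astype(int)))
        pieces = np.split(np.arange(keep.size), edges + 1)
        dv = mesh.v_grid[1] - mesh.v_grid[0]
        da = mesh.a_grid[1] - mesh.a_grid[0]
        for piece in pieces:
            if keep[piece[0]] and piece.size >= 2:
                v = mesh.v_grid[0] + fi[piece] * dv
                a = mesh.a_grid[0] + fj[piece] * da
                branches.append(np.column_stack([v, a]))
    return branches


# ---------------------------------------------------------------------------
# Counting curves
# ---------------------------------------------------------------------------

COUNTING_KINDS = ("spoke", "gsp_isochron", "gsp_twisted", "alif_threshold",
                  "alif_deterministic_isochron", "alif_horizontal_lines",
                  "hh_voltage_threshold", "hh_deterministic_isochron")


@dataclass
class CountingCurve:
    """A counting rule: a phase-lift map whose 2*pi passages are the events.

    `kind` selects the rule; `params` holds kind-specific values (twist factor
    m, line base a0 and spacing delta_a, threshold V_th, ...); `context` the
    geometric object the rule needs (a GSPIsochron, a LimitCycle or an
    AlifPhaseMesh).  `lift(trajectory)` returns the continuous lifted series;
    threshold kinds detect their events directly instead.
    """

    kind: str
    params: dict = field(default_factory=dict)
    context: object = None

    def lift(self, traj) -> np.ndarray:
        if self.kind == "spoke":
            return np.asarray(traj.phi_lift)
        if self.kind == "gsp_isochron":
            return np.asarray(traj.phi_lift) - self.context.phi(traj.rho)
        if self.kind == "gsp_twisted":
            m = self.params["m"]
            return np.asarray(traj.phi_lift) - m * self.context.phi(traj.rho)
        if self.kind == "alif_threshold":
            return TWO_PI * np.asarray(traj.spike_count, dtype=float)
        if self.kind == "alif_deterministic_isochron":
            theta = self.context.phase(traj.v, traj.a)
            return np.unwrap(theta)
        if self.kind == "alif_horizontal_lines":
            a0 = self.params["a0"]
            da = self.params["delta_a"]
            return TWO_PI * (np.asarray(traj.spike_count, dtype=float)
                            - (np.asarray(traj.a) - a0) / da)
        raise NotImplementedError(
            f"kind {self.kind!r} has no generic lift; use its event routine")


def make_counting_curve(kind: str, params: dict | None = None,
                        context=None) -> CountingCurve:
    """Build a CountingCurve, validating that the needed context is present."""
    params = dict(params or {})
    if kind not in COUNTING_KINDS:
        raise ValueError(f"unknown counting-curve kind {kind!r}")
    if kind in ("gsp_isochron", "gsp_twisted"):
        if not isinstance(context, GSPIsochron):
            raise ValueError(f"{kind} needs a GSPIsochron context")
        if kind == "gsp_twisted":
            params.setdefault("m", 5.0)
    if kind == "alif_deterministic_isochron" and not isinstance(
            context, AlifPhaseMesh):
        raise ValueError(f"{kind} needs an AlifPhaseMesh context")
    if kind == "alif_horizontal_lines":
        if "a0" not in params:
            if not isinstance(context, LimitCycle):
                raise ValueError("alif_horizontal_lines needs an a0 param "
                                 "or a LimitCycle context")
            params["a0"] = context.extras["a_threshold"]
        if "delta_a" not in params:
            raise ValueError("alif_horizontal_lines needs the line spacing "
                             "delta_a in params")
    if kind == "hh_deterministic_isochron" and not isinstance(
            context, LimitCycle):
        raise ValueError(f"{kind} needs a LimitCycle context")
    return CountingCurve(kind=kind, params=params, context=context)
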