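"""Stochastic oscillator models and their Euler–Maruyama simulators.

Three concrete Markovian oscillators are implemented:

* the Guckenheimer–Schwabedal–Pikovsky (GSP) oscillator — an isotropic planar
  system with two stable limit cycles (radii 1 and 3) separated by an unstable
  cycle at radius ``c``, multiplicative radial noise and reflecting radial
  boundaries;
* the adaptive leaky integrate-and-fire (ALIF) neuron — voltage with additive
  white noise, a spike-triggered adaptation current, and a fire-and-reset rule;
* a stochastic Hodgkin–Huxley (HH) neuron in the Fox–Lu-type diffusion
  approximation of channel kinetics — 14 dimensions: voltage plus 8 sodium and
  5 potassium channel-state fractions, with one independent Gaussian noise
  source per directed transition edge, scaled by a single parameter ``epsilon``.

All multiplicative noise is interpreted in the Itô sense.  These simulators are
the synthetic-data generators of the whole analysis: the only memory a
trajectory can carry from one rotation to the next is its state at the moment a
counting curve is crossed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Iterator

import numpy as np
import yaml

from . import _kernels


# ---------------------------------------------------------------------------
# Model specifications
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class GSPSpec:
    """Parameters of the GSP oscillator.

    drho = g(rho) dt + sigma*rho dW,   dphi = f(rho) dt, with
    g(rho) = rho(1-rho)(3-rho)(c-rho) + sigma^2 rho/2 (Itô drift included) and
    f(rho) = omega + gamma(rho-2) - (1-rho)(3-rho).  Reflecting boundaries at
    rho_minus and rho_plus confine the radius to an annulus.
    """

    sigma: float = 0.37
    omega: float = 2.0
    gamma: float = 1.0
    c: float = 1.875
    rho_minus: float = 0.5
    rho_plus: float = 4.0

    def __post_init__(self) -> None:
        if not (0.0 < self.rho_minus < 1.0 < self.c < 3.0 < self.rho_plus):
            raise ValueError("require 0 < rho_minus < 1 < c < 3 < rho_plus")
        if self.sigma < 0.0:
            raise ValueError("sigma must be >= 0")


@dataclass(frozen=True)
class ALIFSpec:
    """Adaptive leaky integrate-and-fire neuron.

    dv = (mu - v - a) dt + sqrt(2D) dW, tau_a da = -a dt between spikes;
    on v >= v_T: spike, v <- v_R, a <- a + delta_a.  Mean-driven regime
    (mu > v_T) is required so that the deterministic model fires repetitively.
    """

    mu: float = 2.0
    tau_a: float = 2.0
    delta_a: float = 1.0
    D: float = 0.1
    v_T: float = 1.0
    v_R: float = 0.0

    def __post_init__(self) -> None:
        if self.mu <= self.v_T:
            raise ValueError("mean-driven regime requires mu > v_T")
        if self.tau_a <= 0 or self.delta_a < 0 or self.D < 0:
            raise ValueError("require tau_a > 0, delta_a >= 0, D >= 0")


@dataclass(frozen=True)
class HHSpec:
    """Stochastic Hodgkin–Huxley neuron (channel-noise diffusion limit).

    Classical squid-axon parameters; `epsilon` multiplies every channel-noise
    column linearly (a directed edge with per-capita rate r out of a state
    with occupancy x contributes noise of amplitude epsilon*sqrt(r*x), i.e.
    epsilon ~ 1/sqrt(channel population)).  epsilon = 0 recovers the
    deterministic gate kinetics, which leave the binomial-product manifold of
    the 4-variable HH model invariant.
    """

    C: float = 1.0
    gbar_Na: float = 120.0
    gbar_K: float = 36.0
    g_L: float = 0.3
    V_Na: float = 50.0
    V_K: float = -77.0
    V_L: float = -54.4
    I_app: float = 10.0
    epsilon: float = 0.0281
    V_th: float = -20.0
    dt: float = 0.005

    def __post_init__(self) -> None:
        if self.epsilon < 0:
            raise ValueError("epsilon must be >= 0")
        if not (self.V_K < self.V_L < self.V_th < self.V_Na):
            raise ValueError("require V_K < V_L < V_th < V_Na")


# ---------------------------------------------------------------------------
# Trajectory containers
# ---------------------------------------------------------------------------


@dataclass
class GSPTrajectory:
    dt: float
    t0: float
    rho: np.ndarray
    phi_lift: np.ndarray
    seed: int

    @property
    def t(self) -> np.ndarray:
        return self.t0 + self.dt * np.arange(1, self.rho.size + 1)


@dataclass
class ALIFTrajectory:
    dt: float
    t0: float
    v: np.ndarray
    a: np.ndarray
    spike_count: np.ndarray
    spike_times: np.ndarray
    seed: int

    @property
    def t(self) -> np.ndarray:
        return self.t0 + self.dt * np.arange(1, self.v.size + 1)


@dataclass
class HHTrajectory:
    dt: float
    t0: float
    V: np.ndarray
    M: np.ndarray
    N: np.ndarray
    seed: int

    @property
    def t(self) -> np.ndarray:
        return self.t0 + self.dt * np.arange(1, self.V.size + 1)


# ---------------------------------------------------------------------------
# GSP oscillator
# ---------------------------------------------------------------------------


def gsp_fields(rho: float | np.ndarray, spec: GSPSpec):
    """Radial drift g(rho) (Itô term included) and angular speed f(rho)."""
    rho = np.asarray(rho, dtype=float)
    if np.any(rho <= 0):
        raise ValueError("rho must be positive")
    g = rho * (1 - rho) * (3 - rho) * (spec.c - rho) + 0.5 * spec.sigma**2 * rho
    f = spec.omega + spec.gamma * (rho - 2) - (1 - rho) * (3 - rho)
    return g, f


def _check_step(duration: float, dt: float) -> int:
    if not duration > dt > 0:
        raise ValueError("require duration > dt > 0")
    return int(round(duration / dt))


def iter_gsp(spec: GSPSpec, duration: float, dt: float, seed: int,
             rho0: float = 1.0, phi0: float = 0.0,
             chunk: int = 5_000_000) -> Iterator[tuple[float, np.ndarray, np.ndarray]]:
    """Yield (t_chunk_start, rho, phi_lift) chunks; state carries over."""
    n = _check_step(duration, dt)
    g_all, _ = gsp_fields(np.linspace(spec.rho_minus, spec.rho_plus, 257),
                          spec)
    if np.abs(g_all).max() * dt > (spec.rho_plus - spec.rho_minus):
        raise ValueError("dt too large to resolve the radial drift")
    rng = np.random.default_rng(seed)
    rho, phi = float(rho0), float(phi0)
    done = 0
    while done < n:
        m = min(chunk, n - done)
        xi = rng.standard_normal(m)
        r_arr, p_arr = _kernels.gsp_chunk(
            rho, phi, xi, dt, spec.sigma, spec.omega, spec.gamma, spec.c,
            spec.rho_minus, spec.rho_plus)
        yield done * dt, r_arr, p_arr
        rho, phi = r_arr[-1], p_arr[-1]
        done += m


def simulate_gsp(spec: GSPSpec, duration: float, dt: float, seed: int,
                 rho0: float = 1.0, phi0: float = 0.0) -> GSPTrajectory:
    """Simulate the GSP oscillator; bit-reproducible for fixed arguments."""
    parts_r, parts_p = [], []
    for _, r, p in iter_gsp(spec, duration, dt, seed, rho0, phi0):
        parts_r.append(r)
        parts_p.append(p)
    return GSPTrajectory(dt=dt, t0=0.0, rho=np.concatenate(parts_r),
                         phi_lift=np.concatenate(parts_p), seed=seed)


# ---------------------------------------------------------------------------
# ALIF neuron
# ---------------------------------------------------------------------------


def iter_alif(spec: ALIFSpec, duration: float, dt: float, seed: int,
              v0: float = 0.0, a0: float = 0.0,
              chunk: int = 2_000_000):
    """Yield (t_chunk_start, v, a, count, spike_times) chunks."""
    n = _check_step(duration, dt)
    rng = np.random.default_rng(seed)
    v, a, count = float(v0), float(a0), 0
    done = 0
    while done < n:
        m = min(chunk, n - done)
        xi = rng.standard_normal(m)
        v_arr, a_arr, c_arr, sp, count = _kernels.alif_chunk(
            v, a, count, done * dt, xi, dt, spec.mu, spec.tau_a,
            spec.delta_a, spec.D, spec.v_T, spec.v_R)
        yield done * dt, v_arr, a_arr, c_arr, sp
        v, a = v_arr[-1], a_arr[-1]
        done += m


def simulate_alif(spec: ALIFSpec, duration: float, dt: float, seed: int,
                  v0: float = 0.0, a0: float = 0.0) -> ALIFTrajectory:
    """Simulate the ALIF neuron with exact adaptation decay between spikes.

    Spike times are located by linear interpolation of the voltage within the
    straddling step; the reset is applied at the interpolated time and the
    remainder of the step re-integrated, so interval statistics are not
    quantized at dt resolution.
    """
    pv, pa, pc, ps = [], [], [], []
    for _, v, a, c, sp in iter_alif(spec, duration, dt, seed, v0, a0):
        pv.append(v)
        pa.append(a)
        pc.append(c)
        ps.append(sp)
    return ALIFTrajectory(dt=dt, t0=0.0, v=np.concatenate(pv),
                          a=np.concatenate(pa),
                          spike_count=np.concatenate(pc),
                          spike_times=np.concatenate(ps), seed=seed)


# ---------------------------------------------------------------------------
# Stochastic Hodgkin–Huxley
# ---------------------------------------------------------------------------

def hh_rates(V: float) -> tuple[float, float, float, float, float, float]:
    """Gate rate functions (alpha_m, beta_m, alpha_h, beta_h, alpha_n, beta_n)."""
    return _kernels._hh_rates(V)


def hh_gate_equilibrium(V: float) -> tuple[float, float, float]:
    """Equilibrium open probabilities (m_inf, h_inf, n_inf) at clamped V."""
    am, bm, ah, bh, an, bn = hh_rates(V)
    return am / (am + bm), ah / (ah + bh), an / (an + bn)


def hh_binomial_state(m: float, h: float, n: float) -> tuple[np.ndarray, np.ndarray]:
    """Channel-state fractions on the binomial-product (4-variable) manifold.

    M_{ij} = C(3,i) m^i (1-m)^(3-i) * [j ? h : 1-h], N_k = C(4,k) n^k (1-n)^(4-k).
    """
    from math import comb

    M = np.empty(8)
    for j in range(2):
        hj = h if j == 1 else 1.0 - h
        for i in range(4):
            M[i + 4 * j] = comb(3, i) * m**i * (1 - m) ** (3 - i) * hj
    N = np.array([comb(4, k) * n**k * (1 - n) ** (4 - k) for k in range(5)])
    return M, N


#: directed edges of the sodium gate graph as (source, target, rate_fn) where
#: the rate_fn maps the six gate rates to the per-capita edge rate; the order
#: matches the noise-column order used by the compiled stepper.
def _na_edges():
    edges = []
    for j in range(2):
        for i in range(3):
            edges.append((i + 4 * j, i + 1 + 4 * j, ("am", 3 - i)))
        for i in range(1, 4):
            edges.append((i + 4 * j, i - 1 + 4 * j, ("bm", i)))
    for i in range(4):
        edges.append((i, i + 4, ("ah", 1)))
    for i in range(4):
        edges.append((i + 4, i, ("bh", 1)))
    return edges


def _k_edges():
    edges = []
    for k in range(4):
        edges.append((k, k + 1, ("an", 4 - k)))
    for k in range(1, 5):
        edges.append((k, k - 1, ("bn", k)))
    return edges


def hh_build_matrices(V: float, spec: HHSpec,
                      M: np.ndarray | None = None,
                      N: np.ndarray | None = None):
    """Drift generators and noise matrices of the gating kinetics at voltage V.

    Returns (A_Na 8x8, A_K 5x5, S_Na 8x20, S_K 5x8).  The noise matrices are
    state-dependent; if M/N are omitted they are evaluated at the binomial
    equilibrium for the clamped voltage.  A directed edge with per-capita
    rate r out of a state with occupancy x contributes one noise column of
    amplitude epsilon*sqrt(r*x); negative fractions are clamped to zero
    inside the square root.  Every column of every matrix sums to zero
    (probability conservation).
    """
    if not np.isfinite(V):
        raise ValueError("V must be finite")
    if M is None or N is None:
        M, N = hh_binomial_state(*hh_gate_equilibrium(V))
    am, bm, ah, bh, an, bn = hh_rates(V)
    rates = {"am": am, "bm": bm, "ah": ah, "bh": bh, "an": an, "bn": bn}

    def build(n_states, edges, x):
        A = np.zeros((n_states, n_states))
        S = np.zeros((n_states, len(edges)))
        for e, (s, t, (name, mult)) in enumerate(edges):
            r = mult * rates[name]
            A[s, s] -= r
            A[t, s] += r
            amp = spec.epsilon * np.sqrt(r * max(x[s], 0.0))
            S[s, e] -= amp
            S[t, e] += amp
        return A, S

    A_Na, S_Na = build(8, _na_edges(), M)
    A_K, S_K = build(5, _k_edges(), N)
    return A_Na, A_K, S_Na, S_K


def _hh_args(spec: HHSpec):
    return (spec.C, spec.gbar_Na, spec.gbar_K, spec.g_L, spec.V_Na,
            spec.V_K, spec.V_L, spec.I_app)


def hh_rest_state(spec: HHSpec, V0: float = -65.0):
    """Binomial-manifold state at clamped V0 (convenient initial condition)."""
    M, N = hh_binomial_state(*hh_gate_equilibrium(V0))
    return V0, M, N


def iter_hh(spec: HHSpec, duration: float, dt: float, seed: int,
            V0: float | None = None, M0: np.ndarray | None = None,
            N0: np.ndarray | None = None, chunk: int = 500_000):
    """Yield (t_chunk_start, V, M, N) chunks of the 14-dim diffusion."""
    n = _check_step(duration, dt)
    if V0 is None or M0 is None or N0 is None:
        V0, M0, N0 = hh_rest_state(spec)
    rng = np.random.default_rng(seed)
    V, M, N = float(V0), np.asarray(M0, float), np.asarray(N0, float)
    done = 0
    while done < n:
        m = min(chunk, n - done)
        xi = rng.standard_normal((m, 28))
        V_arr, M_arr, N_arr = _kernels.hh_chunk(
            V, M, N, xi, dt, *_hh_args(spec), spec.epsilon)
        yield done * dt, V_arr, M_arr, N_arr
        V, M, N = V_arr[-1], M_arr[-1].copy(), N_arr[-1].copy()
        done += m


def simulate_hh(spec: HHSpec, duration: float, dt: float | None = None,
                seed: int = 0, V0: float | None = None,
                M0: np.ndarray | None = None,
                N0: np.ndarray | None = None) -> HHTrajectory:
    """Simulate the stochastic HH diffusion (voltage equation is noiseless)."""
    if dt is None:
        dt = spec.dt
    pV, pM, pN = [], [], []
    for _, V, M, N in iter_hh(spec, duration, dt, seed, V0, M0, N0):
        pV.append(V)
        pM.append(M)
        pN.append(N)
    return HHTrajectory(dt=dt, t0=0.0, V=np.concatenate(pV),
                        M=np.concatenate(pM), N=np.concatenate(pN), seed=seed)


def simulate_hh_deterministic(spec: HHSpec, duration: float,
                              dt: float | None = None,
                              V0: float | None = None,
                              M0: np.ndarray | None = None,
                              N0: np.ndarray | None = None) -> HHTrajectory:
    """epsilon = 0 limit of simulate_hh with the same stepper."""
    if dt is None:
        dt = spec.dt
    n = _check_step(duration, dt)
    if V0 is None or M0 is None or N0 is None:
        V0, M0, N0 = hh_rest_state(spec)
    V_arr, M_arr, N_arr = _kernels.hh_det_chunk(
        float(V0), np.asarray(M0, float), np.asarray(N0, float), n, dt,
        *_hh_args(spec))
    return HHTrajectory(dt=dt, t0=0.0, V=V_arr, M=M_arr, N=N_arr, seed=-1)


# ---------------------------------------------------------------------------
# Spec / trajectory IO
# ---------------------------------------------------------------------------

_SPEC_TYPES = {"gsp": GSPSpec, "alif": ALIFSpec, "hh": HHSpec}


def spec_from_dict(model: str, params: dict):
    try:
        cls = _SPEC_TYPES[model]
    except KeyError:
        raise ValueError(f"unknown model {model!r}") from None
    return cls(**params)


def load_spec(path: str | Path):
    """Read a model spec from YAML/JSON: {"model": ..., "params": {...}}."""
    text = Path(path).read_text()
    data = yaml.safe_load(text) if str(path).endswith((".yml", ".yaml")) \
        else json.loads(text)
    return spec_from_dict(data["model"], data.get("params", {}))


def save_spec(spec, path: str | Path) -> None:
    model = {GSPSpec: "gsp", ALIFSpec: "alif", HHSpec: "hh"}[type(spec)]
    data = {"model": model, "params": asdict(spec)}
    p = Path(path)
    if p.suffix in (".yml", ".yaml"):
        p.write_text(yaml.safe_dump(data))
    else:
        p.write_text(json.dumps(data, indent=1))


def trajectory_to_csv(traj, path: str | Path) -> None:
    """Write a trajectory as CSV (t plus state columns, 17 significant digits)."""
    import pandas as pd

    if isinstance(traj, GSPTrajectory):
        df = pd.DataFrame({"t": traj.t, "rho": traj.rho,
                           "phi_lift": traj.phi_lift})
    elif isinstance(traj, ALIFTrajectory):
        df = pd.DataFrame({"t": traj.t, "v": traj.v, "a": traj.a,
                           "spike_count": traj.spike_count})
    elif isinstance(traj, HHTrajectory):
        cols = {"t": traj.t, "V": traj.V}
        for k in range(8):
            cols[f"M{k}"] = traj.M[:, k]
        for k in range(5):
            cols[f"N{k}"] = traj.N[:, k]
        df = pd.DataFrame(cols)
    else:
        raise TypeError(f"unsupported trajectory type {type(traj)!r}")
    df.to_csv(path, index=False, float_format="%.17g")


def trajectory_to_npz(traj, path: str | Path) -> None:
    """Compact binary dump (numpy .npz) of a trajectory."""
    common = dict(dt=traj.dt, t0=traj.t0, seed=traj.seed)
    if isinstance(traj, GSPTrajectory):
        np.savez_compressed(path, rho=traj.rho, phi_lift=traj.phi_lift,
                            **common)
    elif isinstance(traj, ALIFTrajectory):
        np.savez_compressed(path, v=traj.v, a=traj.a,
                            spike_count=traj.spike_count,
                            spike_times=traj.spike_times, **common)
    elif isinstance(traj, HHTrajectory):
        np.savez_compressed(path, V=traj.V, M=traj.M, N=traj.N, **common)
    else:
        raise TypeError(f"unsupported trajectory type {type(traj)!r}")
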