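"""Compiled inner loops for the stochastic-oscillator simulators.

Everything in here is a plain function of scalars and arrays so that numba can
compile it; the public API with its spec objects lives in :mod:`mrtphase.models`.
All SDE integration is explicit Euler–Maruyama in the Itô convention.
"""

import numpy as np
from numba import njit

# ---------------------------------------------------------------------------
# Guckenheimer–Schwabedal–Pikovsky (GSP) oscillator
# ---------------------------------------------------------------------------


@njit(cache=True, inline="always")
def _reflect(x, lo, hi):
    # mirror reflection, iterated for (rare) multi-bounce steps
    while x < lo or x > hi:
        if x < lo:
            x = 2.0 * lo - x
        if x > hi:
            x = 2.0 * hi - x
    return x


@njit(cache=True)
def gsp_chunk(rho0, phi0, xi, dt, sigma, omega, gamma, c, rho_m, rho_p):
    """Advance the GSP oscillator by len(xi) Euler–Maruyama steps.

    Returns the sampled (rho, phi_lift) arrays *after* each step.
    """
    n = xi.shape[0]
    rho_out = np.empty(n)
    phi_out = np.empty(n)
    rho = rho0
    phi = phi0
    sq = sigma * np.sqrt(dt)
    for i in range(n):
        g = rho * (1.0 - rho) * (3.0 - rho) * (c - rho) + 0.5 * sigma * sigma * rho
        f = omega + gamma * (rho - 2.0) - (1.0 - rho) * (3.0 - rho)
        phi = phi + f * dt
        rho = _reflect(rho + g * dt + sq * rho * xi[i], rho_m, rho_p)
        rho_out[i] = rho
        phi_out[i] = phi
    return rho_out, phi_out


@njit(cache=True)
def gsp_passage_time(rho0, phi0, dt, sigma, omega, gamma, c, rho_m, rho_p,
                     phiI, drho, target, seed, max_steps):
    """First-passage time of the isochron lift phi - phi_I(rho) through `target`.

    `phiI` is phi_I sampled on the uniform radius grid rho_m + k*drho.  Uses
    numba's own RNG seeded with `seed`.  Returns -1.0 if max_steps is exceeded.
    """
    np.random.seed(seed)
    rho = rho0
    phi = phi0
    sq = sigma * np.sqrt(dt)
    nj = phiI.shape[0] - 1
    # lift at the current state
    u = (rho - rho_m) / drho
    j = min(max(int(u), 0), nj - 1)
    lift_prev = phi - (phiI[j] + (u - j) * (phiI[j + 1] - phiI[j]))
    t = 0.0
    for _ in range(max_steps):
        g = rho * (1.0 - rho) * (3.0 - rho) * (c - rho) + 0.5 * sigma * sigma * rho
        f = omega + gamma * (rho - 2.0) - (1.0 - rho) * (3.0 - rho)
        phi = phi + f * dt
        rho = _reflect(rho + g * dt + sq * rho * np.random.normal(), rho_m, rho_p)
        t += dt
        u = (rho - rho_m) / drho
        j = min(max(int(u), 0), nj - 1)
        lift = phi - (phiI[j] + (u - j) * (phiI[j + 1] - phiI[j]))
        if lift >= target:
            # linear interpolation inside the straddling step
            if lift > lift_prev:
                return t - dt * (lift - target) / (lift - lift_prev)
            return t
        lift_prev = lift
    return -1.0


@njit(cache=True)
def scaled_exp_recurrence(H, h, dq):
    """D_j = D_{j-1} exp(2(H_{j-1}-H_j)) + trapezoid panel of h e^{2(H-H_j)}.

    Stable evaluation of D(q_j) = int_{q_0}^{q_j} h(u) exp(2(H(u)-H(q_j))) du:
    the integral is always carried in the frame of the current upper limit, so
    only exponentials of per-step differences of H appear.
    """
    n = H.shape[0]
    D = np.empty(n)
    D[0] = 0.0
    for j in range(1, n):
        fac = np.exp(2.0 * (H[j - 1] - H[j]))
        D[j] = D[j - 1] * fac + 0.5 * dq * (h[j - 1] * fac + h[j])
    return D


# ---------------------------------------------------------------------------
# Adaptive leaky integrate-and-fire (ALIF)
# ---------------------------------------------------------------------------


@njit(cache=True)
def alif_chunk(v0, a0, count0, t0, xi, dt, mu, tau_a, delta_a, D, v_T, v_R):
    """Advance the ALIF model by len(xi) steps.

    Voltage: Euler–Maruyama with additive noise sqrt(2D)*xi; adaptation decays
    by the exact factor exp(-dt/tau_a) between spikes.  Threshold crossings are
    located by linear interpolation; the reset is applied at the interpolated
    time and the remainder of the step is re-integrated (drift only).

    Returns (v, a, count) sampled after each step, the spike times recorded in
    this chunk, and the final cumulative spike count.
    """
    n = xi.shape[0]
    v_out = np.empty(n)
    a_out = np.empty(n)
    c_out = np.empty(n, dtype=np.int64)
    spikes = np.empty(n, dtype=np.float64)
    n_sp = 0
    v = v0
    a = a0
    count = count0
    decay = np.exp(-dt / tau_a)
    amp = np.sqrt(2.0 * D * dt)
    for i in range(n):
        v_new = v + dt * (mu - v - a) + amp * xi[i]
        if v_new >= v_T:
            frac = (v_T - v) / (v_new - v)
            tc = t0 + i * dt + frac * dt
            spikes[n_sp] = tc
            n_sp += 1
            count += 1
            a_c = a * np.exp(-frac * dt / tau_a) + delta_a
            rem = (1.0 - frac) * dt
            # drift-only remainder of the step after reset
            v = v_R + rem * (mu - v_R - a_c)
            a = a_c * np.exp(-rem / tau_a)
            if v >= v_T:  # essentially unreachable for sane dt; keep invariant
                v = v_R
        else:
            v = v_new
            a = a * decay
        v_out[i] = v
        a_out[i] = a
        c_out[i] = count
    return v_out, a_out, c_out, spikes[:n_sp].copy(), count


# ---------------------------------------------------------------------------
# Stochastic Hodgkin–Huxley, Fox–Lu-type diffusion approximation
# ---------------------------------------------------------------------------


@njit(cache=True, inline="always")
def _hh_rates(V):
    """Classical squid-axon gate rates (1/ms, V in mV)."""
    x = V + 40.0
    if np.abs(x) < 1e-7:
        am = 1.0
    else:
        am = 0.1 * x / (1.0 - np.exp(-x / 10.0))
    bm = 4.0 * np.exp(-(V + 65.0) / 18.0)
    ah = 0.07 * np.exp(-(V + 65.0) / 20.0)
    bh = 1.0 / (1.0 + np.exp(-(V + 35.0) / 10.0))
    y = V + 55.0
    if np.abs(y) < 1e-7:
        an = 0.1
    else:
        an = 0.01 * y / (1.0 - np.exp(-y / 10.0))
    bn = 0.125 * np.exp(-(V + 65.0) / 80.0)
    return am, bm, ah, bh, an, bn


@njit(cache=True, inline="always")
def _hh_gate_step(M, N, V, dt, eps, xi, dM, dN):
    """One Euler–Maruyama step of the 13 gating fractions, in place.

    Edge-by-edge: each directed transition contributes drift +-rate*x_s and an
    independent noise increment +-eps*sqrt(rate*x_s*dt)*xi_e that moves mass
    from source to target, so column sums (hence sum(M), sum(N)) are conserved
    exactly.  eps ~ 1/sqrt(channel count) scales every noise column linearly.
    xi must hold 28 standard normals (20 Na edges, 8 K edges).
    """
    am, bm, ah, bh, an, bn = _hh_rates(V)
    for k in range(8):
        dM[k] = 0.0
    for k in range(5):
        dN[k] = 0.0
    e = 0
    # sodium: state index i + 4*j, i = number of open m gates, j = h gate
    for j in range(2):
        for i in range(3):  # m gate opens: (i,j) -> (i+1,j), rate (3-i)*am
            s = i + 4 * j
            r = (3.0 - i) * am
            xs = M[s] if M[s] > 0.0 else 0.0
            w = r * M[s] * dt + eps * np.sqrt(r * xs * dt) * xi[e]
            dM[s] -= w
            dM[s + 1] += w
            e += 1
        for i in range(1, 4):  # m gate closes: (i,j) -> (i-1,j), rate i*bm
            s = i + 4 * j
            r = i * bm
            xs = M[s] if M[s] > 0.0 else 0.0
            w = r * M[s] * dt + eps * np.sqrt(r * xs * dt) * xi[e]
            dM[s] -= w
            dM[s - 1] += w
            e += 1
    for i in range(4):  # h gate opens: (i,0) -> (i,1), rate ah
        xs = M[i] if M[i] > 0.0 else 0.0
        w = ah * M[i] * dt + eps * np.sqrt(ah * xs * dt) * xi[e]
        dM[i] -= w
        dM[i + 4] += w
        e += 1
    for i in range(4):  # h gate closes: (i,1) -> (i,0), rate bh
        s = i + 4
        xs = M[s] if M[s] > 0.0 else 0.0
        w = bh * M[s] * dt + eps * np.sqrt(bh * xs * dt) * xi[e]
        dM[s] -= w
        dM[s - 4] += w
        e += 1
    # potassium: state index = number of open n gates
    for k in range(4):  # n gate opens, rate (4-k)*an
        r = (4.0 - k) * an
        xs = N[k] if N[k] > 0.0 else 0.0
        w = r * N[k] * dt + eps * np.sqrt(r * xs * dt) * xi[e]
        dN[k] -= w
        dN[k + 1] += w
        e += 1
    for k in range(1, 5):  # n gate closes, rate k*bn
        r = k * bn
        xs = N[k] if N[k] > 0.0 else 0.0
        w = r * N[k] * dt + eps * np.sqrt(r * xs * dt) * xi[e]
        dN[k] -= w
        dN[k - 1] += w
        e += 1
    for k in range(8):
        M[k] += dM[k]
    for k in range(5):
        N[k] += dN[k]
    # clip to [0,1] and renormalize to unit sum (Fox–Lu truncation)
    sm = 0.0
    for k in range(8):
        if M[k] < 0.0:
            M[k] = 0.0
        elif M[k] > 1.0:
            M[k] = 1.0
        sm += M[k]
    for k in range(8):
        M[k] /= sm
    sn = 0.0
    for k in range(5):
        if N[k] < 0.0:
            N[k] = 0.0
        elif N[k] > 1.0:
            N[k] = 1.0
        sn += N[k]
    for k in range(5):
        N[k] /= sn


@njit(cache=True)
def hh_chunk(V0, M0, N0, xi, dt, C, gNa, gK, gL, VNa, VK, VL, Iapp, eps):
    """Advance the 14-dim HH diffusion by xi.shape[0] steps.

    The voltage equation carries no noise; all fluctuations enter through the
    gating fractions.  Returns (V, M, N) sampled after each step.
    """
    n = xi.shape[0]
    V_out = np.empty(n)
    M_out = np.empty((n, 8))
    N_out = np.empty((n, 5))
    M = M0.copy()
    N = N0.copy()
    dM = np.empty(8)
    dN = np.empty(5)
    V = V0
    for i in range(n):
        I_ion = (gNa * M[7] * (V - VNa) + gK * N[4] * (V - VK) + gL * (V - VL))
        Vn = V + dt * (Iapp - I_ion) / C
        _hh_gate_step(M, N, V, dt, eps, xi[i], dM, dN)
        V = Vn
        V_out[i] = V
        for k in range(8):
            M_out[i, k] = M[k]
        for k in range(5):
            N_out[i, k] = N[k]
    return V_out, M_out, N_out


_ZERO28 = np.zeros(28)


@njit(cache=True)
def hh_det_chunk(V0, M0, N0, n, dt, C, gNa, gK, gL, VNa, VK, VL, Iapp):
    """Deterministic (eps = 0) counterpart of hh_chunk."""
    V_out = np.empty(n)
    M_out = np.empty((n, 8))
    N_out = np.empty((n, 5))
    M = M0.copy()
    N = N0.copy()
    dM = np.empty(8)
    dN = np.empty(5)
    V = V0
    for i in range(n):
        I_ion = (gNa * M[7] * (V - VNa) + gK * N[4] * (V - VK) + gL * (V - VL))
        Vn = V + dt * (Iapp - I_ion) / C
        _hh_gate_step(M, N, V, dt, 0.0, _ZERO28, dM, dN)
        V = Vn
        V_out[i] = V
        for k in range(8):
            M_out[i, k] = M[k]
        for k in range(5):
            N_out[i, k] = N[k]
    return V_out, M_out, N_out


@njit(cache=True)
def hh_det_crossings(V0, M0, N0, dt, C, gNa, gK, gL, VNa, VK, VL, Iapp,
                     V_th, n_cross, max_steps):
    """Times of the first n_cross upcrossings of V_th under the eps=0 flow.

    Crossing times are linearly interpolated.  Returns (times, found).
    """
    times = np.empty(n_cross)
    found = 0
    M = M0.copy()
    N = N0.copy()
    dM = np.empty(8)
    dN = np.empty(5)
    V = V0
    t = 0.0
    for _ in range(max_steps):
        I_ion = (gNa * M[7] * (V - VNa) + gK * N[4] * (V - VK) + gL * (V - VL))
        Vn = V + dt * (Iapp - I_ion) / C
        _hh_gate_step(M, N, V, dt, 0.0, _ZERO28, dM, dN)
        if V < V_th <= Vn:
            times[found] = t + dt * (V_th - V) / (Vn - V)
            found += 1
            if found == n_cross:
                return times, found
        V = Vn
        t += dt
    return times, found


@njit(cache=True)
def hh_project_chunk(V, M, N, cyc, v_scale, idx0, lift0):
    """Coarse phase lift by nearest-point projection onto the stored cycle.

    `cyc` is the limit cycle sampled at K uniform times, as a (K, 14) array of
    (V*v_scale, M, N); sample k sits at phase 2*pi*k/K, with phase 0 at the
    V_th upcrossing.  The projection index is tracked incrementally (local
    search window around the previous index), which is valid because weak noise
    keeps the trajectory near the cycle and the phase advances slowly on the
    sampling grid.  Returns the unwrapped lift per sample and the final index.
    """
    n = V.shape[0]
    K = cyc.shape[0]
    w = max(8, K // 64)
    out = np.empty(n)
    idx = idx0
    lift = lift0
    for i in range(n):
        best = 1e300
        bestj = idx
        for o in range(-w, w + 1):
            j = (idx + o) % K
            d = (V[i] * v_scale - cyc[j, 0]) ** 2
            for k in range(8):
                d += (M[i, k] - cyc[j, 1 + k]) ** 2
            for k in range(5):
                d += (N[i, k] - cyc[j, 9 + k]) ** 2
            if d < best:
                best = d
                bestj = j
        step = (bestj - idx) % K
        if step > K // 2:
            step -= K
        lift += 2.0 * np.pi * step / K
        idx = bestj
        out[i] = lift
    return out, idx


# ---------------------------------------------------------------------------
# ALIF deterministic flow / asymptotic phase (closed-form between spikes)
# ---------------------------------------------------------------------------


@njit(cache=True, inline="always")
def _alif_v_of_t(t, v0, a0, mu, tau_a):
    """Closed-form voltage of the deterministic ALIF flow (tau_a != 1)."""
    kap = tau_a / (tau_a - 1.0)
    return (mu - a0 * kap * np.exp(-t / tau_a)
            + (v0 - mu + a0 * kap) * np.exp(-t))


@njit(cache=True)
def alif_first_crossing(v0, a0, mu, tau_a, v_T, scan, t_max):
    """First time the deterministic flow from (v0, a0) reaches v_T.

    Scans in increments of `scan`, then bisects.  Returns -1.0 on failure
    (cannot happen for mu > v_T within a generous t_max).
    """
    if v0 >= v_T:
        return 0.0
    t_lo = 0.0
    f_lo = v0 - v_T
    t = scan
    while t <= t_max:
        f = _alif_v_of_t(t, v0, a0, mu, tau_a) - v_T
        if f >= 0.0:
            # bisect in (t_lo, t]
            t_hi = t
            for _ in range(80):
                tm = 0.5 * (t_lo + t_hi)
                fm = _alif_v_of_t(tm, v0, a0, mu, tau_a) - v_T
                if fm >= 0.0:
                    t_hi = tm
                else:
                    t_lo = tm
                    f_lo = fm
            return 0.5 * (t_lo + t_hi)
        t_lo = t
        f_lo = f
        t += scan
    return -1.0


@njit(cache=True)
def alif_asymptotic_phase(v0, a0, mu, tau_a, delta_a, v_T, v_R, Tstar,
                          tol, k_max):
    """Asymptotic phase of (v0, a0) under the deterministic ALIF flow.

    theta_K = 2*pi*(K - tau_K / T*) where tau_K is the K-th spike time of the
    noiseless flow started at (v0, a0); iterated until successive estimates
    differ by less than tol.  Phase 0 is the post-reset point of the cycle.
    Returns theta in [0, 2*pi).  NaN if no spike occurs within the scan budget.
    """
    v = v0
    a = a0
    tau = 0.0
    theta_prev = 1e300
    for K in range(1, k_max + 1):
        dtc = alif_first_crossing(v, a, mu, tau_a, v_T, 0.02, 200.0 * Tstar)
        if dtc < 0.0:
            return np.nan
        tau += dtc
        a = a * np.exp(-dtc / tau_a) + delta_a
        v = v_R
        theta = 2.0 * np.pi * (K - tau / Tstar)
        if np.abs(theta - theta_prev) < tol:
            theta_prev = theta
            break
        theta_prev = theta
    th = theta_prev % (2.0 * np.pi)
    if th < 0.0:
        th += 2.0 * np.pi
    return th


@njit(cache=True)
def alif_phase_mesh_kernel(v_grid, a_grid, mu, tau_a, delta_a, v_T, v_R,
                           Tstar, tol, k_max):
    """Asymptotic phase on a rectangular (v, a) mesh."""
    nv = v_grid.shape[0]
    na = a_grid.shape[0]
    out = np.empty((nv, na))
    for i in range(nv):
        for j in range(na):
            out[i, j] = alif_asymptotic_phase(
                v_grid[i], a_grid[j], mu, tau_a, delta_a, v_T, v_R,
                Tstar, tol, k_max)
    return out
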