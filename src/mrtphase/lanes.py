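"""Discrete Markov-renewal oracle for the vanishing-correlation theorem.

The continuous picture: a Markovian oscillator crosses a counting curve at
some point r, and the only memory linking one rotation interval to the next is
that shared crossing point.  Here r is discretised to a finite *lane* index:
a lane-to-lane transition matrix Q carries the memory, each lane has its own
conditional interval law (gamma, with mean mu_r and variance s2_r).  Interval
moments and lag covariances are then exact linear-algebra expressions, so the
theorem — equal conditional means imply exactly zero serial correlation at
every lag, for arbitrary Q and arbitrary per-lane variances — can be checked
with no Monte-Carlo error.

First-step analysis: with pi the stationary lane distribution,

    <I>     = sum_r pi_r mu_r
    cov_k   = sum_r pi_r mu_r (Q^k mu)_r - <I>^2        (k >= 1)
    var     = sum_r pi_r (s2_r + mu_r^2) - <I>^2
    rho_k   = cov_k / var.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy.sparse.csgraph import connected_components
from scipy.sparse import csr_matrix

from .events import IntervalSequence


@dataclass
class LaneRenewalChain:
    """A finite-lane Markov-renewal process.

    mu[r]: conditional mean interval out of lane r; s2[r]: conditional
    variance; Q[r, r']: probability that a rotation starting in lane r lands
    in lane r'.  Q must be a proper irreducible stochastic matrix.
    """

    mu: np.ndarray
    s2: np.ndarray
    Q: np.ndarray

    def __post_init__(self):
        self.mu = np.asarray(self.mu, dtype=float)
        self.s2 = np.asarray(self.s2, dtype=float)
        self.Q = np.asarray(self.Q, dtype=float)
        n = self.mu.size
        if self.Q.shape != (n, n) or self.s2.size != n:
            raise ValueError("inconsistent chain dimensions")
        if np.any(self.mu <= 0) or np.any(self.s2 < 0):
            raise ValueError("require mu > 0 and s2 >= 0")
        if np.any(self.Q < 0) or not np.allclose(self.Q.sum(axis=1), 1.0,
                                                 atol=1e-10):
            raise ValueError("Q rows must be nonnegative and sum to 1")
        n_comp, _ = connected_components(csr_matrix(self.Q > 0),
                                         connection="strong")
        if n_comp != 1:
            raise ValueError("Q must be irreducible")

    @property
    def n_lanes(self) -> int:
        return self.mu.size

    def stationary(self) -> np.ndarray:
        """Stationary lane distribution pi with pi Q = pi."""
        w, v = np.linalg.eig(self.Q.T)
        i = int(np.argmin(np.abs(w - 1.0)))
        pi = np.real(v[:, i])
        pi = np.abs(pi)
        return pi / pi.sum()

    @classmethod
    def from_json(cls, path: str | Path) -> "LaneRenewalChain":
        data = json.loads(Path(path).read_text())
        return cls(mu=np.array(data["mu"]), s2=np.array(data["s2"]),
                   Q=np.array(data["Q"]))

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps({
            "mu": self.mu.tolist(), "s2": self.s2.tolist(),
            "Q": self.Q.tolist()}, indent=1))


def exact_interval_moments(chain: LaneRenewalChain, k: int):
    """Exact (mean, variance, lag-k covariance, rho_k) by first-step analysis."""
    if k < 1:
        raise ValueError("lag k must be >= 1")
    pi = chain.stationary()
    mean = float(pi @ chain.mu)
    var = float(pi @ (chain.s2 + chain.mu**2) - mean**2)
    Qk_mu = np.linalg.matrix_power(chain.Q, k) @ chain.mu
    cov = float(pi @ (chain.mu * Qk_mu) - mean**2)
    return mean, var, cov, cov / var


def exact_scc(chain: LaneRenewalChain, k_max: int) -> np.ndarray:
    """rho_k for k = 1..k_max, exactly."""
    return np.array([exact_interval_moments(chain, k)[3]
                     for k in range(1, k_max + 1)])


def simulate_chain(chain: LaneRenewalChain, n_intervals: int,
                   seed: int = 0) -> IntervalSequence:
    """Monte-Carlo counterpart: lane path from Q, gamma interval per lane.

    Lanes with s2 == 0 emit their mean deterministically (point mass); the
    lane path starts from the stationary distribution.
    """
    if n_intervals < 1:
        raise ValueError("need n_intervals >= 1")
    rng = np.random.default_rng(seed)
    pi = chain.stationary()
    n = chain.n_lanes
    cum = np.cumsum(chain.Q, axis=1)
    lanes = np.empty(n_intervals, dtype=np.int64)
    lane = int(rng.choice(n, p=pi))
    u = rng.random(n_intervals)
    for i in range(n_intervals):
        lanes[i] = lane
        lane = int(np.searchsorted(cum[lane], u[i]))
    intervals = np.empty(n_intervals)
    for r in range(n):
        sel = lanes == r
        m = int(sel.sum())
        if m == 0:
            continue
        if chain.s2[r] == 0.0:
            intervals[sel] = chain.mu[r]
        else:
            shape = chain.mu[r] ** 2 / chain.s2[r]
            scale = chain.s2[r] / chain.mu[r]
            intervals[sel] = rng.gamma(shape, scale, size=m)
    return IntervalSequence(intervals=intervals, label="lane")


def random_chain(n_lanes: int, rng: np.random.Generator,
                 equal_means: bool = False) -> LaneRenewalChain:
    """A random irreducible lane chain (test harness for the theorem)."""
    Q = rng.random((n_lanes, n_lanes)) + 0.05
    Q /= Q.sum(axis=1, keepdims=True)
    mu = (np.full(n_lanes, 1.0) if equal_means
          else rng.uniform(0.5, 2.0, size=n_lanes))
    s2 = rng.uniform(0.0, 0.3, size=n_lanes)
    return LaneRenewalChain(mu=mu, s2=s2, Q=Q)
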