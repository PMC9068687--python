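"""Exact discrete form of the renewalization theorem.

A Markov-renewal 'lane' chain is the discrete skeleton of an oscillator
crossing a counting curve: the lane index is the crossing point, a
transition matrix Q carries the only memory, and each lane draws its
interval from its own distribution.  First-step analysis gives the lag-k
interval correlations in closed form — and whenever all lanes share the same
conditional *mean* (the mean-return-time condition), every lag correlation
is exactly zero, for arbitrary Q and arbitrary per-lane variances.
"""

import numpy as np

import mrtphase as mp

# memory via Q, unequal means -> correlated intervals
chain = mp.LaneRenewalChain(mu=np.array([1.0, 2.0]),
                            s2=np.array([0.0, 0.0]),
                            Q=np.array([[0.9, 0.1], [0.2, 0.8]]))
mean, var, cov, rho1 = mp.exact_interval_moments(chain, 1)
print(f"two-lane chain: <I> = {mean:.4f}, rho_1 = {rho1:.4f} (exact)")
seq = mp.simulate_chain(chain, 200_000, seed=6)
print(f"simulated rho_1 = {mp.scc(seq, 1).rho[1]:.4f} (200k intervals)")

# same memory, equal means -> correlations vanish identically
rng = np.random.default_rng(7)
worst = 0.0
for _ in range(50):
    c = mp.lanes.random_chain(5, rng, equal_means=True)
    worst = max(worst, float(np.abs(mp.exact_scc(c, 5)).max()))
print(f"\n50 random equal-mean chains: max |rho_k|, k=1..5 = {worst:.2e}")
print("equalizing the conditional means (what the MRT isochron does for a")
print("continuous oscillator) removes every linear interval correlation.")
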