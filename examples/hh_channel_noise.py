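"""Channel-noise Hodgkin–Huxley: threshold spikes vs isochron passages.

Simulates the 14-dimensional diffusion approximation (voltage + 8 sodium +
5 potassium channel-state fractions, all noise in the gating variables) and
extracts interspike intervals by voltage-threshold upcrossings and
interphase intervals by passages of the deterministic limit-cycle isochron.
"""

import numpy as np

import mrtphase as mp

spec = mp.HHSpec()  # eps = 0.0281, V_th = -20 mV, I_app = 10
cycle = mp.hh_limit_cycle(spec)
print(f"deterministic period T* = {cycle.period:.3f} ms")

run = mp.hh_single_run(spec, n_isi=400, dt=spec.dt, seed=5, cycle=cycle)
si = mp.interval_summary(run["isi"])
sp = mp.interval_summary(run["ipi"])
print(f"ISI: n={si.n}  mean={si.mean:.3f} ms  CV={si.cv:.3f}")
print(f"IPI: n={sp.n}  mean={sp.mean:.3f} ms  CV={sp.cv:.3f}")
c_isi = mp.scc(run["isi"], 3)
c_ipi = mp.scc(run["ipi"], 3)
print(f"rho_1(ISI) = {c_isi.rho[1]:+.4f} +- {c_isi.se[1]:.4f}")
print(f"rho_1(IPI) = {c_ipi.rho[1]:+.4f} +- {c_ipi.se[1]:.4f}")
print("\nAt this run length both estimates sit inside the null band; the")
print("ensemble experiment (mrtphase run hh_ensemble) resolves the systematic")
print("difference: threshold-counted ISIs are more negatively correlated")
print("than isochron-counted IPIs in every run.")
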