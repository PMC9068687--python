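"""Counting-curve geometry controls interval correlations (GSP oscillator).

Simulates the planar two-limit-cycle oscillator for ~800 rotations and counts
the same trajectory three ways: by a spoke (fixed angle), by the analytic
mean-return-time isochron, and by a five-fold twisted copy of that isochron.
The spoke gives strongly positive serial correlations (slow inner /fast outer
cycle alternation), the MRT isochron removes them, and the over-twisted curve
overshoots into slightly negative correlations.
"""

import numpy as np

import mrtphase as mp

spec = mp.GSPSpec()  # sigma=0.37, omega=2, gamma=1, c=1.875, radii 0.5/4.0
report = mp.run_gsp(spec, 800, dt=1e-4, seed=1, k_max=5)

print(f"mean rotation period 2*pi/omega_bar = {report['mean_period']:.4f}")
for kind in ("spoke", "gsp_isochron", "gsp_twisted"):
    s = report["summary"][kind]
    c = report["scc"][kind]
    print(f"{kind:>13}: n={s.n:5d}  mean={s.mean:.3f}  CV={s.cv:.3f}  "
          f"rho_1 = {c.rho[1]:+.3f} +- {c.se[1]:.3f}")

print("\nrho_1 is the lag-one correlation of successive rotation intervals:")
print("positive for the spoke, consistent with zero for the MRT isochron,")
print("slightly negative for the twisted curve.  The IPI CV exceeds the ISI")
print("CV because removing positive correlations must preserve the")
print("long-term Fano factor.")
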