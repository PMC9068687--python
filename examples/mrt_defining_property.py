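"""The defining property of the mean-return-time isochron.

Starting anywhere on the MRT isochron, the mean first-passage time to its
2*pi-shifted copy equals the oscillator's mean rotation period — the radius
of the start point does not matter.  This script verifies that by direct
Monte-Carlo first-passage simulation from four start radii.
"""

import numpy as np
from scipy import stats

import mrtphase as mp

spec = mp.GSPSpec()
omega_bar = mp.gsp_mean_frequency(spec)
iso = mp.gsp_isochron(spec, omega_bar)
print(f"omega_bar = {omega_bar:.6f}  =>  mean period = {iso.mean_period:.4f}")

samples = mp.gsp_mrt_passage_times(spec, iso, [0.8, 1.5, 2.5, 3.5],
                                   n_samples=300, dt=1e-4, seed=2)
for r, times in samples.items():
    se = times.std(ddof=1) / np.sqrt(times.size)
    print(f"start radius {r:.1f}: mean passage time "
          f"{times.mean():.3f} +- {se:.3f}")

p = stats.f_oneway(*samples.values()).pvalue
print(f"\nANOVA across start radii: p = {p:.3f} (no radius dependence means")
print("the curve satisfies the mean-return-time condition; every mean above")
print(f"should agree with {iso.mean_period:.3f} within its standard error).")
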