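# Methods

## The question the package answers

A noisy oscillator — a spiking neuron, a bistable rotator — induces a point
process once one decides *what counts as a completed rotation*.  The usual
choices (a voltage threshold, a spoke of the annulus) produce interval
sequences with serial correlations: positive when the system alternates
between a slow and a fast mode, negative when a slow adaptation variable
carries memory across resets.  For a Markov process, the *only* channel
through which interval `i` can influence interval `i+1` is the state at the
shared crossing point.  If the counting curve is chosen so that the expected
time to complete the next rotation is the same from every point of the curve
— the defining property of the mean-return-time (MRT) isochron — that channel
carries no linear information and the lag-k correlation coefficient

    rho_k = <dI_i dI_{i+k}> / <dI_i^2>,   dI = I - <I>,

vanishes for every k >= 1.  The package implements that entire argument as
runnable code: three oscillator models, the isochrons, the event extraction,
the interval statistics, and an exact discrete oracle of the theorem.

## Models (the synthetic-data generators)

All stochastic integration is explicit Euler–Maruyama in the Itô convention;
one seeded `numpy` Generator per trajectory; ensembles use `seed + run_index`.
The simulators *are* the study conditions: their defaults are the parameter
sets the analysis is reported at, and the tests run at those defaults.

**GSP oscillator** (polar, isotropic):
`drho = g(rho) dt + sigma rho dW`, `dphi = f(rho) dt` with
`g = rho(1-rho)(3-rho)(c-rho) + sigma^2 rho / 2` (the Itô term is part of the
printed drift) and `f = omega + gamma(rho-2) - (1-rho)(3-rho)`.
Defaults `sigma=0.37, omega=2, gamma=1, c=1.875`, reflecting radii
`0.5/4.0`, `dt=1e-4`.  Two stable limit cycles (rho=1 slow, rho=3 fast)
separated by an unstable cycle at rho=c produce metastable switching and
hence positively correlated spoke-counted intervals.  Reflection is by
iterated mirror folding of the post-step radius — exact for driftless
Brownian motion (method of images) and weakly first-order accurate here;
boundary visits are rare by construction.

**ALIF neuron**: `dv = (mu - v - a) dt + sqrt(2D) dW`,
`tau_a da = -a dt`, reset `v -> v_R`, kick `a -> a + delta_a` at threshold.
Defaults `mu=2, tau_a=2, delta_a=1, D=0.1, v_T=1, v_R=0, dt=1e-4`
(mean-driven regime).  The adaptation decay between spikes uses the exact
factor `exp(-dt/tau_a)`; threshold crossings are located by linear
interpolation inside the step, the reset applied at the interpolated time and
the remainder of the step re-integrated with drift only (one noiseless
sub-step per spike, bias O(dt), removes dt-quantization of the intervals).

**Stochastic HH**: voltage plus 8 sodium (3 m-gates x 1 h-gate) and
5 potassium (4 n-gates) channel-state fractions.  Gate kinetics follow the
classical squid-axon rate functions with modern sign convention (V in mV);
`C=1, gNa=120, gK=36, gL=0.3, VNa=50, VK=-77, VL=-54.4, I_app=10`,
`dt=0.005 ms`, spike threshold `V_th=-20 mV`.  Each of the 28 directed
transition edges is an independent noise source: an edge with per-capita
rate `r` out of a state with occupancy `x` contributes drift `±r x` and
noise `± eps * sqrt(r x) dW_e`, so every column of the drift and noise
matrices sums to zero and the fraction sums are conserved *exactly* by
construction.  `eps` plays the role of `1/sqrt(channel population)`
(`eps = 0.0281` corresponds to ~1266 channels per type); the voltage
equation itself is noiseless, so spikes are unambiguous upcrossings.
After each step fractions are clipped to [0,1] and renormalized to unit sum
(the standard truncation for this class of diffusion approximations).
At `eps=0` the binomial-product manifold `M_ij = C(3,i) m^i (1-m)^{3-i} h_j`,
`N_k = C(4,k) n^k (1-n)^{4-k}` is invariant and the dynamics reduce to the
4-variable HH model; the test suite verifies this against an independently
coded 4-variable integrator (voltage max-norm < 0.5 mV over 100 ms at
`dt=2e-4`; at coarser steps the two discretizations accumulate an O(dt)
relative phase shift, which is a property of explicit Euler, not of the
manifold).

## Isochrons

**GSP (exact MRT isochron).**  The mean rotation frequency `omega_bar` is a
ratio of two radial integrals of the stationary weight
`exp(2H(rho))/(sigma rho)^2`, and the isochron angle is the double integral

    phi_I(rho) = 2 * int_{rho-}^{rho} dq int_{rho-}^{q} du
                 (f(u) - omega_bar)/(sigma^2 u^2) * e^{-2(H(q)-H(u))},

where `H` is the antiderivative of `g/(sigma^2 v^2)`, which this system
admits in closed form (a cubic plus logarithms).  The inner integral is
evaluated by a *rescaled running recurrence*: the accumulated integral is
always expressed in the frame of the current upper limit, so only
exponentials of per-step differences of `H` are formed and the weight (which
spans hundreds of log-units for small sigma) can never overflow.  Both
quadratures refine on doubling grids until the relative change is below
1e-6.  With the default parameters `omega_bar = 1.9191` (mean period
3.2740) and the isochron winds ~3.3 turns around the annulus.  The defining
property is verified by Monte-Carlo: mean first-passage times from four
isochron points to the 2*pi-shifted copy agree with the quadrature period
and are radius-independent (ANOVA).

**ALIF / HH (weak-noise approximation).**  For the neuron models the
stochastic MRT isochron is approximated by the deterministic asymptotic
phase, evaluated by running the noiseless flow forward and timing its K-th
return to the anchor section: `theta = 2*pi*(K - tau_K/T*)`, iterated in K
until two successive estimates agree (geometric convergence, ratio
`exp(-T*/tau_a)` for ALIF).  Phase 0 is the post-reset point (ALIF) or the
`V_th` upcrossing (HH).  For stochastic ALIF runs the phase is pre-tabulated
on a 281x281 `(v, a)` mesh over `[-2, v_T] x [0, 4]` and interpolated
bilinearly on `(cos, sin)` (branch-cut free); the interpolation error is
below 1e-4 * 2*pi, an order of magnitude inside the 1e-3 * 2*pi budget.
Isochron level sets are extracted as zero contours of `sin(theta - theta0)`
with a `cos > 0` gate and every point verified by direct flow evaluation;
the phase field is genuinely discontinuous along the set of grazing
threshold crossings, and unverified contour cells there are dropped.

For HH no 14-dimensional mesh is possible.  A two-tier scheme is used: a
coarse phase from nearest-point projection onto the stored limit cycle
(512 samples, Euclidean metric with V scaled by 1/100, index tracked
incrementally within a local window), and a refinement of every 2*pi-level
passage by exact asymptotic-phase evaluation at two stored samples
bracketing the passage (+-0.2 ms), with the event time interpolated linearly
between their exact phase lifts.  Weak noise keeps the trajectory near the
cycle, where the projection is accurate enough to localize the passage to a
few samples; the refinement then carries the accuracy.

## Event extraction and statistics

Events are *first passages* of the lifted rotation progress through
successive 2*pi levels — re-crossings of an already-passed level never
count, which removes the infinitely-many-crossings pathology of white-noise
paths at a curve.  Crossing times are linearly interpolated; mod-2*pi phases
are unwrapped by nearest-integer winding.  The first 10 mean periods and the
first 5 events of every stochastic run are discarded as burn-in.

The SCC uses the stationary single-global-mean estimator with population
variance, so `rho_0 == 1` identically; the null standard error is
`1/sqrt(n-k)`.  The Fano factor is estimated over disjoint windows.  The
conservation identity `CV_ISI^2 (1 + 2 sum rho_k) = CV_IPI^2` (the long-run
count variance cannot depend on how rotations are counted) is checked with
the lag sum truncated at k = 20 — beyond that the correlations of all three
models are far below their standard errors — and a residual standard error
from a 1000-resample block bootstrap (50 contiguous blocks).  The shuffle
test recomputes `rho_1` on uniform random permutations (dedicated seed
stream); the ensemble test is a one-sample t-test on per-run `rho_1` values
at the 5% level.

## The discrete oracle

The `lanes` module is the theorem with all analysis stripped away: crossing
points become a finite lane index, memory becomes a stochastic matrix Q,
per-lane intervals are gamma distributed with independently settable mean
and variance (the derivation is distribution-free, so any family with two
free moments serves).  First-step analysis gives `<I>`, the variance and
every lag covariance in closed form, so the statement *equal conditional
means imply rho_k = 0 exactly, for arbitrary Q and arbitrary per-lane
variances* is assertable to 1e-12 with zero Monte-Carlo error, and the
simulator cross-checks the closed form at 4-standard-error resolution.

## Problem sizes

The standard experiment sizes are: GSP 5,000 rotations (~1.6e8 Euler steps),
ALIF 10,000 spikes (~2e8 steps), HH an ensemble of 20 runs of 2,000
intervals each (~3e7 SDE steps per run plus a comparable refinement budget),
and the MRT Monte-Carlo 4 x 1,000 passages.  The HH ensemble is a
scaled-down version of a 400-run x >10,000-interval study; 20 x 2,000
resolves the sign structure of the correlations and the significance of the
interval-counting contrast, but not effects below ~5e-3 in `rho_1` (see
Limitations).  Inner loops are numba-compiled; chunked drivers keep memory
flat for arbitrarily long runs.

## Design choices where the design was open

* The caption of the standard GSP parameter set prints a coefficient
  "delta = 1.0" that the model equations do not contain; the only speed
  parameter it can denote is gamma, and gamma = 1.0 is used.
* The unprinted HH constants (gate rates, conductances, applied current) use
  the classical squid-axon values; `I_app = 10` puts the deterministic model
  safely in the repetitive-firing regime (period 14.64 ms).
* Horizontal-line counting for ALIF is formulated as the continuous lift
  `2*pi*(spike_count - (a - a0)/delta_a)` with `a0` the adaptation value of
  the limit cycle at threshold; the lines are effectively unbounded to the
  left (no `v_min` cut), which only matters for excursions that never occur
  at the default noise level.
* `hh_build_matrices` takes the current state vectors because the noise
  matrices are state-dependent; omitting them evaluates at the clamped
  binomial equilibrium.

## What the generators do and do not emulate

The simulators realize exactly the model class the theory addresses:
Markovian dynamics whose only inter-rotation memory is the crossing state.
They do not emulate features of real neurons outside that class — colored
or shared input noise, slow non-Markovian adaptation, synaptic network
feedback — so passing tests demonstrate the counting-geometry mechanism,
not that real spike trains can always be renewalized.

## Known limitations

* The neuron-model isochrons are deterministic (weak-noise) stand-ins for
  the true MRT isochrons; at the ALIF default noise this is already visible
  only below the statistical resolution, but at substantially stronger
  noise the IPI correlations would no longer vanish (observed when the
  potassium channel noise is boosted ~2x in the HH model).
* The HH threshold-counting correlation at the default conditions is weak
  (`rho_1(ISI) - rho_1(IPI) = -0.0035 +- 0.0002` paired across runs, with
  the IPI mean consistent with zero).  The paired contrast is highly
  significant, but a 20 x 2,000 one-sample t-test on the raw ISI `rho_1`
  alone does not reach significance at this effect size; reported published
  values for comparable setups are several times larger, which we attribute
  to details of the channel-noise normalisation and drive not fixed by the
  equations here.
* Event counts over a *fixed window* agree across counting curves only up
  to the number of turns the curve itself winds around the annulus; the
  winding-number (rate) invariance is exact, the +-1 window bookkeeping is
  not, for strongly twisted curves.
* `tau_a = 1` is a removable singularity of the closed-form ALIF flow;
  the limit-cycle solver handles it, the compiled phase evaluator does not.
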