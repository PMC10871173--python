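# Methods

This note documents the models, numerical choices and known limitations of
`rspmf`. It is the package's own account of what it computes; every number
quoted here is produced by the test suite or by `scripts/acceptance.py`.

## The transfer-function approach

A spiking neuron driven by many weak synaptic inputs can be summarized by
its *transfer function* F: the mapping from total Poisson input rate R
(kHz) to mean output firing rate (Hz). Under the mean-field assumption —
all neurons of a population, and their inputs, statistically identical and
independent — one transfer function describes the whole population, and a
recurrent population of in-degree N with background drive R_bg is at
equilibrium exactly when

    r = F(R_bg + N·r).

Instead of deriving F analytically (possible only for particular neuron
models, and only in the diffusion limit), the package *measures* F by
simulation and fits a four-parameter form, Refractory SoftPlus:

    F(R) = [ T_ref + ( α · softplus(q√R − σ₀; β) )⁻¹ ]⁻¹
    softplus(x; β) = ln(1 + e^{βx}) / β

The input enters through √D = q√R because fluctuation-driven firing scales
with the square root of the diffusion coefficient D = q²R, not with R.
Inverting through the interspike interval imposes the refractory ceiling
1/T_ref. Parameters:

| parameter | meaning | units | typical LIF fit (q = 5 mV) |
|---|---|---|---|
| α | gain from SoftPlus output to rate | ms⁻¹ per mV·ms^(−1/2) | ≈ 0.011 |
| β | sharpness of the rectification knee | per mV·ms^(−1/2) | ≈ 2.5 |
| σ₀ | input offset (fluctuation threshold) | mV·ms^(−1/2) | ≈ 3.4 |
| T_ref | effective refractory period | ms | ≈ 1.9 |

## Balanced input model

Input is two independent Poisson streams: excitatory at rate ηR with PSPs
+q_e and inhibitory at (1−η)R with −q_i. *Loose EI balance* (zero mean
drive) fixes q_i = q_e·√(η/(1−η))·…, leaving one effective size q with
q_e = q√((1−η)/η), q_i = q√(η/(1−η)) and D = q²R exactly. The package
default is η = 0.8 (PSPs differing 4×: q = 1 mV → q_e = 0.5, q_i = 2 mV);
the symmetric η = 0.5 is used for the model-generalization protocol.
Rates are carried in kHz and times in ms throughout, so D's natural unit
is mV²/ms; transfer curves are sampled at S rates evenly spaced in
D ∈ [0, 100] mV²/ms (at q = 1 mV this spans R ∈ [0, 100] kHz), which
drives all three neuron models into the tens of hertz.

## Simulators

* **LIF (delta PSPs).** Exact event-driven integration: exponential decay
  between events, instantaneous jumps, reset to rest at threshold, state
  frozen for T_ref (events inside the dead time are discarded). A
  clock-driven path (default dt = 0.1 ms, exact per-step propagator,
  same-step events summed) exists for cross-checking; the two agree on
  spike counts as dt → 0 and to <2% at dt = 0.01 ms. Transfer-curve
  measurement and acceptance runs use the event-driven path. The
  event-driven LIF at q ≤ 0.1 mV matches the Siegert first-passage rate of
  the limiting Ornstein–Uhlenbeck process within Monte-Carlo error (tested
  at 3 combined standard errors).
* **Izhikevich.** The canonical two-variable quadratic model
  (regular-spiking defaults a = 0.02, b = 0.2, c = −65, d = 8), forward
  Euler at dt = 0.1 ms with the voltage advanced in two half steps, spike
  and reset at v ≥ 30 mV. Synapses are alpha-shaped currents propagated
  exactly (the alpha kernel is a linear filter). The model is
  dimensionless in capacitance, so the PSC weight conversion
  w = C_m·q/(e·τ_syn) is applied with a nominal unit capacitance; with
  this convention each event deposits q mV of integrated drive, mirroring
  a delta PSP. This keeps inputs comparable across models but means the
  Izhikevich transfer curve sits at lower absolute rates over the same D
  grid — immaterial to the fit, which adapts α and σ₀.
* **Hodgkin–Huxley.** Standard Na/K/leak kinetics (C_m = 100 pF,
  g_Na = 12 µS, g_K = 3.6 µS, g_L = 30 nS, E_Na = 50, E_K = −77,
  E_L = −54.402 mV), exponential Euler for the gates and forward Euler for
  the voltage at dt = 0.025 ms, separate excitatory (0.2 ms) and
  inhibitory (2 ms) alpha-PSC time constants. A spike is an upward
  crossing of 0 mV; a 2 ms detection lockout stands in for the refractory
  period while the continuous dynamics are never interrupted.

Non-finite states (e.g. Izhikevich blow-up under extreme drive) raise a
`NumericalError` with the spike count reached.

## Fitting

Nonlinear least squares (`scipy.optimize.least_squares`, trust-region
reflective) on the rate residuals, unweighted, with bounds α, β > 0 and
T_ref ≥ 0. Initial guesses are read off the curve: T_ref from the fastest
observed ISI, α from the slope of the upper third against q√R, σ₀ from
the first point exceeding 1% of the maximum rate, β = 1. Three jittered
restarts run only if the first attempt fails to converge; multistart
exploration (30 random starts) finds the same minimum on the reference
curves, so the quoted fits are global. The SoftPlus switches to the exact
ramp at βx > 20, where ln(1+e^{βx})/(βx) − 1 ≈ 1.03·10⁻¹⁰. The reported
error is the residual RMS divided by the maximum observed rate (nrmse).
Standard errors come from the Gauss–Newton covariance at the optimum.

Fit error is assessed against an *independent reference curve* (same
rates, longer duration, different seed): with S = 100 rates at 100 s per
point the LIF fit sits ≈ 0.4% of the maximum rate from a 1000 s/point
reference — below the 0.5% target — and a 5-point curve already fits to a
few percent, reflecting how few parameters the form has.

## Mean-field solver

Fixed points are roots of F(R_bg + N·r·10⁻³) − r (r in Hz, R in kHz),
located by a 2000-point bracketing scan on [0, 1.2 × ceiling] refined by
Brent bisection to 10⁻⁶ Hz, and classified by the loop gain
g = N·10⁻³·F′ (closed-form derivative): stable (g < 1), unstable (g > 1),
half-stable (|g − 1| < 10⁻³, applied only at refined tangencies — a scan
near a fold reports the split pair as distinct stable/unstable points).
The solver agrees with a dense 0.01 Hz sign-change scan on every family
tested.

The saddle-node scan walks integer N (the excess of the consistency curve
beyond the low fixed point flips sign at the fold; the walk is a linear
scan because a second fold can re-absorb the lower pair, making the excess
non-monotone), bisects continuously inside the bracketing integer
interval, then polishes (N*, r*) by solving F = r and N·F′ = 1
simultaneously. Reported: the smallest integer N with multiple fixed
points (the convention in which the critical in-degree is quoted) plus the
continuous tangency (N*, r*).

First-order rate dynamics T·dr/dt = F(N·r + R_bg(t)) − r are integrated
with fixed-step classical Runge–Kutta (default step min(T/10, 0.1 ms));
T = 1 ms is the default for stimulus-following runs, since population
rates track input far faster than the membrane time constant. Stationary
points coincide with the fixed-point solver, perturbations decay with the
linearized timescale T/(1 − g), and a 1 Hz sinusoidal background produces
a near-sinusoidal rate response in the monostable regime.

## Recurrent network simulation

Clock-driven LIF population (delta PSPs) with an axonal-delay ring buffer:
delays i.i.d. uniform on 1–15 ms, rounded to the dt grid. round(η·M)
neurons are excitatory (+q_e), the rest inhibitory (−q_i); presynaptic
sampling ignores identity, so the excitatory fraction of inputs matches
the population fraction in expectation. *Static* wiring gives every
neuron exactly N distinct presynaptic partners (never itself);
*annealed-average* wiring delivers each spike to a Binomial(M, N/M) random
subset with fresh delays, matching the mean input while destroying
temporal correlations. Each neuron also receives its own independent
balanced Poisson background; deliveries landing in a refractory target
are discarded (frozen state). The warm-up protocol adds a purely
excitatory per-neuron Poisson stream ramping linearly from its amplitude
(default R_bg) to zero over 1 s; warm-up spikes never enter rate
estimates.

Population activity is binned at 1 ms (spikes per bin / (M · bin)), and
the binned series is summarized by an Ornstein–Uhlenbeck fit: mean,
stationary standard deviation σ, and timescale from the lag-1
autoregression. On synthetic AR(1) paths all three recover within 10%.

## What the generator emulates — and what it does not

All data in this package is synthetic by construction: the simulators
*are* the study system. The conditions baked into the defaults are the
study conditions — η = 0.8 (η = 0.5 for generalization sweeps), D-grids
spanning [0, 100] mV²/ms, 100 s per point, S = 500 rates for mean-field
fits and S = 100 for convergence work, uniform 1–15 ms delays, M up to
10⁴ at desk scale. Real neural data would add non-Poisson input
statistics, adaptation, heterogeneous cell parameters and non-stationary
backgrounds; passing tests show the pipeline is internally consistent
under its stated input model, not that the fitted constants transfer to
biological recordings.

Finite-size behaviour of the simulated networks, measured by the test
suite:

* fluctuations of the population rate scale as M^(−1/2) (log-log slope
  within [−0.6, −0.4] across M ∈ {10², 10³, 10⁴}) while the mean rate is
  M-independent within a few percent for M ≥ 10³. At M = 100 — where the
  in-degree of 75 means any two neurons share most of their inputs — the
  mean rate is depressed by roughly 40%: the population rate swings by
  ±σ ≈ 45 Hz and the concavity of F at high rates (Jensen's inequality)
  pulls the time-averaged rate well below the fixed point of the mean
  drive. The mean-field equilibrium applies once M ≫ N;
* in the monostable condition (q = 3 mV, R_bg = 10 kHz, N = 75) the
  network equilibrium sits a few percent *above* the mean-field fixed
  point (≈ 89 vs ≈ 85 Hz at M = 10⁴) — shared-input and quenched-wiring
  correlations make recurrent spikes slightly more effective than the
  Poisson input used to calibrate F. The agreement band asserted in the
  tests (7% relative) reflects this measured bias rather than the
  idealized statistical error of the mean, which is far smaller.

## Known limitations

* **The fold rate is ill-conditioned.** For the strong-synapse family
  (q = 5 mV, R_bg = 0.1 kHz) the fitted model reproduces the critical
  in-degree N_c = 51 exactly and the N = 55 watershed (≈ 15.7 Hz), but
  puts the tangency rate at ≈ 27.7 Hz, whereas a nonparametric
  (smoothing-spline) fold of the same raw curve sits at ≈ 33.4 Hz. The
  fold rate depends on the local curvature of F, which a four-parameter
  global fit constrains only weakly: seed-to-seed scatter is ±0.3 Hz, but
  the fit-shape bias is ≈ −18%, and even the spline estimate moves by 5 Hz
  between smoothing choices. Treat reported tangency rates as indicative;
  the critical N and the off-fold fixed points are robust.
* **The literal warm-up cannot ignite the bistable branch.** Ramping an
  extra excitatory drive down from R_bg = 0.1 kHz adds far too little
  input to lift the q = 5 mV network over its ≈ 16 Hz watershed, so
  warm-started runs at the default amplitude remain in the low state and
  practical stability at M = 5000 is 0/10 trivially. The amplitude is
  configurable; with an effective ramp (≈ 2 kHz) the static M = 5000
  network instead locks into a heterogeneous high-rate state (bimodal
  per-neuron rates: ≈ 20% silent, ≈ 20% near the refractory ceiling)
  sustained by the quenched variability of each neuron's
  excitatory/inhibitory in-degree composition, while the annealed network
  — which has no quenched composition — falls back to the low state
  within a few hundred ms. Population-level practical stability in static
  networks is therefore governed by wiring disorder as much as by the
  mean-field fold.
* Only first-order rate dynamics are modelled: no covariances, no
  multi-population coupling, no adaptation variables. Spike-frequency
  adaptation in the Izhikevich model makes its network response lead the
  first-order prediction.
* The Izhikevich network path inherits the unit-capacitance weight
  convention; recurrent simulations are provided for the LIF
  (delta-PSP) model, which is the one used for all quantitative network
  results here.
* No conductance synapses, plasticity, or spatial structure beyond random
  delays.

## Problem sizes

Mean-field pipelines use S = 500 rates × 100 s per point (q = 5 and
q = 3 mV families) and S = 100 × 100 s with a 1000 s/point reference for
fit-quality assessment. Network validation uses M ∈ {10², 10³, 10⁴} × 2 s
recordings for fluctuation scaling and 10 × 2.5 s runs at M = 5000 for
practical stability; these are the package's desk-scale choices for the
published-scale conditions (the originals extend to M = 10⁵ and 50
repetitions).
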