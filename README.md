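# rspmf — Refractory SoftPlus mean-field models of spiking networks

`rspmf` builds data-driven mean-field models of recurrently connected
spiking neural populations. It is aimed at computational neuroscientists
who want population-level predictions (equilibrium firing rates,
bistability, finite-size fluctuations, stimulus responses) for neuron
models whose transfer functions have no tractable analytical form.

The workflow is:

1. **Measure** a neuron's transfer function F(R) — mean firing rate as a
   function of total balanced Poisson input rate R — by direct simulation
   (exact event-driven LIF with delta PSPs; Izhikevich and Hodgkin–Huxley
   with alpha-shaped synaptic currents).
2. **Fit** the four-parameter *Refractory SoftPlus* transfer function

       F(R) = [ T_ref + ( α · softplus(q√R − σ₀; β) )⁻¹ ]⁻¹ ,
       softplus(x; β) = ln(1 + e^{βx}) / β ,

   where q is the effective postsynaptic-potential size, √(q²R) enters
   because fluctuation-driven firing scales with the square root of the
   input diffusion coefficient D = q²R, and T_ref imposes the refractory
   rate ceiling 1/T_ref.
3. **Predict**: the population consistency condition r = F(R_bg + N·r)
   yields equilibrium rates and their stability from the loop gain
   N·F′(R_eff); scanning the in-degree N locates the saddle-node
   bifurcation to bistability; the first-order dynamics
   T·dr/dt = F(N·r + R_bg(t)) − r track time-varying stimuli.
4. **Validate** against full recurrent-network simulations (static
   fixed-in-degree or annealed-average connectivity, axonal delays,
   per-neuron Poisson backgrounds), including Ornstein–Uhlenbeck fits of
   the finite-size population-rate fluctuations, which scale as M^(−1/2).

Inputs are balanced: an excitatory fraction η of events delivers +q_e and
the rest −q_i, with q_i = q_e·η/(1−η) so the mean drive is zero
(loose EI balance) and firing is purely fluctuation-driven.

## Worked example: bifurcation analysis of a strong-synapse population

```python
import rspmf

curve = rspmf.measure_transfer_curve(
    rspmf.LIFParams(), q=5.0, eta=0.8, S=500, duration=100.0, seed=12
)
fit = rspmf.fit_refractory_softplus(curve)
print(fit.summary())

mf = fit.mean_field(0, 0.1)          # background rate R_bg = 0.1 kHz
bif = mf.find_bifurcation((0, 90))
print(f"critical in-degree N_c = {bif.n_critical}, tangency {bif.r_tangent:.1f} Hz")
for fp in mf.with_n(55).fixed_points():
    print(f"N=55: {fp.rate:7.2f} Hz  gain {fp.gain:5.2f}  {fp.stability}")
```

prints

```
Refractory SoftPlus transfer-function fit
=============================================
model: lif   q = 5.0 mV   eta = 0.8
points: 500   T per point: 100.0 s
converged: True   nrmse: 0.009907
---------------------------------------------
   param     estimate      std err
   alpha     0.010817     0.000137
    beta       2.4697        0.125
  sigma0       3.4203        0.023
   t_ref       1.9062        0.146
=============================================
critical in-degree N_c = 51, tangency 27.7 Hz
N=55:    0.05 Hz  gain  0.05  stable
N=55:   15.66 Hz  gain  1.39  unstable
N=55:   47.00 Hz  gain  0.75  stable
```

Reading this: the LIF transfer curve (500 input rates, 100 s each, PSP
size 5 mV) is fitted to about 1% of its maximum rate; the fitted
refractory period (1.91 ms) recovers the simulated 2 ms dead time. With a
sparse 0.1 kHz background, the population is monostable up to N = 50
recurrent inputs per neuron and bistable from N = 51: at N = 55 a quiet
state (0.05 Hz) and an active state (47 Hz) coexist, separated by an
unstable watershed at 15.7 Hz — any fluctuation through it tips the
population to the other basin. The loop gain column shows the stability
classification (gain < 1 stable).

A network-level cross-check of the same condition:

```python
from rspmf.network import NetworkConfig, simulate_network, fit_ou
cfg = NetworkConfig(m_total=1000, n_in=75, q=3.0, r_bg=10.0, seed=3)
res = simulate_network(cfg, duration=2.0, record_spikes=False)
print(fit_ou(res.trace, discard_ms=200))
```

gives a mean population rate within a few percent of the mean-field fixed
point and an OU fluctuation amplitude that shrinks as M^(−1/2).

There is also a thin CLI (`rspmf fit-transfer | bifurcation | network |
dynamics | sweep`), each subcommand taking `--config <json> --seed
--out-dir` and writing CSV/JSON artifacts plus a `run.log`.

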