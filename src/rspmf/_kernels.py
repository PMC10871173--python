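"""Numba kernels for the spiking simulators.

All kernels are nopython-compiled and use numba's internal RNG, seeded
explicitly at the top of each call, so a (seed, parameters) pair fully
determines the output.  Times are ms, rates kHz, voltages mV.

Status codes returned by the integrators: 0 = ok, 1 = non-finite state
(blow-up), 2 = spike buffer overflow.
"""

from __future__ import annotations

import numpy as np
from numba import njit

STATUS_OK = 0
STATUS_BLOWUP = 1
STATUS_OVERFLOW = 2


# ---------------------------------------------------------------------------
# LIF, event-driven (exact between events; delta PSPs)
# ---------------------------------------------------------------------------


@njit(cache=True)
def lif_poisson_counts(
    tau, v_gap, t_ref, qe, qi, p_exc, rate, duration, seed, checkpoints
):
    """Exact event-driven LIF under merged balanced Poisson input.

    The excitatory and inhibitory streams are generated as one Poisson
    process of total rate ``rate`` whose events are excitatory with
    probability ``p_exc`` (thinning).  Returns cumulative spike counts at
    each checkpoint time (sorted ascending, last == duration).
    """
    np.random.seed(seed)
    ncp = checkpoints.shape[0]
    counts = np.zeros(ncp, dtype=np.int64)
    if rate <= 0.0:
        return counts
    inv_rate = 1.0 / rate
    v = 0.0
    t = 0.0
    t_last = 0.0
    t_free = 0.0
    n = 0
    ci = 0
    while True:
        t += np.random.exponential(inv_rate)
        if t >= duration:
            break
        if t < t_free:
            continue
        v *= np.exp(-(t - t_last) / tau)
        t_last = t
        if np.random.random() < p_exc:
            v += qe
        else:
            v -= qi
        if v >= v_gap:
            while ci < ncp and checkpoints[ci] < t:
                counts[ci] = n
                ci += 1
            n += 1
            v = 0.0
            t_free = t + t_ref
            t_last = t_free
    while ci < ncp:
        counts[ci] = n
        ci += 1
    return counts


@njit(cache=True)
def lif_event_driven(
    tau, v_gap, t_ref, exc_times, inh_times, qe, qi, duration, out_times
):
    """Exact event-driven LIF on explicit sorted event streams.

    Writes spike times into ``out_times`` and returns the spike count.
    """
    ne = exc_times.shape[0]
    ni = inh_times.shape[0]
    ie = 0
    ii = 0
    v = 0.0
    t_last = 0.0
    t_free = 0.0
    n = 0
    cap = out_times.shape[0]
    while ie < ne or ii < ni:
        if ii >= ni or (ie < ne and exc_times[ie] <= inh_times[ii]):
            t = exc_times[ie]
            dq = qe
            ie += 1
        else:
            t = inh_times[ii]
            dq = -qi
            ii += 1
        if t >= duration:
            break
        if t < t_free:
            continue
        v *= np.exp(-(t - t_last) / tau)
        t_last = t
        v += dq
        if v >= v_gap:
            if n >= cap:
                return -1
            out_times[n] = t
            n += 1
            v = 0.0
            t_free = t + t_ref
            t_last = t_free
    return n


@njit(cache=True)
def lif_clock_driven(tau, v_gap, t_ref, dt, drive, out_times):
    """Clock-driven LIF on a per-step voltage-increment array ``drive``.

    Exponential decay is applied with the exact per-step propagator; all
    events inside a step are summed into one increment (pre-binned by the
    caller).  Spike times are reported at the end of the step.
    """
    decay = np.exp(-dt / tau)
    ref_steps = int(round(t_ref / dt))
    n_steps = drive.shape[0]
    v = 0.0
    refc = 0
    n = 0
    cap = out_times.shape[0]
    for s in range(n_steps):
        if refc > 0:
            refc -= 1
            continue
        v = v * decay + drive[s]
        if v >= v_gap:
            if n >= cap:
                return -1
            out_times[n] = (s + 1) * dt
            n += 1
            v = 0.0
            refc = ref_steps
    return n


# ---------------------------------------------------------------------------
# Izhikevich, clock-driven with alpha PSCs
# ---------------------------------------------------------------------------


@njit(cache=True)
def izhikevich_run(
    a, b, c, d, tau_e, tau_i, jump_e, jump_i,
    exc_counts, inh_counts, i_const, dt, out_times,
):
    """Izhikevich quadratic model with alpha-shaped synaptic currents.

    ``jump_e``/``jump_i`` are the increments applied to the alpha-filter
    derivative state per presynaptic event (w * e / tau_syn for peak w).
    The v update uses two half steps as in the model's original discrete
    scheme.  Returns (n_spikes, status).
    """
    n_steps = exc_counts.shape[0]
    v = c
    u = b * v
    se = 0.0
    je = 0.0
    si = 0.0
    ji = 0.0
    ee = np.exp(-dt / tau_e)
    ei = np.exp(-dt / tau_i)
    n = 0
    cap = out_times.shape[0]
    for s in range(n_steps):
        se = ee * (se + dt * je)
        je = ee * je + jump_e * exc_counts[s]
        si = ei * (si + dt * ji)
        ji = ei * ji + jump_i * inh_counts[s]
        current = se - si + i_const
        half = 0.5 * dt
        v += half * (0.04 * v * v + 5.0 * v + 140.0 - u + current)
        v += half * (0.04 * v * v + 5.0 * v + 140.0 - u + current)
        u += dt * a * (b * v - u)
        if not np.isfinite(v):
            return n, STATUS_BLOWUP
        if v >= 30.0:
            if n >= cap:
                return n, STATUS_OVERFLOW
            out_times[n] = (s + 1) * dt
            n += 1
            v = c
            u += d
    return n, STATUS_OK


# ---------------------------------------------------------------------------
# Hodgkin-Huxley, clock-driven with alpha PSCs
# ---------------------------------------------------------------------------


@njit(cache=True, inline="always")
def _vtrap(x, scale):
    # x / (1 - exp(-x/scale)) with the removable singularity at x = 0
    y = x / scale
    if abs(y) < 1e-7:
        return scale * (1.0 + 0.5 * y)
    return x / (1.0 - np.exp(-y))


@njit(cache=True)
def hh_run(
    c_m, g_na, g_k, g_l, e_na, e_k, e_l, t_ref,
    tau_e, tau_i, jump_e, jump_i,
    exc_counts, inh_counts, i_const, dt, v0, out_times,
):
    """Standard Na/K/leak Hodgkin-Huxley neuron with alpha PSCs.

    Gating variables use exponential Euler, the voltage forward Euler.  A
    spike is an upward crossing of 0 mV; crossings within ``t_ref`` of the
    previous spike are ignored (detection lockout, dynamics continue).
    Returns (n_spikes, status).
    """
    n_steps = exc_counts.shape[0]
    v = v0
    # steady-state gating at v0
    an = 0.01 * _vtrap(v + 55.0, 10.0)
    bn = 0.125 * np.exp(-(v + 65.0) / 80.0)
    am = 0.1 * _vtrap(v + 40.0, 10.0)
    bm = 4.0 * np.exp(-(v + 65.0) / 18.0)
    ah = 0.07 * np.exp(-(v + 65.0) / 20.0)
    bh = 1.0 / (1.0 + np.exp(-(v + 35.0) / 10.0))
    m = am / (am + bm)
    h = ah / (ah + bh)
    nn = an / (an + bn)
    se = 0.0
    je = 0.0
    si = 0.0
    ji = 0.0
    ee = np.exp(-dt / tau_e)
    eei = np.exp(-dt / tau_i)
    n = 0
    cap = out_times.shape[0]
    last_spike = -1e30
    v_prev = v
    for s in range(n_steps):
        se = ee * (se + dt * je)
        je = ee * je + jump_e * exc_counts[s]
        si = eei * (si + dt * ji)
        ji = eei * ji + jump_i * inh_counts[s]
        i_syn = se - si + i_const
        i_ion = (
            g_na * m * m * m * h * (v - e_na)
            + g_k * nn * nn * nn * nn * (v - e_k)
            + g_l * (v - e_l)
        )
        v_prev = v
        v += dt * (i_syn - i_ion) / c_m
        if not np.isfinite(v) or abs(v) > 1e3:
            return n, STATUS_BLOWUP
        # gates: exponential Euler toward their voltage-dependent targets
        an = 0.01 * _vtrap(v + 55.0, 10.0)
        bn = 0.125 * np.exp(-(v + 65.0) / 80.0)
        am = 0.1 * _vtrap(v + 40.0, 10.0)
        bm = 4.0 * np.exp(-(v + 65.0) / 18.0)
        ah = 0.07 * np.exp(-(v + 65.0) / 20.0)
        bh = 1.0 / (1.0 + np.exp(-(v + 35.0) / 10.0))
        tm = 1.0 / (am + bm)
        th = 1.0 / (ah + bh)
        tn = 1.0 / (an + bn)
        m += (am * tm - m) * (1.0 - np.exp(-dt / tm))
        h += (ah * th - h) * (1.0 - np.exp(-dt / th))
        nn += (an * tn - nn) * (1.0 - np.exp(-dt / tn))
        t_now = (s + 1) * dt
        if v_prev < 0.0 <= v and t_now - last_spike >= t_ref:
            if n >= cap:
                return n, STATUS_OVERFLOW
            out_times[n] = t_now
            n += 1
            last_spike = t_now
    return n, STATUS_OK


# ---------------------------------------------------------------------------
# Recurrent LIF network (delta PSPs, axonal delays, static or annealed wiring)
# ---------------------------------------------------------------------------


@njit(cache=True)
def lif_network_run(
    m_total, tau, v_gap, t_ref, dt,
    qe, qi, n_exc,
    conn_ptr, conn_tgt, conn_dly,
    annealed, p_trans, dly_lo, dly_hi,
    eta, bg_rate, extra_exc_rate,
    bin_steps,
    record_spikes, spike_times, spike_ids,
    seed,
):
    """Clock-driven recurrent LIF population with delta PSPs.

    Each neuron receives an independent balanced Poisson background at
    per-step total rate ``bg_rate[s]`` (kHz) split eta/(1-eta), plus an
    optional purely excitatory drive ``extra_exc_rate[s]`` (warm-up ramp or
    stimulus).  Static wiring is CSR out-adjacency (targets + integer delay
    slots); annealed mode delivers each spike to a Binomial(M, p_trans)
    random subset (distinct targets, self excluded) with per-delivery
    uniform delays in [dly_lo, dly_hi] slots.  Neurons 0..n_exc-1 are
    excitatory (+qe), the rest inhibitory (-qi).  Deliveries landing inside
    a target's refractory period are discarded (state frozen).

    Returns (bin_counts, n_spikes, status).
    """
    np.random.seed(seed)
    M = m_total
    n_steps = bg_rate.shape[0]
    L = dly_hi + 1  # ring-buffer depth covers the largest delay
    buf = np.zeros((L, M))
    v = np.zeros(M)
    refc = np.zeros(M, dtype=np.int64)
    decay = np.exp(-dt / tau)
    ref_steps = int(round(t_ref / dt))
    n_bins = n_steps // bin_steps
    bin_counts = np.zeros(n_bins, dtype=np.int64)
    cap = spike_times.shape[0]
    n = 0
    scratch = np.empty(4096, dtype=np.int64)  # annealed target list per spike
    for s in range(n_steps):
        lam_e = eta * bg_rate[s] * dt
        lam_i = (1.0 - eta) * bg_rate[s] * dt
        lam_x = extra_exc_rate[s] * dt
        idx = s % L
        b = s // bin_steps
        for i in range(M):
            if refc[i] > 0:
                refc[i] -= 1
                buf[idx, i] = 0.0
                continue
            vi = v[i] * decay + buf[idx, i]
            buf[idx, i] = 0.0
            if lam_e > 0.0:
                vi += qe * np.random.poisson(lam_e)
            if lam_i > 0.0:
                vi -= qi * np.random.poisson(lam_i)
            if lam_x > 0.0:
                vi += qe * np.random.poisson(lam_x)
            if vi >= v_gap:
                # spike
                if b < n_bins:
                    bin_counts[b] += 1
                if record_spikes:
                    if n >= cap:
                        return bin_counts, n, STATUS_OVERFLOW
                    spike_times[n] = (s + 1) * dt
                    spike_ids[n] = i
                n += 1
                vi = 0.0
                refc[i] = ref_steps
                w = qe if i < n_exc else -qi
                if annealed:
                    k = np.random.binomial(M, p_trans)
                    if k > scratch.shape[0]:
                        k = scratch.shape[0]
                    nk = 0
                    while nk < k:
                        tgt = np.random.randint(0, M)
                        if tgt == i:
                            continue
                        dup = False
                        for j in range(nk):
                            if scratch[j] == tgt:
                                dup = True
                                break
                        if dup:
                            continue
                        scratch[nk] = tgt
                        nk += 1
                        dly = np.random.randint(dly_lo, dly_hi + 1)
                        buf[(s + dly) % L, tgt] += w
                else:
                    for e in range(conn_ptr[i], conn_ptr[i + 1]):
                        buf[(s + conn_dly[e]) % L, conn_tgt[e]] += w
            v[i] = vi
    return bin_counts, n, STATUS_OK
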