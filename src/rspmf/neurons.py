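"""Single-neuron simulators and empirical transfer-curve measurement.

Three spiking models are provided, all driven by balanced Poisson input:

* leaky integrate-and-fire (LIF) with delta PSPs — exact event-driven
  integration by default, plus a clock-driven path for cross-checking;
* the Izhikevich quadratic two-variable model with alpha-shaped
  postsynaptic currents;
* the standard Na/K/leak Hodgkin-Huxley model with separate excitatory and
  inhibitory alpha-PSC time constants.

A *transfer curve* samples the neuron's mean firing rate at a grid of total
input rates R chosen so that the diffusion coefficient D = q^2 R is evenly
spaced — the empirical material to which the Refractory SoftPlus transfer
function is fitted.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict

import numpy as np

from . import _kernels
from .balance import balanced_psp_sizes, poisson_streams, psc_weight, rate_grid

__all__ = [
    "LIFParams",
    "IzhikevichParams",
    "HHParams",
    "SpikeTrain",
    "TransferCurve",
    "simulate_lif",
    "simulate_izhikevich",
    "simulate_hh",
    "measure_transfer_curve",
    "NumericalError",
]


class NumericalError(RuntimeError):
    """Integration produced a non-finite state (blow-up)."""


@dataclass(frozen=True)
class LIFParams:
    """Leaky integrate-and-fire parameters.

    Voltage is measured relative to rest, so only the gap
    ``v_thresh - v_rest`` enters the dynamics.
    """

    tau_m: float = 10.0      # membrane time constant (ms)
    v_rest: float = -70.0    # resting potential (mV)
    v_thresh: float = -55.0  # threshold (mV)
    t_ref: float = 2.0       # absolute refractory period (ms)
    dt: float = 0.1          # clock-driven integration step (ms)

    def __post_init__(self) -> None:
        if self.tau_m <= 0:
            raise ValueError("tau_m must be positive")
        if self.v_thresh <= self.v_rest:
            raise ValueError("v_thresh must exceed v_rest")
        if self.t_ref < 0:
            raise ValueError("t_ref must be non-negative")
        if self.dt <= 0:
            raise ValueError("dt must be positive")

    @property
    def v_gap(self) -> float:
        return self.v_thresh - self.v_rest


@dataclass(frozen=True)
class IzhikevichParams:
    """Izhikevich model parameters (canonical regular-spiking defaults).

    The model is dimensionless in capacitance; synaptic weights are
    converted from PSP size with a nominal unit capacitance, so an event of
    equivalent PSP size q deposits q mV when integrated.
    """

    a: float = 0.02
    b: float = 0.2
    c: float = -65.0
    d: float = 8.0
    tau_syn_exc: float = 2.0  # alpha-PSC time constant (ms)
    tau_syn_inh: float = 2.0
    dt: float = 0.1

    def __post_init__(self) -> None:
        if self.a <= 0 or self.b <= 0:
            raise ValueError("a and b must be positive")
        if self.dt <= 0:
            raise ValueError("dt must be positive")

    # effective refractory period for ISI invariants: none imposed
    t_ref: float = 0.0


@dataclass(frozen=True)
class HHParams:
    """Hodgkin-Huxley parameters (textbook squid kinetics, pF/nS/mV/ms).

    ``t_ref`` is a spike-detection lockout; the continuous dynamics are
    never interrupted.
    """

    c_m: float = 100.0       # membrane capacitance (pF)
    g_na: float = 12000.0    # peak sodium conductance (nS)
    g_k: float = 3600.0      # peak potassium conductance (nS)
    g_leak: float = 30.0     # leak conductance (nS)
    e_na: float = 50.0       # reversal potentials (mV)
    e_k: float = -77.0
    e_leak: float = -54.402
    v_init: float = -65.0
    t_ref: float = 2.0       # detection lockout (ms)
    tau_syn_exc: float = 0.2
    tau_syn_inh: float = 2.0
    dt: float = 0.025

    def __post_init__(self) -> None:
        if self.c_m <= 0:
            raise ValueError("c_m must be positive")
        for g in (self.g_na, self.g_k, self.g_leak):
            if g < 0:
                raise ValueError("conductances must be non-negative")
        if self.dt <= 0:
            raise ValueError("dt must be positive")


@dataclass(frozen=True)
class SpikeTrain:
    """Ordered spike times (ms) from a single simulated neuron."""

    times: np.ndarray
    duration: float

    def __post_init__(self) -> None:
        times = np.asarray(self.times, dtype=float)
        object.__setattr__(self, "times", times)
        if times.size and (np.any(np.diff(times) <= 0)):
            raise ValueError("spike times must be strictly increasing")
        if times.size and (times[0] < 0 or times[-1] > self.duration):
            raise ValueError("spike times must lie in [0, duration]")

    @property
    def n_spikes(self) -> int:
        return int(self.times.size)

    @property
    def rate_hz(self) -> float:
        """Mean firing rate in Hz (duration is ms)."""
        return 1000.0 * self.n_spikes / self.duration

    def isis(self) -> np.ndarray:
        return np.diff(self.times)

    def to_csv(self, path, neuron_id: int = 0) -> None:
        arr = np.column_stack(
            [np.full(self.n_spikes, neuron_id), self.times]
        )
        np.savetxt(path, arr, delimiter=",", header="neuron_id,time_ms", comments="")


def _check_stream(times: np.ndarray, name: str) -> np.ndarray:
    times = np.asarray(times, dtype=float)
    if times.size and np.any(np.diff(times) < 0):
        raise ValueError(f"{name} event stream must be sorted")
    return times


def simulate_lif(
    params: LIFParams,
    exc_stream,
    inh_stream,
    qe: float,
    qi: float,
    duration: float,
    method: str = "event",
) -> SpikeTrain:
    """Simulate a LIF neuron with delta PSPs on explicit event streams.

    ``method='event'`` integrates exactly (exponential decay between
    events); ``method='clock'`` bins events onto the dt grid and applies the
    exact per-step propagator, as common grid-based simulators do.
    """
    if duration <= 0:
        raise ValueError("duration must be positive")
    exc = _check_stream(exc_stream, "excitatory")
    inh = _check_stream(inh_stream, "inhibitory")
    cap = int(duration / max(params.t_ref, params.dt)) + 2
    out = np.empty(cap)
    if method == "event":
        n = _kernels.lif_event_driven(
            params.tau_m, params.v_gap, params.t_ref, exc, inh, qe, qi, duration, out
        )
    elif method == "clock":
        n_steps = int(round(duration / params.dt))
        edges = np.arange(n_steps + 1) * params.dt
        drive = qe * np.histogram(exc, bins=edges)[0] - qi * np.histogram(inh, bins=edges)[0]
        n = _kernels.lif_clock_driven(
            params.tau_m, params.v_gap, params.t_ref, params.dt, drive.astype(float), out
        )
    else:
        raise ValueError(f"unknown method {method!r}")
    if n < 0:
        raise NumericalError("spike buffer overflow (rate above refractory ceiling?)")
    return SpikeTrain(times=out[:n].copy(), duration=duration)


def _counts_on_grid(times: np.ndarray, dt: float, n_steps: int) -> np.ndarray:
    edges = np.arange(n_steps + 1) * dt
    return np.histogram(times, bins=edges)[0].astype(np.int64)


def simulate_izhikevich(
    params: IzhikevichParams,
    exc_stream,
    inh_stream,
    w_exc: float,
    w_inh: float,
    duration: float,
    i_const: float = 0.0,
) -> SpikeTrain:
    """Izhikevich neuron driven by alpha PSCs with peak amplitudes w_exc/w_inh."""
    if duration <= 0:
        raise ValueError("duration must be positive")
    exc = _check_stream(exc_stream, "excitatory")
    inh = _check_stream(inh_stream, "inhibitory")
    n_steps = int(round(duration / params.dt))
    ec = _counts_on_grid(exc, params.dt, n_steps)
    ic = _counts_on_grid(inh, params.dt, n_steps)
    cap = n_steps + 1
    out = np.empty(cap)
    n, status = _kernels.izhikevich_run(
        params.a, params.b, params.c, params.d,
        params.tau_syn_exc, params.tau_syn_inh,
        w_exc * math.e / params.tau_syn_exc,
        w_inh * math.e / params.tau_syn_inh,
        ec, ic, i_const, params.dt, out,
    )
    if status == _kernels.STATUS_BLOWUP:
        raise NumericalError(
            f"Izhikevich state became non-finite after {n} spikes "
            f"(params a={params.a}, b={params.b}; reduce dt or input)"
        )
    return SpikeTrain(times=out[:n].copy(), duration=duration)


def simulate_hh(
    params: HHParams,
    exc_stream,
    inh_stream,
    w_exc: float,
    w_inh: float,
    duration: float,
    i_const: float = 0.0,
) -> SpikeTrain:
    """Hodgkin-Huxley neuron driven by alpha PSCs (peak amplitudes in pA)."""
    if duration <= 0:
        raise ValueError("duration must be positive")
    exc = _check_stream(exc_stream, "excitatory")
    inh = _check_stream(inh_stream, "inhibitory")
    n_steps = int(round(duration / params.dt))
    ec = _counts_on_grid(exc, params.dt, n_steps)
    ic = _counts_on_grid(inh, params.dt, n_steps)
    cap = int(duration / max(params.t_ref, 1.0)) + 2
    out = np.empty(cap)
    n, status = _kernels.hh_run(
        params.c_m, params.g_na, params.g_k, params.g_leak,
        params.e_na, params.e_k, params.e_leak, params.t_ref,
        params.tau_syn_exc, params.tau_syn_inh,
        w_exc * math.e / params.tau_syn_exc,
        w_inh * math.e / params.tau_syn_inh,
        ec, ic, i_const, params.dt, params.v_init, out,
    )
    if status == _kernels.STATUS_BLOWUP:
        raise NumericalError("Hodgkin-Huxley state became non-finite; reduce dt or input")
    if status == _kernels.STATUS_OVERFLOW:
        raise NumericalError("spike buffer overflow in Hodgkin-Huxley run")
    return SpikeTrain(times=out[:n].copy(), duration=duration)


@dataclass(frozen=True)
class TransferCurve:
    """Sampled (input rate -> firing rate) pairs with input-model metadata.

    ``rates_in`` in kHz (total Poisson input rate R), ``rates_out`` in Hz.
    ``duration`` is the per-point simulated time in seconds.
    """

    rates_in: np.ndarray
    rates_out: np.ndarray
    q: float
    eta: float
    duration: float
    seed: int = 0
    model: str = "lif"
    model_params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        ri = np.asarray(self.rates_in, dtype=float)
        ro = np.asarray(self.rates_out, dtype=float)
        object.__setattr__(self, "rates_in", ri)
        object.__setattr__(self, "rates_out", ro)
        if ri.shape != ro.shape:
            raise ValueError("rates_in and rates_out must have equal length")
        if np.any(ri < 0) or np.any(np.diff(ri) <= 0):
            raise ValueError("rates_in must be non-negative and strictly increasing")
        if np.any(ro < 0):
            raise ValueError("rates_out must be non-negative")

    def __len__(self) -> int:
        return int(self.rates_in.size)

    def subsample(self, S: int) -> "TransferCurve":
        """Evenly spaced subset of S points (endpoints included)."""
        idx = np.unique(np.round(np.linspace(0, len(self) - 1, S)).astype(int))
        return TransferCurve(
            self.rates_in[idx], self.rates_out[idx], self.q, self.eta,
            self.duration, self.seed, self.model, self.model_params,
        )

    def to_csv(self, path) -> None:
        header = (
            f"# q_mV: {self.q}\n# eta: {self.eta}\n# duration_s: {self.duration}\n"
            f"# seed: {self.seed}\n# model: {self.model}\n"
            f"# model_params: {json.dumps(self.model_params)}\n"
            "R_kHz,rate_Hz"
        )
        np.savetxt(
            path, np.column_stack([self.rates_in, self.rates_out]),
            delimiter=",", header=header, comments="",
        )

    @classmethod
    def from_csv(cls, path) -> "TransferCurve":
        meta: dict = {}
        with open(path) as fh:
            for line in fh:
                if not line.startswith("#"):
                    break
                key, _, val = line[1:].partition(":")
                meta[key.strip()] = val.strip()
        data = np.loadtxt(path, delimiter=",", comments="#", skiprows=len(meta) + 1)
        return cls(
            data[:, 0], data[:, 1],
            q=float(meta.get("q_mV", 1.0)), eta=float(meta.get("eta", 0.5)),
            duration=float(meta.get("duration_s", 0.0)),
            seed=int(meta.get("seed", 0)), model=meta.get("model", "lif"),
            model_params=json.loads(meta.get("model_params", "{}")),
        )


def _model_name(params) -> str:
    return {"LIFParams": "lif", "IzhikevichParams": "izhikevich", "HHParams": "hh"}[
        type(params).__name__
    ]


def measure_transfer_curve(
    model,
    q: float,
    eta: float,
    S: int,
    d_max: float = 100.0,
    duration: float = 100.0,
    seed: int = 0,
    checkpoints: np.ndarray | None = None,
):
    """Measure the empirical transfer curve of a neuron model.

    Builds ``S`` input rates evenly spaced in diffusion coefficient on
    [0, d_max] (mV^2/ms), simulates each for ``duration`` seconds with fresh
    seeded balanced Poisson streams, and returns spikes/duration per point.

    Parameters
    ----------
    model : LIFParams | IzhikevichParams | HHParams
        Neuron model; the LIF uses the exact event-driven path.
    q, eta : float
        Effective PSP size (mV) and excitatory input fraction.
    S : int
        Number of grid points (>= 2).
    d_max : float
        Upper end of the diffusion-coefficient grid (mV^2/ms).
    duration : float
        Simulated time per grid point, in seconds.
    checkpoints : array of float, optional
        Ascending intermediate durations (s).  When given, returns
        ``(curve, rates_at_checkpoints)`` where the extra array has shape
        (S, len(checkpoints)) holding the rate estimate using only the
        first ``checkpoints[j]`` seconds — the material for duration-
        convergence studies.

    Returns
    -------
    TransferCurve, or (TransferCurve, ndarray) when checkpoints are given.
    """
    if S < 2:
        raise ValueError("S must be at least 2")
    if duration <= 0:
        raise ValueError("duration must be positive")
    if q <= 0 and d_max > 0:
        raise ValueError("q must be positive when d_max > 0 (rate undefined)")
    rates = rate_grid(q, d_max, S)
    qe, qi = balanced_psp_sizes(q, eta)
    dur_ms = duration * 1000.0
    if checkpoints is None:
        cps = np.array([dur_ms])
    else:
        cps = np.asarray(checkpoints, dtype=float) * 1000.0
        if np.any(np.diff(cps) <= 0) or cps[-1] > dur_ms:
            raise ValueError("checkpoints must be ascending and <= duration")
        if cps[-1] < dur_ms:
            cps = np.append(cps, dur_ms)
    seeds = np.random.SeedSequence(seed).generate_state(S) % np.uint32(2**31 - 1)
    name = _model_name(model)
    out = np.zeros((S, cps.size))
    for i, R in enumerate(rates):
        if R <= 0:
            continue
        if name == "lif":
            counts = _kernels.lif_poisson_counts(
                model.tau_m, model.v_gap, model.t_ref, qe, qi, eta,
                R, dur_ms, int(seeds[i]), cps,
            )
        else:
            rng = np.random.default_rng(int(seeds[i]))
            n_steps = int(round(dur_ms / model.dt))
            ec = rng.poisson(eta * R * model.dt, n_steps)
            ic = rng.poisson((1.0 - eta) * R * model.dt, n_steps)
            if name == "izhikevich":
                w_e = psc_weight(qe, 1.0, model.tau_syn_exc)
                w_i = psc_weight(qi, 1.0, model.tau_syn_inh)
                cap = n_steps + 1
                buf = np.empty(cap)
                n, status = _kernels.izhikevich_run(
                    model.a, model.b, model.c, model.d,
                    model.tau_syn_exc, model.tau_syn_inh,
                    w_e * math.e / model.tau_syn_exc,
                    w_i * math.e / model.tau_syn_inh,
                    ec, ic, 0.0, model.dt, buf,
                )
            else:
                w_e = psc_weight(qe, model.c_m, model.tau_syn_exc)
                w_i = psc_weight(qi, model.c_m, model.tau_syn_inh)
                cap = int(dur_ms / max(model.t_ref, 1.0)) + 2
                buf = np.empty(cap)
                n, status = _kernels.hh_run(
                    model.c_m, model.g_na, model.g_k, model.g_leak,
                    model.e_na, model.e_k, model.e_leak, model.t_ref,
                    model.tau_syn_exc, model.tau_syn_inh,
                    w_e * math.e / model.tau_syn_exc,
                    w_i * math.e / model.tau_syn_inh,
                    ec, ic, 0.0, model.dt, model.v_init, buf,
                )
            if status == _kernels.STATUS_BLOWUP:
                raise NumericalError(f"{name} blow-up at R={R:.3f} kHz")
            times = buf[:n]
            counts = np.searchsorted(times, cps, side="right")
        out[i] = 1000.0 * counts / cps  # Hz
    params_dict = asdict(model)
    curve = TransferCurve(
        rates, out[:, -1], q=q, eta=eta, duration=duration, seed=seed,
        model=name, model_params=params_dict,
    )
    if checkpoints is None:
        return curve
    return curve, out[:, : np.asarray(checkpoints).size]
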