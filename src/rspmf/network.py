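"""Recurrent spiking-network simulation for validating mean-field predictions.

Networks of M LIF neurons with delta PSPs: each neuron receives its own
independent balanced Poisson background (total rate r_bg per neuron) plus
recurrent input from N presynaptic partners.  Wiring is either *static*
(every neuron samples exactly N distinct presynaptic partners, excluding
itself, with i.i.d. uniform axonal delays) or *annealed-average* (all-to-all
with per-spike transmission probability N/M, which matches the mean input
while destroying temporal correlations).  A fraction eta of the neurons is
excitatory (delivering +qe) and the rest inhibitory (-qi).

Population activity is summarized as the binned population rate; its
finite-size fluctuations around the mean-field fixed point behave like an
Ornstein-Uhlenbeck (OU) process whose stationary standard deviation scales
as M^(-1/2).  *Practical stability* measures how often a nominally stable
upper fixed point survives those fluctuations for a whole recording.
"""

from __future__ import annotations

import math
import time
from dataclasses import dataclass, field

import numpy as np

from . import _kernels
from .balance import balanced_psp_sizes
from .neurons import LIFParams

__all__ = [
    "NetworkConfig",
    "Connectivity",
    "PopulationTrace",
    "OUFit",
    "WarmupProtocol",
    "NetworkResult",
    "build_connectivity",
    "warmup_protocol",
    "simulate_network",
    "binned_rate",
    "fit_ou",
    "fit_inverse_sqrt",
    "fluctuation_scaling",
    "FluctuationScaling",
    "practical_stability",
]


@dataclass(frozen=True)
class NetworkConfig:
    """Recurrent-network specification."""

    m_total: int
    n_in: int
    q: float                      # effective PSP size (mV)
    r_bg: float                   # background total rate per neuron (kHz)
    eta: float = 0.8
    delay_range: tuple[float, float] = (1.0, 15.0)  # ms
    connectivity: str = "static_indegree"            # or 'annealed_average'
    dt: float = 0.1
    neuron: LIFParams = field(default_factory=LIFParams)
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.n_in < self.m_total:
            raise ValueError("need 0 <= n_in < m_total")
        if self.delay_range[0] < self.dt:
            raise ValueError("minimum delay must be at least dt")
        if self.delay_range[1] < self.delay_range[0]:
            raise ValueError("delay_range must be (min, max) with min <= max")
        if self.connectivity not in ("static_indegree", "annealed_average"):
            raise ValueError(f"unknown connectivity mode {self.connectivity!r}")

    @property
    def n_exc(self) -> int:
        return int(round(self.eta * self.m_total))


@dataclass(frozen=True)
class Connectivity:
    """Out-adjacency in CSR form (static) or an annealed spec."""

    mode: str
    m_total: int
    ptr: np.ndarray        # (M+1,) int64; empty adjacency for annealed
    targets: np.ndarray    # int64 edge targets
    delay_slots: np.ndarray  # int64 per-edge delays in dt units
    p_trans: float         # annealed per-spike transmission probability
    dly_lo: int            # delay bounds in dt units
    dly_hi: int

    def in_degrees(self) -> np.ndarray:
        deg = np.zeros(self.m_total, dtype=np.int64)
        np.add.at(deg, self.targets, 1)
        return deg


def build_connectivity(cfg: NetworkConfig) -> Connectivity:
    """Construct the wiring for a network configuration (seeded).

    Static mode: every neuron draws exactly ``n_in`` distinct presynaptic
    partners (never itself); each edge carries an i.i.d. uniform delay on
    ``delay_range`` rounded to the dt grid.  Annealed mode: no explicit
    edges; spikes are delivered all-to-all with probability ``n_in/m_total``
    and per-delivery uniform delays.
    """
    M, N = cfg.m_total, cfg.n_in
    dly_lo = max(1, int(round(cfg.delay_range[0] / cfg.dt)))
    dly_hi = max(dly_lo, int(round(cfg.delay_range[1] / cfg.dt)))
    rng = np.random.default_rng(cfg.seed)
    if cfg.connectivity == "annealed_average":
        empty = np.zeros(M + 1, dtype=np.int64)
        return Connectivity(
            "annealed_average", M, empty, np.empty(0, dtype=np.int64),
            np.empty(0, dtype=np.int64), N / M, dly_lo, dly_hi,
        )
    # in-edges: target j picks N distinct sources != j
    src = np.empty(M * N, dtype=np.int64)
    for j in range(M):
        chosen: set[int] = set()
        base = j * N
        k = 0
        while k < N:
            s = int(rng.integers(0, M))
            if s == j or s in chosen:
                continue
            chosen.add(s)
            src[base + k] = s
            k += 1
    tgt = np.repeat(np.arange(M, dtype=np.int64), N)
    delays = rng.integers(dly_lo, dly_hi + 1, size=M * N).astype(np.int64)
    # convert to out-CSR ordered by source
    order = np.argsort(src, kind="stable")
    out_tgt = tgt[order]
    out_dly = delays[order]
    counts = np.bincount(src, minlength=M)
    ptr = np.zeros(M + 1, dtype=np.int64)
    np.cumsum(counts, out=ptr[1:])
    return Connectivity(
        "static_indegree", M, ptr, out_tgt, out_dly, 0.0, dly_lo, dly_hi
    )


@dataclass(frozen=True)
class WarmupProtocol:
    """Transient excitatory drive ramping linearly to zero.

    Each neuron receives an extra excitatory Poisson stream whose rate
    falls linearly from ``amplitude`` (kHz; default R_bg) to 0 over
    ``warmup_time`` seconds.  Spikes during warm-up are excluded from rate
    estimates; the ramp nudges a bistable network into the basin of the
    upper fixed point before recording starts.
    """

    warmup_time: float = 1.0   # s
    amplitude: float | None = None  # kHz; None -> cfg.r_bg

    def rate_at(self, t_ms: float, cfg: NetworkConfig) -> float:
        amp = cfg.r_bg if self.amplitude is None else self.amplitude
        w_ms = self.warmup_time * 1000.0
        if t_ms >= w_ms:
            return 0.0
        return amp * (1.0 - t_ms / w_ms)


def warmup_protocol(
    cfg: NetworkConfig, warmup_time: float = 1.0, amplitude: float | None = None
) -> WarmupProtocol:
    if warmup_time <= 0:
        raise ValueError("warmup_time must be positive")
    return WarmupProtocol(warmup_time=warmup_time, amplitude=amplitude)


@dataclass(frozen=True)
class PopulationTrace:
    """Binned population firing rate (Hz per neuron)."""

    bin_ms: float
    rates: np.ndarray
    t0: float = 0.0  # ms offset of the first bin

    def __post_init__(self) -> None:
        object.__setattr__(self, "rates", np.asarray(self.rates, dtype=float))

    def __len__(self) -> int:
        return int(self.rates.size)

    def to_csv(self, path) -> None:
        t = self.t0 + np.arange(len(self)) * self.bin_ms
        np.savetxt(
            path, np.column_stack([t, self.rates]), delimiter=",",
            header="t_ms,rate_Hz", comments="",
        )


@dataclass(frozen=True)
class NetworkResult:
    """Output of a recurrent simulation (post-warm-up recording)."""

    trace: PopulationTrace
    spike_times: np.ndarray   # ms, absolute (post-warm-up only)
    spike_ids: np.ndarray
    m_total: int
    duration: float           # recorded span (s)
    warmup: float             # warm-up span (s)
    log: list[str]

    @property
    def mean_rate(self) -> float:
        return float(np.mean(self.trace.rates))


def simulate_network(
    cfg: NetworkConfig,
    duration: float,
    warmup: WarmupProtocol | None = None,
    stimulus=None,
    bin_ms: float = 1.0,
    record_spikes: bool = True,
    connectivity: Connectivity | None = None,
    seed: int | None = None,
) -> NetworkResult:
    """Simulate the recurrent network for ``duration`` seconds.

    ``stimulus`` may be a callable t_ms -> R_bg(t) in kHz replacing the
    constant background; ``warmup`` prepends an unrecorded span with the
    ramped extra excitatory drive.  Spikes during warm-up never enter the
    trace or the spike record.
    """
    if duration <= 0:
        raise ValueError("duration must be positive")
    conn = connectivity if connectivity is not None else build_connectivity(cfg)
    qe, qi = balanced_psp_sizes(cfg.q, cfg.eta)
    p = cfg.neuron
    warm_s = warmup.warmup_time if warmup is not None else 0.0
    total_ms = (warm_s + duration) * 1000.0
    n_steps = int(round(total_ms / cfg.dt))
    t_steps = np.arange(n_steps) * cfg.dt
    if stimulus is None:
        bg = np.full(n_steps, cfg.r_bg)
    else:
        bg = np.array([stimulus(t) for t in t_steps])
    if warmup is not None:
        extra = np.array([warmup.rate_at(t, cfg) for t in t_steps])
    else:
        extra = np.zeros(n_steps)
    bin_steps = max(1, int(round(bin_ms / cfg.dt)))
    if record_spikes:
        ceiling = 1000.0 / p.t_ref if p.t_ref > 0 else 1000.0 / cfg.dt
        cap = int(cfg.m_total * ceiling * (warm_s + duration)) + 1024
        st = np.empty(cap)
        si = np.empty(cap, dtype=np.int64)
    else:
        st = np.empty(1)
        si = np.empty(1, dtype=np.int64)
    run_seed = cfg.seed if seed is None else seed
    kern_seed = int(np.random.SeedSequence(run_seed).generate_state(1)[0] % (2**31 - 1))
    t_wall = time.perf_counter()
    bins, n_spk, status = _kernels.lif_network_run(
        cfg.m_total, p.tau_m, p.v_gap, p.t_ref, cfg.dt,
        qe, qi, cfg.n_exc,
        conn.ptr, conn.targets, conn.delay_slots,
        conn.mode == "annealed_average", conn.p_trans, conn.dly_lo, conn.dly_hi,
        cfg.eta, bg, extra,
        bin_steps,
        record_spikes, st, si,
        kern_seed,
    )
    wall = time.perf_counter() - t_wall
    if status == _kernels.STATUS_OVERFLOW:
        raise RuntimeError(
            f"network spike buffer overflow after {n_spk} spikes "
            f"(population rate beyond the refractory ceiling?)"
        )
    warm_ms = warm_s * 1000.0
    warm_bins = int(round(warm_ms / (bin_steps * cfg.dt)))
    rates = 1000.0 * bins[warm_bins:] / (cfg.m_total * bin_steps * cfg.dt)
    trace = PopulationTrace(bin_ms=bin_steps * cfg.dt, rates=rates, t0=warm_ms)
    if record_spikes:
        times = st[:n_spk]
        ids = si[:n_spk]
        keep = times >= warm_ms
        times, ids = times[keep].copy(), ids[keep].copy()
    else:
        times = np.empty(0)
        ids = np.empty(0, dtype=np.int64)
    log = []
    sec_bins = int(round(1000.0 / (bin_steps * cfg.dt)))
    for s in range(int(math.ceil(len(bins) / sec_bins))):
        chunk = bins[s * sec_bins : (s + 1) * sec_bins]
        rate = 1000.0 * chunk.sum() / (cfg.m_total * len(chunk) * bin_steps * cfg.dt)
        log.append(
            f"second {s + 1}: {int(chunk.sum())} spikes, "
            f"running rate {rate:.2f} Hz, wall {wall:.1f}s total"
        )
    return NetworkResult(
        trace=trace, spike_times=times, spike_ids=ids,
        m_total=cfg.m_total, duration=duration, warmup=warm_s, log=log,
    )


def binned_rate(
    spike_times, m_total: int, bin_ms: float = 1.0, duration_ms: float | None = None,
    t0: float = 0.0,
) -> PopulationTrace:
    """Population rate (Hz) from spike times: counts / (M * bin width)."""
    if bin_ms <= 0:
        raise ValueError("bin_ms must be positive")
    times = np.asarray(spike_times, dtype=float)
    if duration_ms is None:
        duration_ms = float(times.max() - t0) if times.size else bin_ms
    n_bins = int(round(duration_ms / bin_ms))
    edges = t0 + np.arange(n_bins + 1) * bin_ms
    counts = np.histogram(times, bins=edges)[0]
    return PopulationTrace(bin_ms=bin_ms, rates=1000.0 * counts / (m_total * bin_ms), t0=t0)


@dataclass(frozen=True)
class OUFit:
    """Ornstein-Uhlenbeck summary of a binned population-rate series.

    sigma is the stationary standard deviation (the fluctuation amplitude);
    timescale the relaxation time from the lag-1 autoregression.  A
    constant series has sigma 0 and an undefined (NaN) timescale.
    """

    mean: float
    sigma: float
    timescale: float
    n_bins: int
    bin_ms: float

    @property
    def mean_se(self) -> float:
        """Standard error of the mean accounting for OU autocorrelation."""
        if self.sigma == 0 or not np.isfinite(self.timescale):
            return 0.0
        rho = math.exp(-self.bin_ms / self.timescale)
        neff = self.n_bins * (1 - rho) / (1 + rho)
        return self.sigma / math.sqrt(max(neff, 1.0))


def fit_ou(trace: PopulationTrace, discard_ms: float = 0.0) -> OUFit:
    """Fit OU parameters (mean, sigma, timescale) to a binned rate series."""
    n_discard = int(round(discard_ms / trace.bin_ms))
    x = trace.rates[n_discard:]
    if x.size < 100:
        raise ValueError("need at least 100 bins after discard")
    mean = float(np.mean(x))
    sigma = float(np.std(x))
    if sigma == 0.0:
        return OUFit(mean, 0.0, math.nan, x.size, trace.bin_ms)
    xc = x - mean
    rho = float(np.dot(xc[:-1], xc[1:]) / np.dot(xc[:-1], xc[:-1]))
    if rho <= 0:
        timescale = trace.bin_ms  # at or below the bin width: no memory
    elif rho >= 1:
        timescale = math.inf
    else:
        timescale = -trace.bin_ms / math.log(rho)
    return OUFit(mean, sigma, timescale, x.size, trace.bin_ms)


def fit_inverse_sqrt(m_values, sigmas) -> float:
    """Least-squares k for sigma = k * M^(-1/2) (closed form, linear in k)."""
    m = np.asarray(m_values, dtype=float)
    s = np.asarray(sigmas, dtype=float)
    if s.ndim == 1:
        s = s[:, None]
    w = m[:, None] ** -0.5
    return float(np.sum(w * s) / (s.shape[1] * np.sum(m**-1)))


@dataclass(frozen=True)
class FluctuationScaling:
    """Finite-size scaling of population-rate fluctuations."""

    m_values: np.ndarray
    sigmas: np.ndarray        # (n_M, n_reps)
    means: np.ndarray         # (n_M, n_reps)
    k: float                  # fitted sigma = k * M^(-1/2)
    loglog_slope: float
    r_squared: float


def fluctuation_scaling(
    cfgs: list[NetworkConfig],
    n_reps: int = 3,
    duration: float = 2.0,
    warmup: WarmupProtocol | None = None,
    discard_ms: float = 200.0,
) -> FluctuationScaling:
    """sigma(M) across configs differing in M, with the M^(-1/2) fit.

    Fits ``sigma = k * M**-0.5`` by least squares (linear in k) and reports
    the log-log slope of the per-M mean sigma as a model-free check.
    """
    if len(cfgs) < 3:
        raise ValueError("need at least 3 distinct M values")
    m_values = np.array([c.m_total for c in cfgs], dtype=float)
    sig = np.zeros((len(cfgs), n_reps))
    mu = np.zeros((len(cfgs), n_reps))
    for i, cfg in enumerate(cfgs):
        for rep in range(n_reps):
            res = simulate_network(
                cfg, duration, warmup=warmup, record_spikes=False,
                seed=cfg.seed + 7919 * rep,
            )
            fit = fit_ou(res.trace, discard_ms=discard_ms)
            sig[i, rep] = fit.sigma
            mu[i, rep] = fit.mean
    k = fit_inverse_sqrt(m_values, sig)
    mean_sig = sig.mean(axis=1)
    slope, intercept = np.polyfit(np.log(m_values), np.log(mean_sig), 1)
    pred = intercept + slope * np.log(m_values)
    ss_res = np.sum((np.log(mean_sig) - pred) ** 2)
    ss_tot = np.sum((np.log(mean_sig) - np.log(mean_sig).mean()) ** 2)
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    return FluctuationScaling(
        m_values=m_values, sigmas=sig, means=mu, k=k,
        loglog_slope=float(slope), r_squared=float(r2),
    )


def practical_stability(
    cfg: NetworkConfig,
    watershed_hz: float,
    n_sims: int = 50,
    duration: float = 2.5,
    warmup: WarmupProtocol | None = None,
    window_ms: float = 100.0,
) -> float:
    """Fraction of warm-started runs staying above the watershed rate.

    A run 'stays' near the upper fixed point when its trailing
    ``window_ms`` mean rate remains above the unstable fixed-point rate
    ``watershed_hz`` for the entire recording.
    """
    if watershed_hz <= 0:
        raise ValueError("watershed_hz must be positive (no upper fixed point?)")
    if warmup is None:
        warmup = WarmupProtocol()
    stayed = 0
    for s in range(n_sims):
        res = simulate_network(
            cfg, duration, warmup=warmup, record_spikes=False,
            seed=cfg.seed + 104729 * s,
        )
        if _stays_above(res.trace, watershed_hz, window_ms):
            stayed += 1
    return stayed / n_sims


def _stays_above(trace: PopulationTrace, watershed: float, window_ms: float) -> bool:
    w = max(1, int(round(window_ms / trace.bin_ms)))
    x = trace.rates
    if x.size < w:
        return bool(np.mean(x) > watershed)
    csum = np.concatenate([[0.0], np.cumsum(x)])
    rolling = (csum[w:] - csum[:-w]) / w
    return bool(np.all(rolling > watershed))
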