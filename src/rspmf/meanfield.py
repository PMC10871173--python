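"""Mean-field predictions from a fitted transfer function.

Under the mean-field assumption a recurrent population of statistically
identical neurons, each receiving background Poisson input at total rate
R_bg (kHz) plus N recurrent inputs firing at the population rate r (Hz),
is at equilibrium when the rate is self-consistent:

    r = F(R_bg + N * r)

with F the fitted Refractory SoftPlus transfer function.  Roots of the
residual F(R_bg + N r) - r are the population's equilibrium rates; a root
is stable when the loop gain N * F'(R_eff) is below one.  As N grows the
consistency curve rises until it touches the identity line — a saddle-node
bifurcation that creates a bistable regime with stable low/high rates
separated by an unstable watershed.

First-order rate dynamics follow the quasistatic relaxation

    T * dr/dt = F(N r + R_bg(t)) - r

with a single characteristic timescale T, which supports time-varying
background stimuli (steps, sinusoids).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize

from .rsp import RSPParams, refractory_softplus, refractory_softplus_derivative

__all__ = [
    "MeanFieldModel",
    "FixedPoint",
    "BifurcationResult",
    "Stimulus",
    "DynamicsConfig",
    "consistency_residual",
    "find_fixed_points",
    "find_bifurcation",
    "integrate_dynamics",
    "recurrent_fraction",
]

#: |gain - 1| below this marks a half-stable (tangency) point
HALF_STABLE_TOL = 1e-3


@dataclass(frozen=True)
class FixedPoint:
    """A root of the consistency condition with its local stability."""

    rate: float       # Hz
    gain: float       # loop gain N * F'(R_eff), dimensionless
    stability: str    # 'stable' | 'unstable' | 'half_stable'


@dataclass(frozen=True)
class BifurcationResult:
    """Saddle-node location of a mean-field family with N free."""

    monostable: bool
    n_critical: int | None = None   # smallest integer N with multiple fixed points
    n_star: float | None = None     # continuous tangency N
    r_tangent: float | None = None  # Hz


@dataclass(frozen=True)
class MeanFieldModel:
    """Fitted transfer function + connectivity: the mean-field system.

    Parameters
    ----------
    params : RSPParams
        Fitted Refractory SoftPlus parameters.
    q : float
        Effective PSP size (mV) the fit was performed at.
    n_recurrent : int
        In-degree N (recurrent inputs per neuron).
    r_bg : float
        Total background input rate R_bg in kHz; optionally expressed as
        ``n_bg * rate_bg`` by passing those instead.
    """

    params: RSPParams
    q: float
    n_recurrent: int = 0
    r_bg: float = 0.0
    n_bg: int | None = None
    rate_bg: float | None = None

    def __post_init__(self) -> None:
        if self.n_bg is not None and self.rate_bg is not None:
            object.__setattr__(self, "r_bg", self.n_bg * self.rate_bg)
        if self.n_recurrent < 0:
            raise ValueError("n_recurrent must be non-negative")
        if self.r_bg < 0:
            raise ValueError("r_bg must be non-negative")

    # -- transfer function -------------------------------------------------
    def F(self, R):
        """Transfer function: rate (Hz) at total input rate R (kHz)."""
        return refractory_softplus(R, self.params, self.q)

    def r_eff(self, r):
        """Total input rate (kHz) when the population fires at r Hz."""
        return self.r_bg + self.n_recurrent * np.asarray(r, dtype=float) * 1e-3

    def residual(self, r):
        """Consistency residual F(R_bg + N r) - r (Hz)."""
        return self.F(self.r_eff(r)) - np.asarray(r, dtype=float)

    def gain(self, r):
        """Loop gain N * F'(R_eff), the slope of the return map at rate r."""
        dF = refractory_softplus_derivative(self.r_eff(r), self.params, self.q)
        return self.n_recurrent * 1e-3 * dF

    @property
    def ceiling(self) -> float:
        """Refractory rate ceiling 1000/t_ref in Hz (inf when t_ref = 0)."""
        return 1000.0 / self.params.t_ref if self.params.t_ref > 0 else math.inf

    def with_n(self, n: int) -> "MeanFieldModel":
        return MeanFieldModel(self.params, self.q, n, self.r_bg)

    # -- equilibria --------------------------------------------------------
    def fixed_points(
        self, r_max: float | None = None, n_scan: int = 2000, tol: float = 1e-6
    ) -> list[FixedPoint]:
        """All fixed points in [0, r_max], classified by loop gain.

        Dense bracketing scan followed by bisection; for this model family
        the count is 1, 2 (at tangency) or 3.
        """
        if r_max is None:
            if not math.isfinite(self.ceiling):
                raise ValueError("r_max required when t_ref = 0 (no rate ceiling)")
            r_max = 1.2 * self.ceiling
        grid = np.linspace(0.0, r_max, n_scan)
        res = self.residual(grid)
        roots: list[float] = []
        for i in range(len(grid) - 1):
            a, b = res[i], res[i + 1]
            if a == 0.0:
                if not roots or abs(grid[i] - roots[-1]) > 10 * tol:
                    roots.append(float(grid[i]))
            elif a * b < 0:
                r0 = optimize.brentq(
                    lambda r: float(self.residual(r)), grid[i], grid[i + 1],
                    xtol=tol,
                )
                roots.append(float(r0))
        out = []
        for r0 in roots:
            g = float(self.gain(r0))
            if g < 1.0 - HALF_STABLE_TOL:
                stab = "stable"
            elif g > 1.0 + HALF_STABLE_TOL:
                stab = "unstable"
            else:
                stab = "half_stable"
            out.append(FixedPoint(rate=r0, gain=g, stability=stab))
        return out

    # -- bifurcation -------------------------------------------------------
    def find_bifurcation(
        self, n_range: tuple[int, int], n_scan: int = 4000
    ) -> BifurcationResult:
        """Saddle-node location: smallest N with an upper fixed-point pair.

        The tangency is located by bisection on continuous N using the
        maximum of the consistency residual beyond the low fixed point
        (negative while monostable, positive once the upper pair exists),
        then refined by solving F(R_eff) = r and N F'(R_eff) = 1
        simultaneously.
        """
        n_lo, n_hi = n_range
        if self._upper_excess(n_lo, n_scan)[0] > 0:
            raise ValueError("family must be monostable at the lower end of n_range")
        # integer pre-scan: the excess need not be monotone in N (a second
        # fold can re-absorb the lower pair), so locate the first crossing
        first_bistable = None
        for n in range(int(n_lo) + 1, int(n_hi) + 1):
            if self._upper_excess(n, n_scan)[0] > 0:
                first_bistable = n
                break
        if first_bistable is None:
            return BifurcationResult(monostable=True)
        lo, hi = float(first_bistable - 1), float(first_bistable)
        for _ in range(40):
            mid = 0.5 * (lo + hi)
            if self._upper_excess(mid, n_scan)[0] > 0:
                hi = mid
            else:
                lo = mid
        n_star = hi
        _, r_guess = self._upper_excess(n_star, n_scan)

        def system(z):
            n, r = z
            reff = self.r_bg + n * r * 1e-3
            f = refractory_softplus(reff, self.params, self.q)
            df = refractory_softplus_derivative(reff, self.params, self.q)
            return [f - r, n * 1e-3 * df - 1.0]

        sol, info, ier, _ = optimize.fsolve(
            system, [n_star, r_guess], full_output=True
        )
        if ier == 1 and n_lo <= sol[0] <= n_hi and sol[1] > 0:
            n_star, r_tangent = float(sol[0]), float(sol[1])
        else:
            r_tangent = float(r_guess)
        n_critical = int(math.ceil(n_star - 1e-9))
        return BifurcationResult(
            monostable=False, n_critical=n_critical,
            n_star=n_star, r_tangent=r_tangent,
        )

    def _upper_excess(self, n: float, n_scan: int) -> tuple[float, float]:
        """(max residual beyond the low fixed point, argmax rate)."""
        r_max = 1.2 * self.ceiling if math.isfinite(self.ceiling) else 2000.0
        grid = np.linspace(0.0, r_max, n_scan)
        reff = self.r_bg + n * grid * 1e-3
        res = refractory_softplus(reff, self.params, self.q) - grid
        # low fixed point: first sign change from + to -
        neg = np.nonzero(res < 0)[0]
        if neg.size == 0:  # runaway: everything above the line
            return float(np.max(res)), float(grid[np.argmax(res)])
        start = neg[0]
        seg = res[start:]
        k = int(np.argmax(seg))
        return float(seg[k]), float(grid[start + k])

    # -- dynamics ----------------------------------------------------------
    def integrate(
        self, cfg: "DynamicsConfig", r0: float
    ) -> pd.DataFrame:
        """Integrate T dr/dt = F(N r + R_bg(t)) - r with a fixed-step RK4.

        Returns a DataFrame with columns t_ms, rate_Hz, R_bg_kHz.  With a
        constant stimulus the stationary points coincide with
        :meth:`fixed_points`.
        """
        if r0 < 0:
            raise ValueError("r0 must be non-negative")
        h = cfg.step
        n_steps = int(round(cfg.horizon / h))
        t = np.arange(n_steps + 1) * h
        rbg = np.array([cfg.stimulus(tt) for tt in t])
        r = np.empty(n_steps + 1)
        r[0] = r0
        invT = 1.0 / cfg.timescale_T

        def rhs(rr, tt):
            reff = cfg.stimulus(tt) + self.n_recurrent * max(rr, 0.0) * 1e-3
            return invT * (
                float(refractory_softplus(reff, self.params, self.q)) - rr
            )

        for i in range(n_steps):
            ti = t[i]
            k1 = rhs(r[i], ti)
            k2 = rhs(r[i] + 0.5 * h * k1, ti + 0.5 * h)
            k3 = rhs(r[i] + 0.5 * h * k2, ti + 0.5 * h)
            k4 = rhs(r[i] + h * k3, ti + h)
            r[i + 1] = r[i] + h * (k1 + 2 * k2 + 2 * k3 + k4) / 6.0
        return pd.DataFrame({"t_ms": t, "rate_Hz": r, "R_bg_kHz": rbg})

    def recurrent_fraction(self, fp) -> float:
        """Fraction of total input that is recurrent at a fixed point."""
        r = fp.rate if isinstance(fp, FixedPoint) else float(fp)
        rec = self.n_recurrent * r * 1e-3
        tot = self.r_bg + rec
        return rec / tot if tot > 0 else 0.0


# ---------------------------------------------------------------------------
# Stimulus / dynamics configuration
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Stimulus:
    """Time-varying background rate R_bg(t) in kHz.

    kinds: 'constant' (base), 'step' (base before t0, level after),
    'sinusoid' (base + amplitude * sin(2 pi f t)); rates clip at zero.
    """

    kind: str = "constant"
    base: float = 0.0
    amplitude: float = 0.0   # kHz (step level or sinusoid amplitude A_bg)
    freq_hz: float = 0.0     # f_bg for sinusoid
    t0: float = 0.0          # ms, step onset

    def __call__(self, t_ms: float) -> float:
        if self.kind == "constant":
            v = self.base
        elif self.kind == "step":
            v = self.base if t_ms < self.t0 else self.amplitude
        elif self.kind == "sinusoid":
            v = self.base + self.amplitude * math.sin(
                2.0 * math.pi * self.freq_hz * t_ms * 1e-3
            )
        else:
            raise ValueError(f"unknown stimulus kind {self.kind!r}")
        return max(v, 0.0)


@dataclass(frozen=True)
class DynamicsConfig:
    """First-order dynamics configuration.

    timescale_T defaults to 1 ms — the population rate tracks input far
    faster than the membrane time constant, so a small T is appropriate for
    stimulus-following runs.
    """

    stimulus: Stimulus
    timescale_T: float = 1.0   # ms
    horizon: float = 1000.0    # ms
    step: float = 0.1          # ms

    def __post_init__(self) -> None:
        if self.timescale_T <= 0:
            raise ValueError("timescale_T must be positive")
        if not 0 < self.step < self.timescale_T:
            raise ValueError("step must be positive and below timescale_T")


# -- functional wrappers --------------------------------------------------


def consistency_residual(r: float, model: MeanFieldModel) -> float:
    """F(R_bg + N r) - r in Hz."""
    if np.any(np.asarray(r) < 0):
        raise ValueError("r must be non-negative")
    return model.residual(r)


def find_fixed_points(model: MeanFieldModel, r_max: float | None = None, **kw):
    return model.fixed_points(r_max=r_max, **kw)


def find_bifurcation(model: MeanFieldModel, n_range: tuple[int, int], **kw):
    return model.find_bifurcation(n_range, **kw)


def integrate_dynamics(model: MeanFieldModel, cfg: DynamicsConfig, r0: float):
    return model.integrate(cfg, r0)


def recurrent_fraction(model: MeanFieldModel, fp) -> float:
    return model.recurrent_fraction(fp)
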