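"""Balanced excitatory-inhibitory Poisson input model.

A neuron embedded in a large network receives a barrage of excitatory and
inhibitory postsynaptic potentials (PSPs).  We model this input as two
independent homogeneous Poisson processes: an excitatory stream at rate
``eta * R`` delivering PSPs of size ``+qe`` and an inhibitory stream at rate
``(1 - eta) * R`` delivering ``-qi``, where ``R`` is the total input rate.

In the diffusion limit the membrane potential then performs an
Ornstein-Uhlenbeck excursion with drift

    mu = eta*R*qe - (1 - eta)*R*qi        [mV/ms]

and diffusion coefficient

    D = eta*R*qe**2 + (1 - eta)*R*qi**2   [mV^2/ms]

*Loose EI balance* is the choice ``mu = 0``, which makes firing purely
fluctuation driven.  Balance ties ``qi`` to ``qe`` and allows both to be
expressed through a single effective PSP size ``q`` with the convenient
identity ``D = q**2 * R``.

Units: rates are carried in kHz (events/ms) and times in ms throughout the
package, so D's natural unit is mV^2/ms.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "InputModel",
    "balanced_psp_sizes",
    "drift_and_diffusion",
    "rate_grid",
    "psc_weight",
    "poisson_streams",
]


def balanced_psp_sizes(q: float, eta: float) -> tuple[float, float]:
    """Excitatory/inhibitory PSP sizes (qe, qi) with zero mean drive.

    Solves ``mu = 0`` together with the definition of the effective PSP
    size ``q``, giving ``qe = q*sqrt((1-eta)/eta)`` and
    ``qi = q*sqrt(eta/(1-eta))``.

    Parameters
    ----------
    q : float
        Effective PSP size in mV (>= 0).
    eta : float
        Excitatory fraction of the input, strictly inside (0, 1).

    Returns
    -------
    (qe, qi) : tuple of float
        Excitatory PSP and inhibitory PSP magnitude in mV (both >= 0; the
        inhibitory PSP is applied with a negative sign).
    """
    if not 0.0 < eta < 1.0:
        raise ValueError(f"eta must be in (0, 1) for balanced sizing, got {eta}")
    if q < 0:
        raise ValueError(f"q must be non-negative, got {q}")
    qe = q * math.sqrt((1.0 - eta) / eta)
    qi = q * math.sqrt(eta / (1.0 - eta))
    return qe, qi


@dataclass(frozen=True)
class InputModel:
    """Balanced Poisson input specification.

    ``qe`` and ``qi`` are derived from (q, eta) at construction; the drift of
    the resulting input is exactly zero for any total rate R.
    """

    q: float
    eta: float
    qe: float = field(init=False)
    qi: float = field(init=False)

    def __post_init__(self) -> None:
        qe, qi = balanced_psp_sizes(self.q, self.eta)
        object.__setattr__(self, "qe", qe)
        object.__setattr__(self, "qi", qi)

    def to_dict(self) -> dict:
        return {"q": self.q, "eta": self.eta, "qe": self.qe, "qi": self.qi}


def drift_and_diffusion(
    R: float, qe: float, qi: float, eta: float
) -> tuple[float, float]:
    """Drift mu (mV/ms) and diffusion coefficient D (mV^2/ms) of the input.

    For the balanced pair from :func:`balanced_psp_sizes` the drift is 0 and
    ``D == q**2 * R`` exactly.
    """
    if R < 0:
        raise ValueError(f"R must be non-negative, got {R}")
    mu = eta * R * qe - (1.0 - eta) * R * qi
    D = eta * R * qe**2 + (1.0 - eta) * R * qi**2
    return mu, D


def rate_grid(q: float, d_max: float, S: int) -> np.ndarray:
    """Input-rate grid (kHz) evenly spaced in the diffusion coefficient.

    Builds ``S`` evenly spaced D values on [0, d_max] (mV^2/ms) and maps
    them to rates via ``R = D / q**2``.  Spacing uniform in D is uniform in
    R for fixed q, so transfer curves measured at different q cover the same
    noise levels.
    """
    if q <= 0:
        raise ValueError("q must be positive to map diffusion to rate")
    if S < 2:
        raise ValueError(f"need at least 2 grid points, got S={S}")
    return np.linspace(0.0, d_max, S) / q**2


def psc_weight(q: float, c_m: float, tau_syn: float) -> float:
    """Peak alpha-PSC amplitude w (pA) equivalent to a delta PSP of size q.

    The alpha current ``alpha(t) = w * (t/tau_syn) * exp(1 - t/tau_syn)``
    integrates to ``w * e * tau_syn``; fixing that charge to ``c_m * q``
    gives ``w = c_m * q / (e * tau_syn)``, so the delivered voltage matches
    a delta PSP of size q independently of tau_syn.
    """
    if tau_syn <= 0:
        raise ValueError("tau_syn must be positive (use the delta-PSP path instead)")
    if c_m <= 0:
        raise ValueError(f"c_m must be positive, got {c_m}")
    return c_m * q / (math.e * tau_syn)


def poisson_streams(
    R: float,
    eta: float,
    duration: float,
    seed: int | np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    """Two independent homogeneous Poisson event-time arrays (ms).

    The excitatory stream has rate ``eta * R`` and the inhibitory stream
    ``(1 - eta) * R`` (R in kHz = events/ms).  eta may be 0 or 1 here; only
    the balanced PSP sizing rejects the degenerate fractions.
    """
    if R < 0:
        raise ValueError(f"R must be non-negative, got {R}")
    if duration <= 0:
        raise ValueError(f"duration must be positive, got {duration}")
    rng = np.random.default_rng(seed)
    exc = _poisson_times(eta * R, duration, rng)
    inh = _poisson_times((1.0 - eta) * R, duration, rng)
    return exc, inh


def _poisson_times(rate: float, duration: float, rng: np.random.Generator) -> np.ndarray:
    if rate <= 0:
        return np.empty(0)
    n = rng.poisson(rate * duration)
    return np.sort(rng.uniform(0.0, duration, n))
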