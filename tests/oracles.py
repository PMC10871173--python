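"""Independent oracles used only by the tests.

These deliberately avoid the package's own code paths: the Siegert
first-passage rate is evaluated by numerical quadrature of its closed form,
and the OU/AR(1) path generator uses the exact discrete transition.
"""

import math

import numpy as np
from scipy import integrate, special


def siegert_rate_hz(tau: float, v_gap: float, t_ref: float, D: float) -> float:
    """Diffusion-limit LIF firing rate (Hz) under zero-drift white noise.

    For dv = -v/tau dt + sqrt(D) dW with reset at 0 and threshold v_gap,
    the mean first-passage time gives

        1/r = t_ref + tau*sqrt(pi) * int_0^{v_gap/sqrt(D*tau)}
                                     e^{u^2} (1 + erf(u)) du
    """
    if D <= 0:
        return 0.0
    upper = v_gap / math.sqrt(D * tau)
    val, _ = integrate.quad(
        lambda u: math.exp(u * u) * (1.0 + special.erf(u)), 0.0, upper
    )
    isi_ms = t_ref + tau * math.sqrt(math.pi) * val
    return 1000.0 / isi_ms


def ou_path(
    mean: float, sigma: float, tau_ms: float, dt_ms: float, n: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """Exact AR(1) discretization of an OU process with stationary sd sigma."""
    rho = math.exp(-dt_ms / tau_ms)
    innov_sd = sigma * math.sqrt(1.0 - rho * rho)
    x = np.empty(n)
    x[0] = mean + sigma * rng.standard_normal()
    eps = innov_sd * rng.standard_normal(n - 1)
    for i in range(1, n):
        x[i] = mean + rho * (x[i - 1] - mean) + eps[i - 1]
    return x
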