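"""Refractory SoftPlus transfer function: evaluation and fitting.

A transfer function F maps a neuron's total Poisson input rate R (kHz) to
its mean output firing rate (Hz).  Refractory SoftPlus composes three
ingredients:

* the input enters through ``x = q*sqrt(R) - sigma0`` because in the
  diffusion regime the firing rate scales with the square root of the
  diffusion coefficient D = q^2 R, not with R itself;
* a SoftPlus ``softplus(x; beta) = log(1 + exp(beta*x)) / beta`` provides a
  smooth rectified-linear shape with sharpness beta;
* an absolute refractory period T_ref is imposed at the level of the
  interspike interval: invert the SoftPlus rate into an ISI, add T_ref,
  invert again,

        F(R) = 1 / (T_ref + 1 / (alpha * softplus(q*sqrt(R) - sigma0; beta)))

with the rate ceiling 1/T_ref built in.  The four parameters
(alpha, beta, sigma0, T_ref) are fitted to a measured transfer curve by
nonlinear least squares.

The module exposes a statsmodels-style surface —
``RefractorySoftPlusModel(curve).fit()`` returning a
:class:`TransferFunctionFit` with parameters, standard errors and a
``summary()`` — plus plain functions mirroring it.  Scale-and-shift tanh
(sigmoid) and ReLU fitters are provided as comparison baselines.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass

import numpy as np
from scipy import optimize

from .neurons import TransferCurve

__all__ = [
    "RSPParams",
    "softplus",
    "refractory_softplus",
    "refractory_softplus_derivative",
    "RefractorySoftPlusModel",
    "TransferFunctionFit",
    "FitResult",
    "fit_refractory_softplus",
    "normalized_rms_error",
    "fit_baselines",
    "BaselineFit",
]

#: beta*x beyond which SoftPlus is evaluated as the exact ramp x;
#: ln(1+exp(20))/20 exceeds 1 by ~1.03e-10, i.e. 9 decimal places.
DEFAULT_CUTOFF = 20.0


@dataclass(frozen=True)
class RSPParams:
    """The fitted quadruple of the Refractory SoftPlus transfer function.

    alpha : gain from SoftPlus output to rate (1/ms per mV ms^-1/2)
    beta : SoftPlus sharpness (per mV ms^-1/2)
    sigma0 : input offset in units of sqrt(D) (mV ms^-1/2)
    t_ref : effective refractory period (ms), the 1/rate ceiling
    """

    alpha: float
    beta: float
    sigma0: float
    t_ref: float

    def __post_init__(self) -> None:
        if self.alpha <= 0 or self.beta <= 0:
            raise ValueError("alpha and beta must be positive")
        if self.t_ref < 0:
            raise ValueError("t_ref must be non-negative")

    def as_array(self) -> np.ndarray:
        return np.array([self.alpha, self.beta, self.sigma0, self.t_ref])


def softplus(x, beta: float, cutoff: float = DEFAULT_CUTOFF):
    """SoftPlus ``log(1 + exp(beta*x)) / beta``, ramp-exact for beta*x > cutoff."""
    if beta <= 0:
        raise ValueError("beta must be positive")
    x = np.asarray(x, dtype=float)
    bx = beta * x
    out = np.where(bx > cutoff, x, np.log1p(np.exp(np.minimum(bx, cutoff))) / beta)
    return out if out.ndim else float(out)


def refractory_softplus(R, params: RSPParams, q: float, cutoff: float = DEFAULT_CUTOFF):
    """Firing rate (Hz) at total input rate R (kHz).

    Strictly positive, strictly increasing in R, bounded by 1000/t_ref Hz.
    """
    R = np.asarray(R, dtype=float)
    if np.any(R < 0):
        raise ValueError("R must be non-negative")
    x = q * np.sqrt(R) - params.sigma0
    # clamp against float underflow of the exponential tail
    s = np.maximum(np.asarray(softplus(x, params.beta, cutoff)), 1e-300)
    rate = 1000.0 / (params.t_ref + 1.0 / (params.alpha * s))
    return rate if R.ndim else float(rate)


def refractory_softplus_derivative(R, params: RSPParams, q: float):
    """dF/dR in Hz per kHz (closed form), for stability analysis."""
    R = np.asarray(R, dtype=float)
    x = q * np.sqrt(R) - params.sigma0
    s = np.asarray(softplus(x, params.beta))
    g = params.alpha * s
    # d softplus / dx is the logistic function
    sig = 1.0 / (1.0 + np.exp(-np.clip(params.beta * x, -500, 500)))
    dg_dx = params.alpha * sig
    denom = (params.t_ref + 1.0 / g) ** 2 * g**2
    dx_dR = np.where(R > 0, q / (2.0 * np.sqrt(np.maximum(R, 1e-300))), np.inf)
    out = 1000.0 * dg_dx * dx_dR / denom
    return out if out.ndim else float(out)


def normalized_rms_error(params: RSPParams, curve: TransferCurve) -> float:
    """RMS of (predicted - observed) over the curve / max observed rate."""
    obs = curve.rates_out
    mx = float(np.max(obs))
    if mx <= 0:
        raise ValueError("curve has no non-zero rates; nrmse undefined")
    pred = refractory_softplus(curve.rates_in, params, curve.q)
    return float(np.sqrt(np.mean((pred - obs) ** 2)) / mx)


# ---------------------------------------------------------------------------
# Model / Results
# ---------------------------------------------------------------------------


class RefractorySoftPlusModel:
    """Nonlinear least-squares model for a measured transfer curve.

    Parameters
    ----------
    curve : TransferCurve
        Measured (R, rate) pairs; q is taken from the curve (the PSP size
        is a known constant of the input model, not a fitted parameter).
    """

    param_names = ("alpha", "beta", "sigma0", "t_ref")

    def __init__(self, curve: TransferCurve, cutoff: float = DEFAULT_CUTOFF):
        if len(curve) < 4:
            raise ValueError("need at least 4 points to fit 4 parameters")
        self.curve = curve
        self.cutoff = cutoff
        self.x = curve.q * np.sqrt(curve.rates_in)
        self.y = curve.rates_out

    def _predict(self, p: np.ndarray) -> np.ndarray:
        alpha, beta, sigma0, t_ref = p
        bx = beta * (self.x - sigma0)
        s = np.where(
            bx > self.cutoff,
            self.x - sigma0,
            np.log1p(np.exp(np.minimum(bx, self.cutoff))) / beta,
        )
        return 1000.0 / (t_ref + 1.0 / (alpha * s))

    def _initial_guess(self) -> np.ndarray:
        y, x = self.y, self.x
        mx = float(np.max(y))
        t_ref0 = 1000.0 / mx  # ms; ISI at the fastest observed point
        hi = x >= x[0] + 2.0 * (x[-1] - x[0]) / 3.0
        if hi.sum() >= 2:
            slope = np.polyfit(x[hi], y[hi], 1)[0]
        else:
            slope = mx / max(x[-1] - x[0], 1e-9)
        alpha0 = max(slope, 1e-3) / 1000.0  # Hz -> 1/ms gain
        above = np.nonzero(y > 0.01 * mx)[0]
        sigma0 = float(x[above[0]]) if above.size else float(x[len(x) // 2])
        return np.array([alpha0, 1.0, sigma0, t_ref0])

    def fit(self, max_restarts: int = 3, seed: int = 0) -> "TransferFunctionFit":
        """Fit by bounded nonlinear least squares with jittered restarts.

        Returns a :class:`TransferFunctionFit`; a curve with no spikes
        anywhere is returned flagged non-converged rather than raising.
        """
        if float(np.max(self.y)) <= 0.0:
            params = RSPParams(1e-6, 1.0, 0.0, 1.0)
            return TransferFunctionFit(self, params, None, np.inf, converged=False)
        lb = np.array([1e-12, 1e-12, -np.inf, 0.0])
        ub = np.array([np.inf, np.inf, np.inf, np.inf])
        p0 = self._initial_guess()
        rng = np.random.default_rng(seed)
        best = None
        for attempt in range(max_restarts + 1):
            start = p0 if attempt == 0 else p0 * rng.lognormal(0.0, 0.3, 4)
            start = np.clip(start, lb + 1e-12, None)
            try:
                res = optimize.least_squares(
                    lambda p: self._predict(p) - self.y,
                    start, bounds=(lb, ub), method="trf", x_scale="jac",
                )
            except Exception:
                continue
            if best is None or res.cost < best.cost:
                best = res
            if res.success and attempt == 0:
                break  # restarts are only for non-convergence of the first try
        if best is None:
            params = RSPParams(*np.maximum(p0, 1e-12))
            return TransferFunctionFit(self, params, None, np.inf, converged=False)
        p = best.x
        params = RSPParams(*p)
        nrmse = float(
            np.sqrt(2.0 * best.cost / len(self.y)) / np.max(self.y)
        )
        cov = _cov_from_jac(best.jac, best.fun)
        return TransferFunctionFit(self, params, cov, nrmse, converged=bool(best.success))


def _cov_from_jac(jac: np.ndarray, resid: np.ndarray) -> np.ndarray | None:
    n, k = jac.shape
    if n <= k:
        return None
    try:
        jtj_inv = np.linalg.pinv(jac.T @ jac)
    except np.linalg.LinAlgError:
        return None
    s2 = float(resid @ resid) / (n - k)
    return s2 * jtj_inv


class TransferFunctionFit:
    """Results of a Refractory SoftPlus fit.

    Attributes
    ----------
    params : RSPParams
    nrmse : float
        Residual RMS normalized by the maximum observed rate.
    bse : dict
        Asymptotic standard errors (Gauss-Newton), NaN when unavailable.
    converged : bool
    """

    def __init__(self, model, params, cov_params, nrmse, converged):
        self.model = model
        self.params = params
        self.cov_params = cov_params
        self.nrmse = float(nrmse)
        self.converged = converged
        self.n_points = len(model.curve)
        names = RefractorySoftPlusModel.param_names
        if cov_params is not None:
            se = np.sqrt(np.clip(np.diag(cov_params), 0, None))
        else:
            se = np.full(4, np.nan)
        self.bse = dict(zip(names, se))

    @property
    def curve(self) -> TransferCurve:
        return self.model.curve

    def predict(self, R) -> np.ndarray:
        """Fitted firing rate (Hz) at input rate R (kHz)."""
        return refractory_softplus(R, self.params, self.curve.q, self.model.cutoff)

    def derivative(self, R) -> np.ndarray:
        return refractory_softplus_derivative(R, self.params, self.curve.q)

    def nrmse_against(self, reference: TransferCurve) -> float:
        """nrmse of this fit evaluated on an independent reference curve."""
        return normalized_rms_error(self.params, reference)

    def mean_field(self, n_recurrent: int, r_bg: float):
        """Build a mean-field model from this fit (N inputs, R_bg in kHz)."""
        from .meanfield import MeanFieldModel

        return MeanFieldModel(
            params=self.params, q=self.curve.q,
            n_recurrent=n_recurrent, r_bg=r_bg,
        )

    def summary(self) -> str:
        p = self.params
        names = RefractorySoftPlusModel.param_names
        lines = [
            "Refractory SoftPlus transfer-function fit",
            "=" * 45,
            f"model: {self.curve.model}   q = {self.curve.q} mV   "
            f"eta = {self.curve.eta}",
            f"points: {self.n_points}   T per point: {self.curve.duration} s",
            f"converged: {self.converged}   nrmse: {self.nrmse:.4g}",
            "-" * 45,
            f"{'param':>8} {'estimate':>12} {'std err':>12}",
        ]
        for name, val in zip(names, p.as_array()):
            lines.append(f"{name:>8} {val:>12.5g} {self.bse[name]:>12.3g}")
        lines.append("=" * 45)
        return "\n".join(lines)

    def to_json(self, path=None) -> str:
        payload = {
            "alpha": self.params.alpha, "beta": self.params.beta,
            "sigma0": self.params.sigma0, "t_ref_ms": self.params.t_ref,
            "nrmse": self.nrmse, "n_points": self.n_points,
            "converged": self.converged,
            "model": self.curve.model, "q_mV": self.curve.q, "eta": self.curve.eta,
        }
        text = json.dumps(payload, indent=2)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text


#: alias: the results object carries params/nrmse/n_points/converged
FitResult = TransferFunctionFit


def fit_refractory_softplus(
    curve: TransferCurve, max_restarts: int = 3, seed: int = 0
) -> TransferFunctionFit:
    """Fit Refractory SoftPlus to a measured transfer curve."""
    return RefractorySoftPlusModel(curve).fit(max_restarts=max_restarts, seed=seed)


# ---------------------------------------------------------------------------
# Baseline transfer functions (comparison only)
# ---------------------------------------------------------------------------


@dataclass
class BaselineFit:
    """A fitted baseline transfer function of x = sqrt(D) = q*sqrt(R)."""

    kind: str
    coeffs: np.ndarray
    nrmse: float
    q: float

    def predict(self, R) -> np.ndarray:
        x = self.q * np.sqrt(np.asarray(R, dtype=float))
        if self.kind == "relu":
            a, x0 = self.coeffs
            return a * np.maximum(x - x0, 0.0)
        amp, x0, width = self.coeffs
        return 0.5 * amp * (1.0 + np.tanh((x - x0) / width))


def fit_baselines(curve: TransferCurve) -> dict[str, BaselineFit]:
    """Least-squares sigmoid (tanh) and ReLU fits to a transfer curve.

    Both are scale-and-shift functions of sqrt(D); the sigmoid saturates at
    its fitted amplitude, which is what makes it extrapolate poorly.
    """
    if len(curve) < 4:
        raise ValueError("need at least 4 points")
    x = curve.q * np.sqrt(curve.rates_in)
    y = curve.rates_out
    mx = float(np.max(y))
    if mx <= 0:
        raise ValueError("all-zero curve")
    out: dict[str, BaselineFit] = {}

    def relu(x, a, x0):
        return a * np.maximum(x - x0, 0.0)

    def sigmoid(x, amp, x0, width):
        return 0.5 * amp * (1.0 + np.tanh((x - x0) / width))

    span = max(x[-1] - x[0], 1e-9)
    for kind, fn, p0 in [
        ("relu", relu, [mx / span, x[0]]),
        ("sigmoid", sigmoid, [mx, 0.5 * (x[0] + x[-1]), span / 4]),
    ]:
        try:
            coeffs, _ = optimize.curve_fit(fn, x, y, p0=p0, maxfev=20000)
        except RuntimeError:
            coeffs = np.asarray(p0, dtype=float)
        resid = fn(x, *coeffs) - y
        out[kind] = BaselineFit(
            kind=kind, coeffs=np.asarray(coeffs), q=curve.q,
            nrmse=float(np.sqrt(np.mean(resid**2)) / mx),
        )
    return out
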