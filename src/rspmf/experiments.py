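"""End-to-end experiment drivers: randomized-parameter sweeps and
fit-convergence studies.

These wire the simulators and the Refractory SoftPlus fitter into the two
standard validation experiments:

* ``sweep_random_parameters`` — how well does the four-parameter fit
  generalize when the neuron-model parameters are drawn at random?  Each
  draw measures a fresh transfer curve and fits it; the distribution of
  normalized RMS errors is returned with the default-parameter fit marked.
* ``convergence_study`` — how much simulation does a good fit need?  One
  long measurement is reused: evenly spaced subsets of the rate grid
  (vary_S) or growing prefixes of the simulated time (vary_T), with the
  error always assessed against the full reference curve.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .neurons import (
    HHParams,
    IzhikevichParams,
    LIFParams,
    TransferCurve,
    measure_transfer_curve,
)
from .rsp import fit_refractory_softplus, normalized_rms_error

__all__ = [
    "ParamDistributionSpec",
    "default_distribution_spec",
    "SweepResult",
    "sweep_random_parameters",
    "ConvergenceStudy",
    "convergence_study",
]

_MODEL_CLASSES = {"lif": LIFParams, "izhikevich": IzhikevichParams, "hh": HHParams}


@dataclass(frozen=True)
class ParamDistributionSpec:
    """Per-parameter distribution descriptors for a neuron model.

    Each entry maps a parameter name to a tuple:
    ``('exp', mean)``, ``('normal', mean, sd)``, ``('uniform', lo, hi)`` or
    ``('fixed', value)``.  Draws violating the model's invariants are
    resampled.
    """

    model_kind: str
    distributions: dict = field(default_factory=dict)

    def draw(self, rng: np.random.Generator, max_tries: int = 100):
        cls = _MODEL_CLASSES[self.model_kind]
        for _ in range(max_tries):
            kwargs = {}
            for name, desc in self.distributions.items():
                kind = desc[0]
                if kind == "exp":
                    kwargs[name] = float(rng.exponential(desc[1]))
                elif kind == "normal":
                    kwargs[name] = float(rng.normal(desc[1], desc[2]))
                elif kind == "uniform":
                    kwargs[name] = float(rng.uniform(desc[1], desc[2]))
                elif kind == "fixed":
                    kwargs[name] = desc[1]
                else:
                    raise ValueError(f"unknown distribution kind {kind!r}")
            try:
                return cls(**kwargs)
            except ValueError:
                continue  # invariant violated; resample
        raise RuntimeError("could not draw valid parameters in 100 tries")


def default_distribution_spec(model_kind: str) -> ParamDistributionSpec:
    """Randomization used for the generalization sweep.

    Time constants are exponential about their defaults, capacitances
    normal; Izhikevich parameters are uniform over their canonical ranges.
    For the delta-PSP LIF, capacitance does not enter the dynamics (PSPs
    are specified directly in mV), so only the refractory period varies.
    """
    if model_kind == "lif":
        return ParamDistributionSpec("lif", {"t_ref": ("exp", 2.0)})
    if model_kind == "izhikevich":
        return ParamDistributionSpec(
            "izhikevich",
            {
                "a": ("uniform", 0.02, 0.1),
                "b": ("uniform", 0.2, 0.25),
                "c": ("uniform", -65.0, -50.0),
                "d": ("uniform", 2.0, 8.0),
            },
        )
    if model_kind == "hh":
        return ParamDistributionSpec(
            "hh",
            {
                "t_ref": ("exp", 2.0),
                "c_m": ("normal", 100.0, 10.0),
                "tau_syn_exc": ("exp", 1.0),
                "tau_syn_inh": ("exp", 1.0),
            },
        )
    raise ValueError(f"unknown model kind {model_kind!r}")


@dataclass(frozen=True)
class SweepResult:
    """nrmse distribution over randomized parameter draws."""

    model_kind: str
    nrmse: np.ndarray          # (n_draws,)
    default_nrmse: float
    drawn_params: list

    def default_percentile(self) -> float:
        """Percentile rank of the default-parameter fit in the sweep."""
        return float(100.0 * np.mean(self.nrmse <= self.default_nrmse))


def sweep_random_parameters(
    model_kind: str,
    spec: ParamDistributionSpec | None = None,
    n_draws: int = 50,
    q: float = 1.0,
    eta: float = 0.5,
    S: int = 100,
    duration: float = 100.0,
    d_max: float = 100.0,
    seed: int = 0,
) -> SweepResult:
    """Fit quality across randomly parametrized instances of a model.

    Defaults follow the generalization protocol: eta = 0.5, q = 1 mV, each
    instance simulated for ``duration`` seconds at ``S`` input rates.
    """
    if n_draws < 1:
        raise ValueError("n_draws must be at least 1")
    spec = spec if spec is not None else default_distribution_spec(model_kind)
    rng = np.random.default_rng(seed)
    seeds = np.random.SeedSequence(seed).generate_state(n_draws + 1)
    default_model = _MODEL_CLASSES[model_kind]()
    ref_curve = measure_transfer_curve(
        default_model, q=q, eta=eta, S=S, d_max=d_max,
        duration=duration, seed=int(seeds[0] % (2**31 - 1)),
    )
    default_nrmse = fit_refractory_softplus(ref_curve).nrmse
    errs = np.empty(n_draws)
    drawn = []
    for i in range(n_draws):
        model = spec.draw(rng)
        drawn.append(model)
        curve = measure_transfer_curve(
            model, q=q, eta=eta, S=S, d_max=d_max,
            duration=duration, seed=int(seeds[i + 1] % (2**31 - 1)),
        )
        errs[i] = fit_refractory_softplus(curve).nrmse
    return SweepResult(
        model_kind=model_kind, nrmse=errs,
        default_nrmse=default_nrmse, drawn_params=drawn,
    )


@dataclass(frozen=True)
class ConvergenceStudy:
    """Fit error versus data volume (number of rates S or duration T)."""

    mode: str
    grid: np.ndarray
    nrmse: np.ndarray        # fitted-curve error vs the full reference
    raw_error: np.ndarray | None  # short-time estimate error (vary_T only)
    reference: TransferCurve


def convergence_study(
    model_kind: str = "lif",
    mode: str = "vary_S",
    grid=(5, 10, 25, 50, 100),
    reference_spec: dict | None = None,
    seed: int = 0,
) -> ConvergenceStudy:
    """Convergence of the fit with S (rate-grid size) or T (duration).

    One reference simulation is performed and reused: vary_S fits evenly
    spaced subsets of the rate grid; vary_T fits rate estimates from
    growing prefixes of the simulated time (so startup transients are
    represented identically at every T).  Errors are nrmse against the full
    reference curve.
    """
    grid = np.asarray(sorted(grid), dtype=float)
    spec = {
        "q": 1.0, "eta": 0.5, "S": 200, "duration": 20.0, "d_max": 100.0,
    }
    if reference_spec:
        spec.update(reference_spec)
    model = _MODEL_CLASSES[model_kind]()
    if mode == "vary_S":
        reference = measure_transfer_curve(
            model, q=spec["q"], eta=spec["eta"], S=spec["S"],
            d_max=spec["d_max"], duration=spec["duration"], seed=seed,
        )
        errs = np.empty(grid.size)
        for i, S in enumerate(grid.astype(int)):
            sub = reference.subsample(S)
            fit = fit_refractory_softplus(sub)
            errs[i] = normalized_rms_error(fit.params, reference)
        return ConvergenceStudy(mode, grid, errs, None, reference)
    if mode != "vary_T":
        raise ValueError("mode must be 'vary_S' or 'vary_T'")
    durations = grid  # seconds
    if durations[-1] > spec["duration"]:
        spec["duration"] = float(durations[-1])
    reference, partial = measure_transfer_curve(
        model, q=spec["q"], eta=spec["eta"], S=spec["S"], d_max=spec["d_max"],
        duration=spec["duration"], seed=seed, checkpoints=durations,
    )
    mx = float(np.max(reference.rates_out))
    errs = np.empty(durations.size)
    raw = np.empty(durations.size)
    for j, T in enumerate(durations):
        sub = replace_rates(reference, partial[:, j], T)
        fit = fit_refractory_softplus(sub)
        errs[j] = normalized_rms_error(fit.params, reference)
        raw[j] = float(
            np.sqrt(np.mean((partial[:, j] - reference.rates_out) ** 2)) / mx
        )
    return ConvergenceStudy("vary_T", durations, errs, raw, reference)


def replace_rates(curve: TransferCurve, rates_out, duration) -> TransferCurve:
    return TransferCurve(
        curve.rates_in, rates_out, curve.q, curve.eta, float(duration),
        curve.seed, curve.model, curve.model_params,
    )
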