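"""Behavioural summaries and simulation-based model fitting.

The model is fit to response-category proportions and RT quantiles
(0.1, 0.3, 0.5, 0.7, 0.9) of the initial and change-of-mind responses
simultaneously: the loss simulates the model at candidate parameters,
summarises the simulated behaviour the same way as the data, and takes the
root-mean-squared error over the concatenated summary vector.  A Nelder-Mead
simplex searches a transformed unconstrained space; every loss evaluation
re-uses the same seed (common random numbers) so the simplex sees a
quasi-deterministic landscape.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace, field

import numpy as np
import pandas as pd
from scipy import optimize

from .kernels import (
    KernelEstimate,
    classify_responses,
    compute_kernels,
    median_split_com_rt,
    response_type_groups,
)
from .model import ModelParams, simulate_experiment
from .stats import apply_exclusions
from .stimuli import TaskConfig

__all__ = [
    "QUANTILE_PROBS",
    "BehaviourSummary",
    "summarize_behaviour",
    "loss",
    "FitResult",
    "fit",
    "predicted_kernels",
]

QUANTILE_PROBS = (0.1, 0.3, 0.5, 0.7, 0.9)
_MIN_CELL = 10


@dataclass
class BehaviourSummary:
    """Fitting target: response-type shares and per-cell RT quantiles.

    ``proportions`` covers {correct, error, corrected_error, spoilt_correct}
    among responded, retained trials and sums to 1.  ``initial_rt_quantiles``
    holds quantiles of the initial RT for initially-correct and
    initially-wrong responses; ``com_latency_quantiles`` holds quantiles of
    the change-of-mind latency for corrected errors and spoilt corrects.
    Cells with fewer than 10 trials are dropped (None) with a warning.
    """

    proportions: dict[str, float]
    initial_rt_quantiles: dict[str, np.ndarray | None]
    com_latency_quantiles: dict[str, np.ndarray | None]
    n_trials: int = 0

    def cells(self) -> dict[str, np.ndarray]:
        out = {f"prop_{k}": np.array([v]) for k, v in self.proportions.items()}
        for k, v in self.initial_rt_quantiles.items():
            if v is not None:
                out[f"rt_{k}"] = np.asarray(v)
        for k, v in self.com_latency_quantiles.items():
            if v is not None:
                out[f"com_{k}"] = np.asarray(v)
        return out


def summarize_behaviour(trials: pd.DataFrame) -> BehaviourSummary:
    """Summarise retained, responded trials into the fitting target."""
    rt_type = classify_responses(trials)
    keep = rt_type != "excluded"
    t = trials[keep]
    rt_type = rt_type[keep]
    n = len(t)
    if n == 0:
        raise ValueError("no classifiable trials to summarise")
    props = {
        name: float((rt_type == name).sum()) / n
        for name in ("correct", "error", "corrected_error", "spoilt_correct")
    }
    init_correct = t["initial_choice"].eq(t["correct_side"])
    irq = {
        "initial_correct": _quantiles(t.loc[init_correct, "initial_rt"]),
        "initial_error": _quantiles(t.loc[~init_correct, "initial_rt"]),
    }
    comq = {
        "corrected_error": _quantiles(
            t.loc[rt_type == "corrected_error", "com_latency"]
        ),
        "spoilt_correct": _quantiles(
            t.loc[rt_type == "spoilt_correct", "com_latency"]
        ),
    }
    return BehaviourSummary(
        proportions=props,
        initial_rt_quantiles=irq,
        com_latency_quantiles=comq,
        n_trials=n,
    )


def _quantiles(x: pd.Series) -> np.ndarray | None:
    x = x.dropna().to_numpy(float)
    if len(x) < _MIN_CELL:
        warnings.warn(
            f"cell with {len(x)} trials dropped from summary (min {_MIN_CELL})",
            stacklevel=2,
        )
        return None
    return np.quantile(x, QUANTILE_PROBS)  # linear interpolation


def loss(
    params: ModelParams,
    observed: BehaviourSummary,
    config: TaskConfig,
    n_sim: int = 50_000,
    seed: int = 0,
    variant: str = "coupled",
    weights: dict[str, float] | None = None,
) -> float:
    """RMSE between observed and simulated behaviour summaries.

    All cells enter unweighted by default (proportions dimensionless,
    quantiles in seconds); ``weights`` maps cell-name prefixes to
    multipliers.  Cells empty on either side are omitted.  The same ``seed``
    always yields the same simulated summary (common random numbers).
    """
    if n_sim < 1000:
        raise ValueError("n_sim must be >= 1000")
    rng = np.random.default_rng(seed)
    sim_trials, _ = simulate_experiment(params, variant, config, n_sim, rng)
    sim_retained, _ = apply_exclusions(sim_trials)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        sim_summary = summarize_behaviour(sim_retained)
    obs_cells = observed.cells()
    sim_cells = sim_summary.cells()
    diffs = []
    for name, ov in sorted(obs_cells.items()):
        if name not in sim_cells:
            continue
        w = 1.0
        if weights:
            for prefix, val in weights.items():
                if name.startswith(prefix):
                    w = val
        diffs.append((sim_cells[name] - ov) * w)
    if not diffs:
        raise ValueError("no overlapping summary cells between data and model")
    v = np.concatenate(diffs)
    return float(np.sqrt(np.mean(v**2)))


# transformations to an unconstrained search space, per parameter
_POSITIVE = ("B", "B_CoM", "eta", "slope", "s", "theta", "tnd", "tndVar")


def _to_unconstrained(name: str, value: float) -> float:
    if name in _POSITIVE:
        return float(np.log(value))
    if name == "timeOut":
        v = np.clip(value, 1e-6, 1 - 1e-6)
        return float(np.log(v / (1 - v)))
    return float(value)  # mu, Sz handled as free reals (validated on rebuild)


def _from_unconstrained(name: str, value: float) -> float:
    if name in _POSITIVE:
        return float(np.exp(value))
    if name == "timeOut":
        return float(1.0 / (1.0 + np.exp(-value)))
    return float(value)


@dataclass
class FitResult:
    params: ModelParams
    loss: float
    n_sim_per_eval: int
    n_eval: int
    iterations: int
    converged: bool
    seed: int
    free: tuple[str, ...]
    trace: list = field(default_factory=list)


def fit(
    observed: BehaviourSummary,
    init: ModelParams,
    config: TaskConfig,
    free: tuple[str, ...] = ("mu", "B"),
    n_sim: int = 50_000,
    seed: int = 0,
    variant: str = "coupled",
    max_evals: int = 200,
    xatol: float = 1e-3,
    fatol: float = 1e-4,
) -> FitResult:
    """Nelder-Mead simplex minimisation of the simulation RMSE.

    Only the parameters named in ``free`` are searched (log/logit transforms
    keep them feasible); the rest stay at their ``init`` values.  Identical
    seeds and inits give identical trajectories.
    """
    x0 = np.array([_to_unconstrained(f, getattr(init, f)) for f in free])
    trace: list[tuple[float, ...]] = []

    def objective(x: np.ndarray) -> float:
        updates = {f: _from_unconstrained(f, xi) for f, xi in zip(free, x)}
        try:
            p = replace(init, **updates)
        except ValueError:
            return 1e6
        val = loss(p, observed, config, n_sim=n_sim, seed=seed, variant=variant)
        trace.append((*updates.values(), val))
        return val

    res = optimize.minimize(
        objective,
        x0,
        method="Nelder-Mead",
        options={
            "maxfev": max_evals,
            "xatol": xatol,
            "fatol": fatol,
            "adaptive": len(free) > 3,
        },
    )
    best = {f: _from_unconstrained(f, xi) for f, xi in zip(free, res.x)}
    return FitResult(
        params=replace(init, **best),
        loss=float(res.fun),
        n_sim_per_eval=n_sim,
        n_eval=int(res.nfev),
        iterations=int(res.nit),
        converged=bool(res.success),
        seed=seed,
        free=tuple(free),
        trace=trace,
    )


def predicted_kernels(
    params: ModelParams,
    variant: str,
    config: TaskConfig,
    n: int = 100_000,
    seed: int = 0,
    min_trials: int = 100,
) -> dict:
    """Model-predicted psychophysical kernels for all three locks.

    Simulates ``n`` trials, applies the standard exclusions, and reverse
    correlates the simulated stimulus noise with the simulated outcomes, for
    the four response types and the fast/slow change-of-mind splits.
    Conditions with no simulated trials are omitted with a warning (rare
    categories do go empty at small n).
    """
    rng = np.random.default_rng(seed)
    trials, residuals = simulate_experiment(params, variant, config, n, rng)
    retained, _ = apply_exclusions(trials)
    res_kept = residuals[retained.index.to_numpy()]
    retained = retained.reset_index(drop=True)

    groups = response_type_groups(retained)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        split = median_split_com_rt(retained)
    rtypes = classify_responses(retained)
    for rt_name in ("corrected_error", "spoilt_correct"):
        for speed in ("fast", "slow"):
            groups[f"{speed}_{rt_name}"] = (
                (rtypes == rt_name) & (split == speed)
            ).to_numpy()
    groups = {k: v for k, v in groups.items() if np.asarray(v).any()}

    out = {"trials": retained, "residuals": res_kept, "kernels": {}}
    for lock in ("stimulus_onset", "initial_response", "com_response"):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            out["kernels"][lock] = compute_kernels(
                retained, res_kept, config, lock=lock, groups=groups,
                min_trials=min_trials,
            )
    return out
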