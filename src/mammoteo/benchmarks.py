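"""Analytic benchmark functions and a multi-run trial harness.

The suite is the unshifted analytic set commonly used to exercise
box-constrained single-objective optimizers: sphere, bent cigar,
Rastrigin, Rosenbrock, Ackley, Griewank, Schwefel 1.2 (rotated
hyper-ellipsoid) and the expanded Griewank-Rosenbrock composition.
Every function is vectorized over the last axis so a whole population
can be evaluated in one call.

``run_trials`` replicates the usual evaluation protocol: independent
seeded runs, final error = best cost minus the known optimum, errors
below an error floor recorded as exactly 0, and the (mean, std) of the
final errors reported per (algorithm, function) cell.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Callable, Dict, List, Sequence

import numpy as np
import pandas as pd

from .optimize import TEOConfig, run_ateo, run_teo

__all__ = ["BenchmarkFunction", "get_function", "list_functions", "evaluate", "run_trials"]


@dataclass(frozen=True)
class BenchmarkFunction:
    name: str
    dimension: int
    lower: float
    upper: float
    optimum_value: float
    optimum_point: np.ndarray
    fn: Callable[[np.ndarray], np.ndarray]

    def __call__(self, x: np.ndarray) -> np.ndarray:
        return evaluate(self, x)


def _sphere(x):
    return np.sum(x * x, axis=-1)


def _bent_cigar(x):
    return x[..., 0] ** 2 + 1e6 * np.sum(x[..., 1:] ** 2, axis=-1)


def _rastrigin(x):
    return np.sum(x * x - 10.0 * np.cos(2 * np.pi * x) + 10.0, axis=-1)


def _rosenbrock(x):
    a = x[..., :-1]
    b = x[..., 1:]
    return np.sum(100.0 * (b - a * a) ** 2 + (1.0 - a) ** 2, axis=-1)


def _ackley(x):
    d = x.shape[-1]
    s1 = np.sum(x * x, axis=-1) / d
    s2 = np.sum(np.cos(2 * np.pi * x), axis=-1) / d
    return -20.0 * np.exp(-0.2 * np.sqrt(s1)) - np.exp(s2) + 20.0 + np.e


def _griewank(x):
    d = x.shape[-1]
    i = np.arange(1, d + 1, dtype=float)
    return np.sum(x * x, axis=-1) / 4000.0 - np.prod(np.cos(x / np.sqrt(i)), axis=-1) + 1.0


def _schwefel_12(x):
    c = np.cumsum(x, axis=-1)
    return np.sum(c * c, axis=-1)


def _grie_rosen(x):
    # expanded Griewank-of-Rosenbrock over consecutive pairs, wrapped
    xs = np.concatenate([x, x[..., :1]], axis=-1)
    a = xs[..., :-1]
    b = xs[..., 1:]
    r = 100.0 * (b - a * a) ** 2 + (1.0 - a) ** 2
    return np.sum(r * r / 4000.0 - np.cos(r) + 1.0, axis=-1)


_CATALOG: Dict[str, tuple] = {
    # name -> (callable, optimum point builder)
    "sphere": (_sphere, lambda d: np.zeros(d)),
    "bent_cigar": (_bent_cigar, lambda d: np.zeros(d)),
    "rastrigin": (_rastrigin, lambda d: np.zeros(d)),
    "rosenbrock": (_rosenbrock, lambda d: np.ones(d)),
    "ackley": (_ackley, lambda d: np.zeros(d)),
    "griewank": (_griewank, lambda d: np.zeros(d)),
    "schwefel_12": (_schwefel_12, lambda d: np.zeros(d)),
    "grie_rosen": (_grie_rosen, lambda d: np.ones(d)),
}


def list_functions() -> List[str]:
    return list(_CATALOG)


def get_function(name: str, dimension: int, lower: float = -100.0, upper: float = 100.0) -> BenchmarkFunction:
    """Instantiate a named benchmark at the given dimension.

    The default box is the symmetric [-100, 100] used in standard
    bound-constrained benchmark protocols.
    """
    if name not in _CATALOG:
        raise KeyError(f"unknown benchmark function {name!r}; choose from {list_functions()}")
    fn, opt = _CATALOG[name]
    return BenchmarkFunction(
        name=name,
        dimension=dimension,
        lower=lower,
        upper=upper,
        optimum_value=0.0,
        optimum_point=opt(dimension),
        fn=fn,
    )


def evaluate(function: BenchmarkFunction, x: np.ndarray) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    if x.shape[-1] != function.dimension:
        raise ValueError(
            f"{function.name} expects dimension {function.dimension}, got {x.shape[-1]}"
        )
    return function.fn(x)


_ALGORITHMS = {"ateo": run_ateo, "teo": run_teo}


def run_trials(
    algorithm: str,
    function: BenchmarkFunction,
    n_runs: int,
    max_fes: int,
    error_floor: float = 1e-8,
    seeds: Sequence[int] | None = None,
    config: TEOConfig | None = None,
) -> dict:
    """Run ``n_runs`` independent seeded trials and summarize final errors.

    Final error is the best cost minus the known optimum; values below
    ``error_floor`` are recorded as 0.  Returns a row dict with the
    per-run finals included so mean/std can be recomputed externally.
    """
    if algorithm not in _ALGORITHMS:
        raise KeyError(f"unknown algorithm {algorithm!r}")
    if seeds is None:
        seeds = list(range(1, n_runs + 1))
    if len(seeds) != n_runs:
        raise ValueError("len(seeds) must equal n_runs")
    base = config if config is not None else TEOConfig()
    runner = _ALGORITHMS[algorithm]
    finals = []
    for seed in seeds:
        cfg = replace(
            base,
            lower=function.lower,
            upper=function.upper,
            max_fes=max_fes,
            error_floor=function.optimum_value + error_floor,
            seed=int(seed),
            vectorized=True,
        )
        best, _ = runner(function, function.dimension, cfg)
        err = best.cost - function.optimum_value
        finals.append(0.0 if err < error_floor else err)
    finals = np.asarray(finals)
    return {
        "algorithm": algorithm,
        "function": function.name,
        "mean": float(finals.mean()),
        "std": float(finals.std(ddof=0)),
        "n_runs": n_runs,
        "finals": finals.tolist(),
    }


def trial_table(rows: List[dict]) -> pd.DataFrame:
    """Arrange trial rows into a function x (algorithm: mean/std) table."""
    df = pd.DataFrame(rows)
    return df.pivot(index="function", columns="algorithm", values=["mean", "std"])
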