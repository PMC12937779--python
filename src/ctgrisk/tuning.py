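"""Sequential model-based hyperparameter search.

A small Gaussian-process optimiser: parameters are mapped to the unit cube,
a Matern-5/2 GP with estimated noise is fitted to the observed objective
values, and the next point maximises expected improvement over a random
candidate set.  Deterministic given seed and budget.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable

import numpy as np
from scipy.stats import norm
from sklearn.gaussian_process import GaussianProcessRegressor
from sklearn.gaussian_process.kernels import Matern, WhiteKernel

from .errors import ConfigError


@dataclass(frozen=True)
class Real:
    low: float
    high: float
    log: bool = False


@dataclass(frozen=True)
class Integer:
    low: int
    high: int
    log: bool = False


@dataclass(frozen=True)
class Categorical:
    choices: tuple


Dimension = Real | Integer | Categorical
SearchSpace = dict[str, Dimension]


def _validate_space(space: SearchSpace) -> None:
    if not space:
        raise ConfigError("empty search space")
    for name, dim in space.items():
        if isinstance(dim, (Real, Integer)):
            if not (math.isfinite(dim.low) and math.isfinite(dim.high)):
                raise ConfigError(f"{name}: bounds must be finite")
            if dim.high < dim.low:
                raise ConfigError(f"{name}: high < low")
            if dim.log and dim.low <= 0:
                raise ConfigError(f"{name}: log dimension requires positive low")
        elif isinstance(dim, Categorical):
            if not dim.choices:
                raise ConfigError(f"{name}: empty choices")
        else:
            raise ConfigError(f"{name}: unknown dimension type {type(dim)}")


def _decode(space: SearchSpace, u: np.ndarray) -> dict:
    params = {}
    for j, (name, dim) in enumerate(space.items()):
        x = float(np.clip(u[j], 0.0, 1.0))
        if isinstance(dim, Categorical):
            k = min(int(x * len(dim.choices)), len(dim.choices) - 1)
            params[name] = dim.choices[k]
        elif isinstance(dim, Real):
            if dim.log:
                params[name] = float(np.exp(np.log(dim.low) + x * (np.log(dim.high) - np.log(dim.low))))
            else:
                params[name] = float(dim.low + x * (dim.high - dim.low))
        else:
            if dim.log:
                v = np.exp(np.log(dim.low) + x * (np.log(dim.high) - np.log(dim.low)))
            else:
                v = dim.low + x * (dim.high - dim.low)
            params[name] = int(np.clip(round(v), dim.low, dim.high))
    return params


@dataclass
class TrialLog:
    params: dict
    value: float


def maximize(
    objective: Callable[[dict], float],
    space: SearchSpace,
    budget: int,
    seed: int,
    n_initial: int | None = None,
    n_candidates: int = 256,
) -> tuple[dict, list[TrialLog]]:
    """Maximise ``objective`` over ``space`` with ``budget`` evaluations.

    Returns the best parameters among evaluated points and the trial log.
    Failed evaluations (exceptions) are recorded as -inf; if every trial
    fails the search raises with the per-trial log attached.
    """
    _validate_space(space)
    if budget < 1:
        raise ConfigError("budget must be at least 1 evaluation")
    rng = np.random.default_rng(seed)
    d = len(space)
    if n_initial is None:
        n_initial = min(budget, max(4, d + 1))
    n_initial = min(n_initial, budget)

    X: list[np.ndarray] = []
    y: list[float] = []
    log: list[TrialLog] = []

    def evaluate(u: np.ndarray) -> None:
        params = _decode(space, u)
        try:
            val = float(objective(params))
        except Exception:  # recorded, not fatal unless everything fails
            val = -np.inf
        X.append(u)
        y.append(val)
        log.append(TrialLog(params=params, value=val))

    for _ in range(n_initial):
        evaluate(rng.random(d))

    kernel = Matern(nu=2.5, length_scale=np.full(d, 0.3)) + WhiteKernel(
        noise_level=1e-4, noise_level_bounds=(1e-8, 1e-1)
    )
    while len(y) < budget:
        finite = np.isfinite(y)
        if finite.sum() >= 2:
            gp = GaussianProcessRegressor(
                kernel=kernel, normalize_y=True, random_state=0, alpha=1e-10
            )
            ymat = np.array(y)
            ymat[~finite] = np.min(ymat[finite])
            gp.fit(np.array(X), ymat)
            cand = rng.random((n_candidates, d))
            mu, sigma = gp.predict(cand, return_std=True)
            best = float(np.max(ymat))
            sigma = np.maximum(sigma, 1e-12)
            z = (mu - best) / sigma
            ei = (mu - best) * norm.cdf(z) + sigma * norm.pdf(z)
            u = cand[int(np.argmax(ei))]
        else:
            u = rng.random(d)
        evaluate(u)

    if not np.isfinite(y).any():
        raise ConfigError(f"all {budget} evaluations failed: {log}")
    best_i = int(np.nanargmax(np.where(np.isfinite(y), y, -np.inf)))
    return log[best_i].params, log
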