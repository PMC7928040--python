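"""Model-based (Bayesian) hyperparameter search.

Sequential optimization over a box-constrained space: a preliminary block
of uniformly random evaluations seeds a Gaussian-process surrogate (Matern
5/2 plus observation noise) on the unit cube, and each subsequent round
evaluates the candidate maximizing expected improvement over the incumbent.
Integer-valued parameters are rounded at evaluation time.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.gaussian_process import GaussianProcessRegressor
from sklearn.gaussian_process.kernels import Matern, WhiteKernel, ConstantKernel

__all__ = ["OptimizationResult", "minimize_ei"]


@dataclass
class OptimizationResult:
    best_params: dict
    best_value: float
    trace: pd.DataFrame  # one row per evaluation: params, value, phase


def _decode(u: np.ndarray, names, bounds, integer_params) -> dict:
    params = {}
    for j, name in enumerate(names):
        lo, hi = bounds[name]
        v = lo + u[j] * (hi - lo)
        params[name] = int(round(v)) if name in integer_params else float(v)
    return params


def _expected_improvement(mu, sd, best):
    with np.errstate(divide="ignore", invalid="ignore"):
        z = (best - mu) / sd
        ei = (best - mu) * stats.norm.cdf(z) + sd * stats.norm.pdf(z)
    ei[sd <= 0] = 0.0
    return ei


def minimize_ei(
    objective,
    bounds: dict[str, tuple[float, float]],
    n_random: int = 30,
    n_iter: int = 100,
    seed: int = 0,
    integer_params: set[str] | frozenset[str] = frozenset(),
    n_candidates: int = 512,
) -> OptimizationResult:
    """Minimize ``objective(params_dict)`` over a box via GP + EI.

    ``n_random`` uniformly random preliminary rounds are followed by
    ``n_iter`` surrogate-guided rounds.  Fully deterministic under
    ``seed`` for a deterministic objective.
    """
    if n_random < 1 or n_iter < 0:
        raise ValueError("need at least one random round and n_iter >= 0")
    rng = np.random.default_rng(seed)
    names = list(bounds)
    d = len(names)
    U: list[np.ndarray] = []
    vals: list[float] = []
    rows: list[dict] = []

    def evaluate(u, phase):
        params = _decode(u, names, bounds, integer_params)
        v = float(objective(params))
        U.append(u)
        vals.append(v)
        rows.append({**params, "value": v, "phase": phase})
        return v

    for _ in range(n_random):
        evaluate(rng.random(d), "random")

    kernel = ConstantKernel(1.0) * Matern(
        length_scale=np.full(d, 0.3), nu=2.5, length_scale_bounds=(1e-2, 1e2)
    ) + WhiteKernel(noise_level=1e-4, noise_level_bounds=(1e-8, 1e1))
    for _ in range(n_iter):
        Xs = np.vstack(U)
        ys = np.asarray(vals)
        gp = GaussianProcessRegressor(
            kernel=kernel, normalize_y=True, random_state=int(rng.integers(2**31))
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            gp.fit(Xs, ys)
        cand = rng.random((n_candidates, d))
        mu, sd = gp.predict(cand, return_std=True)
        ei = _expected_improvement(mu, sd, ys.min())
        evaluate(cand[int(np.argmax(ei))], "model")

    best = int(np.argmin(vals))
    return OptimizationResult(
        best_params=_decode(U[best], names, bounds, integer_params),
        best_value=vals[best],
        trace=pd.DataFrame(rows),
    )
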