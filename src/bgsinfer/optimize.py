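"""Derivative-free maximization: Controlled Random Search + Nelder-Mead.

The composite likelihoods in this package are cheap to evaluate but not
smooth enough (B-map rounding, quadrature grids) for gradient methods, so
point estimation follows a two-step scheme: a global Controlled Random
Search (CRS2 with local mutation) over box bounds, then a local Nelder-Mead
polish from the best point.  Confidence intervals come from bootstrap
resampling of replicate data units (2.5/97.5 percentiles), not curvature.

Everything is deterministic given the seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import optimize as _sciopt

__all__ = [
    "FitResult",
    "crs_maximize",
    "nelder_mead_polish",
    "two_step_maximize",
    "bootstrap_ci",
]


@dataclass
class FitResult:
    """Outcome of a maximum composite likelihood fit."""

    params: dict
    lnCL: float
    n_evals: int
    seed: int
    bounds: dict
    ci: dict | None = None
    converged: bool = True
    extras: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "params": {k: float(v) for k, v in self.params.items()},
            "lnCL": float(self.lnCL),
            "n_evals": int(self.n_evals),
            "seed": int(self.seed),
            "bounds": {k: [float(a), float(b)] for k, (a, b) in self.bounds.items()},
            "ci": None if self.ci is None else
            {k: [float(a), float(b)] for k, (a, b) in self.ci.items()},
            "converged": bool(self.converged),
        }


def crs_maximize(
    objective,
    bounds,
    seed: int,
    population: int | None = None,
    max_evals: int = 5000,
    ftol: float = 1e-3,
):
    """Controlled Random Search (CRS2 with local mutation) maximization.

    A population of ``max(10 (d+1), 50)`` points is sampled uniformly in the
    box; trial points are reflections of a random simplex member through the
    centroid of d other members, replacing the current worst point when
    better.  Stops when the population's objective spread falls below
    ``ftol`` or after ``max_evals`` evaluations.

    Returns (best_x, best_f, n_evals).
    """
    bounds = np.asarray(bounds, dtype=float)
    lo, hi = bounds[:, 0], bounds[:, 1]
    if not np.all(np.isfinite(bounds)):
        raise ValueError("CRS requires finite box bounds")
    d = len(bounds)
    rng = np.random.default_rng(seed)
    n_pop = population or max(10 * (d + 1), 50)
    X = rng.uniform(lo, hi, size=(n_pop, d))
    f = np.array([objective(x) for x in X])
    n_evals = n_pop
    if not np.any(np.isfinite(f)):
        raise RuntimeError("objective not finite anywhere in the initial population")
    f[~np.isfinite(f)] = -np.inf
    while n_evals < max_evals:
        fin = f[np.isfinite(f)]
        if len(fin) == n_pop and fin.max() - fin.min() < ftol:
            break
        worst = int(np.argmin(f))
        idx = rng.choice(n_pop, size=d + 1, replace=False)
        simplex = X[idx]
        centroid = simplex[:d].mean(axis=0)
        trial = 2.0 * centroid - simplex[d]
        if np.any(trial < lo) or np.any(trial > hi):
            # local mutation around the current best point (CRS2-LM)
            best = X[int(np.argmax(f))]
            w = rng.uniform(0.0, 1.0, size=d)
            trial = np.clip(best + w * (centroid - simplex[d]), lo, hi)
        ft = objective(trial)
        n_evals += 1
        if np.isfinite(ft) and ft > f[worst]:
            X[worst], f[worst] = trial, ft
    best = int(np.argmax(f))
    return X[best].copy(), float(f[best]), n_evals


def nelder_mead_polish(objective, start, bounds, maxiter: int = 2000,
                       xatol: float = 1e-6, fatol: float = 1e-8):
    """Nelder-Mead refinement of ``start``; never returns a worse point.

    Bounds are enforced by scipy's clipping simplex; a degenerate simplex is
    restarted once from the best point found.
    """
    start = np.asarray(start, dtype=float)
    bounds = np.asarray(bounds, dtype=float)
    f0 = objective(start)
    neg = lambda x: -objective(x)
    best_x, best_f = start, f0
    for attempt in range(2):
        res = _sciopt.minimize(
            neg, best_x, method="Nelder-Mead",
            bounds=[tuple(b) for b in bounds],
            options={"maxiter": maxiter, "xatol": xatol, "fatol": fatol},
        )
        if -res.fun > best_f:
            best_x, best_f = np.clip(res.x, bounds[:, 0], bounds[:, 1]), -res.fun
        if res.success:
            break
    return best_x, float(best_f)


def two_step_maximize(objective, bounds, seed: int, max_evals: int = 5000,
                      names=None, transform=None, global_objective=None) -> FitResult:
    """CRS global search followed by Nelder-Mead polish.

    ``global_objective`` (default: ``objective``) is used during the CRS
    phase, allowing a cheaper surrogate (e.g. rounded B-maps) there.
    ``transform`` maps internal coordinates to natural-scale parameters for
    reporting.
    """
    gobj = global_objective or objective
    x0, f0, n_evals = crs_maximize(gobj, bounds, seed=seed, max_evals=max_evals)
    x1, f1 = nelder_mead_polish(objective, x0, bounds)
    fx1 = f1
    if f1 < f0 and gobj is not objective:
        # the surrogate and the exact objective can rank differently
        fx1 = objective(x1)
        f0x = objective(x0)
        if f0x > fx1:
            x1, fx1 = x0, f0x
    vals = transform(x1) if transform is not None else x1
    names = names or [f"x{i}" for i in range(len(x1))]
    return FitResult(
        params=dict(zip(names, np.atleast_1d(vals))),
        lnCL=float(fx1),
        n_evals=n_evals,
        seed=seed,
        bounds={nm: tuple(b) for nm, b in zip(names, np.asarray(bounds, dtype=float))},
    )


def bootstrap_ci(units, fit_fn, n_boot: int = 100, seed: int = 0):
    """Percentile bootstrap CIs over resampled replicate units.

    ``fit_fn(resampled_units) -> dict`` of parameter estimates.  Failed
    refits are recorded and excluded; the returned dict maps parameter name
    to (2.5th, 97.5th percentile).  A ``"_failures"`` key counts failures.
    """
    units = list(units)
    if len(units) < 2:
        raise ValueError("need at least two resampleable units")
    rng = np.random.default_rng(seed)
    draws: dict[str, list] = {}
    failures = 0
    for _ in range(n_boot):
        sample = [units[i] for i in rng.integers(0, len(units), size=len(units))]
        try:
            est = fit_fn(sample)
        except Exception:
            failures += 1
            continue
        for k, v in est.items():
            draws.setdefault(k, []).append(float(v))
    ci = {k: (float(np.percentile(v, 2.5)), float(np.percentile(v, 97.5)))
          for k, v in draws.items()}
    ci["_failures"] = (failures, failures)
    return ci
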