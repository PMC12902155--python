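"""Classic-BGS estimator: composite likelihood of windowed pairwise diversity.

Each window contributes a two-outcome likelihood per site: a random pair of
samples is polymorphic with probability theta_i / (theta_i + 1) and
monomorphic otherwise, where theta_i = B_i * 4 * Nmax * mu_n (divided by
(1 + F) under partial selfing).  The four free parameters are Nmax and the
deleterious DFE (mu, s_mean, beta); the neutral mutation rate mu_n and
dominance h are fixed before fitting.

For samples of n > 2 the polymorphic count p_i is the mean over all sample
pairs, i.e. sum over sites of 2 j (n - j) / (n (n - 1)) for derived count j,
so p_i may be fractional.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .bgs_theory import (
    RANDOM_MATING,
    GammaDFE,
    MatingSystem,
    PairwiseSummer,
    bmap_for_genome,
)
from . import optimize as _opt

__all__ = [
    "WindowedDiversity",
    "ClassicModelConfig",
    "lnCL_diversity",
    "classic_bmap",
    "fit_classic",
]


@dataclass
class WindowedDiversity:
    """Per-window pairwise polymorphic (p) and monomorphic (m) site counts."""

    p: np.ndarray
    m: np.ndarray

    def __post_init__(self):
        self.p = np.asarray(self.p, dtype=float)
        self.m = np.asarray(self.m, dtype=float)
        if np.any(self.p < 0) or np.any(self.m < 0):
            raise ValueError("p and m must be non-negative")
        if len(self.p) != len(self.m):
            raise ValueError("p and m must have equal length")

    def __len__(self) -> int:
        return len(self.p)

    def to_tsv(self, path, genome=None) -> None:
        df = pd.DataFrame({"p": self.p, "m": self.m})
        if genome is not None:
            df.insert(0, "chrom", genome.chrom)
            df.insert(1, "start", genome.start)
            df.insert(2, "end", genome.end)
        df.to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path) -> "WindowedDiversity":
        df = pd.read_csv(path, sep="\t")
        return cls(df["p"].to_numpy(), df["m"].to_numpy())


@dataclass
class ClassicModelConfig:
    """Fixed quantities and DFE for the classic-BGS likelihood.

    ``Ne_truncation`` is the coalescent Ne used for the DFE truncation
    bound; by convention it is implied by observed genome-wide diversity
    (Ne = pi / (4 mu_n)) and is held fixed during fitting.
    """

    Nmax: float
    mu_n: float
    dfe: GammaDFE
    mating: MatingSystem = RANDOM_MATING
    Ne_truncation: float | None = None
    min_callable: float = 1000.0

    def __post_init__(self):
        if self.Nmax <= 0:
            raise ValueError("Nmax must be > 0")
        if self.mu_n <= 0:
            raise ValueError("mu_n must be > 0")

    @property
    def ne_trunc(self) -> float:
        return self.Ne_truncation if self.Ne_truncation is not None else self.Nmax


def theta_per_window(B, config: ClassicModelConfig):
    """theta_i = B_i 4 Nmax mu_n / (1 + F)."""
    F = config.mating.F
    return np.asarray(B) * 4.0 * config.Nmax * config.mu_n / (1.0 + F)


def lnCL_diversity(data: WindowedDiversity, B, config: ClassicModelConfig,
                   include=None) -> float:
    """Log composite likelihood of windowed pairwise diversity.

    ``B`` is the per-window B value (a 1-d array or the first epoch of an
    EpochBMap); windows where ``include`` is False contribute nothing.
    """
    B = np.asarray(B, dtype=float)
    if B.ndim == 2:
        B = B[:, 0]
    if len(B) != len(data):
        raise ValueError("B-map and data have different numbers of windows")
    theta = theta_per_window(B, config)
    if np.any(theta <= 0):
        raise ValueError("theta must be positive in all windows with data")
    if include is None:
        include = np.ones(len(B), dtype=bool)
    t = theta[include]
    return float(
        np.sum(data.p[include] * np.log(t / (1.0 + t)))
        - np.sum(data.m[include] * np.log1p(t))
    )


def classic_bmap(genome, config: ClassicModelConfig, summer=None):
    """B per window under the config's DFE and mating system."""
    B, Bb, Bw = bmap_for_genome(
        genome, config.dfe, config.ne_trunc, config.mating, summer=summer
    )
    return B, Bb, Bw


def fit_classic(
    data: WindowedDiversity,
    genome,
    config: ClassicModelConfig,
    bounds: dict[str, tuple[float, float]],
    seed: int,
    max_evals: int = 3000,
    bootstrap_units=None,
    n_boot: int = 100,
) -> "_opt.FitResult":
    """Maximum composite likelihood fit of (Nmax, mu, s_mean, beta).

    Two-step derivative-free optimization: a Controlled Random Search over
    log10-transformed box bounds followed by a Nelder-Mead polish.  The DFE
    truncation Ne is held at ``config.ne_trunc`` throughout.  ``bounds``
    maps parameter names ("Nmax", "mu", "s_mean", "beta") to (low, high) on
    the natural scale.
    """
    names = ["Nmax", "mu", "s_mean", "beta"]
    for nm in names:
        if nm not in bounds:
            raise ValueError(f"missing bound for {nm}")
    summer = PairwiseSummer(genome)
    include = genome.callable >= config.min_callable

    def objective(x):
        Nmax, mu, s_mean, beta = 10.0 ** np.asarray(x)
        dfe = replace(config.dfe, mu=mu, s_mean=s_mean, beta=beta)
        cfg = replace(config, Nmax=Nmax, dfe=dfe)
        B, _, _ = bmap_for_genome(
            genome, dfe, cfg.ne_trunc, cfg.mating, summer=summer
        )
        return lnCL_diversity(data, B, cfg, include=include)

    log_bounds = [tuple(np.log10(bounds[nm])) for nm in names]
    result = _opt.two_step_maximize(
        objective, log_bounds, seed=seed, max_evals=max_evals, names=names,
        transform=lambda x: 10.0 ** np.asarray(x),
    )
    # report B-bar at the optimum
    dfe = replace(config.dfe, mu=result.params["mu"],
                  s_mean=result.params["s_mean"], beta=result.params["beta"])
    cfg = replace(config, Nmax=result.params["Nmax"], dfe=dfe)
    B, _, _ = bmap_for_genome(genome, dfe, cfg.ne_trunc, cfg.mating, summer=summer)
    result.extras["B"] = B
    result.extras["Bbar"] = float(np.average(B[include], weights=genome.callable[include]))
    if bootstrap_units is not None:
        result.ci = _opt.bootstrap_ci(
            bootstrap_units,
            lambda units: _refit_units(units, genome, config, bounds, seed, max_evals),
            n_boot=n_boot,
            seed=seed,
        )
    return result


def _refit_units(units, genome, config, bounds, seed, max_evals):
    p = np.sum([u.p for u in units], axis=0)
    m = np.sum([u.m for u in units], axis=0)
    res = fit_classic(WindowedDiversity(p, m), genome, config, bounds,
                      seed=seed, max_evals=max_evals)
    return res.params
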