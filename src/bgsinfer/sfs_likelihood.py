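"""Joint inference of background selection, demography and partial selfing
from windowed unfolded site frequency spectra.

The model: demography is piecewise-constant (sizes N_t, boundaries T_t,
most recent epoch first) and shared genome-wide; each window carries
epoch-specific B values computed from the local recombination and
selected-site context.  A window's coalescent history is the demographic
history with every epoch size rescaled by that window's epoch B, plus a
two-step transition in recent time that captures the decline of the
coalescent Ne from Nmax toward B*Nmax as lineages sort into fitness
classes.  Under partial selfing all coalescence rates gain a factor (1+F)
and the sampled spectrum is distorted by non-HWE diploid sampling
(P(het) = 2p(1-p)(1-F)).  Expected spectra come from closed-form branch
lengths of the piecewise-constant coalescent; an allele polarization error
``eps`` swaps mass between frequency classes j and n-j.  The composite
likelihood multiplies multinomial window likelihoods with the monomorphic
class as bin 0.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from ._coalescent import branch_spectrum, diploid_branch_spectrum
from .bgs_theory import (
    RANDOM_MATING,
    GammaDFE,
    MatingSystem,
    PairwiseSummer,
    PiecewiseHistory,
    iterate_epoch_bmap,
    transition_times,
    truncation_bound,
    _transition_fraction,
)
from . import optimize as _opt

__all__ = [
    "PiecewiseHistory",
    "WindowedSFS",
    "SFSModelConfig",
    "window_history",
    "expected_sfs",
    "apply_polarization_error",
    "lnCL_sfs",
    "estimate_epsilon_neutral",
    "fit_joint",
    "fit_pi_selfing",
]

XI_FLOOR = 1e-300


@dataclass
class WindowedSFS:
    """Per-window unfolded SFS counts, monomorphic sites in bin 0.

    ``counts`` has shape (windows, n) for haploid sample size n; bins listed
    in ``masked_bins`` (by derived count j) are excluded from likelihoods.
    """

    counts: np.ndarray
    n: int
    masked_bins: tuple = ()

    def __post_init__(self):
        self.counts = np.atleast_2d(np.asarray(self.counts, dtype=float))
        if self.counts.shape[1] != self.n:
            raise ValueError("counts must have n columns (j = 0..n-1)")
        if np.any(self.counts < 0):
            raise ValueError("counts must be non-negative")
        self.masked_bins = tuple(int(j) for j in self.masked_bins)

    def __len__(self) -> int:
        return self.counts.shape[0]

    def mask_top(self, k: int = 2) -> "WindowedSFS":
        """Mask the k highest derived-count bins (n-1, n-2, ...)."""
        return replace(self, masked_bins=tuple(range(self.n - k, self.n)))

    @property
    def unmasked(self) -> np.ndarray:
        keep = np.ones(self.n, dtype=bool)
        keep[list(self.masked_bins)] = False
        return keep

    def total(self) -> np.ndarray:
        """Genome-wide SFS (summed over windows)."""
        return self.counts.sum(axis=0)

    def pairwise_diversity(self) -> float:
        """Mean pairwise diversity per site implied by the counts."""
        j = np.arange(self.n)
        w = 2.0 * j * (self.n - j) / (self.n * (self.n - 1.0))
        tot = self.counts.sum()
        return float((self.counts @ w).sum() / tot) if tot > 0 else 0.0

    def to_tsv(self, path, genome=None) -> None:
        cols = {f"j{j}": self.counts[:, j] for j in range(self.n)}
        df = pd.DataFrame(cols)
        df.insert(0, "n", self.n)
        if genome is not None:
            df.insert(0, "chrom", genome.chrom)
            df.insert(1, "start", genome.start)
            df.insert(2, "end", genome.end)
        df.to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path) -> "WindowedSFS":
        df = pd.read_csv(path, sep="\t")
        n = int(df["n"].iloc[0])
        counts = df[[f"j{j}" for j in range(n)]].to_numpy(dtype=float)
        return cls(counts, n)


@dataclass
class SFSModelConfig:
    """Fixed inputs of the joint SFS likelihood."""

    dfe: GammaDFE
    history: PiecewiseHistory
    mu_n: float
    epsilon: float = 0.0
    mating: MatingSystem = RANDOM_MATING
    b_round_decimals: int = 2
    min_callable: float = 1000.0

    def __post_init__(self):
        if not 0.0 <= self.epsilon < 0.5:
            raise ValueError("epsilon must be in [0, 0.5)")
        if self.mu_n <= 0:
            raise ValueError("mu_n must be > 0")


# ---------------------------------------------------------------------------
# model building blocks


def window_history(
    history: PiecewiseHistory,
    B: np.ndarray,
    dfe: GammaDFE,
    Ne_for_truncation: float,
    mating: MatingSystem = RANDOM_MATING,
):
    """Per-window piecewise-constant coalescent histories.

    Prepends two short transition epochs to the rescaled demographic
    history: breakpoints are placed where the Nmax -> B*Nmax transition is
    half and 19/20 complete, each step taking the transition Ne at the
    midpoint of its interval.  Under selfing every size is divided by
    (1 + F).

    Returns (durations, Ne) where ``durations`` is a shared (E+2,) array of
    epoch lengths in generations (last entry inf) and ``Ne`` the (W, E+2)
    matrix of effective sizes.
    """
    B = np.atleast_2d(np.asarray(B, dtype=float))
    W, E = B.shape
    if E != history.n_epochs:
        raise ValueError("B must have one column per demographic epoch")
    N = np.asarray(history.N)
    if dfe.mu == 0 or np.allclose(B, 1.0):
        t1, t2 = 1.0, 2.0
        G1 = G2 = 1.0  # degenerate: steps equal B0*N0 = N0
    else:
        t1, t2 = transition_times(dfe, Ne_for_truncation, mating)
        if history.T and t2 >= history.T[0]:
            warnings.warn(
                "transition epochs longer than T0; truncating to fit the first epoch"
            )
            t1 = min(t1, history.T[0] / 3.0)
            t2 = min(t2, 2.0 * history.T[0] / 3.0)
        s_lo = truncation_bound(Ne_for_truncation, dfe.h, mating)
        G1 = _transition_fraction(t1 / 2.0, dfe, s_lo, mating)
        G2 = _transition_fraction((t1 + t2) / 2.0, dfe, s_lo, mating)
    B0 = B[:, 0]
    step1 = N[0] * (1.0 - (1.0 - B0) * G1)
    step2 = N[0] * (1.0 - (1.0 - B0) * G2)
    cols = [step1, step2, B0 * N[0]]
    for e in range(1, E):
        cols.append(B[:, e] * N[e])
    Ne = np.column_stack(cols)
    bounds = [t1, t2] + [t for t in history.T]
    durations = np.diff(np.concatenate([[0.0], bounds, [np.inf]]))
    Ne /= 1.0 + mating.F
    return durations, Ne


def apply_polarization_error(xi: np.ndarray, epsilon: float) -> np.ndarray:
    """Mix frequency classes j and n-j: xi'_j = (1-eps) xi_j + eps xi_{n-j}.

    Applies to segregating entries 1..n-1 only; the fixed-derived class
    (j = n) is taken as zero, so entry j = n/2 and the total over
    segregating entries are conserved.
    """
    if not 0.0 <= epsilon < 0.5:
        raise ValueError("epsilon must be in [0, 0.5)")
    xi = np.atleast_2d(np.asarray(xi, dtype=float))
    n = xi.shape[1]
    out = xi.copy()
    seg = xi[:, 1:]                      # j = 1..n-1
    out[:, 1:] = (1.0 - epsilon) * seg + epsilon * seg[:, ::-1]
    return out


def expected_sfs(
    durations,
    Ne,
    n: int,
    mu_n: float,
    epsilon: float = 0.0,
    mating: MatingSystem = RANDOM_MATING,
    n_diploids: int | None = None,
) -> np.ndarray:
    """Expected per-site SFS proportions xi_j, j = 0..n-1, per window.

    Segregating entries are mu_n times the expected branch length
    subtending j leaves (infinite sites); bin 0 holds the monomorphic
    remainder.  Under selfing (F > 0) the spectrum is computed for
    ``n_diploids`` diploid samples whose within-individual lineage pairs
    are IBD with probability F.  Polarization error is applied last.
    """
    if n < 4:
        raise ValueError("need n >= 4")
    F = mating.F
    if F > 0:
        nd = n_diploids if n_diploids is not None else n // 2
        if 2 * nd != n:
            raise ValueError("n must equal 2 * n_diploids under selfing")
        ell = diploid_branch_spectrum(Ne, durations, nd, F)
    else:
        ell = branch_spectrum(Ne, durations, n)
    xi_seg = mu_n * ell
    xi0 = 1.0 - xi_seg.sum(axis=1)
    if np.any(xi0 < 0):
        raise ValueError(
            "expected monomorphic proportion < 0: theta too large for infinite sites"
        )
    xi = np.column_stack([xi0, xi_seg])
    if epsilon > 0:
        xi = apply_polarization_error(xi, epsilon)
    return xi


def lnCL_sfs(data: WindowedSFS, xi: np.ndarray, include=None) -> float:
    """Composite log likelihood sum_i sum_j p_ij ln xi_ij over unmasked bins.

    Raises if observed counts sit where the model puts (numerically) zero
    probability.
    """
    xi = np.atleast_2d(np.asarray(xi, dtype=float))
    if xi.shape != data.counts.shape:
        raise ValueError("expected xi with the same shape as the data counts")
    keep = data.unmasked
    if include is None:
        include = np.ones(len(data), dtype=bool)
    p = data.counts[np.ix_(include, keep)]
    x = xi[np.ix_(include, keep)]
    bad = (p > 0) & (x <= 0)
    if np.any(bad):
        raise ValueError("observed counts where expected frequency is zero")
    return float(np.sum(p * np.log(np.maximum(x, XI_FLOOR))))


# ---------------------------------------------------------------------------
# fitting


def _history_from_vector(x, n_epochs: int, mating: MatingSystem):
    """(N_0..N_{E-1}, T_0, dT_1, ...) on log10 scale -> PiecewiseHistory."""
    N = 10.0 ** np.asarray(x[:n_epochs])
    T = []
    acc = 0.0
    for i in range(n_epochs - 1):
        acc += 10.0 ** x[n_epochs + i]
        T.append(acc)
    return PiecewiseHistory(tuple(N), tuple(T), mating=mating)


def _expected_windowed_sfs(genome, config: SFSModelConfig, summer=None,
                           initial_Ne=None, round_decimals=None, n: int = 20,
                           return_bmap: bool = False):
    """Expected xi for every window under the full model (grouped by
    identical per-window histories for speed)."""
    mating = config.mating
    ebm = iterate_epoch_bmap(
        genome, config.dfe, config.history, mating,
        initial_Ne=initial_Ne, summer=summer,
    )
    B = ebm.B
    if round_decimals is not None:
        B = np.clip(np.round(B, round_decimals), 1e-6, 1.0)
    Ne0 = initial_Ne if initial_Ne is not None else config.history.Nmax / (1 + mating.F)
    durations, Ne = window_history(
        config.history, B, config.dfe, Ne0, mating,
    )
    uniq, inv = np.unique(np.round(Ne, 6), axis=0, return_inverse=True)
    xi_u = expected_sfs(
        durations, uniq, n, config.mu_n, config.epsilon, mating,
        n_diploids=n // 2,
    )
    xi = xi_u[inv]
    if return_bmap:
        return xi, ebm
    return xi


def fit_joint(
    data: WindowedSFS,
    genome,
    config: SFSModelConfig,
    bounds: dict[str, tuple[float, float]],
    seed: int,
    n_epochs: int | None = None,
    max_evals: int = 4000,
    fit_alpha: bool = False,
) -> "_opt.FitResult":
    """Joint MCL fit of demography, DFE (and optionally selfing rate).

    Parameters are, in order: N_0..N_{E-1}, T_0 (and epoch gaps dT for
    E = 3), mu, s_mean, beta, [alpha].  ``bounds`` uses those names on the
    natural scale.  During the CRS global phase per-window B values are
    rounded to ``config.b_round_decimals`` decimal places so many windows
    share an expected SFS; the Nelder-Mead polish uses unrounded B.
    """
    E = n_epochs if n_epochs is not None else config.history.n_epochs
    names = [f"N{e}" for e in range(E)]
    names += ["T0"] + [f"dT{e}" for e in range(1, E - 1)]
    names += ["mu", "s_mean", "beta"]
    if fit_alpha:
        warnings.warn("free alpha converges slowly; consider fixing it from FIS")
        names += ["alpha"]
    for nm in names:
        if nm not in bounds:
            raise ValueError(f"missing bound for {nm}")
    summer = PairwiseSummer(genome)
    include = genome.callable >= config.min_callable
    pi_obs = data.pairwise_diversity()
    Ne_init = max(pi_obs / (4.0 * config.mu_n), 10.0)
    n_dfe = 3

    def build_config(x):
        x = np.asarray(x, dtype=float)
        k = 2 * E - 1
        if fit_alpha:
            mating = MatingSystem(float(np.clip(x[-1], 0.0, 1.0)))
            xd = x[k:-1]
        else:
            mating = config.mating
            xd = x[k:]
        mu, s_mean, beta = 10.0 ** xd[:n_dfe]
        hist = _history_from_vector(x[:k], E, mating)
        dfe = replace(config.dfe, mu=mu, s_mean=s_mean, beta=beta)
        return replace(config, dfe=dfe, history=hist, mating=mating)

    def objective(x, round_decimals):
        cfg = build_config(x)
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                xi = _expected_windowed_sfs(
                    genome, cfg, summer=summer, initial_Ne=Ne_init,
                    round_decimals=round_decimals, n=data.n,
                )
            return lnCL_sfs(data, xi, include=include)
        except (ValueError, RuntimeError, FloatingPointError):
            return -np.inf

    log_bounds = []
    for nm in names:
        lo, hi = bounds[nm]
        if nm == "alpha":
            log_bounds.append((lo, hi))
        else:
            log_bounds.append((np.log10(lo), np.log10(hi)))

    def transform(x):
        out = []
        for nm, v in zip(names, x):
            out.append(v if nm == "alpha" else 10.0 ** v)
        return np.asarray(out)

    result = _opt.two_step_maximize(
        lambda x: objective(x, None),
        log_bounds,
        seed=seed,
        max_evals=max_evals,
        names=names,
        transform=transform,
        global_objective=lambda x: objective(x, config.b_round_decimals),
    )
    # derived outputs at the optimum
    cfg = build_config([np.log10(result.params[nm]) if nm != "alpha"
                        else result.params[nm] for nm in names])
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        xi, ebm = _expected_windowed_sfs(
            genome, cfg, summer=summer, initial_Ne=Ne_init, n=data.n,
            return_bmap=True,
        )
    result.extras["bmap"] = ebm
    result.extras["Bbar"] = float(
        np.average(ebm.B[include, 0], weights=genome.callable[include])
    )
    result.extras["history"] = cfg.history
    # reconstruct absolute epoch boundaries for reporting
    T = list(cfg.history.T)
    for e, t in enumerate(T):
        result.extras[f"T{e}_abs"] = float(t)
    return result


def fit_pi_selfing(
    data,
    genome,
    config,
    bounds,
    seed: int,
    max_evals: int = 3000,
    **kw,
):
    """BGS-with-partial-selfing fit from windowed diversity only.

    The classic composite likelihood (pairwise polymorphic/monomorphic
    counts) with the selfing B kernels and theta rescaled by 1/(1+F);
    demography is not modeled.  With alpha = 0 this is exactly
    ``fit_classic``.
    """
    from .classic_likelihood import fit_classic

    return fit_classic(data, genome, config, bounds, seed=seed,
                       max_evals=max_evals, **kw)


def estimate_epsilon_neutral(
    sfs: np.ndarray,
    n: int,
    mu_n: float,
    seed: int,
    n_epochs: int = 3,
    bounds: dict | None = None,
    mating: MatingSystem = RANDOM_MATING,
    max_evals: int = 4000,
):
    """Estimate polarization error from a genome-wide SFS under neutrality.

    Fits an ``n_epochs`` piecewise-constant neutral history together with
    eps by maximum composite likelihood; the returned eps is meant to be
    fixed in subsequent BGS fits.  Warns when the input spectrum is
    (nearly) symmetric, in which case eps is unidentifiable, and when the
    estimate sits at the 0.5 boundary.
    """
    sfs = np.asarray(sfs, dtype=float)
    if sfs.shape != (n,):
        raise ValueError("sfs must be the genome-wide spectrum, bins 0..n-1")
    seg = sfs[1:]
    if np.allclose(seg, seg[::-1], rtol=0.05):
        warnings.warn("spectrum is (nearly) symmetric: epsilon is unidentifiable")
    data = WindowedSFS(sfs[None, :], n)
    if bounds is None:
        Ne_guess = max(data.pairwise_diversity() / (4.0 * mu_n), 10.0)
        bounds = {}
        for e in range(n_epochs):
            bounds[f"N{e}"] = (Ne_guess / 100.0, Ne_guess * 100.0)
        bounds["T0"] = (Ne_guess / 100.0, Ne_guess * 100.0)
        for e in range(1, n_epochs - 1):
            bounds[f"dT{e}"] = (Ne_guess / 100.0, Ne_guess * 100.0)
        bounds["eps"] = (0.0, 0.499)
    names = [f"N{e}" for e in range(n_epochs)]
    names += ["T0"] + [f"dT{e}" for e in range(1, n_epochs - 1)]
    names += ["eps"]

    def objective(x):
        hist = _history_from_vector(x[:-1], n_epochs, mating)
        eps = float(np.clip(x[-1], 0.0, 0.4999))
        durations = np.diff(np.concatenate([[0.0], hist.T, [np.inf]]))
        Ne = np.asarray(hist.N)[None, :] / (1.0 + mating.F)
        try:
            xi = expected_sfs(durations, Ne, n, mu_n, eps, mating,
                              n_diploids=n // 2)
            return lnCL_sfs(data, xi)
        except ValueError:
            return -np.inf

    log_bounds = [
        (b[0], b[1]) if nm == "eps" else (np.log10(b[0]), np.log10(b[1]))
        for nm, b in ((nm, bounds[nm]) for nm in names)
    ]

    def transform(x):
        return np.asarray([
            v if nm == "eps" else 10.0 ** v for nm, v in zip(names, x)
        ])

    result = _opt.two_step_maximize(
        objective, log_bounds, seed=seed, max_evals=max_evals,
        names=names, transform=transform,
    )
    eps_hat = float(result.params["eps"])
    if eps_hat > 0.45:
        warnings.warn("epsilon estimate near 0.5: polarization uninformative")
    history = PiecewiseHistory(
        tuple(result.params[f"N{e}"] for e in range(n_epochs)),
        tuple(np.cumsum([result.params["T0"]] +
                        [result.params[f"dT{e}"] for e in range(1, n_epochs - 1)])),
        mating=mating,
    )
    return eps_hat, history, result
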