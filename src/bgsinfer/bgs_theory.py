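"""Analytic background-selection kernels.

Background selection (BGS) reduces neutral diversity at a focal site by a
factor ``B = exp(-sum of per-selected-site exponent terms)``.  This module
provides:

* the per-site exponent under random mating (valid from tight linkage up to
  unlinked sites, r = 1/2) and its partial-selfing counterpart, in which the
  recombination fraction and dominance coefficient are rescaled by the
  equilibrium inbreeding coefficient ``F = alpha / (2 - alpha)``:
  ``r' = r (1 - F)``, ``h' = h (1 - F) + F``;
* the between-window contribution ``Bb`` obtained by integrating the kernel
  over a gamma distribution of fitness effects (DFE) truncated below at
  ``s = 3 / (2 Ne h_eff)``, where selection is too weak relative to drift
  for the deterministic theory to apply;
* the within-window contribution ``Bw``, the average of the per-site
  exponent over uniformly placed selected and neutral positions inside a
  window of recombination fraction ``R``;
* interpolation tables over r and R that make genome-wide B-maps cheap to
  evaluate inside a likelihood;
* the transition of the coalescent effective size from ``Nmax`` toward
  ``B * Nmax`` in recent time, and the fixed-point iteration that makes
  per-epoch B-maps self-consistent with the coalescent Ne they imply.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np
from scipy import integrate, special, stats


@lru_cache(maxsize=32)
def _leggauss(n: int):
    return np.polynomial.legendre.leggauss(n)

__all__ = [
    "GammaDFE",
    "MatingSystem",
    "EpochBMap",
    "exponent_single",
    "exponent_single_selfing",
    "nordborg_exponent",
    "bw_exponent_closed_form",
    "bw_window",
    "bb_window",
    "BInterpolator",
    "build_interpolators",
    "ne_transition",
    "transition_times",
    "iterate_epoch_bmap",
]


# ---------------------------------------------------------------------------
# domain types


@dataclass(frozen=True)
class MatingSystem:
    """Mating system parameterized by the selfing rate alpha.

    F = alpha / (2 - alpha) at inbreeding equilibrium.  Effective
    recombination shrinks by (1 - F) and dominance moves toward 1:
    h' = h (1 - F) + F.
    """

    alpha: float = 0.0

    def __post_init__(self):
        if not 0.0 <= self.alpha <= 1.0:
            raise ValueError("selfing rate alpha must be in [0, 1]")

    @property
    def F(self) -> float:
        return self.alpha / (2.0 - self.alpha)

    def r_eff(self, r):
        return np.asarray(r) * (1.0 - self.F)

    def h_eff(self, h):
        return h * (1.0 - self.F) + self.F


RANDOM_MATING = MatingSystem(0.0)


@dataclass(frozen=True)
class GammaDFE:
    """Gamma distribution of deleterious fitness effects.

    Parameters
    ----------
    mu : deleterious mutation rate per selected site per generation.
    s_mean : mean homozygous selection coefficient (s-bar).
    beta : gamma shape; small beta => many nearly-neutral mutations.
    h : dominance coefficient (0.5 by default; only s*h is identifiable).
    """

    mu: float
    s_mean: float
    beta: float
    h: float = 0.5

    def __post_init__(self):
        if self.mu < 0:
            raise ValueError("mu must be >= 0")
        if not 0 < self.s_mean <= 1:
            raise ValueError("s_mean must be in (0, 1]")
        if self.beta <= 0:
            raise ValueError("beta must be > 0")
        if not 0 <= self.h <= 1:
            raise ValueError("h must be in [0, 1]")

    @property
    def scale(self) -> float:
        return self.s_mean / self.beta

    def pdf(self, s):
        return stats.gamma.pdf(s, a=self.beta, scale=self.scale)

    def truncated_mass(self, s_lo: float, s_hi: float = 1.0) -> float:
        """Probability mass of the DFE on [s_lo, s_hi]."""
        a, sc = self.beta, self.scale
        return float(special.gammainc(a, s_hi / sc) - special.gammainc(a, max(s_lo, 0.0) / sc))

    def quad_nodes(self, s_lo: float, s_hi: float = 1.0, n: int = 96):
        """Gauss-Legendre nodes/weights for integrating kernel(s)*f(s) ds.

        Nodes are placed in log-s, where the kernels vary smoothly; weights
        absorb the pdf and the Jacobian.  Returns (s, w) with
        sum(w * K(s)) ~ integral of f(s) K(s) over [s_lo, s_hi].
        """
        if s_lo >= s_hi:
            return np.empty(0), np.empty(0)
        x, wx = _leggauss(n)
        lo, hi = np.log(s_lo), np.log(s_hi)
        u = 0.5 * (hi - lo) * x + 0.5 * (hi + lo)
        s = np.exp(u)
        w = self.pdf(s) * s * wx * 0.5 * (hi - lo)
        return s, w


# ---------------------------------------------------------------------------
# per-site kernels


def exponent_single(mu_i, s, h, r):
    """Per-site BGS exponent under random mating.

    ``mu_i * s h (1 + (-2r + s h (2r - 1))^2) / (r + s h - r s h)^2``.
    B over many sites is exp(-sum of these).  Valid for any r in [0, 0.5],
    including unlinked sites.
    """
    s, r = np.asarray(s, dtype=float), np.asarray(r, dtype=float)
    sh = s * h
    if np.any((sh <= 0) | (sh >= 1)):
        raise ValueError("requires 0 < s*h < 1 (DFE truncation should exclude s*h = 0)")
    if np.any((r < 0) | (r > 0.5)):
        raise ValueError("recombination fraction must be in [0, 0.5]")
    denom = r + sh - r * sh
    out = mu_i * sh * (1.0 + (-2.0 * r + sh * (2.0 * r - 1.0)) ** 2) / denom**2
    return out if np.ndim(out) else float(out)


def exponent_single_selfing(mu_i, s, h, r, mating: MatingSystem):
    """Per-site BGS exponent under partial selfing.

    ``mu_i * s h' (1 + 2r)^2 / (r' + s h' (1 + 2r))^2`` with r' = r(1-F)
    and h' = h(1-F) + F.  Reduces to the random-mating kernel's r -> 0
    limit (mu/(s h)) when F = 0 and r -> 0.
    """
    s, r = np.asarray(s, dtype=float), np.asarray(r, dtype=float)
    hp = mating.h_eff(h)
    rp = mating.r_eff(r)
    shp = s * hp
    if np.any(shp <= 0):
        raise ValueError("requires s*h' > 0")
    denom = rp + shp * (1.0 + 2.0 * r)
    out = mu_i * shp * (1.0 + 2.0 * r) ** 2 / denom**2
    return out if np.ndim(out) else float(out)


def nordborg_exponent(mu_i, s, h, r):
    """Classic per-site exponent ``mu sh / (sh + r(1 - sh))^2``.

    This is the kernel averaged within windows for Bw; it agrees with
    `exponent_single` under tight linkage but undershoots at loose linkage,
    which is immaterial within a window (R <= 0.5 but typically small).
    """
    s, r = np.asarray(s, dtype=float), np.asarray(r, dtype=float)
    sh = s * h
    out = mu_i * sh / (sh + r * (1.0 - sh)) ** 2
    return out if np.ndim(out) else float(out)


def _kernel_per_mu(s, h, r, mating: MatingSystem):
    """Between-window exponent per unit mu, dispatching on mating system."""
    if mating.alpha == 0.0:
        return exponent_single(1.0, s, h, r)
    return exponent_single_selfing(1.0, s, h, r, mating)


# ---------------------------------------------------------------------------
# within-window exponent (Bw)


def bw_exponent_closed_form(U, R, s, h, mating: MatingSystem = RANDOM_MATING):
    """Within-window exponent for a point DFE at s.

    Average of the Nordborg per-site kernel over uniformly placed selected
    and neutral positions in a window with (effective) recombination
    fraction R, times the diploid deleterious rate U = 2 mu L:

        E = U * (b - a ln(1 + b/a)) / b^2,  a = s h', b = R' (1 - s h')

    with the R -> 0 limit E -> U / (2 s h') = mu L / (s h'), the classic
    zero-recombination exponent.  Distances within the window are assumed
    proportional to position offsets (valid for small R).
    """
    a = np.asarray(s, dtype=float) * mating.h_eff(h)
    b = mating.r_eff(np.asarray(R, dtype=float)) * (1.0 - a)
    small = b < 1e-9 * a
    with np.errstate(divide="ignore", invalid="ignore"):
        val = (b - a * np.log1p(b / a)) / b**2
    # series: b^2/(2a) - b^3/(3a^2) -> val ~ 1/(2a) - b/(3a^2)
    val = np.where(small, 1.0 / (2.0 * a) - b / (3.0 * a**2), val)
    out = U * val
    return out if np.ndim(out) else float(out)


def _bw_exponent_point_bruteforce(U, R, s, h, mating=RANDOM_MATING, n_grid=1000):
    """Discretization oracle: window as n_grid selected x n_grid neutral sites."""
    a = s * mating.h_eff(h)
    x = (np.arange(n_grid) + 0.5) / n_grid
    d = np.abs(x[:, None] - x[None, :])
    r = mating.r_eff(R) * d  # linear map within window
    g = a / (a + r * (1.0 - a)) ** 2
    return 0.5 * U * float(g.mean())


def bw_window(U, R, dfe: GammaDFE, Ne, mating: MatingSystem = RANDOM_MATING,
              n_nodes: int = 96):
    """Within-window B contribution, DFE-integrated.

    Bw = exp(-U * integral f(s) * A(s h_eff, R_eff) ds) over the truncated
    support [3/(2 Ne h_eff), 1], with A the uniform-position average of the
    per-site exponent (see `bw_exponent_closed_form`).
    """
    if U < 0:
        raise ValueError("U must be >= 0")
    if not 0 <= R <= 0.5:
        raise ValueError("R must be in [0, 0.5]")
    if U == 0 or dfe.mu == 0:
        return 1.0
    s_lo = truncation_bound(Ne, dfe.h, mating)
    if s_lo >= 1.0:
        return 1.0
    s, w = dfe.quad_nodes(s_lo, 1.0, n_nodes)
    expo = float(np.sum(w * bw_exponent_closed_form(1.0, R, s, dfe.h, mating)))
    return float(np.exp(-U * expo))


# ---------------------------------------------------------------------------
# between-window exponent (Bb)


def truncation_bound(Ne, h, mating: MatingSystem = RANDOM_MATING) -> float:
    """Lower DFE truncation ``s = 3 / (2 Ne h_eff)``.

    Below this bound drift dominates and the deterministic BGS kernels do
    not apply; such mutations are excluded from the integrals.  Under
    selfing the effective dominance h' is used.
    """
    if Ne <= 0:
        raise ValueError("Ne must be > 0")
    return 3.0 / (2.0 * Ne * mating.h_eff(h))


def bb_integral(r, dfe: GammaDFE, s_lo: float, mating: MatingSystem = RANDOM_MATING,
                n_nodes: int = 96):
    """integral_{s_lo}^{1} f(s) * kernel(s, r) ds per unit mu (vectorized in r)."""
    if s_lo >= 1.0:
        return np.zeros(np.shape(r)) if np.ndim(r) else 0.0
    s, w = dfe.quad_nodes(s_lo, 1.0, n_nodes)
    r = np.asarray(r, dtype=float)
    vals = _kernel_per_mu(s[None, :], dfe.h, r.reshape(-1, 1), mating)
    out = vals @ w
    return out.reshape(np.shape(r)) if np.ndim(r) else float(out[0])


def bb_window(genome, k: int, dfe: GammaDFE, Ne, mating: MatingSystem = RANDOM_MATING,
              quad_rtol: float = 1e-6):
    """Between-window B for window k by adaptive quadrature over the DFE.

    Bb_k = exp(-sum_{i != k} mu L_i * integral f(s) kernel(s, r_ki) ds),
    truncated below at 3/(2 Ne h_eff).  This is the reference (slow) path;
    `build_interpolators` provides the gridded fast path.
    """
    if len(genome) == 0 or dfe.mu == 0:
        return 1.0
    s_lo = truncation_bound(Ne, dfe.h, mating)
    if s_lo >= 1.0:
        return 1.0
    r_row = genome.pairwise_r()[k]
    total = 0.0
    for i in range(len(genome)):
        if i == k or genome.L[i] == 0:
            continue
        val, _ = integrate.quad(
            lambda u: dfe.pdf(np.exp(u)) * np.exp(u)
            * _kernel_per_mu(np.exp(u), dfe.h, r_row[i], mating),
            np.log(s_lo), 0.0, epsrel=quad_rtol, limit=200,
        )
        if not np.isfinite(val):
            raise FloatingPointError(f"non-finite Bb quadrature for window {k} vs {i}")
        total += dfe.mu * genome.L[i] * val
    return float(np.exp(-total))


# ---------------------------------------------------------------------------
# interpolation tables


class BInterpolator:
    """Gridded per-unit-rate exponent integrals over r (between windows) and
    R (within windows), with linear interpolation in the exponent.

    Queries outside the grid are clamped (with a warning).
    """

    def __init__(self, r_grid, bb_values, R_grid, bw_values):
        self.r_grid = np.asarray(r_grid, dtype=float)
        self.bb_values = np.asarray(bb_values, dtype=float)
        self.R_grid = np.asarray(R_grid, dtype=float)
        self.bw_values = np.asarray(bw_values, dtype=float)

    def bb_per_mu(self, r):
        r = np.asarray(r, dtype=float)
        if np.any(r < self.r_grid[0] - 1e-12) or np.any(r > self.r_grid[-1] + 1e-12):
            warnings.warn("r query outside interpolation grid; clamping")
        return np.interp(r, self.r_grid, self.bb_values)

    def bw_per_U(self, R):
        R = np.asarray(R, dtype=float)
        if np.any(R < self.R_grid[0] - 1e-12) or np.any(R > self.R_grid[-1] + 1e-12):
            warnings.warn("R query outside interpolation grid; clamping")
        return np.interp(R, self.R_grid, self.bw_values)


def build_interpolators(
    genome,
    dfe: GammaDFE,
    Ne,
    mating: MatingSystem = RANDOM_MATING,
    n_r: int = 40,
    n_R: int = 11,
    n_nodes: int = 96,
    r_min: float | None = None,
) -> BInterpolator:
    """Evaluate the DFE-integrated exponents on a 40 x 11 grid of r and R.

    r is log-spaced from the smallest positive inter-window recombination
    fraction to 0.5; R is linearly spaced from 0 to the largest window R.
    ``r_min`` short-circuits the pairwise-distance scan when the caller
    already knows the smallest inter-window recombination fraction.
    """
    if len(genome) == 0:
        raise ValueError("empty genome")
    s_lo = truncation_bound(Ne, dfe.h, mating)
    from .genome_model import haldane

    if r_min is None:
        d, same = genome.pairwise_distance()
        off = d[same & (d > 0)]
        d_min = float(off.min()) if len(off) else 1e-8
        r_min = float(haldane(d_min))
    r_min = max(r_min, 1e-12)
    r_grid = np.geomspace(r_min, 0.5, n_r)
    bb_vals = bb_integral(r_grid, dfe, s_lo, mating, n_nodes)
    R_max = max(float(genome.R.max()), 1e-12)
    R_grid = np.linspace(0.0, R_max, n_R)
    if s_lo >= 1.0:
        bw_vals = np.zeros(n_R)
    else:
        s, w = dfe.quad_nodes(s_lo, 1.0, n_nodes)
        bw_vals = np.array(
            [np.sum(w * bw_exponent_closed_form(1.0, R, s, dfe.h, mating)) for R in R_grid]
        )
    return BInterpolator(r_grid, bb_vals, R_grid, bw_vals)


class PairwiseSummer:
    """Precomputed distance-binned weights so that, for every window k,
    ``sum_i L_i * g(r_ki)`` over other windows is a single matvec.

    Distances are binned on a log grid (default 2048 bins); cross-chromosome
    pairs contribute through the unlinked value g(0.5).
    """

    def __init__(self, genome, n_bins: int = 2048):
        from .genome_model import haldane

        d, same = genome.pairwise_distance()
        W = len(genome)
        eye = np.eye(W, dtype=bool)
        linked = same & ~eye
        dl = d[linked]
        pos = dl[dl > 0]
        d_lo = float(pos.min()) if len(pos) else 1e-9
        d_hi = float(dl.max()) if len(dl) else 1.0
        d_hi = max(d_hi, d_lo * (1 + 1e-9))
        edges = np.geomspace(d_lo, d_hi, n_bins)
        self.r_rep = haldane(np.concatenate([[d_lo], np.sqrt(edges[:-1] * edges[1:]), [d_hi]]))
        self.r_min = float(haldane(d_lo))
        idx = np.searchsorted(edges, d, side="left")  # 0 => d <= d_lo
        idx = np.clip(idx, 0, n_bins)
        L = genome.L
        C = np.zeros((W, n_bins + 1))
        for k in range(W):
            row = linked[k]
            if row.any():
                C[k] = np.bincount(idx[k][row], weights=L[row], minlength=n_bins + 1)
        self.C = C
        self.L_cross = np.array([(L[~same[k]] ).sum() for k in range(W)])

    def weighted_sum(self, g_of_r) -> np.ndarray:
        """sum_i L_i g(r_ki) for all k, g given as a callable on r."""
        g_bins = g_of_r(self.r_rep)
        g_half = g_of_r(np.array([0.5]))[0]
        return self.C @ g_bins + self.L_cross * g_half


def bmap_for_genome(
    genome,
    dfe: GammaDFE,
    Ne,
    mating: MatingSystem = RANDOM_MATING,
    summer: PairwiseSummer | None = None,
    interp: BInterpolator | None = None,
    n_nodes: int = 96,
):
    """(B, Bb, Bw) arrays for all windows via the gridded fast path."""
    if summer is None:
        summer = PairwiseSummer(genome)
    if interp is None:
        interp = build_interpolators(genome, dfe, Ne, mating, n_nodes=n_nodes,
                                     r_min=summer.r_min)
    expo_b = dfe.mu * summer.weighted_sum(interp.bb_per_mu)
    Bb = np.exp(-expo_b)
    U = 2.0 * dfe.mu * genome.L
    Bw = np.exp(-U * interp.bw_per_U(genome.R))
    return Bb * Bw, Bb, Bw


# ---------------------------------------------------------------------------
# coalescent-Ne transition and epoch B-maps


def _transition_fraction(t, dfe: GammaDFE, s_lo: float,
                         mating: MatingSystem = RANDOM_MATING, n_nodes: int = 96):
    """G(t) = E_f~[(1 - e^{-s h' t})^2] over the truncated, renormalized DFE."""
    if s_lo >= 1.0:
        return np.ones(np.shape(t)) if np.ndim(t) else 1.0
    s, w = dfe.quad_nodes(s_lo, 1.0, n_nodes)
    mass = w.sum()
    hp = mating.h_eff(dfe.h)
    t = np.asarray(t, dtype=float)
    vals = (1.0 - np.exp(-s[None, :] * hp * t.reshape(-1, 1))) ** 2
    out = (vals @ w) / mass
    return out.reshape(np.shape(t)) if np.ndim(t) else float(out[0])


def ne_transition(t, Nmax, B, dfe: GammaDFE, Ne_for_truncation,
                  mating: MatingSystem = RANDOM_MATING, renormalize: bool = True):
    """Coalescent Ne at time t generations in the past.

    Ne(t) = Nmax * (1 - (1 - B) * G(t)) with G the DFE-averaged
    ``(1 - e^{-s h' t})^2``.  With the truncated support renormalized
    (default) Ne(0) = Nmax and Ne(inf) = B * Nmax; the literal
    unnormalized form is kept behind ``renormalize=False``.
    """
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError("t must be >= 0")
    if not 0 < B <= 1:
        raise ValueError("B must be in (0, 1]")
    s_lo = truncation_bound(Ne_for_truncation, dfe.h, mating)
    G = _transition_fraction(t, dfe, s_lo, mating)
    if not renormalize:
        G = np.asarray(G) * dfe.truncated_mass(s_lo, 1.0)
    out = Nmax * (1.0 - (1.0 - B) * G)
    return out if np.ndim(out) else float(out)


def transition_times(dfe: GammaDFE, Ne_for_truncation,
                     mating: MatingSystem = RANDOM_MATING) -> tuple[float, float]:
    """Times at which the Nmax -> B*Nmax transition is 1/2 and 19/20 complete.

    Solved on G(t) alone, so the times are shared genome-wide (the speed of
    the transition does not depend on B).
    """
    s_lo = truncation_bound(Ne_for_truncation, dfe.h, mating)
    if s_lo >= 1.0:
        return 1.0, 2.0  # degenerate: no selected mass, transition irrelevant
    # G(t) is monotone in t; evaluate on a coarse log grid, then refine
    logt = np.linspace(-10.0, 40.0, 201)
    G = _transition_fraction(np.exp(logt), dfe, s_lo, mating)

    def invert(level):
        lt = np.interp(level, G, logt)
        fine = np.linspace(lt - 0.3, lt + 0.3, 41)
        Gf = _transition_fraction(np.exp(fine), dfe, s_lo, mating)
        return float(np.exp(np.interp(level, Gf, fine)))

    return invert(0.5), invert(0.95)


@dataclass
class PiecewiseHistory:
    """Piecewise-constant demography, most recent epoch first.

    ``N`` are diploid sizes per epoch; ``T`` the epoch boundary times in
    generations (len(T) = len(N) - 1, strictly increasing).  ``Nmax`` is
    N[0] unless overridden.  The mating system applies to the whole history.
    """

    N: tuple
    T: tuple = ()
    mating: MatingSystem = RANDOM_MATING

    def __post_init__(self):
        self.N = tuple(float(n) for n in np.atleast_1d(self.N))
        self.T = tuple(float(t) for t in np.atleast_1d(self.T))
        if any(n <= 0 for n in self.N):
            raise ValueError("epoch sizes must be positive")
        if len(self.T) != len(self.N) - 1:
            raise ValueError("need len(T) == len(N) - 1")
        if any(b <= a for a, b in zip(self.T, self.T[1:])):
            raise ValueError("epoch boundaries must be strictly increasing")

    @property
    def n_epochs(self) -> int:
        return len(self.N)

    @property
    def Nmax(self) -> float:
        return self.N[0]


@dataclass
class EpochBMap:
    """Per-window, per-epoch B values with their Bb/Bw decomposition."""

    B: np.ndarray          # (windows, epochs)
    Bb: np.ndarray
    Bw: np.ndarray
    Bbar: np.ndarray       # per-epoch genome-wide mean over callable windows
    n_iterations: int = 0

    def __post_init__(self):
        for name in ("B", "Bb", "Bw"):
            a = np.atleast_2d(np.asarray(getattr(self, name), dtype=float))
            setattr(self, name, a)
        if np.any(self.B <= 0) or np.any(self.B > 1 + 1e-12):
            raise ValueError("B must be in (0, 1]")

    def to_frame(self, genome):
        import pandas as pd

        rows = []
        for e in range(self.B.shape[1]):
            rows.append(pd.DataFrame({
                "chrom": genome.chrom, "start": genome.start, "end": genome.end,
                "epoch": e, "Bb": self.Bb[:, e], "Bw": self.Bw[:, e],
                "B": self.B[:, e],
            }))
        return pd.concat(rows, ignore_index=True)

    def to_tsv(self, path, genome) -> None:
        self.to_frame(genome).to_csv(path, sep="\t", index=False)


def plot_reduction_vs_r(dfe: GammaDFE, Ne, L: float = 1e6,
                        mating: MatingSystem = RANDOM_MATING,
                        r_range=(1e-6, 0.5), ax=None, **kwargs):
    """Plot the predicted diversity reduction 1 - B against recombination
    distance r from a block of ``L`` selected sites under the DFE.

    Visualizes how each DFE parameter shapes linked diversity: mu scales the
    curve uniformly, s_mean shifts the reach of the reduction in r, and beta
    spreads it.  Returns the matplotlib axes.
    """
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    s_lo = truncation_bound(Ne, dfe.h, mating)
    r = np.geomspace(r_range[0], r_range[1], 200)
    reduction = 1.0 - np.exp(-dfe.mu * L * bb_integral(r, dfe, s_lo, mating))
    ax.plot(r, reduction, **kwargs)
    ax.set_xscale("log")
    ax.set_xlabel("recombination distance r")
    ax.set_ylabel("1 - B")
    return ax


def iterate_epoch_bmap(
    genome,
    dfe: GammaDFE,
    history: PiecewiseHistory,
    mating: MatingSystem | None = None,
    initial_Ne: float | None = None,
    rel_tol: float = 1e-3,
    max_iter: int = 50,
    summer: PairwiseSummer | None = None,
    n_nodes: int = 96,
) -> EpochBMap:
    """Self-consistent per-epoch B-map.

    The DFE truncation bound in each epoch depends on that epoch's
    coalescent Ne = B-bar_t * N_t / (1 + F), which itself depends on the
    B-map; iterate until successive values of B-bar_t * N_t change by less
    than ``rel_tol`` in every epoch.
    """
    if mating is None:
        mating = history.mating
    W, E = len(genome), history.n_epochs
    F = mating.F
    if dfe.mu == 0:
        ones = np.ones((W, E))
        return EpochBMap(ones, ones.copy(), ones.copy(),
                         np.ones(E), n_iterations=0)
    if summer is None:
        summer = PairwiseSummer(genome)
    if initial_Ne is None:
        initial_Ne = history.Nmax / (1.0 + F)
    use = genome.callable > 0
    weights = genome.callable[use]
    Ne_coal = np.full(E, float(initial_Ne))
    prev = None
    B = Bb = Bw = None
    for it in range(1, max_iter + 1):
        B = np.empty((W, E))
        Bb = np.empty((W, E))
        Bw = np.empty((W, E))
        for e in range(E):
            Be, Bbe, Bwe = bmap_for_genome(
                genome, dfe, Ne_coal[e], mating, summer=summer, n_nodes=n_nodes
            )
            B[:, e], Bb[:, e], Bw[:, e] = Be, Bbe, Bwe
        Bbar = np.array([np.average(B[use, e], weights=weights) for e in range(E)])
        target = Bbar * np.asarray(history.N)
        if prev is not None and np.all(np.abs(target - prev) <= rel_tol * np.abs(prev)):
            return EpochBMap(B, Bb, Bw, Bbar, n_iterations=it)
        prev = target
        Ne_coal = target / (1.0 + F)
    raise RuntimeError(
        f"epoch B-map iteration did not converge in {max_iter} iterations; "
        f"last B-bar*N = {prev}"
    )
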