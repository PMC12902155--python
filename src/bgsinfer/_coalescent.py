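"""Expected branch-length spectra under piecewise-constant coalescent histories.

The number-of-lineages process of the Kingman coalescent is a pure death
process with rate k(k-1)/2 in coalescent time.  For a piecewise-constant
history the cumulative coalescent time Lambda(t) is piecewise linear, so the
probability of having k ancestral lineages at generation t is a finite
mixture of exponentials in Lambda(t) (Tavare's formula), and the expected
time spent with k lineages reduces to closed-form per-epoch integrals.

Coefficients alternate in sign and grow combinatorially with sample size;
they are accumulated in extended precision (long double) which keeps n up to
a few tens well-conditioned.  Everything here works in units of generations
and diploid sizes N (coalescence rate 1/(2N) per pair per generation).
"""

from __future__ import annotations

from functools import lru_cache

import numpy as np
from scipy import special, stats

__all__ = [
    "expected_durations",
    "branch_spectrum",
    "diploid_branch_spectrum",
    "expected_pairwise_time",
]


@lru_cache(maxsize=64)
def _tavare_matrix(n: int) -> np.ndarray:
    """A[k-2, i-2] such that P(k lineages at tau | n at 0) =
    sum_i A[k,i] * exp(-i(i-1)/2 * tau), for k, i in 2..n."""
    A = np.zeros((n - 1, n - 1), dtype=np.longdouble)
    for k in range(2, n + 1):
        for i in range(k, n + 1):
            # (2i-1) (-1)^(i-k) * rising(k, i-1) * falling(n, i)
            #   / ( k! (i-k)! rising(n, i) )
            term = np.longdouble(2 * i - 1)
            if (i - k) % 2:
                term = -term
            for m in range(i - 1):
                term *= np.longdouble(k + m)
            for m in range(i):
                term *= np.longdouble(n - m)
                term /= np.longdouble(n + m)
            term /= np.longdouble(special.factorial(k, exact=True))
            term /= np.longdouble(special.factorial(i - k, exact=True))
            A[k - 2, i - 2] = term
    return A


def _rho_integrals(N: np.ndarray, durations: np.ndarray, n: int) -> np.ndarray:
    """rho_i = integral_0^inf exp(-i(i-1)/2 * Lambda(t)) dt for i = 2..n.

    ``N`` is (W, E) diploid sizes per window and epoch, ``durations`` (E,)
    epoch lengths in generations with the last entry inf.  Returns (W, n-1).
    """
    N = np.atleast_2d(np.asarray(N, dtype=float))
    durations = np.asarray(durations, dtype=float)
    W, E = N.shape
    lam = np.array([i * (i - 1) / 2.0 for i in range(2, n + 1)])  # (n-1,)
    rho = np.zeros((W, n - 1), dtype=np.longdouble)
    Lam0 = np.zeros(W)  # Lambda at epoch start
    for e in range(E):
        Ne = N[:, e]
        with np.errstate(over="ignore"):
            pre = np.exp(-lam[None, :] * Lam0[:, None])
        if np.isinf(durations[e]):
            rho += pre * (2.0 * Ne[:, None] / lam[None, :])
            break
        dLam = durations[e] / (2.0 * Ne)
        rho += pre * (2.0 * Ne[:, None] / lam[None, :]) * (
            -np.expm1(-lam[None, :] * dLam[:, None])
        )
        Lam0 = Lam0 + dLam
    return rho


def expected_durations(N, durations, n: int) -> np.ndarray:
    """E[time with k lineages] in generations, k = 2..n; shape (W, n-1)."""
    A = _tavare_matrix(n)
    rho = _rho_integrals(N, durations, n)
    ET = rho @ A.T  # (W, n-1) over k
    return np.asarray(np.maximum(ET, 0.0), dtype=float)


@lru_cache(maxsize=64)
def _subtend_matrix(n: int) -> np.ndarray:
    """P[branch during k-lineage period subtends j leaves] as (j-1, k-2)."""
    P = np.zeros((n - 1, n - 1))
    for k in range(2, n + 1):
        for j in range(1, n - k + 2):
            P[j - 1, k - 2] = (
                special.comb(n - j - 1, k - 2) / special.comb(n - 1, k - 1)
            )
    return P


def branch_spectrum(N, durations, n: int) -> np.ndarray:
    """Expected branch length subtending j = 1..n-1 leaves, in generations.

    Shape (W, n-1).  For constant N this reduces to E[l_j] = 4N/j.
    """
    ET = expected_durations(N, durations, n)  # (W, k)
    k = np.arange(2, n + 1)
    P = _subtend_matrix(n)  # (j, k)
    return (ET * k[None, :]) @ P.T


def expected_pairwise_time(N, durations) -> np.ndarray:
    """E[TMRCA] of a pair in generations (constant N gives 2N)."""
    return expected_durations(N, durations, 2)[:, 0]


@lru_cache(maxsize=256)
def _ibd_mapping(n_d: int, k_ibd: int) -> np.ndarray:
    """Map a branch spectrum over n_eff = 2*n_d - k_ibd lineages to derived
    counts in the sample of n = 2*n_d alleles, where k_ibd lineages are
    counted twice (both alleles of a selfed, identical-by-descent diploid).

    Returns M with shape (n-1, n_eff-1): sample_l = M @ l_eff.  A branch
    subtending j of the n_eff exchangeable lineages contains
    x ~ Hypergeometric(n_eff, k_ibd, j) doubled lineages, giving sample
    count c = j + x (c = n is excluded: that branch is the root side).
    """
    n = 2 * n_d
    n_eff = n - k_ibd
    M = np.zeros((n - 1, n_eff - 1))
    for j in range(1, n_eff):
        rv = stats.hypergeom(n_eff, k_ibd, j)
        for x in range(max(0, j + k_ibd - n_eff), min(k_ibd, j) + 1):
            c = j + x
            if 1 <= c <= n - 1:
                M[c - 1, j - 1] += rv.pmf(x)
    return M


def diploid_branch_spectrum(N, durations, n_diploids: int, F: float) -> np.ndarray:
    """Expected branch spectrum for 2*n_diploids sampled alleles under
    inbreeding coefficient F.

    Each diploid's two lineages are identical by descent with probability F
    (coalescing at the sampling time, before entering the population
    process); the remaining distinct lineages follow the history in ``N``
    (whose sizes should already carry any (1+F) rate rescaling).  Mixing
    over the binomial number of IBD pairs compounds the population spectrum
    with non-HWE diploid sampling, P(het) = 2p(1-p)(1-F).
    """
    n = 2 * n_diploids
    if F == 0.0:
        return branch_spectrum(N, durations, n)
    N = np.atleast_2d(np.asarray(N, dtype=float))
    W = N.shape[0]
    out = np.zeros((W, n - 1))
    pK = stats.binom.pmf(np.arange(n_diploids + 1), n_diploids, F)
    for k_ibd in range(n_diploids + 1):
        if pK[k_ibd] < 1e-14:
            continue
        n_eff = n - k_ibd
        if n_eff < 2:
            continue  # all lineages IBD-paired down to < 2: no branches
        l_eff = branch_spectrum(N, durations, n_eff)
        M = _ibd_mapping(n_diploids, k_ibd)
        out += pK[k_ibd] * (l_eff @ M.T)
    return out
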