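"""Synthetic genomes, model-based data samplers, and simulation oracles.

Three layers of ground truth, all deterministic under a fixed seed:

* ``make_toy_genome`` builds small genomes with heterogeneous selected-site
  density and recombination (uniform or hotspot), standing in for the gene
  / recombination landscape real analyses condition on;
* ``sample_windowed_sfs`` / ``sample_windowed_diversity`` draw data from
  the inference model itself (multinomial site counts given the expected
  spectra), enabling parameter-recovery tests;
* ``coalescent_oracle`` (Monte-Carlo genealogies under piecewise-constant
  rates, with selfing handled as instant within-diploid coalescence with
  probability F plus (1+F)-rescaled rates) and ``wf_forward_oracle`` (a
  discrete Wright-Fisher population with multiplicative selection against
  gamma-distributed deleterious mutations, crossover per the map, and
  selfing) validate the analytic kernels independently of the model's own
  machinery.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .genome_model import RecombinationMap, SelectedAnnotation, WindowedGenome, build_windows

__all__ = [
    "ToyGenomeConfig",
    "make_toy_genome",
    "sample_windowed_sfs",
    "sample_windowed_diversity",
    "coalescent_oracle",
    "wf_forward_oracle",
]


@dataclass(frozen=True)
class ToyGenomeConfig:
    """Layout of a synthetic genome.

    ``selected_fraction`` of each chromosome is covered by selected blocks
    of ``block_size`` sites whose local density varies smoothly along the
    chromosome (emulating gene-density variation).  ``hotspot_fold`` > 1
    overlays recombination hotspots of ``hotspot_length`` sites at rate
    ``rate * hotspot_fold`` on a uniform background.
    """

    n_chromosomes: int = 3
    chrom_length: int = 2_000_000
    selected_fraction: float = 0.2
    block_size: int = 2_000
    rate: float = 1e-8
    hotspot_fold: float = 1.0
    hotspot_length: int = 20_000
    n_hotspots: int = 0
    window_size: int = 10_000
    density_amplitude: float = 0.8
    density_periods: float = 1.0
    gene_free_chromosomes: int = 0
    seed: int = 0

    def __post_init__(self):
        if not 0.0 <= self.selected_fraction <= 1.0:
            raise ValueError("selected_fraction must be in [0, 1]")
        if min(self.n_chromosomes, self.chrom_length, self.block_size,
               self.window_size) <= 0:
            raise ValueError("all lengths must be positive")


def make_toy_genome(cfg: ToyGenomeConfig, mu: float = 0.0):
    """Deterministically build (RecombinationMap, SelectedAnnotation,
    WindowedGenome) from a ToyGenomeConfig."""
    rng = np.random.default_rng(cfg.seed)
    if cfg.selected_fraction > 0 and cfg.block_size > cfg.chrom_length * cfg.selected_fraction:
        raise ValueError("block_size too large for the requested selected fraction")
    ann_iv: dict[str, np.ndarray] = {}
    map_iv: dict[str, np.ndarray] = {}
    map_rt: dict[str, np.ndarray] = {}
    for c in range(cfg.n_chromosomes):
        chrom = f"chr{c + 1}"
        # selected blocks: one slot per block_size/selected_fraction stretch,
        # kept with a probability that varies sinusoidally along the chromosome
        blocks = []
        gene_free = c >= cfg.n_chromosomes - cfg.gene_free_chromosomes
        if cfg.selected_fraction > 0 and not gene_free:
            if cfg.selected_fraction <= 0.5:
                # half-occupancy slots: keep probability averages 1/2 and is
                # modulated along the chromosome (gene-density variation)
                slot = int(round(cfg.block_size / (2.0 * cfg.selected_fraction)))
                base_keep = 0.5
            else:
                slot = int(round(cfg.block_size / cfg.selected_fraction))
                base_keep = 1.0
            n_slots = cfg.chrom_length // slot
            for i in range(n_slots):
                center = (i + 0.5) / max(n_slots, 1)
                keep_p = base_keep * (1.0 + cfg.density_amplitude * np.sin(
                    2 * np.pi * (cfg.density_periods * center + 0.13 * c)))
                if rng.random() < np.clip(keep_p, 0.0, 1.0):
                    off = int(rng.integers(0, max(slot - cfg.block_size, 0) + 1))
                    s = i * slot + off
                    blocks.append((s, min(s + cfg.block_size, cfg.chrom_length)))
        ann_iv[chrom] = np.asarray(blocks, dtype=np.int64).reshape(-1, 2)
        # recombination: uniform background, optional hotspots
        if cfg.n_hotspots > 0 and cfg.hotspot_fold != 1.0:
            edges = [0]
            rates = []
            centers = np.sort(rng.integers(
                cfg.hotspot_length, cfg.chrom_length - cfg.hotspot_length,
                size=cfg.n_hotspots))
            for h in centers:
                s, e = int(h), int(h) + cfg.hotspot_length
                if s <= edges[-1]:
                    continue
                edges += [s, e]
                rates += [cfg.rate, cfg.rate * cfg.hotspot_fold]
            edges.append(cfg.chrom_length)
            rates.append(cfg.rate)
            iv = np.column_stack([edges[:-1], edges[1:]]).astype(np.int64)
            map_iv[chrom] = iv
            map_rt[chrom] = np.asarray(rates, dtype=float)
        else:
            map_iv[chrom] = np.array([[0, cfg.chrom_length]], dtype=np.int64)
            map_rt[chrom] = np.array([cfg.rate])
    rmap = RecombinationMap(map_iv, map_rt)
    ann = SelectedAnnotation(ann_iv)
    genome = build_windows(rmap, ann, cfg.window_size, mu=mu)
    return rmap, ann, genome


# ---------------------------------------------------------------------------
# model-based samplers


def sample_windowed_sfs(genome, config, n: int, seed: int, depth: float = 1.0):
    """Draw per-window SFS counts multinomially from the model's expected
    spectra (callable sites trials per window).

    ``depth`` multiplies the trial count per window, emulating data pooled
    over ``depth`` independent simulation replicates of the same genome.

    Returns (WindowedSFS, truth) where ``truth`` records the generating
    expected spectra and the config.
    """
    from .sfs_likelihood import WindowedSFS, _expected_windowed_sfs

    rng = np.random.default_rng(seed)
    # condition the truncation / transition Ne on the model's own expected
    # diversity, mirroring what a fit to the resulting data will do with
    # the observed diversity
    xi = _expected_windowed_sfs(genome, config, n=n)
    j = np.arange(n)
    wpair = 2.0 * j * (n - j) / (n * (n - 1.0))
    pi_exp = float(np.average(xi @ wpair, weights=np.maximum(genome.callable, 1.0)))
    xi = _expected_windowed_sfs(genome, config, n=n,
                                initial_Ne=max(pi_exp / (4.0 * config.mu_n), 10.0))
    counts = np.empty_like(xi)
    for i in range(len(genome)):
        counts[i] = rng.multinomial(int(genome.callable[i] * depth),
                                    xi[i] / xi[i].sum())
    return WindowedSFS(counts, n), {"xi": xi, "config": config}


def sample_windowed_diversity(genome, B, Nmax: float, mu_n: float, seed: int,
                              F: float = 0.0, depth: float = 1.0):
    """Draw pairwise polymorphic/monomorphic counts from the classic model.

    Each callable site is pairwise-polymorphic with probability
    theta_i / (1 + theta_i), theta_i = B_i 4 Nmax mu_n / (1 + F).
    ``depth`` multiplies the trial count (pooled replicates).
    """
    from .classic_likelihood import WindowedDiversity

    rng = np.random.default_rng(seed)
    theta = np.asarray(B) * 4.0 * Nmax * mu_n / (1.0 + F)
    trials = (genome.callable * depth).astype(int)
    p = rng.binomial(trials, theta / (1.0 + theta))
    return WindowedDiversity(p, trials - p)


# ---------------------------------------------------------------------------
# Monte-Carlo coalescent oracle


def coalescent_oracle(durations, N, n: int, reps: int, seed: int,
                      F: float = 0.0, n_diploids: int | None = None):
    """Monte-Carlo expected branch spectrum and pairwise TMRCA.

    Simulates ``reps`` genealogies of ``n`` lineages under the
    piecewise-constant history (``durations`` in generations, last inf;
    ``N`` diploid sizes, which should already include any (1+F) rescaling).
    With F > 0 the sample is ``n_diploids`` diploids whose two lineages
    coalesce immediately with probability F.

    Returns dict with per-bin mean branch lengths (generations), their
    standard errors, and mean pairwise TMRCA.
    """
    if reps < 10:
        raise ValueError("reps too small for a meaningful oracle")
    rng = np.random.default_rng(seed)
    durations = np.asarray(durations, dtype=float)
    N = np.asarray(N, dtype=float)
    # cumulative Lambda at epoch boundaries for generation<->coalescent time
    fin = np.isfinite(durations)
    dLam = np.where(fin, durations / (2.0 * N), np.inf)
    Lam_edges = np.concatenate([[0.0], np.cumsum(dLam)])
    t_edges = np.concatenate([[0.0], np.cumsum(np.where(fin, durations, np.inf))])

    def lam_to_gen(lam):
        e = np.searchsorted(Lam_edges, lam, side="right") - 1
        e = np.clip(e, 0, len(N) - 1)
        return t_edges[e] + (lam - Lam_edges[e]) * 2.0 * N[e]

    spectrum = np.zeros((reps, n - 1))
    tpair = np.full(reps, np.nan)

    def run_group(rep_idx, counts0, la0=0, lb0=1):
        """Vectorized genealogy simulation for replicates sharing a start
        configuration ``counts0`` (list of lineage leaf-counts).  ``la0``
        and ``lb0`` are the slots of the two focal lineages whose merge
        time is recorded as the pairwise TMRCA (equal slots => time 0)."""
        R = len(rep_idx)
        if R == 0:
            return
        k0 = len(counts0)
        counts = np.tile(np.asarray(counts0, dtype=np.int64), (R, 1))
        la = np.full(R, la0, dtype=np.int64)
        lb = np.full(R, lb0, dtype=np.int64)
        t_rec = np.full(R, 0.0 if la0 == lb0 else np.nan)
        lam = np.zeros(R)
        rows = np.arange(R)
        for k in range(k0, 1, -1):
            rate = k * (k - 1) / 2.0
            t0 = lam_to_gen(lam)
            lam = lam + rng.exponential(1.0 / rate, size=R)
            t1 = lam_to_gen(lam)
            dt = t1 - t0
            live = counts[:, :k]
            np.add.at(
                spectrum,
                (np.repeat(rep_idx, k), (live - 1).ravel()),
                np.repeat(dt, k),
            )
            a = rng.integers(0, k, size=R)
            b = (a + 1 + rng.integers(0, k - 1, size=R)) % k
            # keep the merged lineage out of the vacated last slot
            swap = a == k - 1
            a, b = np.where(swap, b, a), np.where(swap, a, b)
            hit = np.isnan(t_rec) & (((la == a) & (lb == b)) | ((la == b) & (lb == a)))
            t_rec[hit] = t1[hit]
            counts[rows, a] += counts[rows, b]
            # remove slot b by moving the last live slot into it
            counts[rows, b] = counts[rows, k - 1]
            la = np.where(la == b, a, np.where(la == k - 1, b, la))
            lb = np.where(lb == b, a, np.where(lb == k - 1, b, lb))
            merged_focal = la == lb
            t_rec[np.isnan(t_rec) & merged_focal] = t1[np.isnan(t_rec) & merged_focal]
        tpair[rep_idx] = t_rec

    if F > 0:
        nd = n_diploids if n_diploids is not None else n // 2
        if 2 * nd != n:
            raise ValueError("n must be 2 * n_diploids when F > 0")
        m_ibd = rng.binomial(nd, F, size=reps)
        for m in np.unique(m_ibd):
            m = int(m)
            idx = np.flatnonzero(m_ibd == m)
            counts0 = [2] * m + [1] * (2 * (nd - m))
            if m < nd:
                # focal pair: both alleles of a random diploid; with
                # probability m/nd that diploid is IBD (TMRCA 0)
                run_group(idx, counts0, la0=m, lb0=m + 1)
                focal_ibd = idx[rng.random(len(idx)) < m / nd]
                tpair[focal_ibd] = 0.0
            elif len(counts0) >= 2:
                run_group(idx, counts0, la0=0, lb0=0)
            else:
                spectrum[idx] = 0.0
                tpair[idx] = 0.0
    else:
        run_group(np.arange(reps), [1] * n)
    return {
        "branch_lengths": spectrum.mean(axis=0),
        "branch_se": spectrum.std(axis=0, ddof=1) / np.sqrt(reps),
        "pairwise_t": float(tpair.mean()),
        "pairwise_t_se": float(tpair.std(ddof=1) / np.sqrt(reps)),
        "reps": reps,
    }


# ---------------------------------------------------------------------------
# Wright-Fisher forward oracle


_KERNELS = None


def _build_kernels():
    """JIT-compiled inner loops of the forward simulator (compiled lazily on
    first use; the hot path is ~2N x S byte operations per generation)."""
    from numba import njit

    @njit(cache=False)
    def fitness_kernel(haps, del_cols, log_het, log_hom):
        N = haps.shape[0] // 2
        out = np.zeros(N)
        for i in range(N):
            acc = 0.0
            for k in range(del_cols.size):
                col = del_cols[k]
                g = haps[2 * i, col] + haps[2 * i + 1, col]
                if g == 1:
                    acc += log_het[k]
                elif g == 2:
                    acc += log_hom[k]
            out[i] = acc
        return out

    @njit(cache=False)
    def gamete_kernel(haps, child, par, phase0, px, offsets, col_order, pos,
                      col_bounds):
        n2 = child.shape[0]
        n_chrom = phase0.shape[1]
        for g in range(n2):
            a = 2 * par[g]
            for c in range(n_chrom):
                ph = int(phase0[g, c])
                ptr = offsets[g * n_chrom + c]
                end = offsets[g * n_chrom + c + 1]
                for idx in range(col_bounds[c], col_bounds[c + 1]):
                    col = col_order[idx]
                    p = pos[col]
                    while ptr < end and px[ptr] <= p:
                        ph ^= 1
                        ptr += 1
                    child[g, col] = haps[a + ph, col]

    return fitness_kernel, gamete_kernel


def _fitness_kernel(haps, del_cols, log_het, log_hom):
    global _KERNELS
    if _KERNELS is None:
        _KERNELS = _build_kernels()
    return _KERNELS[0](haps, del_cols, log_het, log_hom)


def _gamete_kernel(haps, child, par, phase0, px, offsets, col_order, pos,
                   col_bounds):
    global _KERNELS
    if _KERNELS is None:
        _KERNELS = _build_kernels()
    return _KERNELS[1](haps, child, par, phase0, px, offsets, col_order, pos,
                       col_bounds)


class _Population:
    """Bit-matrix Wright-Fisher population with sparse mutation tracking."""

    def __init__(self, N, rmap, ann, capacity, rng, rng_repro=None):
        self.N = N
        self.rng = rng                      # mutation / placement stream
        self.rng_repro = rng_repro or rng   # reproduction stream (see oracle)
        self.chrom_names = rmap.chromosomes
        self.n_chrom = len(self.chrom_names)
        self.chrom_len = np.array([rmap.chrom_length(c) for c in self.chrom_names])
        self.morgans = np.array([rmap.chrom_morgans(c) for c in self.chrom_names])
        self.rmap = rmap
        # selected intervals, flattened with cumulative length for sampling
        self.sel_iv = [ann.intervals.get(c, np.empty((0, 2), dtype=np.int64))
                       for c in self.chrom_names]
        self.L_sel = np.array([float((iv[:, 1] - iv[:, 0]).sum()) if len(iv) else 0.0
                               for iv in self.sel_iv])
        self.L_neu = self.chrom_len - self.L_sel
        self.haps = np.zeros((2 * N, capacity), dtype=np.uint8)
        self.chrom_of = np.zeros(capacity, dtype=np.int16)
        self.pos = np.zeros(capacity, dtype=np.float64)
        self.s = np.zeros(capacity, dtype=np.float64)
        self.is_del = np.zeros(capacity, dtype=bool)
        self.S = 0

    def _grow(self, need):
        cap = self.haps.shape[1]
        if self.S + need <= cap:
            return
        new_cap = max(2 * cap, self.S + need)
        for name in ("chrom_of", "pos", "s", "is_del"):
            arr = getattr(self, name)
            new = np.zeros(new_cap, dtype=arr.dtype)
            new[: self.S] = arr[: self.S]
            setattr(self, name, new)
        new_h = np.zeros((2 * self.N, new_cap), dtype=np.uint8)
        new_h[:, : self.S] = self.haps[:, : self.S]
        self.haps = new_h

    def _sample_positions(self, chrom_idx, selected, size):
        if selected:
            iv = self.sel_iv[chrom_idx]
            lens = (iv[:, 1] - iv[:, 0]).astype(float)
            cum = np.cumsum(lens)
            u = self.rng.random(size) * cum[-1]
            b = np.searchsorted(cum, u, side="right")
            off = u - np.concatenate([[0.0], cum])[b]
            return iv[b, 0] + off
        # neutral: rejection-sample outside selected intervals
        out = np.empty(size)
        filled = 0
        iv = self.sel_iv[chrom_idx]
        while filled < size:
            cand = self.rng.random(size - filled) * self.chrom_len[chrom_idx]
            if len(iv):
                b = np.searchsorted(iv[:, 0], cand, side="right") - 1
                inside = (b >= 0) & (cand < iv[np.clip(b, 0, len(iv) - 1), 1])
                cand = cand[~inside]
            out[filled: filled + len(cand)] = cand
            filled += len(cand)
        return out

    def mutate(self, mu_del, mu_neu, dfe):
        rng = self.rng
        counts = []
        for c in range(self.n_chrom):
            nd = rng.poisson(2 * self.N * mu_del * self.L_sel[c])
            nn = rng.poisson(2 * self.N * mu_neu * self.L_neu[c])
            counts.append((nd, nn))
        total = sum(a + b for a, b in counts)
        if total == 0:
            return
        self._grow(total)
        for c, (nd, nn) in enumerate(counts):
            for selected, cnt in ((True, nd), (False, nn)):
                if cnt == 0:
                    continue
                sl = slice(self.S, self.S + cnt)
                self.chrom_of[sl] = c
                self.pos[sl] = self._sample_positions(c, selected, cnt)
                self.is_del[sl] = selected
                if selected:
                    self.s[sl] = np.minimum(
                        rng.gamma(dfe.beta, dfe.scale, size=cnt), 1.0)
                carriers = rng.integers(0, 2 * self.N, size=cnt)
                self.haps[carriers, np.arange(self.S, self.S + cnt)] = 1
                self.S += cnt

    def fitness(self, h):
        idx = np.flatnonzero(self.is_del[: self.S])
        if len(idx) == 0:
            return np.full(self.N, 1.0)
        s = self.s[idx]
        logw = _fitness_kernel(self.haps, idx, np.log1p(-h * s), np.log1p(-s))
        logw -= logw.max()
        return np.exp(logw)

    def next_generation(self, h, alpha):
        rng = self.rng_repro
        w = self.fitness(h)
        tot = w.sum()
        if not np.isfinite(tot) or tot <= 0:
            raise RuntimeError(
                "population fitness collapsed (all individuals inviable); "
                "use a weaker DFE or larger N")
        cum = np.cumsum(w / tot)
        mothers = np.searchsorted(cum, rng.random(self.N))
        fathers = np.searchsorted(cum, rng.random(self.N))
        if alpha > 0:
            selfed = rng.random(self.N) < alpha
            fathers[selfed] = mothers[selfed]
        par = np.empty(2 * self.N, dtype=np.int64)
        par[0::2] = mothers
        par[1::2] = fathers
        S = self.S
        n2 = 2 * self.N
        phase0 = rng.integers(0, 2, size=(n2, self.n_chrom)).astype(np.uint8)
        ncross = rng.poisson(self.morgans, size=(n2, self.n_chrom))
        # crossover positions: uniform in Morgans on each gamete-chromosome,
        # flattened gamete-major and sorted within each (gamete, chromosome)
        K = int(ncross.sum())
        offsets = np.zeros(n2 * self.n_chrom + 1, dtype=np.int64)
        np.cumsum(ncross.reshape(-1), out=offsets[1:])
        if K > 0:
            gid = np.repeat(np.arange(n2 * self.n_chrom), ncross.reshape(-1))
            cid = gid % self.n_chrom
            gx = rng.random(K) * self.morgans[cid]
            order_ev = np.lexsort((gx, gid))
            gx, cid = gx[order_ev], cid[order_ev]
            px = np.empty(K)
            for c in range(self.n_chrom):
                m = cid == c
                if m.any():
                    edges, cums = self._gmap(c)
                    px[m] = np.interp(gx[m], cums, edges)
        else:
            px = np.empty(0)
        # columns in (chromosome, position) order for the sweep
        col_order = np.lexsort((self.pos[:S], self.chrom_of[:S]))
        chrom_sorted = self.chrom_of[:S][col_order]
        col_bounds = np.searchsorted(chrom_sorted, np.arange(self.n_chrom + 1))
        child = np.empty((n2, S), dtype=np.uint8)
        _gamete_kernel(self.haps, child, par, phase0, px, offsets,
                       col_order, self.pos, col_bounds)
        self.haps[:, :S] = child

    def _gmap(self, c):
        if not hasattr(self, "_gmap_cache"):
            self._gmap_cache = {}
        if c not in self._gmap_cache:
            name = self.chrom_names[c]
            iv = self.rmap.intervals[name]
            rt = self.rmap.rates[name]
            edges = np.concatenate([[iv[0, 0]], iv[:, 1]]).astype(float)
            cum = np.concatenate([[0.0], np.cumsum((iv[:, 1] - iv[:, 0]) * rt)])
            self._gmap_cache[c] = (edges, cum)
        return self._gmap_cache[c]

    def cleanup(self):
        S = self.S
        if S == 0:
            return
        freq = self.haps[:, :S].sum(axis=0)
        keep = np.flatnonzero((freq > 0) & (freq < 2 * self.N))
        k = len(keep)
        self.haps[:, :k] = self.haps[:, keep]
        self.haps[:, k: S] = 0
        for name in ("chrom_of", "pos", "s", "is_del"):
            arr = getattr(self, name)
            arr[:k] = arr[keep]
        self.S = k


def wf_forward_oracle(
    rmap: RecombinationMap,
    ann: SelectedAnnotation,
    N: int,
    dfe,
    mu_neutral: float,
    alpha: float = 0.0,
    generations: int | None = None,
    reps: int = 1,
    seed: int = 0,
    windows: WindowedGenome | None = None,
    cleanup_every: int = 25,
):
    """Forward Wright-Fisher oracle for observed B.

    Multiplicative fitness, per-site deleterious mutation restricted to the
    selected annotation with gamma-distributed s, neutral mutations tracked
    outside it, crossovers per the recombination map, and selfing with
    probability ``alpha``.  Runs ``12 N / (1 + F)`` generations by default
    (burn-in to mutation-selection-drift equilibrium), then measures
    population nucleotide diversity at neutral sites.

    Returns a dict with per-replicate B-bar (pi / (4 N mu_neutral / (1+F))),
    per-window pi when ``windows`` is given, and the per-replicate pi.
    """
    if N > 5000:
        warnings.warn("wf_forward_oracle is meant for desk-scale N <= 5000")
    F = alpha / (2.0 - alpha)
    if generations is None:
        generations = int(round(12 * N / (1.0 + F)))
    rng = np.random.default_rng(seed)
    theta_exp = 4.0 * N * mu_neutral / (1.0 + F)
    bbars, pis, pi_windows = [], [], []

    def run_population(repro_seed, mut_seed, mu_del):
        pop = _Population(
            N, rmap, ann, capacity=1024,
            rng=np.random.default_rng(mut_seed),
            rng_repro=np.random.default_rng(repro_seed),
        )
        for gen in range(generations):
            pop.next_generation(dfe.h, alpha)
            pop.mutate(mu_del, mu_neutral, dfe)
            if (gen + 1) % cleanup_every == 0:
                pop.cleanup()
        pop.cleanup()
        return pop

    def neutral_pi(pop):
        S = pop.S
        neu = np.flatnonzero(~pop.is_del[:S])
        freq = pop.haps[:, neu].sum(axis=0).astype(float)
        het = 2.0 * freq * (2 * N - freq) / (2 * N * (2 * N - 1.0))
        return het, neu, het.sum() / pop.L_neu.sum()

    for rep in range(reps):
        repro_seed = int(rng.integers(0, 2**31 - 1))
        mut_seed = int(rng.integers(0, 2**31 - 1))
        pop = run_population(repro_seed, mut_seed, dfe.mu)
        het, neu, pi = neutral_pi(pop)
        pis.append(pi)
        bbars.append(pi / theta_exp)
        if windows is not None:
            pw = np.zeros(len(windows))
            neu_len = np.zeros(len(windows))
            lk = _window_lookup_arrays(windows)
            for i, col in enumerate(neu):
                c = pop.chrom_of[col]
                w = _find_window(lk, pop.chrom_names[c], pop.pos[col])
                if w is not None:
                    pw[w] += het[i]
            for w in range(len(windows)):
                sel = ann.selected_length(windows.chrom[w], windows.start[w],
                                          windows.end[w])
                neu_len[w] = (windows.end[w] - windows.start[w]) - sel
            with np.errstate(invalid="ignore", divide="ignore"):
                pi_windows.append(np.where(neu_len > 0, pw / neu_len, np.nan))
    out = {
        "Bbar": np.asarray(bbars),
        "Bbar_mean": float(np.mean(bbars)),
        "Bbar_se": float(np.std(bbars, ddof=1) / np.sqrt(reps)) if reps > 1 else np.nan,
        "pi": np.asarray(pis),
        "theta_expected": theta_exp,
        "generations": generations,
    }
    if windows is not None:
        out["pi_windows"] = np.asarray(pi_windows)
    return out


def _window_lookup_arrays(genome):
    by = {}
    for i in range(len(genome)):
        by.setdefault(genome.chrom[i], []).append(i)
    return {c: (genome.start[np.asarray(ix)], genome.end[np.asarray(ix)],
                np.asarray(ix)) for c, ix in by.items()}


def _find_window(lookup, chrom, pos):
    if chrom not in lookup:
        return None
    starts, ends, idx = lookup[chrom]
    i = np.searchsorted(starts, pos, side="right") - 1
    if i >= 0 and pos < ends[i]:
        return int(idx[i])
    return None
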