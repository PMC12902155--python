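"""Tallying windowed summaries from variant data.

Builds the windowed unfolded SFS / pairwise-diversity inputs of the
likelihood modules from a VCF, a callable-sites mask (BED), the window grid
and outgroup alleles for polarization.  Also provides the inbreeding
statistics used to fix the selfing rate prior to fitting.

Read mapping, genotype calling and paralog filtering stay upstream; this
module consumes their outputs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "CallableMask",
    "tally_windowed_sfs",
    "tally_windowed_diversity",
    "hypergeometric_projection",
    "estimate_fis",
    "inbreeding_het_prob",
    "read_outgroup_alleles",
]


@dataclass
class CallableMask:
    """Sorted, non-overlapping half-open intervals of callable sites."""

    intervals: dict[str, np.ndarray]

    def __post_init__(self):
        for chrom, iv in self.intervals.items():
            iv = np.asarray(iv, dtype=np.int64).reshape(-1, 2)
            iv = iv[np.argsort(iv[:, 0])]
            if np.any(iv[1:, 0] < iv[:-1, 1]):
                raise ValueError(f"{chrom}: overlapping mask intervals")
            self.intervals[chrom] = iv

    @classmethod
    def from_bed(cls, path) -> "CallableMask":
        df = pd.read_csv(path, sep="\t", header=None, comment="#", usecols=[0, 1, 2],
                         names=["chrom", "start", "end"], dtype={"chrom": str})
        return cls({c: g[["start", "end"]].to_numpy(dtype=np.int64)
                    for c, g in df.groupby("chrom", sort=False)})

    def overlap(self, chrom: str, start: int, end: int) -> int:
        if chrom not in self.intervals:
            return 0
        iv = self.intervals[chrom]
        lo = np.maximum(iv[:, 0], start)
        hi = np.minimum(iv[:, 1], end)
        return int(np.sum(np.maximum(hi - lo, 0)))

    def contains(self, chrom: str, pos: int) -> bool:
        if chrom not in self.intervals:
            return False
        iv = self.intervals[chrom]
        i = np.searchsorted(iv[:, 0], pos, side="right") - 1
        return i >= 0 and pos < iv[i, 1]


def inbreeding_het_prob(p, F):
    """P(heterozygote) = 2 p (1 - p) (1 - F) at derived frequency p."""
    p = np.asarray(p, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p must be in [0, 1]")
    if not 0 <= F <= 1:
        raise ValueError("F must be in [0, 1]")
    out = 2.0 * p * (1.0 - p) * (1.0 - F)
    return out if np.ndim(out) else float(out)


def estimate_fis(genotype_counts) -> float:
    """Moment estimator of FIS from per-site genotype counts.

    ``genotype_counts`` is an (S, 3) array of (hom-ref, het, hom-alt)
    counts.  F-hat = 1 - sum(H_obs) / sum(H_exp) with the small-sample
    corrected H_exp = 2 p (1-p) * 2n/(2n - 1), aggregated over sites.
    """
    g = np.atleast_2d(np.asarray(genotype_counts, dtype=float))
    n = g.sum(axis=1)
    poly = n > 0
    g, n = g[poly], n[poly]
    p = (g[:, 1] + 2.0 * g[:, 2]) / (2.0 * n)
    seg = (p > 0) & (p < 1)
    if not np.any(seg):
        raise ValueError("no polymorphic sites: FIS undefined")
    g, n, p = g[seg], n[seg], p[seg]
    h_obs = g[:, 1] / n
    h_exp = 2.0 * p * (1.0 - p) * (2.0 * n) / (2.0 * n - 1.0)
    f = 1.0 - h_obs.sum() / h_exp.sum()
    return float(np.clip(f, -1.0, 1.0))


def alpha_from_fis(fis: float) -> float:
    """Selfing rate implied by FIS at equilibrium: alpha = 2F/(1+F)."""
    return float(np.clip(2.0 * fis / (1.0 + fis), 0.0, 1.0))


def hypergeometric_projection(sfs: np.ndarray, n_to: int) -> np.ndarray:
    """Project an unfolded SFS (bins 0..n-1) down to n_to alleles.

    Expected spectrum under sampling ``n_to`` of the n alleles without
    replacement (multivariate hypergeometric in expectation): a site with
    derived count j contributes pmf Hypergeom(n, j, n_to) across bins;
    derived counts that become 0 or n_to join the monomorphic bin 0.
    """
    from scipy import stats

    sfs = np.asarray(sfs, dtype=float)
    n = len(sfs)
    if n_to >= n:
        raise ValueError("n_to must be smaller than the input sample size")
    out = np.zeros(n_to)
    out[0] += sfs[0]
    for j in range(1, n):
        if sfs[j] == 0:
            continue
        k = np.arange(0, min(j, n_to) + 1)
        pmf = stats.hypergeom.pmf(k, n, j, n_to)
        for kk, pr in zip(k, pmf):
            if kk >= n_to or kk == 0:
                out[0] += sfs[j] * pr  # monomorphic (or fixed-derived) in subsample
            else:
                out[kk] += sfs[j] * pr
    return out


def read_outgroup_alleles(path) -> dict:
    """Read `chrom  pos(1-based)  allele` TSV into {(chrom, pos): base}.

    An allele of "." or "N" marks a site polymorphic/uncallable in the
    outgroup; such sites are set non-callable during tallying.
    """
    df = pd.read_csv(path, sep="\t", header=None, comment="#",
                     names=["chrom", "pos", "allele"], dtype={"chrom": str})
    return {(c, int(p)): str(a) for c, p, a in df.itertuples(index=False)}


def _window_lookup(genome):
    by_chrom = {}
    for i in range(len(genome)):
        by_chrom.setdefault(genome.chrom[i], []).append(i)
    out = {}
    for chrom, idx in by_chrom.items():
        idx = np.asarray(idx)
        out[chrom] = (genome.start[idx], genome.end[idx], idx)
    return out


def _locate(lookup, chrom, pos0):
    if chrom not in lookup:
        return None
    starts, ends, idx = lookup[chrom]
    i = np.searchsorted(starts, pos0, side="right") - 1
    if i >= 0 and pos0 < ends[i]:
        return int(idx[i])
    return None


def _iter_biallelic(vcf_path, samples):
    """Yield (chrom, pos1, ref, alt, genotype array) for biallelic SNPs."""
    from cyvcf2 import VCF

    vcf = VCF(str(vcf_path), samples=list(samples) if samples else None)
    got = list(vcf.samples)
    if samples:
        missing = set(samples) - set(got)
        if missing:
            raise ValueError(f"samples missing from VCF: {sorted(missing)}")
    for var in vcf:
        if not var.is_snp or len(var.ALT) != 1:
            continue
        # genotypes: (n_samples, 3) with allele indices and phase flag
        g = np.array(var.genotypes, dtype=np.int32)[:, :2]
        yield var.CHROM, var.POS, var.REF, var.ALT[0], g


def _derived_count(g, ref, alt, anc):
    """(derived count, total called alleles) given the ancestral base."""
    called = g >= 0
    n_called = int(called.sum())
    alt_count = int((g[called] == 1).sum())
    if anc == ref:
        return alt_count, n_called
    if anc == alt:
        return n_called - alt_count, n_called
    return None, n_called  # outgroup allele matches neither: unpolarizable


def tally_windowed_sfs(
    vcf_path,
    mask: CallableMask,
    genome,
    samples,
    outgroup: dict,
    n_target_diploids: int,
    selected=None,
    seed: int | None = None,
    require_complete: bool = True,
):
    """Tally per-window unfolded SFS from a VCF.

    Sites are polarized against ``outgroup`` (mapping (chrom, 1-based pos)
    -> ancestral base; "."/"N" marks outgroup-polymorphic sites, which are
    set non-callable).  Selected intervals (``selected``, a
    SelectedAnnotation) are excluded from both polymorphic and monomorphic
    tallies.  Spectra are downsampled to ``n_target_diploids`` diploids by
    multivariate hypergeometric sampling of genotypes (deterministic
    projection in expectation when ``seed`` is None).

    With ``require_complete`` (default) any site with a missing genotype is
    excluded and subtracted from the callable count; otherwise sites are
    kept and projected from the called alleles.

    Returns (WindowedSFS, diagnostics dict).
    """
    from .sfs_likelihood import WindowedSFS

    if samples is None:
        from cyvcf2 import VCF

        samples = list(VCF(str(vcf_path)).samples)
    n_full = 2 * len(samples)
    n = 2 * n_target_diploids
    if n > n_full:
        raise ValueError("cannot downsample to more diploids than sampled")
    lookup = _window_lookup(genome)
    W = len(genome)
    counts = np.zeros((W, n))
    # callable sites per window: mask minus selected intervals
    callable_sites = np.array([
        mask.overlap(genome.chrom[i], genome.start[i], genome.end[i])
        - (selected.selected_length(genome.chrom[i], genome.start[i], genome.end[i])
           if selected is not None else 0.0)
        for i in range(W)
    ])
    callable_sites = np.maximum(callable_sites, 0.0)
    diag = {"no_outgroup": 0, "outgroup_polymorphic": 0, "unpolarizable": 0,
            "missing_genotypes": 0, "in_selected": 0}
    removed = np.zeros(W)
    rng = np.random.default_rng(seed) if seed is not None else None
    for chrom, pos1, ref, alt, g in _iter_biallelic(vcf_path, samples):
        pos0 = pos1 - 1
        w = _locate(lookup, chrom, pos0)
        if w is None or not mask.contains(chrom, pos0):
            continue
        if selected is not None and selected.selected_length(chrom, pos0, pos0 + 1) > 0:
            diag["in_selected"] += 1
            continue
        anc = outgroup.get((chrom, pos1))
        if anc is None:
            diag["no_outgroup"] += 1
            removed[w] += 1
            continue
        if anc in (".", "N"):
            diag["outgroup_polymorphic"] += 1
            removed[w] += 1
            continue
        flat = g.reshape(-1)
        if require_complete and np.any(flat < 0):
            diag["missing_genotypes"] += 1
            removed[w] += 1
            continue
        j, n_called = _derived_count(flat, ref, alt, anc)
        if j is None:
            diag["unpolarizable"] += 1
            removed[w] += 1
            continue
        if n_called == 0:
            removed[w] += 1
            continue
        if j == 0 or j == n_called:
            continue  # monomorphic in the ingroup sample
        if n_called == n:
            counts[w, j] += 1
        elif rng is not None:
            jj = rng.hypergeometric(j, n_called - j, n)
            if 0 < jj < n:
                counts[w, jj] += 1
        else:
            site = np.zeros(n_called)
            site[j] = 1.0
            counts[w, 1:] += hypergeometric_projection(site, n)[1:]
    seg = counts[:, 1:].sum(axis=1)
    counts[:, 0] = np.maximum(callable_sites - removed - seg, 0.0)
    return WindowedSFS(counts, n), diag


def tally_windowed_diversity(vcf_path, mask, genome, samples, selected=None,
                             require_complete: bool = True):
    """Per-window mean-pairwise polymorphic (p) and monomorphic (m) counts.

    p_i sums 2 j (n-j) / (n (n-1)) over sites with derived (or simply
    alternate) allele count j; m_i is the callable remainder.  Polarization
    is irrelevant because j(n-j) is symmetric.
    """
    from .classic_likelihood import WindowedDiversity

    lookup = _window_lookup(genome)
    W = len(genome)
    p = np.zeros(W)
    removed = np.zeros(W)
    callable_sites = np.array([
        mask.overlap(genome.chrom[i], genome.start[i], genome.end[i])
        - (selected.selected_length(genome.chrom[i], genome.start[i], genome.end[i])
           if selected is not None else 0.0)
        for i in range(W)
    ])
    callable_sites = np.maximum(callable_sites, 0.0)
    for chrom, pos1, ref, alt, g in _iter_biallelic(vcf_path, samples):
        pos0 = pos1 - 1
        w = _locate(lookup, chrom, pos0)
        if w is None or not mask.contains(chrom, pos0):
            continue
        if selected is not None and selected.selected_length(chrom, pos0, pos0 + 1) > 0:
            continue
        flat = g.reshape(-1)
        if require_complete and np.any(flat < 0):
            removed[w] += 1
            continue
        called = flat >= 0
        nc = int(called.sum())
        if nc < 2:
            removed[w] += 1
            continue
        j = int((flat[called] == 1).sum())
        p[w] += 2.0 * j * (nc - j) / (nc * (nc - 1.0))
    m = np.maximum(callable_sites - removed - p, 0.0)
    return WindowedDiversity(p, m)


def genotype_counts_from_vcf(vcf_path, samples=None) -> np.ndarray:
    """Per-site (hom-ref, het, hom-alt) counts for `estimate_fis`."""
    rows = []
    for _, _, _, _, g in _iter_biallelic(vcf_path, samples):
        ok = np.all(g >= 0, axis=1)
        gt = g[ok].sum(axis=1)
        rows.append([int((gt == 0).sum()), int((gt == 1).sum()), int((gt == 2).sum())])
    return np.asarray(rows, dtype=float)
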