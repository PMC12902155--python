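"""Windowed genome representation for background-selection calculations.

The genome is modelled as a set of fixed-width windows tiling each
chromosome.  Every window carries the quantities the BGS kernels need: the
number of selected sites it contains (``L``), the number of callable sites,
its internal recombination fraction ``R`` (Haldane over the window's genetic
length) and its genetic midpoint, from which pairwise recombination
fractions between windows are derived.  Windows on different chromosomes are
unlinked (``r = 0.5``).

Coordinates are 0-based half-open internally; GFF3 input (1-based closed) is
converted on read.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "RecombinationMap",
    "SelectedAnnotation",
    "WindowedGenome",
    "haldane",
    "build_windows",
    "coarsen_map",
]


def haldane(d):
    """Haldane's mapping function: map distance (Morgans) -> recombination fraction.

    r = (1 - exp(-2 d)) / 2, with r in [0, 0.5).

    Parameters
    ----------
    d : float or array
        Map distance in Morgans; must be non-negative.
    """
    d = np.asarray(d, dtype=float)
    if np.any(d < 0):
        raise ValueError("map distance must be non-negative")
    r = 0.5 * (1.0 - np.exp(-2.0 * d))
    return r if r.ndim else float(r)


@dataclass
class RecombinationMap:
    """Per-chromosome piecewise-constant crossover rates.

    ``intervals[chrom]`` is an (n, 2) int array of half-open [start, end)
    intervals, sorted and non-overlapping, covering the chromosome;
    ``rates[chrom]`` the matching per-site per-generation crossover rates.
    """

    intervals: dict[str, np.ndarray]
    rates: dict[str, np.ndarray]

    def __post_init__(self):
        for chrom, iv in self.intervals.items():
            iv = np.asarray(iv, dtype=np.int64).reshape(-1, 2)
            rt = np.atleast_1d(np.asarray(self.rates[chrom], dtype=float))
            if len(rt) != len(iv):
                raise ValueError(f"{chrom}: interval/rate length mismatch")
            if np.any(rt < 0):
                raise ValueError(f"{chrom}: negative recombination rate")
            order = np.argsort(iv[:, 0])
            iv, rt = iv[order], rt[order]
            if np.any(iv[1:, 0] != iv[:-1, 1]):
                raise ValueError(f"{chrom}: intervals must be contiguous")
            self.intervals[chrom] = iv
            self.rates[chrom] = rt

    @property
    def chromosomes(self) -> list[str]:
        return list(self.intervals)

    def chrom_length(self, chrom: str) -> int:
        return int(self.intervals[chrom][-1, 1])

    def chrom_morgans(self, chrom: str) -> float:
        iv = self.intervals[chrom]
        return float(np.sum((iv[:, 1] - iv[:, 0]) * self.rates[chrom]))

    def genetic_position(self, chrom: str, pos):
        """Cumulative genetic position (Morgans) at physical position(s)."""
        iv = self.intervals[chrom]
        rt = self.rates[chrom]
        cum = np.concatenate([[0.0], np.cumsum((iv[:, 1] - iv[:, 0]) * rt)])
        pos = np.asarray(pos, dtype=float)
        idx = np.clip(np.searchsorted(iv[:, 1], pos, side="right"), 0, len(rt) - 1)
        g = cum[idx] + (pos - iv[idx, 0]) * rt[idx]
        return g if g.ndim else float(g)

    @classmethod
    def from_tsv(cls, path) -> "RecombinationMap":
        """Read `chrom  start  end  rate_per_site_per_gen` (no header)."""
        df = pd.read_csv(
            path, sep="\t", header=None, comment="#",
            names=["chrom", "start", "end", "rate"],
            dtype={"chrom": str},
        )
        intervals, rates = {}, {}
        for chrom, g in df.groupby("chrom", sort=False):
            intervals[chrom] = g[["start", "end"]].to_numpy(dtype=np.int64)
            rates[chrom] = g["rate"].to_numpy(dtype=float)
        return cls(intervals, rates)

    def to_tsv(self, path) -> None:
        rows = []
        for chrom in self.chromosomes:
            for (s, e), c in zip(self.intervals[chrom], self.rates[chrom]):
                rows.append((chrom, s, e, c))
        pd.DataFrame(rows).to_csv(path, sep="\t", header=False, index=False)


def coarsen_map(rmap: RecombinationMap, interval: int) -> RecombinationMap:
    """Re-measure a map in coarser intervals, conserving genetic length.

    Each coarse interval's rate is the genetic-length-preserving average of
    the fine map across it, so total Morgans per chromosome is unchanged.
    """
    if interval <= 0:
        raise ValueError("interval must be positive")
    intervals, rates = {}, {}
    for chrom in rmap.chromosomes:
        length = rmap.chrom_length(chrom)
        edges = np.arange(0, length, interval, dtype=np.int64)
        edges = np.append(edges, length)
        g = rmap.genetic_position(chrom, edges)
        widths = np.diff(edges).astype(float)
        intervals[chrom] = np.column_stack([edges[:-1], edges[1:]])
        rates[chrom] = np.diff(g) / widths
    return RecombinationMap(intervals, rates)


@dataclass
class SelectedAnnotation:
    """Half-open intervals of sites under purifying selection (CDS)."""

    intervals: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self):
        for chrom, iv in self.intervals.items():
            self.intervals[chrom] = _merge_intervals(np.asarray(iv, dtype=np.int64).reshape(-1, 2))

    @property
    def chromosomes(self) -> list[str]:
        return list(self.intervals)

    def selected_length(self, chrom: str, start: int, end: int) -> float:
        """Total selected sites overlapping [start, end)."""
        if chrom not in self.intervals:
            return 0.0
        iv = self.intervals[chrom]
        lo = np.maximum(iv[:, 0], start)
        hi = np.minimum(iv[:, 1], end)
        return float(np.sum(np.maximum(hi - lo, 0)))

    @classmethod
    def from_gff3(cls, path, feature: str = "CDS") -> "SelectedAnnotation":
        df = pd.read_csv(
            path, sep="\t", header=None, comment="#",
            names=["seqid", "source", "type", "start", "end",
                   "score", "strand", "phase", "attributes"],
            dtype={"seqid": str},
        )
        df = df[df["type"] == feature]
        intervals = {}
        for chrom, g in df.groupby("seqid", sort=False):
            # GFF3 is 1-based closed
            intervals[chrom] = np.column_stack(
                [g["start"].to_numpy(dtype=np.int64) - 1, g["end"].to_numpy(dtype=np.int64)]
            )
        return cls(intervals)

    @classmethod
    def from_bed(cls, path) -> "SelectedAnnotation":
        df = pd.read_csv(
            path, sep="\t", header=None, comment="#", usecols=[0, 1, 2],
            names=["chrom", "start", "end"], dtype={"chrom": str},
        )
        intervals = {}
        for chrom, g in df.groupby("chrom", sort=False):
            intervals[chrom] = g[["start", "end"]].to_numpy(dtype=np.int64)
        return cls(intervals)


def _merge_intervals(iv: np.ndarray) -> np.ndarray:
    if len(iv) == 0:
        return iv.reshape(0, 2)
    iv = iv[np.argsort(iv[:, 0])]
    merged = [list(iv[0])]
    for s, e in iv[1:]:
        if s <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], e)
        else:
            merged.append([s, e])
    return np.asarray(merged, dtype=np.int64)


@dataclass
class WindowedGenome:
    """Ordered genomic windows with the per-window quantities BGS needs.

    Attributes
    ----------
    chrom : array of str, window chromosome.
    start, end : int arrays, physical bounds (half-open).
    L : float array, selected sites per window (boundary-spanning features
        apportioned by overlap).
    callable : float array, callable sites per window.
    R : float array, within-window recombination fraction (Haldane of the
        window's genetic length).
    gpos : float array, genetic midpoint (Morgans, per-chromosome origin).
    mu : per-site deleterious mutation rate used for U = 2 mu L.
    """

    chrom: np.ndarray
    start: np.ndarray
    end: np.ndarray
    L: np.ndarray
    callable: np.ndarray
    R: np.ndarray
    gpos: np.ndarray
    mu: float = 0.0

    def __post_init__(self):
        self.chrom = np.asarray(self.chrom, dtype=object)
        for name in ("start", "end"):
            setattr(self, name, np.asarray(getattr(self, name), dtype=np.int64))
        for name in ("L", "callable", "R", "gpos"):
            setattr(self, name, np.asarray(getattr(self, name), dtype=float))
        if not (np.all(self.R >= 0) and np.all(self.R <= 0.5)):
            raise ValueError("window R must lie in [0, 0.5]")
        _, self.chrom_index = np.unique(self.chrom, return_inverse=True)

    def __len__(self) -> int:
        return len(self.start)

    @property
    def n_windows(self) -> int:
        return len(self.start)

    @property
    def U(self) -> np.ndarray:
        """Diploid deleterious mutation rate per window, 2*mu*L."""
        return 2.0 * self.mu * self.L

    def pairwise_r(self) -> np.ndarray:
        """Matrix of recombination fractions between window midpoints.

        0.5 exactly for windows on different chromosomes; Haldane of the
        genetic midpoint distance otherwise.
        """
        d = np.abs(self.gpos[:, None] - self.gpos[None, :])
        r = 0.5 * (1.0 - np.exp(-2.0 * d))
        same = self.chrom_index[:, None] == self.chrom_index[None, :]
        r[~same] = 0.5
        return r

    def pairwise_distance(self) -> tuple[np.ndarray, np.ndarray]:
        """(|d| in Morgans, same-chromosome mask) between window midpoints."""
        d = np.abs(self.gpos[:, None] - self.gpos[None, :])
        same = self.chrom_index[:, None] == self.chrom_index[None, :]
        return d, same

    def to_tsv(self, path) -> None:
        pd.DataFrame(
            {
                "chrom": self.chrom,
                "start": self.start,
                "end": self.end,
                "L": self.L,
                "callable": self.callable,
                "R": self.R,
                "genetic_midpoint": self.gpos,
            }
        ).to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path, mu: float = 0.0) -> "WindowedGenome":
        df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
        return cls(
            chrom=df["chrom"].to_numpy(),
            start=df["start"].to_numpy(),
            end=df["end"].to_numpy(),
            L=df["L"].to_numpy(),
            callable=df["callable"].to_numpy(),
            R=df["R"].to_numpy(),
            gpos=df["genetic_midpoint"].to_numpy(),
            mu=mu,
        )


def build_windows(
    rmap: RecombinationMap,
    ann: SelectedAnnotation,
    window_size: int,
    mu: float = 0.0,
    callable_mask=None,
) -> WindowedGenome:
    """Tile each chromosome of ``rmap`` into fixed-width windows.

    The last window of a chromosome may be short.  ``callable`` defaults to
    the full window width when no mask is given.

    Raises if the annotation names a chromosome absent from the map.
    """
    if window_size <= 0:
        raise ValueError("window_size must be positive")
    for chrom in ann.chromosomes:
        if chrom not in rmap.intervals:
            raise ValueError(f"chromosome {chrom!r} in annotation but not in recombination map")
    chroms, starts, ends, Ls, calls, Rs, gpos = [], [], [], [], [], [], []
    for chrom in rmap.chromosomes:
        length = rmap.chrom_length(chrom)
        edges = np.arange(0, length, window_size, dtype=np.int64)
        edges = np.append(edges, length)
        g_edges = rmap.genetic_position(chrom, edges)
        g_mid = rmap.genetic_position(chrom, (edges[:-1] + edges[1:]) / 2.0)
        for i in range(len(edges) - 1):
            s, e = int(edges[i]), int(edges[i + 1])
            chroms.append(chrom)
            starts.append(s)
            ends.append(e)
            Ls.append(ann.selected_length(chrom, s, e))
            if callable_mask is None:
                calls.append(e - s)
            else:
                calls.append(callable_mask.overlap(chrom, s, e))
            Rs.append(haldane(g_edges[i + 1] - g_edges[i]))
            gpos.append(g_mid[i])
    return WindowedGenome(
        chrom=np.array(chroms, dtype=object),
        start=np.array(starts),
        end=np.array(ends),
        L=np.array(Ls),
        callable=np.array(calls, dtype=float),
        R=np.array(Rs),
        gpos=np.array(gpos),
        mu=mu,
    )
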