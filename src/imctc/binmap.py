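"""Genomic bin maps for sparse single-cell whole-genome copy-number profiling.

Low-pass single-cell WGS is analysed on a fixed partition of the genome into
a few thousand variable-length bins; read counts per bin, after GC correction
and mean normalisation, carry the copy-number signal.  The bin map here is an
abstract genome: ordered chromosomes, half-open bin coordinates, and a GC
fraction per bin.  Nothing downstream depends on real reference coordinates,
only on the bin structure.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["BinMap", "make_bin_map", "read_bin_map", "write_bin_map"]

# Relative chromosome sizes patterned on the human karyotype (chr1..chr22, X, Y),
# used to apportion bins when a 24-chromosome genome is requested.
_HUMAN_LIKE_WEIGHTS = np.array(
    [249, 243, 198, 191, 181, 171, 159, 146, 141, 136, 135, 134,
     115, 107, 102, 90, 81, 78, 59, 63, 48, 51, 155, 59],
    dtype=float,
)


def _chromosome_labels(n_chromosomes: int) -> list[str]:
    if n_chromosomes == 24:
        return [f"chr{i}" for i in range(1, 23)] + ["chrX", "chrY"]
    return [f"chr{i}" for i in range(1, n_chromosomes + 1)]


@dataclass(frozen=True)
class BinMap:
    """Ordered, non-overlapping, half-open genomic bins with GC content.

    Attributes
    ----------
    chrom : array of str, one label per bin (bins grouped and ordered by
        chromosome).
    start, end : int arrays, half-open base-pair coordinates within the
        chromosome; within a chromosome bins are sorted and non-overlapping.
    gc : float array, GC fraction per bin, strictly in (0, 1).
    """

    chrom: np.ndarray
    start: np.ndarray
    end: np.ndarray
    gc: np.ndarray
    chromosomes: tuple[str, ...] = field(init=False)

    def __post_init__(self) -> None:
        chrom = np.asarray(self.chrom, dtype=object)
        start = np.asarray(self.start, dtype=np.int64)
        end = np.asarray(self.end, dtype=np.int64)
        gc = np.asarray(self.gc, dtype=float)
        if not (len(chrom) == len(start) == len(end) == len(gc)):
            raise ValueError("chrom/start/end/gc must have equal length")
        if len(chrom) == 0:
            raise ValueError("bin map must contain at least one bin")
        if np.any(end <= start):
            raise ValueError("bins must have positive length (end > start)")
        if np.any(gc <= 0.0) or np.any(gc >= 1.0):
            raise ValueError("gc fractions must lie strictly in (0, 1)")
        # chromosome blocks must be contiguous, bins sorted within each
        order = pd.Series(chrom).ne(pd.Series(chrom).shift()).cumsum()
        if order.groupby(pd.Series(chrom).values, sort=False).nunique().max() > 1:
            raise ValueError("bins of a chromosome must form one contiguous block")
        for _, idx in pd.Series(np.arange(len(chrom))).groupby(chrom, sort=False):
            s, e = start[idx.values], end[idx.values]
            if np.any(s[1:] < e[:-1]):
                raise ValueError("bins within a chromosome overlap or are unsorted")
        object.__setattr__(self, "chrom", chrom)
        object.__setattr__(self, "start", start)
        object.__setattr__(self, "end", end)
        object.__setattr__(self, "gc", gc)
        object.__setattr__(self, "chromosomes", tuple(pd.unique(chrom)))

    @property
    def n_bins(self) -> int:
        return len(self.chrom)

    @property
    def lengths(self) -> np.ndarray:
        """Bin lengths in base pairs."""
        return self.end - self.start

    def chrom_slice(self, chromosome: str) -> slice:
        """Global-index slice covering one chromosome's bins."""
        mask = self.chrom == chromosome
        if not mask.any():
            raise KeyError(f"unknown chromosome: {chromosome!r}")
        idx = np.flatnonzero(mask)
        return slice(int(idx[0]), int(idx[-1]) + 1)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, BinMap):
            return NotImplemented
        return (
            self.n_bins == other.n_bins
            and bool(np.all(self.chrom == other.chrom))
            and bool(np.all(self.start == other.start))
            and bool(np.all(self.end == other.end))
            and bool(np.allclose(self.gc, other.gc))
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"chrom": self.chrom, "start": self.start, "end": self.end, "gc": self.gc}
        )


def make_bin_map(
    n_bins: int,
    n_chromosomes: int = 24,
    seed: int = 0,
    mean_bin_length: int = 600_000,
) -> BinMap:
    """Draw a synthetic genome partition of ``n_bins`` variable-length bins.

    Bins are apportioned over chromosomes (human-karyotype-like size ranking
    for 24 chromosomes, near-equal otherwise), bin lengths are gamma-distributed
    around ``mean_bin_length`` (CV ~0.3, emulating variable-length bins sized
    for uniform mappability), and GC fractions are Beta-distributed within
    (0.2, 0.8).
    """
    if n_bins < 1:
        raise ValueError("n_bins must be positive")
    if n_chromosomes < 1 or n_bins < n_chromosomes:
        raise ValueError("need n_bins >= n_chromosomes >= 1")
    rng = np.random.default_rng(seed)

    if n_chromosomes == 24:
        weights = _HUMAN_LIKE_WEIGHTS.copy()
    else:
        weights = np.linspace(1.5, 0.8, n_chromosomes)
    weights /= weights.sum()
    # largest-remainder apportionment, at least one bin per chromosome
    raw = weights * n_bins
    alloc = np.maximum(np.floor(raw).astype(int), 1)
    while alloc.sum() > n_bins:
        alloc[int(np.argmax(alloc))] -= 1
    remainder = raw - np.floor(raw)
    while alloc.sum() < n_bins:
        i = int(np.argmax(remainder))
        alloc[i] += 1
        remainder[i] = -1.0

    labels = _chromosome_labels(n_chromosomes)
    chrom, start, end = [], [], []
    shape = 1.0 / 0.3**2  # gamma CV 0.3
    for label, k in zip(labels, alloc):
        lens = np.maximum(
            rng.gamma(shape, mean_bin_length / shape, size=k).astype(np.int64), 1000
        )
        e = np.cumsum(lens)
        s = e - lens
        chrom.extend([label] * k)
        start.append(s)
        end.append(e)
    gc = 0.2 + 0.6 * rng.beta(2.5, 3.5, size=n_bins)
    gc = np.clip(gc, 0.2 + 1e-9, 0.8 - 1e-9)
    return BinMap(
        np.array(chrom, dtype=object),
        np.concatenate(start),
        np.concatenate(end),
        gc,
    )


def write_bin_map(bin_map: BinMap, path) -> None:
    """Write a BED-like TSV (chrom, start, end, gc; no header)."""
    bin_map.to_frame().to_csv(path, sep="\t", header=False, index=False)


def read_bin_map(path) -> BinMap:
    df = pd.read_csv(path, sep="\t", header=None, names=["chrom", "start", "end", "gc"])
    return BinMap(
        df["chrom"].to_numpy(dtype=object),
        df["start"].to_numpy(),
        df["end"].to_numpy(),
        df["gc"].to_numpy(),
    )
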