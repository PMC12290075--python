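"""Copy-number ratio profiles: GC correction, normalisation, segmentation.

The profiling chain mirrors the standard sparse single-cell WGS workflow:
bin read counts are length-normalised, detrended against GC content with a
locally weighted fit, expressed as ratios to the genome-wide mean (so 1.0 is
baseline ploidy), segmented by circular binary segmentation (CBS) with a
permutation test per split, and rounded to integer copy states.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.nonparametric.smoothers_lowess import lowess

from .binmap import BinMap
from .errors import InsufficientDataError
from .simulate import CellCountVector

__all__ = [
    "RatioProfile",
    "SegmentSet",
    "SegmentationConfig",
    "gc_correct",
    "ratio_normalize",
    "segment_cbs",
    "call_states",
    "mean_profile",
    "region_ratio_test",
    "profile_cell",
]

_LOG_EPS = 1e-6  # added before log2 to guard zero ratios


@dataclass(frozen=True)
class RatioProfile:
    """GC-corrected per-bin ratios to the genome-wide mean (mean exactly 1)."""

    ratios: np.ndarray
    bin_map: BinMap
    cell_id: str = "cell"
    cell_type: str = ""
    draw: int = 1

    def __post_init__(self) -> None:
        ratios = np.asarray(self.ratios, dtype=float)
        if len(ratios) != self.bin_map.n_bins:
            raise ValueError("ratio length must match the bin map")
        if not np.all(np.isfinite(ratios)):
            raise ValueError("ratios must be finite")
        if abs(ratios.mean() - 1.0) > 1e-9:
            raise ValueError("ratio profile must have genome-wide mean 1")
        object.__setattr__(self, "ratios", ratios)

    def __len__(self) -> int:
        return len(self.ratios)


@dataclass(frozen=True)
class SegmentSet:
    """Segments tiling the genome for one cell.

    ``table`` columns: chrom, start_bin, end_bin (global bin indices,
    half-open), n_bins, mean_ratio and, after :func:`call_states`, state.
    """

    table: pd.DataFrame
    cell_id: str = "cell"

    def __post_init__(self) -> None:
        required = {"chrom", "start_bin", "end_bin", "n_bins", "mean_ratio"}
        missing = required - set(self.table.columns)
        if missing:
            raise ValueError(f"segment table missing columns: {missing}")

    def __len__(self) -> int:
        return len(self.table)

    def non_neutral(self, baseline_state: int = 2) -> pd.DataFrame:
        if "state" not in self.table.columns:
            raise ValueError("call_states must be run before selecting by state")
        return self.table[self.table["state"] != baseline_state]


@dataclass(frozen=True)
class SegmentationConfig:
    """CBS hyperparameters: permutation significance level ``alpha``,
    permutation count, minimum segment width in bins, and RNG seed.
    ``merge_pruning`` optionally merges adjacent segments whose means differ
    by less than ``merge_sd_mult`` residual SDs (off by default)."""

    alpha: float = 0.01
    n_perm: int = 1000
    min_width: int = 3
    seed: int = 0
    merge_pruning: bool = False
    merge_sd_mult: float = 2.0

    def __post_init__(self) -> None:
        if not 0.0 < self.alpha < 1.0:
            raise ValueError("alpha must lie in (0, 1)")
        if self.n_perm < 100:
            raise ValueError("n_perm must be >= 100")
        if self.min_width < 2:
            raise ValueError("min_width must be >= 2")


# ---------------------------------------------------------------------------
# GC correction and normalisation


def _length_normalize(counts: np.ndarray, bin_map: BinMap) -> np.ndarray:
    lengths = bin_map.lengths.astype(float)
    return counts / lengths * lengths.mean()


def gc_correct(counts: CellCountVector | np.ndarray, bin_map: BinMap) -> np.ndarray:
    """Detrend length-normalised bin counts against GC content.

    A locally weighted (lowess, span 0.3) fit of count on GC supplies the
    trend for >= 100 bins; a quadratic least-squares fit is used below that.
    Counts are divided by the trend and rescaled so the overall mean of the
    length-normalised counts is preserved.
    """
    raw = counts.counts if isinstance(counts, CellCountVector) else np.asarray(counts)
    if len(raw) != bin_map.n_bins:
        raise ValueError("counts length must match the bin map")
    if raw.sum() <= 0:
        raise InsufficientDataError("cell has no reads")
    if np.count_nonzero(raw) < 10:
        raise InsufficientDataError("fewer than 10 nonzero bins")
    cn = _length_normalize(raw.astype(float), bin_map)
    gc = bin_map.gc
    if len(cn) >= 100:
        span = gc.max() - gc.min()
        trend = lowess(
            cn, gc, frac=0.3, it=1, delta=0.01 * span, return_sorted=False
        )
    else:
        coef = np.polyfit(gc, cn, deg=2)
        trend = np.polyval(coef, gc)
    floor = 0.01 * cn.mean()
    trend = np.maximum(trend, floor)
    corrected = cn / trend
    corrected *= cn.mean() / corrected.mean()
    return corrected


def ratio_normalize(
    corrected: np.ndarray,
    bin_map: BinMap,
    cell_id: str = "cell",
    cell_type: str = "",
    draw: int = 1,
) -> RatioProfile:
    """Divide by the genome-wide mean so ratio 1.0 marks baseline ploidy."""
    corrected = np.asarray(corrected, dtype=float)
    m = corrected.mean()
    if not np.isfinite(m) or m <= 0:
        raise ValueError("corrected values must have a positive mean")
    return RatioProfile(corrected / m, bin_map, cell_id, cell_type, draw)


def profile_cell(cell: CellCountVector, bin_map: BinMap) -> RatioProfile:
    """Counts -> GC-corrected, mean-normalised ratio profile (one cell)."""
    return ratio_normalize(
        gc_correct(cell, bin_map), bin_map, cell.cell_id, cell.cell_type, cell.draw
    )


# ---------------------------------------------------------------------------
# Circular binary segmentation

# The pooled two-sample t^2 between in-arc and out-of-arc bins equals
# (n - 2) * BSS / (TSS - BSS), where TSS is the total centered sum of squares
# (invariant under permutation) and BSS = n * u^2 / (n1 * n2) with u the
# centered arc sum.  t^2 is therefore monotone in the arc score u^2/(n1*n2),
# so both the arc scan and the permutation comparison run on that score.

_PAIR_CHUNK = 4_000_000  # max arc pairs evaluated per vectorised chunk


from functools import lru_cache


@lru_cache(maxsize=256)
def _valid_pairs(n: int, min_width: int) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Admissible (i, j) arc endpoints and inverse-size weights 1/(n1*n2).

    Arc [i, j) and its complement must each hold >= min_width bins, and a
    flank segment created at i > 0 or j < n must too.  Circularity makes the
    complement of any arc an arc, so i < j covers all circular splits.
    """
    idx = np.arange(n + 1)
    i = idx[:, None]
    j = idx[None, :]
    width = j - i
    ok = (width >= min_width) & (n - width >= min_width)
    ok &= (i == 0) | (i >= min_width)
    ok &= (j == n) | (n - j >= min_width)
    i_arr, j_arr = np.nonzero(ok)
    n1 = (j_arr - i_arr).astype(float)
    w = 1.0 / (n1 * (n - n1))
    return i_arr, j_arr, w


def _prefix_centered(x: np.ndarray) -> np.ndarray:
    """Prefix sums of mean-centered rows; shape (m, n+1)."""
    xc = x - x.mean(axis=1, keepdims=True)
    S = np.zeros((x.shape[0], x.shape[1] + 1))
    np.cumsum(xc, axis=1, out=S[:, 1:])
    return S


def _score_to_tsq(score: float, tss: float, n: int) -> float:
    """Convert the max arc score u^2/(n1*n2) to the two-sample t^2."""
    bss = n * score
    if bss <= 0:
        return 0.0
    if tss - bss <= 0:
        return np.inf
    return (n - 2) * bss / (tss - bss)


def _best_arc(x: np.ndarray, min_width: int) -> tuple[int, int, float, float] | None:
    """Arc maximising t^2; returns (i, j, t^2, score)."""
    n = len(x)
    if n < 2 * min_width:
        return None
    i_arr, j_arr, w = _valid_pairs(n, min_width)
    S = _prefix_centered(x[None, :])[0]
    best_score = -1.0
    best_k = -1
    for a in range(0, len(w), _PAIR_CHUNK):
        b = min(a + _PAIR_CHUNK, len(w))
        u = S[j_arr[a:b]] - S[i_arr[a:b]]
        sc = u * u * w[a:b]
        k = int(np.argmax(sc))
        if sc[k] > best_score:
            best_score = float(sc[k])
            best_k = a + k
    tss = float(np.sum((x - x.mean()) ** 2))
    tsq = _score_to_tsq(best_score, tss, n)
    return int(i_arr[best_k]), int(j_arr[best_k]), tsq, best_score


def _max_score_batch(
    X: np.ndarray, i_arr: np.ndarray, j_arr: np.ndarray, w: np.ndarray
) -> np.ndarray:
    """Max arc score per row of X (m, n)."""
    S = _prefix_centered(X)
    m = X.shape[0]
    rows = max(1, _PAIR_CHUNK // max(len(w), 1))
    out = np.empty(m)
    for a in range(0, m, rows):
        b = min(a + rows, m)
        u = S[a:b][:, j_arr] - S[a:b][:, i_arr]
        out[a:b] = (u * u * w).max(axis=1)
    return out


def _split_pvalue(
    x: np.ndarray,
    score_obs: float,
    config: SegmentationConfig,
    rng: np.random.Generator,
) -> float:
    """Permutation p-value of the best split (comparison on the monotone arc
    score, identical decisions to comparing t^2), with early stopping once
    the exceedance count guarantees p >= alpha.  Uses the add-one estimator
    p = (1 + #exceed) / (1 + n_perm)."""
    n = len(x)
    i_arr, j_arr, w = _valid_pairs(n, config.min_width)
    reject_at = config.alpha * (config.n_perm + 1) - 1  # exceed > this => keep
    exceed = 0
    done = 0
    block = 250
    while done < config.n_perm:
        m = min(block, config.n_perm - done)
        X = rng.permuted(np.broadcast_to(x, (m, n)).copy(), axis=1)
        smax = _max_score_batch(X, i_arr, j_arr, w)
        exceed += int(np.sum(smax >= score_obs * (1 - 1e-12)))
        done += m
        if exceed > reject_at:
            break
    return (1 + exceed) / (1 + done)


def _segment_values(
    x: np.ndarray, config: SegmentationConfig, rng: np.random.Generator
) -> list[tuple[int, int]]:
    """Recursive CBS on one chromosome's values; returns half-open bin spans."""
    out: list[tuple[int, int]] = []

    def recurse(lo: int, hi: int) -> None:
        seg = x[lo:hi]
        res = _best_arc(seg, config.min_width)
        if res is None:
            out.append((lo, hi))
            return
        i, j, tsq, score = res
        if tsq <= 0:
            out.append((lo, hi))
            return
        p = _split_pvalue(seg, score, config, rng)
        if p >= config.alpha:
            out.append((lo, hi))
            return
        for a, b in ((0, i), (i, j), (j, hi - lo)):
            if b > a:
                recurse(lo + a, lo + b)

    recurse(0, len(x))
    out.sort()
    return out


def _merge_segments(
    spans: list[tuple[int, int]], x: np.ndarray, sd_mult: float
) -> list[tuple[int, int]]:
    """Optionally merge adjacent segments whose means differ by less than
    sd_mult x the pooled within-segment residual SD."""
    if len(spans) < 2:
        return spans
    resid = np.concatenate([x[a:b] - x[a:b].mean() for a, b in spans])
    sd = resid.std()
    merged = [spans[0]]
    for a, b in spans[1:]:
        pa, pb = merged[-1]
        if abs(x[a:b].mean() - x[pa:pb].mean()) < sd_mult * sd:
            merged[-1] = (pa, b)
        else:
            merged.append((a, b))
    return merged


def segment_cbs(profile: RatioProfile, config: SegmentationConfig) -> SegmentSet:
    """Circular binary segmentation of a ratio profile, per chromosome.

    The statistic is the pooled-variance two-sample t between bins inside and
    outside a circular arc, computed on log2(ratio + 1e-6); splits are
    accepted when their permutation p-value falls below ``config.alpha``.
    Segment means are reported on the linear ratio scale.
    """
    rng = np.random.default_rng(config.seed)
    logr = np.log2(profile.ratios + _LOG_EPS)
    rows = []
    for chrom in profile.bin_map.chromosomes:
        sl = profile.bin_map.chrom_slice(chrom)
        spans = _segment_values(logr[sl], config, rng)
        if config.merge_pruning:
            spans = _merge_segments(spans, logr[sl], config.merge_sd_mult)
        for a, b in spans:
            lo, hi = sl.start + a, sl.start + b
            rows.append(
                {
                    "chrom": chrom,
                    "start_bin": lo,
                    "end_bin": hi,
                    "n_bins": hi - lo,
                    "mean_ratio": float(profile.ratios[lo:hi].mean()),
                }
            )
    return SegmentSet(pd.DataFrame(rows), cell_id=profile.cell_id)


def call_states(segments: SegmentSet, baseline_ploidy: int = 2) -> SegmentSet:
    """Integer copy state per segment: round(mean ratio x baseline ploidy),
    halves rounded up, floored at 0."""
    table = segments.table.copy()
    if np.any(table["mean_ratio"] < 0):
        raise ValueError("segment mean ratios must be non-negative")
    table["state"] = np.maximum(
        np.floor(table["mean_ratio"] * baseline_ploidy + 0.5).astype(int), 0
    )
    return SegmentSet(table, cell_id=segments.cell_id)


def mean_profile(cells: Sequence[RatioProfile]) -> RatioProfile:
    """Per-bin arithmetic mean ratio across cells sharing a bin map."""
    if len(cells) == 0:
        raise ValueError("need at least one cell")
    bm = cells[0].bin_map
    for c in cells[1:]:
        if c.bin_map != bm:
            raise ValueError("all cells must share a bin map")
    mean = np.mean([c.ratios for c in cells], axis=0)
    # mean of unit-mean profiles has unit mean up to fp error; snap it
    mean = mean / mean.mean()
    return RatioProfile(mean, bm, cell_id=f"mean_of_{len(cells)}")


class TTestResult(NamedTuple):
    t: float
    p: float
    degenerate: bool = False


def region_ratio_test(group_a: np.ndarray, group_b: np.ndarray) -> TTestResult:
    """Pooled-variance two-sided Student's t-test comparing per-cell mean
    ratios at a genomic region between two cell groups (e.g. the PTPRC locus
    in CD45+ versus CD45- tumor cells)."""
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise InsufficientDataError("each group needs at least 2 cells")
    na, nb = len(a), len(b)
    sp2 = ((na - 1) * a.var(ddof=1) + (nb - 1) * b.var(ddof=1)) / (na + nb - 2)
    diff = a.mean() - b.mean()
    if sp2 == 0:
        if diff == 0:
            return TTestResult(0.0, 1.0)
        return TTestResult(np.sign(diff) * np.inf, 0.0, degenerate=True)
    t = diff / np.sqrt(sp2 * (1.0 / na + 1.0 / nb))
    p = 2.0 * stats.t.sf(abs(t), df=na + nb - 2)
    return TTestResult(float(t), float(p))
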