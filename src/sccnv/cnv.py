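"""Per-cell copy-number core: GC normalization, ratios, segmentation, ploidy.

The transformation chain for one cell is

    raw bin counts
      -> ``gc_normalize``   (divide out the lowess count-vs-GC trend)
      -> ``compute_ratios`` (divide by the cell's mean bin count; mean == 1)
      -> ``segment``        (permutation-thresholded binary segmentation,
                             per chromosome)
      -> ``integer_cn``     (round(segment ratio x sample ploidy))

Sample ploidy comes from flow-sorting DAPI intensities via
``estimate_ploidy`` (2 x A-peak/D-peak median), assuming most sequenced
cells derive from the aneuploid peak.

Coordinates are 0-based half-open throughout; bin indices are the unit of
genomic length.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from statsmodels.nonparametric.smoothers_lowess import lowess as _sm_lowess

__all__ = [
    "BinGrid",
    "CellProfile",
    "gc_normalize",
    "compute_ratios",
    "segment",
    "estimate_ploidy",
    "integer_cn",
    "round_half_away",
]


class BinGrid:
    """Ordered genomic bins: chromosome, half-open coordinates, GC fraction.

    Thin wrapper around a DataFrame with columns ``chrom, start, end, gc``,
    sorted by chromosome then coordinate.
    """

    REQUIRED = ("chrom", "start", "end", "gc")

    def __init__(self, table: pd.DataFrame):
        missing = [c for c in self.REQUIRED if c not in table.columns]
        if missing:
            raise ValueError(f"bin grid missing columns: {missing}")
        t = table.reset_index(drop=True)
        if (t["end"] <= t["start"]).any():
            raise ValueError("bin grid has non-positive bin widths")
        if ((t["gc"] <= 0) | (t["gc"] >= 1)).any():
            raise ValueError("GC fractions must lie in (0, 1)")
        for _, sub in t.groupby("chrom", sort=False):
            s = sub[["start", "end"]].to_numpy()
            if (np.diff(s[:, 0]) <= 0).any() or (s[1:, 0] < s[:-1, 1]).any():
                raise ValueError("bins must be sorted and non-overlapping "
                                 "within each chromosome")
        self.table = t

    def __len__(self) -> int:
        return len(self.table)

    @property
    def chrom(self) -> np.ndarray:
        return self.table["chrom"].to_numpy()

    @property
    def gc(self) -> np.ndarray:
        return self.table["gc"].to_numpy(float)

    @property
    def widths(self) -> np.ndarray:
        return (self.table["end"] - self.table["start"]).to_numpy(float)

    def chromosome_slices(self) -> list[tuple[str, slice]]:
        """Contiguous (chrom, slice) pairs in grid order."""
        out, start = [], 0
        chroms = self.chrom
        for i in range(1, len(chroms) + 1):
            if i == len(chroms) or chroms[i] != chroms[start]:
                out.append((chroms[start], slice(start, i)))
                start = i
        return out

    def chromosome_boundaries(self) -> np.ndarray:
        """Start indices of each chromosome plus the total bin count."""
        idx = [s.start for _, s in self.chromosome_slices()]
        return np.asarray(idx + [len(self)], dtype=int)


@dataclass
class CellProfile:
    """All per-cell derived vectors, one array slot per grid bin."""

    cell_id: str
    counts: np.ndarray
    norm_counts: np.ndarray | None = None
    ratios: np.ndarray | None = None
    segment_ratios: np.ndarray | None = None
    segments: pd.DataFrame | None = None  # chrom, start_bin, end_bin, mean_ratio
    integer_cn: np.ndarray | None = None
    mapq: float | None = None

    @property
    def cv(self) -> float:
        """Coefficient of variation of the segment-ratio values."""
        if self.segment_ratios is None:
            raise ValueError("segment() has not been run for this cell")
        m = float(np.mean(self.segment_ratios))
        if m == 0:
            return float("nan")
        return float(np.std(self.segment_ratios) / m)


def round_half_away(x):
    """Round to nearest integer, ties away from zero (2.5 -> 3)."""
    x = np.asarray(x, dtype=float)
    return np.sign(x) * np.floor(np.abs(x) + 0.5)


def gc_normalize(counts, gc, span: float = 0.3, iters: int = 3) -> np.ndarray:
    """Divide bin counts by the lowess-fitted count-vs-GC trend.

    The trend is rescaled to mean 1 before division so the output preserves
    the input mean.  Constant GC yields an identity transform with a warning.
    """
    counts = np.asarray(counts, dtype=float)
    gc = np.asarray(gc, dtype=float)
    if counts.shape != gc.shape:
        raise ValueError("counts and gc must be the same length")
    if np.count_nonzero(counts) < 20:
        raise ValueError("need at least 20 non-zero bins for GC normalization")
    if np.ptp(gc) == 0:
        warnings.warn("constant GC across bins; GC normalization is a no-op")
        return counts.copy()
    fitted = _sm_lowess(counts, gc, frac=span, it=iters,
                        xvals=gc, is_sorted=False)
    # guard against non-positive fits in sparse GC tails
    floor = 1e-3 * counts.mean()
    trend = np.maximum(fitted, floor)
    trend = trend / trend.mean()
    return counts / trend


def compute_ratios(norm_counts) -> np.ndarray:
    """Bin-wise ratios: counts divided by the cell's mean bin count."""
    x = np.asarray(norm_counts, dtype=float)
    m = x.mean()
    if m <= 0:
        raise ValueError("mean bin count must be positive")
    return x / m


def _split_stats(x: np.ndarray, min_width: int) -> np.ndarray:
    """|t|-like statistic for every admissible split of one segment.

    Entry k is the standardized mean difference between x[:k] and x[k:]
    for k in [min_width, n-min_width]; other entries are 0.  Vectorized for
    reuse on a whole permutation matrix (2-D input, splits along axis 1).
    """
    x = np.atleast_2d(x)
    n = x.shape[1]
    ks = np.arange(1, n)
    cs = np.cumsum(x, axis=1)
    tot = cs[:, -1][:, None]
    css = np.cumsum(x * x, axis=1)
    tots = css[:, -1][:, None]
    n1 = ks[None, :].astype(float)
    n2 = n - n1
    s1 = cs[:, :-1]
    m1 = s1 / n1
    m2 = (tot - s1) / n2
    ss1 = css[:, :-1] - s1 * s1 / n1
    ss2 = (tots - css[:, :-1]) - (tot - s1) * (tot - s1) / n2
    dof = np.maximum(n - 2, 1)
    pooled = np.sqrt(np.maximum((ss1 + ss2) / dof, 1e-18) * (1 / n1 + 1 / n2))
    t = np.abs(m1 - m2) / pooled
    if min_width > 1:
        t[:, : min_width - 1] = 0.0
        t[:, n - min_width:] = 0.0
    return t


def _segment_chromosome(x: np.ndarray, alpha: float, min_width: int,
                        n_perm: int, rng: np.random.Generator) -> list[int]:
    """Recursive binary segmentation; returns interior breakpoints."""
    breaks: list[int] = []

    def recurse(lo: int, hi: int) -> None:
        n = hi - lo
        if n < 2 * min_width:
            return
        seg = x[lo:hi]
        if np.ptp(seg) == 0:
            return
        t = _split_stats(seg, min_width)[0]
        k = int(np.argmax(t))
        t_obs = t[k]
        if t_obs <= 0:
            return
        # batched permutation test with early stop: abort once the
        # exceedance count already rules out significance at alpha
        max_exceed = alpha * (1 + n_perm) - 1
        exceed, done = 0, 0
        batch = max(100, n_perm // 10)
        while done < n_perm:
            m = min(batch, n_perm - done)
            perm_idx = np.argsort(rng.random((m, n)), axis=1)
            t_perm = _split_stats(seg[perm_idx], min_width).max(axis=1)
            exceed += int(np.sum(t_perm >= t_obs))
            done += m
            if exceed > max_exceed:
                return
        p = (1 + exceed) / (1 + n_perm)
        if p > alpha:
            return
        split = lo + k + 1
        breaks.append(split)
        recurse(lo, split)
        recurse(split, hi)

    recurse(0, len(x))
    return sorted(breaks)


def segment(ratios, grid: BinGrid, alpha: float = 0.01, min_width: int = 3,
            n_perm: int = 1000,
            rng: np.random.Generator | None = None
            ) -> tuple[pd.DataFrame, np.ndarray]:
    """Segment per-bin ratios into piecewise-constant segments.

    Chromosomes are segmented independently; breakpoints never cross a
    chromosome boundary.  A split is accepted only when a permutation test on
    the maximal split statistic is significant at ``alpha``.  Returns a
    segment table (chrom, start_bin, end_bin, mean_ratio) and the per-bin
    segment-ratio vector.
    """
    ratios = np.asarray(ratios, dtype=float)
    if not np.all(np.isfinite(ratios)):
        raise ValueError("ratios must be finite")
    if len(ratios) != len(grid):
        raise ValueError("ratios length must match the bin grid")
    rng = np.random.default_rng(0) if rng is None else rng
    seg_ratios = np.empty_like(ratios)
    rows = []
    for chrom, sl in grid.chromosome_slices():
        x = ratios[sl]
        breaks = _segment_chromosome(x, alpha, min_width, n_perm, rng)
        edges = [0] + breaks + [len(x)]
        for a, b in zip(edges[:-1], edges[1:]):
            mean = float(x[a:b].mean())
            seg_ratios[sl.start + a: sl.start + b] = mean
            rows.append((chrom, sl.start + a, sl.start + b, mean))
    table = pd.DataFrame(rows, columns=["chrom", "start_bin", "end_bin",
                                        "mean_ratio"])
    return table, seg_ratios


def estimate_ploidy(dapi_a_median: float, dapi_d_median: float) -> float:
    """Sample ploidy from DAPI peaks: 2 x (aneuploid / diploid peak median).

    Valid when the majority of sequenced cells/nuclei derive from the
    aneuploid peak; the caller asserts that condition.
    """
    if dapi_a_median <= 0 or dapi_d_median <= 0:
        raise ValueError("DAPI peak medians must be positive")
    return 2.0 * dapi_a_median / dapi_d_median


def integer_cn(segment_ratios, ploidy: float) -> np.ndarray:
    """Integer copy number per bin: round(segment ratio x ploidy).

    Ties round half away from zero; results are floored at 0.
    """
    if ploidy <= 0:
        raise ValueError("ploidy must be positive")
    x = np.asarray(segment_ratios, dtype=float) * ploidy
    return np.maximum(round_half_away(x), 0).astype(int)
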