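"""Multi-cell breakpoint detection and segment aggregation.

Copy-number events typically span many bins, so before any tree inference the
genome is partitioned into segments of consecutive bins sharing a state.  At
every bin boundary we compare, per cell, a model with a step change in read
rate against a constant-rate model inside a local window, under a
negative-binomial observation model; the rectified per-cell evidence is summed
across cells and boundaries clearly above the noise floor are reported as
candidate breakpoints.  All window statistics are evaluated from prefix sums,
so the whole scan costs O(m*B) for m cells and B bins.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "BinCountMatrix",
    "BreakpointSet",
    "SegmentMap",
    "SegmentCounts",
    "per_cell_step_statistic",
    "combined_signal",
    "call_breakpoints",
    "build_segments",
    "aggregate_counts",
    "mask_outlier_bins",
]


@dataclass
class BinCountMatrix:
    """Corrected read counts, cells as rows, genomic bins as columns.

    ``bins`` optionally holds per-bin ``(chrom, start, end)`` records (BED
    convention, 0-based half-open), in genome order.
    """

    counts: np.ndarray
    bins: list[tuple[str, int, int]] | None = None

    def __post_init__(self):
        self.counts = np.asarray(self.counts, dtype=float)
        if self.counts.ndim != 2:
            raise ValueError("counts must be a cells x bins matrix")
        if (self.counts < 0).any() or np.isnan(self.counts).any():
            raise ValueError("counts must be non-negative and finite")
        if self.bins is not None and len(self.bins) != self.n_bins:
            raise ValueError("bin annotation length must match matrix columns")

    @property
    def n_cells(self) -> int:
        return self.counts.shape[0]

    @property
    def n_bins(self) -> int:
        return self.counts.shape[1]


@dataclass
class BreakpointSet:
    """Bin boundaries where copy number changes in a subset of cells.

    Boundary ``b`` means a break between bin ``b-1`` and bin ``b``.
    """

    boundaries: np.ndarray
    signal: np.ndarray

    def __post_init__(self):
        self.boundaries = np.asarray(self.boundaries, dtype=int)
        self.signal = np.asarray(self.signal, dtype=float)
        if np.any(np.diff(self.boundaries) <= 0):
            raise ValueError("boundaries must be strictly increasing")

    def __len__(self) -> int:
        return len(self.boundaries)


@dataclass
class SegmentMap:
    """Half-open bin intervals covering ``0..n_bins`` exactly once."""

    starts: np.ndarray
    ends: np.ndarray

    def __post_init__(self):
        self.starts = np.asarray(self.starts, dtype=int)
        self.ends = np.asarray(self.ends, dtype=int)
        if self.starts[0] != 0 or np.any(self.starts[1:] != self.ends[:-1]):
            raise ValueError("segments must tile the bins contiguously")
        if np.any(self.sizes < 1):
            raise ValueError("segments must contain at least one bin")

    @property
    def sizes(self) -> np.ndarray:
        return self.ends - self.starts

    @property
    def n_segments(self) -> int:
        return len(self.starts)

    @property
    def n_bins(self) -> int:
        return int(self.ends[-1])

    def bin_to_segment(self) -> np.ndarray:
        """Length-``n_bins`` vector mapping each bin to its segment index."""
        return np.repeat(np.arange(self.n_segments), self.sizes)

    def expand(self, per_segment: np.ndarray) -> np.ndarray:
        """Broadcast per-segment values over bins (last axis)."""
        return np.repeat(per_segment, self.sizes, axis=-1)


@dataclass
class SegmentCounts:
    """Per-cell counts summed within segments; row totals are preserved."""

    D: np.ndarray
    sizes: np.ndarray

    @property
    def totals(self) -> np.ndarray:
        return self.D.sum(axis=1)


def _nb_window_loglik(total: np.ndarray, n_bins: np.ndarray, nu_bp: float) -> np.ndarray:
    """Maximized NB log-likelihood of a window, up to data-only constants.

    Counts in a window of ``n_bins`` bins with sum ``total`` are modelled as
    i.i.d. negative binomial with mean mu and shape ``nu_bp`` (variance
    mu + mu^2/nu_bp); the mean's MLE is the window average.  Terms involving
    lgamma of the data cancel between the step and constant models, leaving
    total*log(mu/(mu+nu)) + n*nu*log(nu/(mu+nu)).
    """
    total = np.asarray(total, dtype=float)
    n_bins = np.asarray(n_bins, dtype=float)
    mu = np.divide(total, n_bins, out=np.zeros_like(total), where=n_bins > 0)
    with np.errstate(divide="ignore", invalid="ignore"):
        t1 = np.where(total > 0, total * np.log(mu / (mu + nu_bp)), 0.0)
    t2 = n_bins * nu_bp * np.log(nu_bp / (mu + nu_bp))
    return t1 + t2


def per_cell_step_statistic(
    row: np.ndarray, window: int = 10, nu_bp: float = 1.0
) -> np.ndarray:
    """Log-likelihood ratio of a step vs constant rate at every bin boundary.

    For boundary ``b`` the left window is ``[max(0, b-w), b)`` and the right
    ``[b, min(B, b+w))`` (truncated near the chromosome ends); the statistic
    is the maximized two-mean log-likelihood minus the one-mean value, and is
    zero whenever the two window averages coincide.
    """
    row = np.asarray(row, dtype=float)
    B = row.size
    if window < 2:
        raise ValueError("window must be at least 2 bins")
    if B <= 2 * window:
        raise ValueError("need more than 2*window bins")
    csum = np.concatenate([[0.0], np.cumsum(row)])
    b = np.arange(1, B)
    lo = np.maximum(b - window, 0)
    hi = np.minimum(b + window, B)
    left = csum[b] - csum[lo]
    right = csum[hi] - csum[b]
    nl = (b - lo).astype(float)
    nr = (hi - b).astype(float)
    stat = (
        _nb_window_loglik(left, nl, nu_bp)
        + _nb_window_loglik(right, nr, nu_bp)
        - _nb_window_loglik(left + right, nl + nr, nu_bp)
    )
    # single-bin truncated windows carry no averaging and only produce noise
    stat[(nl < 2) | (nr < 2)] = 0.0
    # numerically the sup of nested models; clip tiny negative round-off
    return np.maximum(stat, 0.0)


def combined_signal(
    matrix: BinCountMatrix, window: int = 10, nu_bp: float = 1.0
) -> np.ndarray:
    """Sum rectified per-cell step evidence over all cells.

    Each cell's counts are first scaled to a common mean so that depth
    differences between cells do not dominate the combined statistic (read
    probabilities, not absolute counts, carry the copy-number signal).
    """
    counts = matrix.counts
    means = counts.mean(axis=1, keepdims=True)
    target = float(means.mean()) or 1.0
    scale = np.divide(target, means, out=np.ones_like(means), where=means > 0)
    scaled = counts * scale
    signal = np.zeros(matrix.n_bins - 1)
    for row in scaled:
        signal += per_cell_step_statistic(row, window=window, nu_bp=nu_bp)
    return signal


def call_breakpoints(
    signal: np.ndarray,
    threshold_sd: float = 6.0,
    min_separation: int = 10,
) -> BreakpointSet:
    """Threshold the combined signal and greedily pick separated peaks.

    A boundary qualifies when its signal exceeds ``median + threshold_sd *
    MAD``; qualifying boundaries are taken in decreasing signal order (ties
    broken toward the lower index), each claiming an exclusion zone of
    ``min_separation`` bins.
    """
    signal = np.asarray(signal, dtype=float)
    med = np.median(signal)
    mad = np.median(np.abs(signal - med))
    cutoff = med + threshold_sd * mad
    candidates = np.nonzero(signal > cutoff)[0]
    # decreasing signal, increasing index on ties
    order = candidates[np.lexsort((candidates, -signal[candidates]))]
    taken: list[int] = []
    blocked = np.zeros(signal.size, dtype=bool)
    for idx in order:
        if not blocked[idx]:
            taken.append(idx)
            lo = max(idx - min_separation + 1, 0)
            blocked[lo : idx + min_separation] = True
    taken.sort()
    boundaries = np.asarray(taken, dtype=int) + 1  # boundary b splits b-1 | b
    return BreakpointSet(boundaries, signal[boundaries - 1])


def build_segments(breakpoints: BreakpointSet | np.ndarray, n_bins: int) -> SegmentMap:
    """Collate bins between consecutive breakpoints: k breaks -> k+1 segments."""
    bounds = (
        breakpoints.boundaries
        if isinstance(breakpoints, BreakpointSet)
        else np.asarray(breakpoints, dtype=int)
    )
    if bounds.size and (bounds[0] < 1 or bounds[-1] > n_bins - 1):
        raise ValueError("breakpoints out of range")
    edges = np.concatenate([[0], bounds, [n_bins]])
    return SegmentMap(edges[:-1], edges[1:])


def aggregate_counts(matrix: BinCountMatrix, segmap: SegmentMap) -> SegmentCounts:
    """Sum counts within segments: D[j, k] = sum of cell j's bins in segment k."""
    if segmap.n_bins != matrix.n_bins:
        raise ValueError("segment map does not cover the bin matrix")
    D = np.add.reduceat(matrix.counts, segmap.starts, axis=1)
    return SegmentCounts(D, segmap.sizes.copy())


def mask_outlier_bins(matrix: BinCountMatrix, fold: float = 3.0) -> np.ndarray:
    """Boolean mask of bins whose total count exceeds ``fold`` x the median."""
    per_bin = matrix.counts.sum(axis=0)
    return per_bin > fold * np.median(per_bin)
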