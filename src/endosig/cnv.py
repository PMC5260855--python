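"""Low-coverage WGS copy-number analysis.

Reads are binned into fixed 10-kb non-overlapping tiles; per-bin counts are
scaled to the reference sample's total and turned into
``log2((scaled + 1) / (reference + 1))`` ratios; ordered ratios are
partitioned by circular binary segmentation (CBS) with a permutation test
per candidate split; segments whose mean deviates from the genome baseline
by more than 3 genome-wide ratio standard deviations are flagged as copy
number split calls.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

try:  # jitted permutation kernel; a numpy path covers its absence
    import numba

    _HAVE_NUMBA = True
except ImportError:  # pragma: no cover
    _HAVE_NUMBA = False

__all__ = [
    "BinnedCoverage",
    "SegmentationProfile",
    "bin_reads",
    "normalize_log2_ratio",
    "max_t_split",
    "cbs_segment",
    "call_splits",
]

DEFAULT_BIN_WIDTH = 10_000


@dataclass
class BinnedCoverage:
    """Per-chromosome fixed-width bin counts for one sample."""

    bins: dict[str, np.ndarray]  # chrom -> integer counts per bin
    bin_width: int = DEFAULT_BIN_WIDTH
    total_reads: int | None = None

    def __post_init__(self) -> None:
        self.bins = {c: np.asarray(v, dtype=np.int64) for c, v in self.bins.items()}
        if any((v < 0).any() for v in self.bins.values()):
            raise ValueError("bin counts must be non-negative")
        n = int(sum(v.sum() for v in self.bins.values()))
        if self.total_reads is None:
            self.total_reads = n
        elif self.total_reads < n:
            raise ValueError("binned counts exceed the stated total mapped reads")

    @property
    def chroms(self) -> list[str]:
        return sorted(self.bins)


def bin_reads(
    read_positions: dict[str, np.ndarray],
    bin_width: int = DEFAULT_BIN_WIDTH,
    chrom_sizes: dict[str, int] | None = None,
) -> BinnedCoverage:
    """Count read start positions into half-open ``bin_width`` tiles.

    A read at position ``p`` lands in bin ``floor(p / bin_width)``. When
    ``chrom_sizes`` is given, each chromosome is tiled to
    ``ceil(size / bin_width)`` bins even if trailing bins are empty.
    """
    bins: dict[str, np.ndarray] = {}
    for chrom, pos in read_positions.items():
        pos = np.asarray(pos, dtype=np.int64)
        if (pos < 0).any():
            raise ValueError(f"negative read position on {chrom}")
        if chrom_sizes is not None:
            if chrom not in chrom_sizes:
                raise ValueError(f"no size for chromosome {chrom}")
            if pos.size and pos.max() >= chrom_sizes[chrom]:
                raise ValueError(f"read position beyond {chrom} end")
            n_bins = -(-chrom_sizes[chrom] // bin_width)
        else:
            n_bins = int(pos.max() // bin_width) + 1 if pos.size else 1
        idx = pos // bin_width
        bins[chrom] = np.bincount(idx, minlength=n_bins).astype(np.int64)
    return BinnedCoverage(bins=bins, bin_width=bin_width)


def normalize_log2_ratio(
    sample: BinnedCoverage, reference: BinnedCoverage
) -> dict[str, np.ndarray]:
    """Reference-scaled, +1-adjusted per-bin log2 ratios.

    Sample counts are scaled by ``N_ref / N_sample`` so both profiles sit
    at the reference depth, both sides take a +1 adjustment to keep ratios
    finite, and the ratio is
    ``log2((scaled_sample + 1) / (reference + 1))`` per bin.
    """
    if sample.bin_width != reference.bin_width:
        raise ValueError("bin widths differ between sample and reference")
    if set(sample.bins) != set(reference.bins) or any(
        sample.bins[c].shape != reference.bins[c].shape for c in sample.bins
    ):
        raise ValueError("sample and reference bin grids do not match")
    if not sample.total_reads or not reference.total_reads:
        raise ValueError("total read counts must be positive")
    scale = reference.total_reads / sample.total_reads
    return {
        c: np.log2((sample.bins[c] * scale + 1.0) / (reference.bins[c] + 1.0))
        for c in sample.bins
    }


@dataclass
class SegmentationProfile:
    """CBS output: segments partitioning the binned genome plus split calls."""

    segments: pd.DataFrame  # chrom, start_bin, end_bin, mean, n_bins [, split_call]
    ratios: dict[str, np.ndarray] = field(repr=False)
    sd: float = 0.0  # genome-wide per-bin ratio standard deviation
    bin_width: int = DEFAULT_BIN_WIDTH


def _pair_index(n: int, min_width: int) -> tuple[np.ndarray, np.ndarray]:
    """Circular split pairs (i, j), lexicographic, both arcs wide enough.

    Pairs with ``j == n`` are excluded: arc ``[i, n)`` defines the same
    two-arc partition as ``(0, i)``, so each partition appears exactly once
    and ties resolve to one canonical pair.
    """
    i, j = np.meshgrid(np.arange(n), np.arange(n), indexing="ij")
    w = j - i
    ok = (w >= min_width) & (n - w >= min_width)
    return i[ok], j[ok]


def _arc_t(
    arc_sum: np.ndarray, w: np.ndarray, total: float, ss_total: float, n: int
) -> np.ndarray:
    """Two-sample t for arc vs complement, pooled variance."""
    m1 = arc_sum / w
    m2 = (total - arc_sum) / (n - w)
    ss_within = ss_total - w * m1**2 - (n - w) * m2**2
    s2 = np.maximum(ss_within, 0.0) / max(n - 2, 1)
    denom = np.sqrt(np.maximum(s2, 1e-300) * (1.0 / w + 1.0 / (n - w)))
    return (m1 - m2) / denom


def max_t_split(
    x: np.ndarray, min_width: int = 2
) -> tuple[float, int, int] | None:
    """Best circular split of ``x``: maximal |t| arc ``[i, j)`` vs the rest.

    Ties resolve to the lexicographically smallest ``(i, j)``. Returns
    ``None`` when the array is too short for any valid split.
    """
    x = np.asarray(x, dtype=float)
    n = x.size
    if n < 2 * min_width:
        return None
    ii, jj = _pair_index(n, min_width)
    S = np.concatenate([[0.0], np.cumsum(x)])
    t = _arc_t(S[jj] - S[ii], (jj - ii).astype(float), S[-1], float(np.sum(x**2)), n)
    k = int(np.argmax(np.abs(t)))  # first max = lexicographic smallest pair
    return float(np.abs(t[k])), int(ii[k]), int(jj[k])


if _HAVE_NUMBA:

    @numba.njit(cache=True)
    def _max_t2_exceed(perms, t2_obs, min_width, stop_at):  # pragma: no cover
        m, n = perms.shape
        exceed = 0
        S = np.empty(n + 1)
        for p in range(m):
            S[0] = 0.0
            ss_tot = 0.0
            for k in range(n):
                S[k + 1] = S[k] + perms[p, k]
                ss_tot += perms[p, k] * perms[p, k]
            total = S[n]
            best = 0.0
            for i in range(0, n - min_width + 1):
                jmax = min(i + n - min_width, n - 1)
                for j in range(i + min_width, jmax + 1):
                    w = j - i
                    if n - w < min_width:
                        continue
                    arc = S[j] - S[i]
                    m1 = arc / w
                    m2 = (total - arc) / (n - w)
                    d = m1 - m2
                    ssw = ss_tot - w * m1 * m1 - (n - w) * m2 * m2
                    if ssw < 1e-300:
                        ssw = 1e-300
                    t2 = d * d * (n - 2) / (ssw * (1.0 / w + 1.0 / (n - w)))
                    if t2 > best:
                        best = t2
            if best >= t2_obs:
                exceed += 1
                if exceed >= stop_at:
                    return exceed, p + 1
        return exceed, m


def _perm_pvalue(
    x: np.ndarray,
    t_obs: float,
    min_width: int,
    n_permutations: int,
    alpha: float,
    rng: np.random.Generator,
    chunk: int = 100,
) -> float:
    """Permutation p of the max-|t| statistic, with early stopping.

    Stops as soon as the number of exceedances guarantees ``p >= alpha``.
    """
    n = x.size
    stop_at = int(np.ceil(alpha * n_permutations))
    perms = rng.permuted(np.broadcast_to(x, (n_permutations, n)), axis=1)
    if _HAVE_NUMBA:
        exceed, done = _max_t2_exceed(
            perms.astype(np.float64), t_obs * t_obs, min_width, stop_at
        )
        if exceed >= stop_at:
            return 1.0  # p >= alpha already certain; exact value irrelevant
        return exceed / n_permutations
    ii, jj = _pair_index(n, min_width)
    w = (jj - ii).astype(float)
    ss_total = float(np.sum(x**2))  # invariant under permutation
    exceed = 0
    for lo in range(0, n_permutations, chunk):
        block = perms[lo : lo + chunk]
        S = np.concatenate(
            [np.zeros((block.shape[0], 1)), np.cumsum(block, axis=1)], axis=1
        )
        t = _arc_t(S[:, jj] - S[:, ii], w, S[0, -1], ss_total, n)
        exceed += int((np.abs(t).max(axis=1) >= t_obs).sum())
        if exceed >= stop_at:
            return 1.0
    return exceed / n_permutations


def cbs_segment(
    log2_ratios: dict[str, np.ndarray] | np.ndarray,
    alpha: float = 0.01,
    n_permutations: int = 1000,
    min_width: int = 2,
    seed: int = 17,
    bin_width: int = DEFAULT_BIN_WIDTH,
) -> SegmentationProfile:
    """Recursive circular binary segmentation of ordered log2 ratios.

    For each current segment the two-arc mean-difference t-statistic is
    maximised over all circular splits; the split is accepted iff its
    within-segment permutation p (``n_permutations`` shuffles) is below
    ``alpha``, and the procedure recurses into the resulting pieces.
    Deterministic for a fixed ``seed``.
    """
    if not isinstance(log2_ratios, dict):
        log2_ratios = {"chr1": np.asarray(log2_ratios, dtype=float)}
    rng = np.random.default_rng(seed)
    rows = []
    for chrom in sorted(log2_ratios):
        x_all = np.asarray(log2_ratios[chrom], dtype=float)
        if x_all.size == 0:
            continue
        stack = [(0, x_all.size)]
        found: list[tuple[int, int]] = []
        while stack:
            s, e = stack.pop()
            seg = x_all[s:e]
            best = max_t_split(seg, min_width)
            accept = False
            if best is not None and np.ptp(seg) > 0:
                t_obs, i, j = best
                p = _perm_pvalue(
                    seg, t_obs, min_width, n_permutations, alpha, rng
                )
                accept = p < alpha
            if accept:
                cuts = sorted({s + i, s + j} - {s, e})
                if not cuts:
                    accept = False
                else:
                    bounds = [s] + cuts + [e]
                    for a, b in zip(bounds[:-1], bounds[1:]):
                        stack.append((a, b))
            if not accept:
                found.append((s, e))
        for s, e in sorted(found):
            rows.append(
                {
                    "chrom": chrom,
                    "start_bin": s,
                    "end_bin": e,
                    "mean": float(x_all[s:e].mean()),
                    "n_bins": e - s,
                }
            )
    segments = pd.DataFrame(
        rows, columns=["chrom", "start_bin", "end_bin", "mean", "n_bins"]
    )
    all_bins = np.concatenate([np.asarray(v, float) for v in log2_ratios.values()])
    return SegmentationProfile(
        segments=segments,
        ratios={c: np.asarray(v, float) for c, v in log2_ratios.items()},
        sd=float(all_bins.std()),
        bin_width=bin_width,
    )


def _weighted_median(values: np.ndarray, weights: np.ndarray) -> float:
    order = np.argsort(values)
    v, w = values[order], weights[order]
    cum = np.cumsum(w)
    return float(v[np.searchsorted(cum, 0.5 * w.sum())])


def call_splits(
    profile: SegmentationProfile, sd_multiple: float = 3.0
) -> SegmentationProfile:
    """Flag segments deviating > ``sd_multiple`` genome s.d. from baseline.

    The baseline is the bin-weighted median of segment means; the scale is
    the genome-wide per-bin ratio standard deviation. The inequality is
    strict: a segment exactly at the threshold is not called.
    """
    seg = profile.segments.copy()
    if len(seg) == 0:
        profile.segments = seg.assign(split_call=pd.Series(dtype=bool))
        return profile
    baseline = _weighted_median(
        seg["mean"].to_numpy(), seg["n_bins"].to_numpy(dtype=float)
    )
    seg["split_call"] = np.abs(seg["mean"] - baseline) > sd_multiple * profile.sd
    profile.segments = seg
    return profile
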