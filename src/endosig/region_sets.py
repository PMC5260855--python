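"""Set algebra over bound-region sets.

Implements the comparisons used to dissect a transcription factor's binding
purview across cell states: the Core set shared by all cell types, the
Up/Down sets from a differential-binding contrast, a Unique set excluded
from other cell types, pairwise percent-shared statistics and Venn counts.

"Shared" throughout means an overlap of at least 1 bp between half-open
intervals; no reciprocal-fraction requirement is imposed.
"""
from __future__ import annotations

from typing import Sequence

import pandas as pd

from .intervals import GenomicInterval, RegionSet, union

__all__ = [
    "core_set",
    "differential_sets",
    "unique_set",
    "percent_shared",
    "venn_counts",
]


def core_set(dbr_sets: Sequence[RegionSet], name: str = "core") -> RegionSet:
    """Intervals of the first set that overlap every other set.

    The anchor is the first set: its intervals are reported unchanged, so the
    core inherits the first set's region boundaries.
    """
    if len(dbr_sets) < 2:
        raise ValueError("core_set requires at least two region sets")
    first, rest = dbr_sets[0], dbr_sets[1:]
    masks = [first.overlap_mask(other) for other in rest]
    kept = [
        iv for i, iv in enumerate(first) if all(mask[i] for mask in masks)
    ]
    return RegionSet(kept, name=name)


def differential_sets(
    results: pd.DataFrame, name_prefix: str = ""
) -> tuple[RegionSet, RegionSet]:
    """Split a called differential-binding table into (up, down) region sets.

    ``results`` must carry columns ``chrom, start, end, call`` with calls in
    {"up", "down", "ns"}. Up and down are disjoint by construction.
    """
    if "call" not in results.columns:
        raise ValueError("results table has no 'call' column")

    def _subset(call: str) -> RegionSet:
        sub = results[results["call"] == call]
        return RegionSet(
            (
                GenomicInterval(r.chrom, int(r.start), int(r.end))
                for r in sub.itertuples()
            ),
            name=f"{name_prefix}{call}",
        )

    return _subset("up"), _subset("down")


def unique_set(
    down: RegionSet, exclusion_sets: Sequence[RegionSet], name: str = "unique"
) -> RegionSet:
    """Members of ``down`` that overlap no interval of any exclusion set."""
    kept = list(down)
    for excl in exclusion_sets:
        mask = RegionSet(kept).overlap_mask(excl)
        kept = [iv for iv, hit in zip(kept, mask) if not hit]
    return RegionSet(kept, name=name)


def percent_shared(a: RegionSet, b: RegionSet) -> float:
    """Percent of ``a``'s intervals overlapping ``b`` (asymmetric)."""
    if len(a) == 0:
        raise ValueError("percent_shared undefined for an empty query set")
    return 100.0 * a.count_overlapping(b) / len(a)


def venn_counts(sets: Sequence[RegionSet]) -> dict[str, int]:
    """Venn membership counts for 2–4 region sets.

    Counting is anchored on the merged union of all sets: each union interval
    is assigned the signature of input sets it overlaps, which keeps counts
    well-defined when the sets fragment each other. Keys are '&'-joined set
    names (or positional names ``set1``..); every non-empty signature appears,
    including zero-count cells.
    """
    if not (2 <= len(sets) <= 4):
        raise ValueError("venn_counts supports 2 to 4 region sets")
    names = [rs.name or f"set{i + 1}" for i, rs in enumerate(sets)]
    if len(set(names)) != len(names):
        raise ValueError("region set names must be distinct for Venn counting")
    anchor = union(sets)
    counts: dict[tuple[bool, ...], int] = {}
    masks = [anchor.overlap_mask(rs) for rs in sets]
    for i in range(len(anchor)):
        sig = tuple(mask[i] for mask in masks)
        counts[sig] = counts.get(sig, 0) + 1
    out: dict[str, int] = {}
    for code in range(1, 2 ** len(sets)):
        sig = tuple(bool(code & (1 << k)) for k in range(len(sets)))
        key = "&".join(n for n, inc in zip(names, sig) if inc)
        out[key] = counts.get(sig, 0)
    return out
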