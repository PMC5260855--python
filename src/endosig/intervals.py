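"""Genomic interval primitives.

All coordinates are 0-based, half-open ``[start, end)`` on named
chromosomes — the BED convention. These types are the currency of every
set, overlap and enrichment operation in the package.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Iterator, Sequence

from intervaltree import IntervalTree

__all__ = ["GenomicInterval", "RegionSet", "union", "subtract"]


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A half-open genomic interval ``[start, end)`` on ``chrom``."""

    chrom: str
    start: int
    end: int
    score: float | None = field(default=None, compare=False)

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end}: "
                "require 0 <= start < end"
            )

    @property
    def length(self) -> int:
        return self.end - self.start

    def overlap_bp(self, other: "GenomicInterval") -> int:
        """Number of base pairs shared with ``other`` (0 if different chrom)."""
        if self.chrom != other.chrom:
            return 0
        return max(0, min(self.end, other.end) - max(self.start, other.start))

    def overlaps(self, other: "GenomicInterval", min_bp: int = 1) -> bool:
        """True iff the two intervals share at least ``min_bp`` base pairs.

        With the half-open convention, abutting intervals (``a.end ==
        b.start``) do not overlap.
        """
        return self.overlap_bp(other) >= min_bp


class RegionSet:
    """An ordered collection of :class:`GenomicInterval`.

    Intervals are kept sorted by ``(chrom, start, end)``. ``merged`` is set
    when the intervals are known to be mutually non-overlapping (abutting
    intervals are allowed and kept separate).
    """

    def __init__(
        self,
        intervals: Iterable[GenomicInterval] = (),
        name: str = "",
        merged: bool = False,
    ) -> None:
        self.intervals: list[GenomicInterval] = sorted(
            intervals, key=lambda iv: (iv.chrom, iv.start, iv.end)
        )
        self.name = name
        self.merged = merged
        self._trees: dict[str, IntervalTree] | None = None

    @classmethod
    def from_tuples(
        cls, tuples: Iterable[tuple], name: str = ""
    ) -> "RegionSet":
        return cls((GenomicInterval(*t) for t in tuples), name=name)

    def __len__(self) -> int:
        return len(self.intervals)

    def __iter__(self) -> Iterator[GenomicInterval]:
        return iter(self.intervals)

    def __getitem__(self, i: int) -> GenomicInterval:
        return self.intervals[i]

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, RegionSet):
            return NotImplemented
        return self.intervals == other.intervals

    def __repr__(self) -> str:
        return f"RegionSet({self.name!r}, n={len(self)})"

    @property
    def chroms(self) -> list[str]:
        return sorted({iv.chrom for iv in self.intervals})

    def lengths(self) -> list[int]:
        return [iv.length for iv in self.intervals]

    def _tree_index(self) -> dict[str, IntervalTree]:
        if self._trees is None:
            trees: dict[str, IntervalTree] = {}
            for iv in self.intervals:
                trees.setdefault(iv.chrom, IntervalTree()).addi(iv.start, iv.end)
            self._trees = trees
        return self._trees

    def overlaps_point_set(self, iv: GenomicInterval, min_bp: int = 1) -> bool:
        """True iff ``iv`` overlaps any member by at least ``min_bp`` bp."""
        tree = self._tree_index().get(iv.chrom)
        if tree is None:
            return False
        if min_bp == 1:
            return bool(tree.overlap(iv.start, iv.end))
        return any(
            min(h.end, iv.end) - max(h.begin, iv.start) >= min_bp
            for h in tree.overlap(iv.start, iv.end)
        )

    def overlap_mask(self, other: "RegionSet", min_bp: int = 1) -> list[bool]:
        """Per-interval flags: does each member overlap ``other``?"""
        return [other.overlaps_point_set(iv, min_bp=min_bp) for iv in self]

    def count_overlapping(self, other: "RegionSet", min_bp: int = 1) -> int:
        return sum(self.overlap_mask(other, min_bp=min_bp))

    def merge(self, name: str | None = None) -> "RegionSet":
        """Merge strictly-overlapping intervals; abutting intervals stay apart."""
        merged: list[GenomicInterval] = []
        for iv in self.intervals:
            if (
                merged
                and merged[-1].chrom == iv.chrom
                and iv.start < merged[-1].end  # strict overlap, not abutment
            ):
                prev = merged.pop()
                merged.append(
                    GenomicInterval(prev.chrom, prev.start, max(prev.end, iv.end))
                )
            else:
                merged.append(iv)
        return RegionSet(merged, name=self.name if name is None else name, merged=True)


def _chrom_events(sets: Sequence[RegionSet]) -> dict[str, list[tuple[int, int]]]:
    by_chrom: dict[str, list[tuple[int, int]]] = {}
    for rs in sets:
        for iv in rs:
            by_chrom.setdefault(iv.chrom, []).append((iv.start, iv.end))
    return by_chrom


def union(sets: Sequence[RegionSet], name: str = "union") -> RegionSet:
    """Base-pair union of several region sets, as maximal merged intervals.

    Unlike :meth:`RegionSet.merge`, abutting pieces coalesce here: the result
    describes covered base pairs, not input fragments.
    """
    out: list[GenomicInterval] = []
    for chrom, spans in _chrom_events(sets).items():
        spans.sort()
        cur_s, cur_e = spans[0]
        for s, e in spans[1:]:
            if s <= cur_e:
                cur_e = max(cur_e, e)
            else:
                out.append(GenomicInterval(chrom, cur_s, cur_e))
                cur_s, cur_e = s, e
        out.append(GenomicInterval(chrom, cur_s, cur_e))
    return RegionSet(out, name=name, merged=True)


def subtract(a: RegionSet, b: RegionSet, name: str = "difference") -> RegionSet:
    """Base pairs covered by ``a`` but not by ``b``, as merged intervals."""
    a_u = union([a]) if len(a) else RegionSet(name=name, merged=True)
    if not len(a_u):
        return RegionSet(name=name, merged=True)
    b_u = union([b]) if len(b) else None
    out: list[GenomicInterval] = []
    for iv in a_u:
        cuts: list[tuple[int, int]] = []
        if b_u is not None:
            tree = b_u._tree_index().get(iv.chrom)
            if tree is not None:
                cuts = sorted((h.begin, h.end) for h in tree.overlap(iv.start, iv.end))
        pos = iv.start
        for s, e in cuts:
            if s > pos:
                out.append(GenomicInterval(iv.chrom, pos, min(s, iv.end)))
            pos = max(pos, e)
            if pos >= iv.end:
                break
        if pos < iv.end:
            out.append(GenomicInterval(iv.chrom, pos, iv.end))
    return RegionSet(out, name=name, merged=True)
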