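"""Annotation-overlap log-odds enrichment with a matched random control.

A query region set is compared to an annotation track by counting how many
query intervals overlap the track versus how many intervals of a random
control set do. The control mimics the query: every control interval has
the query's median bp length and is placed uniformly on the genome, with
chromosomes drawn proportionally to their lengths. The enrichment statistic
is the continuity-corrected log-odds ratio of the resulting 2x2 table.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .intervals import GenomicInterval, RegionSet, subtract, union

__all__ = [
    "AnnotationTrack",
    "OverlapEnrichment",
    "sample_matched_control",
    "overlap_log_odds",
    "derived_chromatin_maps",
    "cross_track_overlap",
]


@dataclass
class AnnotationTrack:
    """Labelled intervals: one :class:`RegionSet` per element-type label."""

    name: str
    by_label: dict[str, RegionSet]

    def __post_init__(self) -> None:
        if any(not lab for lab in self.by_label):
            raise ValueError("annotation labels must be nonempty")

    @property
    def labels(self) -> list[str]:
        return sorted(self.by_label)

    def all_regions(self) -> RegionSet:
        ivs = [iv for rs in self.by_label.values() for iv in rs]
        return RegionSet(ivs, name=self.name)


@dataclass
class OverlapEnrichment:
    """2x2 overlap table of a query vs a track, with its log-odds ratio."""

    query_name: str
    track_name: str
    a: int  # query intervals overlapping the track
    b: int  # query intervals not overlapping
    c: int  # control intervals overlapping
    d: int  # control intervals not overlapping
    log_odds: float
    log_base: str = "e"
    n_control: int = 0
    control_length: int = 0
    seed: int | None = None

    @property
    def query_fraction(self) -> float:
        return self.a / (self.a + self.b)

    @property
    def control_fraction(self) -> float:
        return self.c / (self.c + self.d)


def sample_matched_control(
    query: RegionSet,
    chrom_sizes: dict[str, int],
    n_control: int,
    seed: int,
    match: str = "median",
) -> RegionSet:
    """Random genomic locations with the query's median bp length.

    Chromosomes are drawn with probability proportional to their length and
    starts uniformly over the positions where the interval fits. With
    ``match='sample'`` each control interval instead draws its length from
    the empirical query length distribution.
    """
    if n_control <= 0:
        raise ValueError("n_control must be positive")
    if len(query) == 0:
        raise ValueError("cannot match an empty query set")
    missing = set(query.chroms) - set(chrom_sizes)
    if missing:
        raise ValueError(f"chrom sizes missing for {sorted(missing)}")
    lengths = np.asarray(query.lengths())
    med = int(round(float(np.median(lengths))))
    min_size = min(chrom_sizes.values())
    if med > min_size:
        raise ValueError(
            f"median query length {med} exceeds the smallest chromosome ({min_size} bp)"
        )
    rng = np.random.default_rng(seed)
    chroms = sorted(chrom_sizes)
    sizes = np.array([chrom_sizes[c] for c in chroms], dtype=float)
    picks = rng.choice(len(chroms), size=n_control, p=sizes / sizes.sum())
    if match == "sample":
        ctrl_lengths = rng.choice(lengths, size=n_control)
    else:
        ctrl_lengths = np.full(n_control, med)
    ivs = []
    for k, L in zip(picks, ctrl_lengths):
        L = int(min(L, chrom_sizes[chroms[k]]))
        start = int(rng.integers(0, chrom_sizes[chroms[k]] - L + 1))
        ivs.append(GenomicInterval(chroms[k], start, start + L))
    return RegionSet(ivs, name=f"{query.name or 'query'}_control")


def overlap_log_odds(
    query: RegionSet,
    track: RegionSet | AnnotationTrack,
    control: RegionSet,
    log_base: str = "e",
    seed: int | None = None,
) -> OverlapEnrichment:
    """Continuity-corrected log-odds of query-vs-control overlap with a track.

    ``log_odds = log[ ((a+.5)(d+.5)) / ((b+.5)(c+.5)) ]`` where a/b count
    query intervals overlapping / not overlapping the track (>= 1 bp) and
    c/d do the same for the control. Natural log by default
    (``log_base='2'`` for log2).
    """
    if len(query) == 0:
        raise ValueError("empty query set")
    if len(control) == 0:
        raise ValueError("empty control set")
    track_rs = track.all_regions() if isinstance(track, AnnotationTrack) else track
    a = query.count_overlapping(track_rs)
    b = len(query) - a
    c = control.count_overlapping(track_rs)
    d = len(control) - c
    lo = np.log(((a + 0.5) * (d + 0.5)) / ((b + 0.5) * (c + 0.5)))
    if log_base == "2":
        lo /= np.log(2.0)
    elif log_base != "e":
        raise ValueError("log_base must be 'e' or '2'")
    ctrl_lengths = control.lengths()
    return OverlapEnrichment(
        query_name=query.name,
        track_name=track.name if isinstance(track, AnnotationTrack) else track_rs.name,
        a=a,
        b=b,
        c=c,
        d=d,
        log_odds=float(lo),
        log_base=log_base,
        n_control=len(control),
        control_length=int(ctrl_lengths[0]) if ctrl_lengths else 0,
        seed=seed,
    )


def derived_chromatin_maps(
    tracks_by_celltype: dict[str, AnnotationTrack],
    focal_celltype: str = "HUVEC",
) -> tuple[AnnotationTrack, AnnotationTrack, AnnotationTrack]:
    """Composite / focal-unique / focal-excluded chromatin-state maps.

    Per element-type label, composite is the bp union over all cell types,
    focal-unique the focal cell type's bp minus all others, and
    focal-excluded the others' bp minus the focal — the three derived maps
    used to ask where a binding site set falls relative to a reference
    cell type's regulatory landscape.
    """
    if focal_celltype not in tracks_by_celltype:
        raise ValueError(f"focal cell type {focal_celltype!r} absent")
    if len(tracks_by_celltype) < 2:
        raise ValueError("need at least two cell types")
    labels = sorted(
        {lab for tr in tracks_by_celltype.values() for lab in tr.by_label}
    )
    comp: dict[str, RegionSet] = {}
    uniq: dict[str, RegionSet] = {}
    excl: dict[str, RegionSet] = {}
    empty = RegionSet()
    for lab in labels:
        focal = tracks_by_celltype[focal_celltype].by_label.get(lab, empty)
        others = [
            tr.by_label.get(lab, empty)
            for ct, tr in tracks_by_celltype.items()
            if ct != focal_celltype
        ]
        other_u = union(others) if others else empty
        comp[lab] = union([focal, other_u], name=f"composite|{lab}")
        uniq[lab] = subtract(focal, other_u, name=f"{focal_celltype}_unique|{lab}")
        excl[lab] = subtract(other_u, focal, name=f"{focal_celltype}_excluded|{lab}")
    return (
        AnnotationTrack("composite", comp),
        AnnotationTrack(f"{focal_celltype}_unique", uniq),
        AnnotationTrack(f"{focal_celltype}_excluded", excl),
    )


def cross_track_overlap(
    query_sets: list[RegionSet],
    track: RegionSet | AnnotationTrack,
    control: RegionSet | None = None,
    chrom_sizes: dict[str, int] | None = None,
    n_control: int | None = None,
    seed: int = 17,
    log_base: str = "e",
) -> pd.DataFrame:
    """One log-odds enrichment per query set against one track and control.

    Sharing a single control across query sets makes their log-odds values
    directly comparable. If no control is given one is sampled, matched to
    the pooled queries (requires ``chrom_sizes``); ``n_control`` defaults
    to ``max(10 * total query size, 10000)``.
    """
    if control is None:
        if chrom_sizes is None:
            raise ValueError("chrom_sizes required to sample a shared control")
        pooled = RegionSet(
            [iv for rs in query_sets for iv in rs], name="pooled_query"
        )
        if n_control is None:
            n_control = max(10 * len(pooled), 10_000)
        control = sample_matched_control(pooled, chrom_sizes, n_control, seed)
    rows = []
    for rs in query_sets:
        enr = overlap_log_odds(rs, track, control, log_base=log_base, seed=seed)
        rows.append(
            {
                "query": enr.query_name,
                "track": enr.track_name,
                "a": enr.a,
                "b": enr.b,
                "c": enr.c,
                "d": enr.d,
                "query_fraction": enr.query_fraction,
                "control_fraction": enr.control_fraction,
                "log_odds": enr.log_odds,
            }
        )
    return pd.DataFrame(rows)
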