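"""Known-motif (PWM) scanning and enrichment over sequence sets.

Position weight matrices are scored as per-position log2 odds against a
background composition; a hit is any window scoring at least a fraction
(default 0.8) of the matrix's maximum achievable score, on either strand.
Enrichment of a motif in a foreground vs a background sequence set is a
one-sided Fisher exact test on sequence-level hit counts; p-values are
scaled by the number of motifs tested into E-values and reported as
``-log10(E)`` ("inverse log E", higher = more enriched).
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import fisher_exact

__all__ = [
    "PWM",
    "scan_pwm",
    "motif_enrichment",
    "accessory_motif_search",
    "read_jaspar",
]

_ALPHABET = "ACGT"
_CODE = {b: i for i, b in enumerate(_ALPHABET)}
_CODE["N"] = 4
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

INVERSE_LOG_E_FLOOR = 1e-300


@dataclass
class PWM:
    """A motif as an L x 4 probability matrix over A, C, G, T."""

    name: str
    matrix: np.ndarray  # (L, 4), rows sum to 1
    background: np.ndarray | None = None  # (4,), defaults to uniform

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.ndim != 2 or self.matrix.shape[1] != 4:
            raise ValueError("PWM matrix must be L x 4 (A, C, G, T)")
        if len(self) < 4:
            raise ValueError("PWM must span at least 4 positions")
        if not np.allclose(self.matrix.sum(axis=1), 1.0, atol=1e-9):
            raise ValueError("PWM rows must each sum to 1")
        if self.background is None:
            self.background = np.full(4, 0.25)
        self.background = np.asarray(self.background, dtype=float)
        if not np.isclose(self.background.sum(), 1.0, atol=1e-9):
            raise ValueError("background frequencies must sum to 1")

    def __len__(self) -> int:
        return self.matrix.shape[0]

    @classmethod
    def from_counts(
        cls,
        name: str,
        counts: np.ndarray,
        pseudo: float = 0.25,
        background: np.ndarray | None = None,
    ) -> "PWM":
        """Normalise a count matrix to probabilities with a +``pseudo``
        weight per cell."""
        counts = np.asarray(counts, dtype=float) + pseudo
        return cls(name, counts / counts.sum(axis=1, keepdims=True), background)

    def score_matrix(self) -> np.ndarray:
        """(L, 5) log2(p/q) lookup; the 5th column scores N as 0."""
        sm = np.log2(np.maximum(self.matrix, 1e-12) / self.background[None, :])
        return np.column_stack([sm, np.zeros(len(self))])

    def max_score(self) -> float:
        return float(self.score_matrix()[:, :4].max(axis=1).sum())

    def consensus(self) -> str:
        return "".join(_ALPHABET[i] for i in self.matrix.argmax(axis=1))

    def reverse_complement(self) -> "PWM":
        return PWM(self.name, self.matrix[::-1, ::-1], self.background)


def encode(seq: str) -> np.ndarray:
    try:
        return np.array([_CODE[b] for b in seq.upper()], dtype=np.int8)
    except KeyError as e:
        raise ValueError(f"sequence contains non-ACGTN base {e.args[0]!r}") from None


def reverse_complement(seq: str) -> str:
    return seq.upper().translate(_COMPLEMENT)[::-1]


def _window_scores(codes: np.ndarray, sm: np.ndarray) -> np.ndarray:
    """Scores of every window of one encoded sequence (len L matrix)."""
    L = sm.shape[0]
    n = codes.size - L + 1
    if n <= 0:
        return np.empty(0)
    windows = np.lib.stride_tricks.sliding_window_view(codes, L)
    return sm[np.arange(L)[None, :], windows].sum(axis=1)


def scan_pwm(
    sequence: str, pwm: PWM, score_threshold_fraction: float = 0.8
) -> list[tuple[int, str, float]]:
    """All PWM hits in a sequence, both strands.

    Returns ``(position, strand, score)`` triples sorted by position;
    positions index the forward strand (leftmost base of the matched
    window). A hit scores at least ``score_threshold_fraction`` of the
    motif's maximum achievable score; N bases contribute 0.
    """
    codes = encode(sequence)
    sm = pwm.score_matrix()
    thr = score_threshold_fraction * pwm.max_score()
    hits: list[tuple[int, str, float]] = []
    fwd = _window_scores(codes, sm)
    for pos in np.nonzero(fwd >= thr)[0]:
        hits.append((int(pos), "+", float(fwd[pos])))
    rc_sm = pwm.reverse_complement().score_matrix()
    rev = _window_scores(codes, rc_sm)
    for pos in np.nonzero(rev >= thr)[0]:
        hits.append((int(pos), "-", float(rev[pos])))
    return sorted(hits)


def _hit_count(
    seqs: list[str], pwm: PWM, threshold_fraction: float
) -> tuple[int, np.ndarray]:
    """Number of sequences with >= 1 hit, plus the per-sequence flags."""
    sm = pwm.score_matrix()
    rc_sm = pwm.reverse_complement().score_matrix()
    thr = threshold_fraction * pwm.max_score()
    flags = np.zeros(len(seqs), dtype=bool)
    for i, s in enumerate(seqs):
        codes = encode(s)
        fwd = _window_scores(codes, sm)
        if fwd.size and fwd.max() >= thr:
            flags[i] = True
            continue
        rev = _window_scores(codes, rc_sm)
        flags[i] = bool(rev.size and rev.max() >= thr)
    return int(flags.sum()), flags


def motif_enrichment(
    fg_sequences: list[str],
    bg_sequences: list[str],
    pwms: list[PWM],
    score_threshold_fraction: float = 0.8,
) -> pd.DataFrame:
    """Per-motif foreground-vs-background enrichment table.

    One-sided Fisher exact p on the 2x2 (hit / no-hit x fg / bg) table of
    sequence-level hits; ``E = p * len(pwms)``;
    ``inverse_log_E = -log10(max(E, 1e-300))``. Rows are sorted by
    ``inverse_log_E`` descending.
    """
    if not fg_sequences or not bg_sequences:
        raise ValueError("foreground and background sets must be nonempty")
    if not pwms:
        raise ValueError("no PWMs supplied")
    rows = []
    for pwm in pwms:
        k_fg, _ = _hit_count(fg_sequences, pwm, score_threshold_fraction)
        k_bg, _ = _hit_count(bg_sequences, pwm, score_threshold_fraction)
        n_fg, n_bg = len(fg_sequences), len(bg_sequences)
        _, p = fisher_exact(
            [[k_fg, n_fg - k_fg], [k_bg, n_bg - k_bg]], alternative="greater"
        )
        e = min(p * len(pwms), np.inf)
        rows.append(
            {
                "pwm": pwm.name,
                "k_fg": k_fg,
                "n_fg": n_fg,
                "k_bg": k_bg,
                "n_bg": n_bg,
                "p": p,
                "E": e,
                "inverse_log_E": -np.log10(max(e, INVERSE_LOG_E_FLOOR)),
            }
        )
    out = pd.DataFrame(rows)
    return out.sort_values(
        ["inverse_log_E", "pwm"], ascending=[False, True]
    ).reset_index(drop=True)


def accessory_motif_search(
    sequences: list[str],
    primary_pwm: PWM,
    candidate_pwms: list[PWM],
    window: int = 50,
    score_threshold_fraction: float = 0.8,
    seed: int = 17,
) -> pd.DataFrame:
    """Enrichment of candidate motifs near the best primary-motif hit.

    Foreground: +-``window`` bp around the best (highest-scoring, then
    leftmost) primary hit of each sequence with a hit. Background:
    same-width windows at seeded random positions of the same sequences
    that avoid the chosen hit window. Candidates identical in name to the
    primary are reported but flagged ``self_match``.
    """
    rng = np.random.default_rng(seed)
    fg: list[str] = []
    bg: list[str] = []
    n_with_hit = 0
    for s in sequences:
        hits = scan_pwm(s, primary_pwm, score_threshold_fraction)
        if not hits:
            continue
        n_with_hit += 1
        best = max(hits, key=lambda h: (h[2], -h[0]))
        h_start, h_end = best[0], best[0] + len(primary_pwm)
        w_start = max(0, h_start - window)
        w_end = min(len(s), h_end + window)
        fg.append(s[w_start:w_end])
        width = w_end - w_start
        # prefer windows disjoint from the hit window; in short sequences
        # fall back to any window not anchored on a primary hit
        valid = [
            st
            for st in range(0, len(s) - width + 1)
            if st + width <= w_start or st >= w_end
        ]
        if not valid:
            hit_starts = {h[0] for h in hits}
            valid = [
                st
                for st in range(0, len(s) - width + 1)
                if st not in hit_starts and st != w_start
            ]
        if valid:
            st = int(rng.choice(valid))
            bg.append(s[st : st + width])
    if n_with_hit < 10:
        raise ValueError(
            f"primary motif hits only {n_with_hit} sequences (need >= 10)"
        )
    if not bg:
        raise ValueError("no hit-free background windows available")
    table = motif_enrichment(fg, bg, candidate_pwms, score_threshold_fraction)
    table["self_match"] = table["pwm"] == primary_pwm.name
    return table


def _sharp_pwm(name: str, consensus: str, strength: float = 0.85) -> PWM:
    mat = np.full((len(consensus), 4), (1.0 - strength) / 3.0)
    for i, b in enumerate(consensus):
        mat[i, _CODE[b]] = strength
    return PWM(name, mat)


def example_pwms() -> list[PWM]:
    """Small built-in motif panel: an Ets-family GGAA-core matrix plus
    CCAAT-box and Sox-consensus matrices, built from their textbook
    consensus sequences (synthetic stand-ins for database matrices)."""
    return [
        _sharp_pwm("Ets_like", "ACAGGAAGTG"),
        _sharp_pwm("CCAAT_box", "AGCCAATCAG"),
        _sharp_pwm("Sox_like", "AACAATGGCA"),
    ]


def read_jaspar(path: str, pseudo: float = 0.25) -> list[PWM]:
    """Read JASPAR-format PFM text into probability PWMs.

    Counts are normalised per column with a +``pseudo`` weight per cell.
    """
    from Bio import motifs as bio_motifs

    with open(path) as fh:
        records = bio_motifs.parse(fh, "jaspar")
    out = []
    for m in records:
        counts = np.array(
            [[m.counts[b][i] for b in _ALPHABET] for i in range(m.length)]
        )
        name = m.matrix_id or m.name
        out.append(PWM.from_counts(str(name), counts, pseudo=pseudo))
    return out
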