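"""Synthetic data with known ground truth for every pipeline stage.

Each generator is a pure function of its arguments including the seed:
replaying a call reproduces its output bitwise. Generators emulate the
statistical structure the analyses assume — negative-binomial ChIP counts
with group fold changes and library-size offsets, FPKM matrices with group
structure, Poisson-binned coverage with planted copy-number segments, and
random DNA with planted motif occurrences — and return a
:class:`SimTruth` recording the planted labels and the exact request.
"""
from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .cnv import BinnedCoverage
from .diffbind import RegionCounts, SampleDesign
from .expression import ExpressionMatrix
from .intervals import GenomicInterval, RegionSet
from .motifs import PWM

__all__ = [
    "SimTruth",
    "DEFAULT_SEED",
    "simulate_chip_counts",
    "simulate_expression",
    "simulate_binned_coverage",
    "simulate_log2_ratio_profile",
    "simulate_sequences",
]

DEFAULT_SEED = 17


@dataclass
class SimTruth:
    """Ground truth of one simulation: per-unit labels plus the request.

    ``table`` carries one row per simulated unit (region, gene, bin or
    sequence); ``params`` echoes the generator's arguments, including the
    seed.
    """

    kind: str
    seed: int
    params: dict
    table: pd.DataFrame
    segments: pd.DataFrame | None = field(default=None)

    def to_tsv(self, path: str) -> None:
        """Write the truth table with the request as '#key=json' header
        lines."""
        with open(path, "w") as fh:
            fh.write(f"#kind={json.dumps(self.kind)}\n")
            fh.write(f"#seed={json.dumps(self.seed)}\n")
            fh.write(f"#params={json.dumps(self.params, sort_keys=True)}\n")
            self.table.to_csv(fh, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path: str) -> "SimTruth":
        meta: dict[str, object] = {}
        skip = 0
        with open(path) as fh:
            for line in fh:
                if not line.startswith("#"):
                    break
                skip += 1
                key, _, val = line[1:].rstrip("\n").partition("=")
                meta[key] = json.loads(val)
        table = pd.read_csv(path, sep="\t", skiprows=skip)
        return cls(
            kind=str(meta.get("kind", "")),
            seed=int(meta.get("seed", DEFAULT_SEED)),
            params=dict(meta.get("params", {})),
            table=table,
        )


def _nb_draw(rng: np.random.Generator, mu: np.ndarray, phi: float) -> np.ndarray:
    """NB(mean mu, variance mu + phi mu^2) draws; Poisson when phi == 0."""
    if phi == 0:
        return rng.poisson(mu)
    r = 1.0 / phi
    return rng.negative_binomial(r, r / (r + mu))


def _tiled_regions(n: int, width: int = 500, gap: int = 1500) -> RegionSet:
    step = width + gap
    return RegionSet(
        (GenomicInterval("chr1", i * step, i * step + width) for i in range(n)),
        name="simulated_regions",
    )


def simulate_chip_counts(
    n_regions: int,
    design: list[str],
    dbr_fraction: float,
    lfc: float,
    dispersion: float,
    lib_sizes: list[int],
    seed: int = DEFAULT_SEED,
    mean_log_mu: float = np.log(100.0),
    sd_log_mu: float = 1.0,
) -> tuple[RegionCounts, SimTruth]:
    """NB ChIP count matrix over candidate regions with planted DBRs.

    ``design`` lists one group label per sample. Exactly
    ``round(n_regions * dbr_fraction)`` regions carry a true
    ``|log2 fold change| = lfc`` between the first and second group level
    (sign randomised); baseline region means are log-normal. Library-size
    imbalance acts multiplicatively on the mean.
    """
    if not (0.0 <= dbr_fraction <= 1.0):
        raise ValueError("dbr_fraction must lie in [0, 1]")
    if dispersion < 0:
        raise ValueError("dispersion must be non-negative")
    if len(lib_sizes) != len(design):
        raise ValueError("lib_sizes and design lengths differ")
    if any(float(s) != int(s) for s in lib_sizes):
        raise ValueError("library sizes must be integers")
    levels = sorted(set(design))
    if len(levels) != 2:
        raise ValueError("design must contain exactly two group levels")
    counts_per_level = {lv: design.count(lv) for lv in levels}
    if min(counts_per_level.values()) < 2:
        raise ValueError("each group level needs at least two samples")

    rng = np.random.default_rng(seed)
    n_dbr = int(round(n_regions * dbr_fraction))
    is_dbr = np.zeros(n_regions, dtype=bool)
    is_dbr[rng.choice(n_regions, size=n_dbr, replace=False)] = True
    signs = np.where(rng.random(n_regions) < 0.5, -1.0, 1.0)
    true_lfc = np.where(is_dbr, signs * lfc, 0.0)

    base_mu = np.exp(rng.normal(mean_log_mu, sd_log_mu, size=n_regions))
    libs = np.asarray(lib_sizes, dtype=float)
    lib_factor = libs / libs.mean()
    in_group_b = np.array([g == levels[1] for g in design], dtype=float)
    mu = (
        base_mu[:, None]
        * np.power(2.0, true_lfc[:, None] * in_group_b[None, :])
        * lib_factor[None, :]
    )
    counts = _nb_draw(rng, mu, dispersion)

    samples = [f"{g}_{i}" for i, g in enumerate(design)]
    sd = SampleDesign(
        pd.DataFrame(
            {
                "sample": samples,
                "cell_type": design,
                "antibody": "Fli1",
                "replicate": list(range(len(design))),
                "lib_size": [int(s) for s in lib_sizes],
            }
        )
    )
    rc = RegionCounts(regions=_tiled_regions(n_regions), counts=counts, design=sd)
    truth = SimTruth(
        kind="chip_counts",
        seed=seed,
        params={
            "n_regions": n_regions,
            "design": design,
            "dbr_fraction": dbr_fraction,
            "lfc": lfc,
            "dispersion": dispersion,
            "lib_sizes": [int(s) for s in lib_sizes],
            "seed": seed,
        },
        table=pd.DataFrame(
            {
                "region": [f"{iv.chrom}:{iv.start}-{iv.end}" for iv in rc.regions],
                "is_dbr": is_dbr,
                "true_log2fc": true_lfc,
            }
        ),
    )
    return rc, truth


def simulate_expression(
    n_genes: int,
    groups: list[str],
    de_fraction: float,
    lfc: float,
    noise_sd: float,
    seed: int = DEFAULT_SEED,
    base_mean: float = 5.0,
    base_sd: float = 2.0,
) -> tuple[ExpressionMatrix, SimTruth]:
    """FPKM matrix with two sample groups and planted DE genes.

    Gene baselines are drawn on the log2 scale (``N(base_mean, base_sd)``),
    DE genes shift by ``+lfc`` in the second group, Gaussian noise of
    ``noise_sd`` is added per observation on the log2 scale, and
    ``FPKM = 2^value`` (hence non-negative).
    """
    if not (0.0 <= de_fraction <= 1.0):
        raise ValueError("de_fraction must lie in [0, 1]")
    levels = sorted(set(groups))
    if len(levels) != 2:
        raise ValueError("groups must contain exactly two levels")
    if min(groups.count(lv) for lv in levels) < 2:
        raise ValueError("each group needs at least two samples")
    rng = np.random.default_rng(seed)
    n_de = int(round(n_genes * de_fraction))
    is_de = np.zeros(n_genes, dtype=bool)
    is_de[rng.choice(n_genes, size=n_de, replace=False)] = True

    base = rng.normal(base_mean, base_sd, size=n_genes)
    in_b = np.array([g == levels[1] for g in groups], dtype=float)
    log2val = (
        base[:, None]
        + lfc * is_de[:, None] * in_b[None, :]
        + rng.normal(0.0, noise_sd, size=(n_genes, len(groups)))
    )
    fpkm = np.power(2.0, log2val)
    genes = [f"gene{i:05d}" for i in range(n_genes)]
    samples = [f"{g}_{i}" for i, g in enumerate(groups)]
    expr = ExpressionMatrix(
        values=pd.DataFrame(fpkm, index=genes, columns=samples),
        groups=pd.Series(groups, index=samples),
    )
    truth = SimTruth(
        kind="expression",
        seed=seed,
        params={
            "n_genes": n_genes,
            "groups": groups,
            "de_fraction": de_fraction,
            "lfc": lfc,
            "noise_sd": noise_sd,
            "seed": seed,
        },
        table=pd.DataFrame(
            {"gene": genes, "is_de": is_de, "true_log2fc": np.where(is_de, lfc, 0.0)}
        ),
    )
    return expr, truth


def _check_segments(segments: list[tuple[int, int, float]], n_bins: int) -> None:
    prev_end = -1
    for s, e, _ in sorted(segments):
        if not (0 <= s < e <= n_bins):
            raise ValueError(f"segment ({s}, {e}) outside [0, {n_bins})")
        if s < prev_end:
            raise ValueError("planted segments overlap")
        prev_end = e


def simulate_binned_coverage(
    n_bins: int,
    segments: list[tuple[int, int, float]],
    depth: float,
    noise_sd: float,
    seed: int = DEFAULT_SEED,
    chrom: str = "chr1",
    bin_width: int = 10_000,
) -> tuple[tuple[BinnedCoverage, BinnedCoverage], SimTruth]:
    """Sample/reference Poisson bin counts with planted copy-number shifts.

    Reference bins draw from ``Poisson(depth)``; sample bins from
    ``Poisson(depth * 2^(shift + eps))`` where ``shift`` is the planted
    log2 change inside each ``(start_bin, end_bin, shift)`` segment and
    ``eps ~ N(0, noise_sd)`` is per-bin log-scale noise.
    """
    _check_segments(segments, n_bins)
    rng = np.random.default_rng(seed)
    shift = np.zeros(n_bins)
    for s, e, d in segments:
        shift[s:e] = d
    eps = rng.normal(0.0, noise_sd, size=n_bins) if noise_sd > 0 else 0.0
    ref = rng.poisson(depth, size=n_bins)
    sam = rng.poisson(depth * np.power(2.0, shift + eps))
    sample = BinnedCoverage(bins={chrom: sam}, bin_width=bin_width)
    reference = BinnedCoverage(bins={chrom: ref}, bin_width=bin_width)
    truth = SimTruth(
        kind="binned_coverage",
        seed=seed,
        params={
            "n_bins": n_bins,
            "segments": [list(map(float, s)) for s in segments],
            "depth": depth,
            "noise_sd": noise_sd,
            "seed": seed,
        },
        table=pd.DataFrame({"bin": np.arange(n_bins), "true_log2_shift": shift}),
        segments=pd.DataFrame(
            segments, columns=["start_bin", "end_bin", "log2_shift"]
        ),
    )
    return (sample, reference), truth


def simulate_log2_ratio_profile(
    n_bins: int,
    segments: list[tuple[int, int, float]],
    noise_sd: float,
    seed: int = DEFAULT_SEED,
) -> tuple[np.ndarray, SimTruth]:
    """Gaussian log2-ratio profile with planted mean shifts.

    Directly emulates a normalised copy-number ratio track:
    ``ratio_b ~ N(shift_b, noise_sd)`` — the idealised input of the
    segmentation stage, bypassing count noise.
    """
    _check_segments(segments, n_bins)
    rng = np.random.default_rng(seed)
    shift = np.zeros(n_bins)
    for s, e, d in segments:
        shift[s:e] = d
    ratios = shift + rng.normal(0.0, noise_sd, size=n_bins)
    truth = SimTruth(
        kind="log2_ratio_profile",
        seed=seed,
        params={
            "n_bins": n_bins,
            "segments": [list(map(float, s)) for s in segments],
            "noise_sd": noise_sd,
            "seed": seed,
        },
        table=pd.DataFrame({"bin": np.arange(n_bins), "true_log2_shift": shift}),
        segments=pd.DataFrame(
            segments, columns=["start_bin", "end_bin", "log2_shift"]
        ),
    )
    return ratios, truth


def simulate_sequences(
    n_fg: int,
    n_bg: int,
    length: int,
    background_freqs: list[float],
    pwm: PWM,
    plant_rate_fg: float,
    plant_rate_bg: float,
    seed: int = DEFAULT_SEED,
) -> tuple[dict[str, list[str]], SimTruth]:
    """Foreground/background DNA with motif occurrences planted at known
    spots.

    Sequences draw i.i.d. bases from ``background_freqs`` (A, C, G, T). A
    sequence selected for planting (probability ``plant_rate_fg`` /
    ``plant_rate_bg``) receives one occurrence sampled column-wise from the
    PWM at a uniform random position and strand; the exact position, strand
    and planted string are recorded in the truth table.
    """
    freqs = np.asarray(background_freqs, dtype=float)
    if freqs.shape != (4,) or abs(freqs.sum() - 1.0) > 1e-9:
        raise ValueError("background_freqs must be 4 values summing to 1")
    for rate in (plant_rate_fg, plant_rate_bg):
        if not (0.0 <= rate <= 1.0):
            raise ValueError("plant rates must lie in [0, 1]")
    if len(pwm) > length:
        raise ValueError("PWM longer than the sequences")
    rng = np.random.default_rng(seed)
    alphabet = np.array(list("ACGT"))
    rows = []

    def make_set(n: int, rate: float, prefix: str) -> list[str]:
        seqs = []
        for i in range(n):
            sid = f"{prefix}{i:04d}"
            seq = rng.choice(4, size=length, p=freqs)
            if rng.random() < rate:
                pos = int(rng.integers(0, length - len(pwm) + 1))
                strand = "+" if rng.random() < 0.5 else "-"
                site = np.array(
                    [rng.choice(4, p=pwm.matrix[k]) for k in range(len(pwm))]
                )
                if strand == "-":
                    site = 3 - site[::-1]  # reverse complement in code space
                seq[pos : pos + len(pwm)] = site
                rows.append(
                    {
                        "seq_id": sid,
                        "set": prefix.rstrip("_"),
                        "position": pos,
                        "strand": strand,
                        "planted_seq": "".join(alphabet[site]),
                    }
                )
            seqs.append("".join(alphabet[seq]))
        return seqs

    fg = make_set(n_fg, plant_rate_fg, "fg_")
    bg = make_set(n_bg, plant_rate_bg, "bg_")
    truth = SimTruth(
        kind="sequences",
        seed=seed,
        params={
            "n_fg": n_fg,
            "n_bg": n_bg,
            "length": length,
            "background_freqs": [float(f) for f in freqs],
            "pwm": pwm.name,
            "plant_rate_fg": plant_rate_fg,
            "plant_rate_bg": plant_rate_bg,
            "seed": seed,
        },
        table=pd.DataFrame(
            rows, columns=["seq_id", "set", "position", "strand", "planted_seq"]
        ),
    )
    return {"fg": fg, "bg": bg}, truth
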