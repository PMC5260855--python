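import numpy as np
import pytest

from endosig.intervals import GenomicInterval, RegionSet

GENOME = {"chr1": 50_000, "chr2": 30_000, "chr3": 20_000}


def random_region_set(rng, n, genome=GENOME, max_len=400, name="rand"):
    ivs = []
    chroms = sorted(genome)
    for _ in range(n):
        chrom = chroms[rng.integers(len(chroms))]
        length = int(rng.integers(1, max_len))
        start = int(rng.integers(0, genome[chrom] - length))
        ivs.append(GenomicInterval(chrom, start, start + length))
    return RegionSet(ivs, name=name)


def bitmap(rs, genome=GENOME):
    """Per-bp boolean coverage masks — the brute-force oracle for set ops."""
    masks = {c: np.zeros(size, dtype=bool) for c, size in genome.items()}
    for iv in rs:
        masks[iv.chrom][iv.start : iv.end] = True
    return masks


def bitmap_overlaps(iv, masks):
    return bool(masks[iv.chrom][iv.start : iv.end].any())


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
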