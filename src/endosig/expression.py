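"""Transcriptome procedures on FPKM matrices.

Differential-expression calling on averaged FPKMs with a Welch two-sided
t-test, 1-Pearson correlation distances on log2-transformed values,
deterministic agglomerative clustering, distance to an average reference
sample, and per-transcript max-normalisation for heatmaps.

A pseudocount of 1 is added before every log2 transform so zero FPKMs are
well-defined.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "ExpressionMatrix",
    "Dendrogram",
    "de_genes",
    "correlation_distance_matrix",
    "hierarchical_cluster",
    "distance_to_reference_average",
    "heatmap_normalize",
]


@dataclass
class ExpressionMatrix:
    """Gene-by-sample FPKM values with per-sample group labels."""

    values: pd.DataFrame  # genes (rows) x samples (columns), FPKM
    groups: pd.Series  # sample id -> group label

    def __post_init__(self) -> None:
        if (self.values.to_numpy() < 0).any():
            raise ValueError("FPKM values must be non-negative")
        if self.values.index.duplicated().any():
            raise ValueError("duplicate gene identifiers")
        if self.values.columns.duplicated().any():
            raise ValueError("duplicate sample identifiers")
        missing = set(self.values.columns) - set(self.groups.index)
        if missing:
            raise ValueError(f"samples without group labels: {sorted(missing)}")
        self.groups = self.groups.loc[self.values.columns]

    @property
    def genes(self) -> pd.Index:
        return self.values.index

    @property
    def samples(self) -> pd.Index:
        return self.values.columns

    def group_samples(self, group: str) -> list[str]:
        hits = [s for s in self.samples if self.groups[s] == group]
        if not hits:
            raise ValueError(f"unknown group label {group!r}")
        return hits

    def log2(self, pseudocount: float = 1.0) -> pd.DataFrame:
        return np.log2(self.values + pseudocount)


def de_genes(
    expr: ExpressionMatrix,
    group_a: str,
    group_b: str,
    lfc_threshold: float = 1.0,
    p_threshold: float = 0.05,
    pseudocount: float = 1.0,
    test_scale: str = "log",
) -> pd.DataFrame:
    """Differential expression between two groups of samples.

    ``log2FC = log2((mean_B + pc) / (mean_A + pc))`` on averaged FPKMs;
    p from a two-sided Welch (unequal-variance) t-test, by default on
    ``log2(FPKM + pc)`` (``test_scale='raw'`` tests raw FPKMs). A gene is
    flagged DE iff ``|log2FC| > lfc_threshold`` and ``p < p_threshold``.
    """
    if test_scale not in ("log", "raw"):
        raise ValueError("test_scale must be 'log' or 'raw'")
    sa = expr.group_samples(group_a)
    sb = expr.group_samples(group_b)
    if len(sa) < 2 or len(sb) < 2:
        raise ValueError("each group needs at least two samples for Welch's test")
    va = expr.values[sa].to_numpy(dtype=float)
    vb = expr.values[sb].to_numpy(dtype=float)
    log2fc = np.log2((vb.mean(axis=1) + pseudocount) / (va.mean(axis=1) + pseudocount))
    if test_scale == "log":
        ta, tb = np.log2(va + pseudocount), np.log2(vb + pseudocount)
    else:
        ta, tb = va, vb
    with np.errstate(divide="ignore", invalid="ignore"):
        _, p = stats.ttest_ind(tb, ta, axis=1, equal_var=False)
    p = np.where(np.isnan(p), 1.0, p)  # zero variance in both groups
    de = (np.abs(log2fc) > lfc_threshold) & (p < p_threshold)
    return pd.DataFrame(
        {"log2FC": log2fc, "p": p, "de_flag": de}, index=expr.genes
    ).rename_axis("gene")


def correlation_distance_matrix(
    expr: ExpressionMatrix, log_transform: bool = True, pseudocount: float = 1.0
) -> pd.DataFrame:
    """Pairwise ``1 - Pearson r`` sample distances.

    Computed on ``log2(FPKM + pc)`` unless ``log_transform`` is off. A
    zero-variance sample has no defined correlation: its pairs are NaN with
    a warning. Diagonal is 0, values lie in [0, 2].
    """
    mat = expr.log2(pseudocount) if log_transform else expr.values.astype(float)
    arr = mat.to_numpy()
    sd = arr.std(axis=0)
    bad = sd == 0
    if bad.any():
        warnings.warn(
            f"zero-variance sample(s) {list(expr.samples[bad])}: distances undefined"
        )
    with np.errstate(invalid="ignore"):
        r = np.corrcoef(arr, rowvar=False)
    d = 1.0 - r
    np.fill_diagonal(d, 0.0)
    d[bad, :] = np.nan
    d[:, bad] = np.nan
    d[np.ix_(bad, bad)] = np.nan
    return pd.DataFrame(d, index=expr.samples, columns=expr.samples)


@dataclass
class Dendrogram:
    """Agglomeration history over ``n`` leaves.

    ``merges`` lists ``(left_id, right_id, height, size)`` rows in merge
    order; leaf ids are 0..n-1 and each merge creates id ``n + k`` (the
    linkage-matrix convention).
    """

    n_leaves: int
    merges: list[tuple[int, int, float, int]]
    labels: list[str]
    _members: dict[int, list[int]] = field(default_factory=dict, repr=False)

    def cophenetic_matrix(self) -> np.ndarray:
        coph = np.zeros((self.n_leaves, self.n_leaves))
        for k, (a, b, h, _) in enumerate(self.merges):
            for i in self._members[a]:
                for j in self._members[b]:
                    coph[i, j] = coph[j, i] = h
        return coph

    def cut(self, k: int) -> np.ndarray:
        """Leaf labels for the partition into ``k`` clusters (0-based)."""
        if not (1 <= k <= self.n_leaves):
            raise ValueError("k out of range")
        parents = list(range(self.n_leaves))
        clusters = {i: [i] for i in range(self.n_leaves)}
        for step, (a, b, _, _) in enumerate(self.merges[: self.n_leaves - k]):
            new = self.n_leaves + step
            clusters[new] = clusters.pop(a) + clusters.pop(b)
        out = np.empty(self.n_leaves, dtype=int)
        for lab, (_cid, members) in enumerate(sorted(clusters.items())):
            out[members] = lab
        return out

    def to_newick(self) -> str:
        def render(node: int) -> str:
            if node < self.n_leaves:
                return self.labels[node]
            a, b, h, _ = self.merges[node - self.n_leaves]
            ha = 0.0 if a < self.n_leaves else self.merges[a - self.n_leaves][2]
            hb = 0.0 if b < self.n_leaves else self.merges[b - self.n_leaves][2]
            return (
                f"({render(a)}:{(h - ha) / 2:.6g},{render(b)}:{(h - hb) / 2:.6g})"
            )

        return render(self.n_leaves + len(self.merges) - 1) + ";"


def hierarchical_cluster(dist: pd.DataFrame, linkage: str = "complete") -> Dendrogram:
    """Agglomerative clustering of a precomputed distance matrix.

    Supports complete, single and average linkage. The merge order is
    deterministic: among equally close pairs the one with the lowest
    (sorted) cluster ids merges first.
    """
    if linkage not in ("complete", "single", "average"):
        raise ValueError(f"unsupported linkage {linkage!r}")
    d = dist.to_numpy(dtype=float)
    if np.isnan(d).any():
        raise ValueError("distance matrix contains missing values")
    if d.shape[0] != d.shape[1] or not np.allclose(d, d.T, atol=1e-12):
        raise ValueError("distance matrix must be square and symmetric")
    n = d.shape[0]
    labels = [str(s) for s in dist.index]
    active: dict[int, list[int]] = {i: [i] for i in range(n)}
    merges: list[tuple[int, int, float, int]] = []
    members: dict[int, list[int]] = {i: [i] for i in range(n)}

    def cluster_dist(a: int, b: int) -> float:
        block = d[np.ix_(active[a], active[b])]
        if linkage == "complete":
            return float(block.max())
        if linkage == "single":
            return float(block.min())
        return float(block.mean())

    next_id = n
    for _ in range(n - 1):
        ids = sorted(active)
        best: tuple[float, int, int] | None = None
        for i_pos, a in enumerate(ids):
            for b in ids[i_pos + 1 :]:
                dd = cluster_dist(a, b)
                if best is None or dd < best[0] - 1e-15:
                    best = (dd, a, b)
        assert best is not None
        h, a, b = best
        active[next_id] = active.pop(a) + active.pop(b)
        members[next_id] = members[a] + members[b]
        merges.append((a, b, h, len(active[next_id])))
        next_id += 1
    return Dendrogram(n_leaves=n, merges=merges, labels=labels, _members=members)


def distance_to_reference_average(
    expr: ExpressionMatrix,
    reference_sample_ids: list[str],
    pseudocount: float = 1.0,
) -> pd.Series:
    """1-Pearson distance of every sample to the mean reference profile.

    The average profile is the per-gene mean of the reference samples on
    the ``log2(FPKM + pc)`` scale; each sample's distance is
    ``1 - r(sample, average)``.
    """
    if not reference_sample_ids:
        raise ValueError("reference sample list is empty")
    missing = set(reference_sample_ids) - set(expr.samples)
    if missing:
        raise ValueError(f"unknown reference samples: {sorted(missing)}")
    logv = expr.log2(pseudocount)
    ref = logv[reference_sample_ids].mean(axis=1).to_numpy()
    out = {}
    for s in expr.samples:
        r = np.corrcoef(logv[s].to_numpy(), ref)[0, 1]
        out[s] = 1.0 - r
    return pd.Series(out, name="distance_to_reference")


def heatmap_normalize(
    expr: ExpressionMatrix, gene_subset: list[str] | None = None
) -> pd.DataFrame:
    """Divide each gene row by its maximum FPKM; all-zero rows stay zero.

    The result lies in [0, 1] with the row maximum mapped to exactly 1 —
    the scaling used for 0-to-max heatmap colouring.
    """
    if gene_subset is None:
        sub = expr.values
    else:
        missing = set(gene_subset) - set(expr.genes)
        if missing:
            raise ValueError(f"genes not in matrix: {sorted(missing)}")
        sub = expr.values.loc[gene_subset]
    arr = sub.to_numpy(dtype=float)
    rowmax = arr.max(axis=1)
    safe = np.where(rowmax > 0, rowmax, 1.0)
    return pd.DataFrame(
        arr / safe[:, None], index=sub.index, columns=sub.columns
    )
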