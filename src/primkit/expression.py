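"""Differential-expression selection and the two-class gene clustering.

Genes differentially expressed among SSC, MASC and ESC are selected by the
joint rule |log2FC| >= 1 (two-fold) and P < 0.05 in at least one pairwise
comparison, with log2 fold change the difference of cell-type means of
log2-transformed expression and P from Welch's two-sample t-test on the
replicate values (a substitute for a moderated-statistics fit; the selection
rule is unchanged). No multiplicity adjustment is applied.

Selected genes are clustered hierarchically: rows mean-centered, gene-gene
distance 1 - uncentered correlation, centroid linkage, equal-distance merges
broken toward the lowest cluster-index pair. Cutting the tree at the root
yields the two expression classes; the branch with the higher MASC/ESC vs
SSC mean is class I (activated after reprogramming), the other class II.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import stats

PAIR_SEP = "_vs_"


@dataclass
class ExpressionTable:
    """Genes x samples matrix of log2 expression plus sample -> cell type."""

    values: pd.DataFrame
    sample_groups: dict[str, str]

    def __post_init__(self) -> None:
        missing = set(self.values.columns) - set(self.sample_groups)
        if missing:
            raise ValueError(f"samples missing from group map: {sorted(missing)}")
        if self.values.isna().any().any():
            raise ValueError("expression table contains missing entries")

    @property
    def cell_types(self) -> list[str]:
        return list(dict.fromkeys(self.sample_groups[s] for s in self.values.columns))

    def columns_of(self, cell_type: str) -> list[str]:
        return [s for s in self.values.columns if self.sample_groups[s] == cell_type]


@dataclass
class DEGeneSet:
    """Selected genes with per-pair statistics and (optionally) classes."""

    table: pd.DataFrame  # index: selected genes; log2fc_/p_ columns per pair
    classes: pd.Series | None = None  # gene -> "I" / "II"

    @property
    def genes(self) -> list[str]:
        return list(self.table.index)


def _welch_t(
    a: np.ndarray, b: np.ndarray
) -> np.ndarray:
    res = stats.ttest_ind(a, b, axis=1, equal_var=False)
    return np.asarray(res.pvalue)


def select_differential_genes(
    expr: ExpressionTable,
    fc_threshold: float = 1.0,
    alpha: float = 0.05,
) -> DEGeneSet:
    """Genes with |log2FC| >= fc_threshold and p < alpha in >= 1 pair."""
    cts = expr.cell_types
    if len(cts) < 2:
        raise ValueError("need at least two cell types")
    for ct in cts:
        if len(expr.columns_of(ct)) < 2:
            raise ValueError(f"cell type {ct} has < 2 replicates; test undefined")
    stats_cols: dict[str, pd.Series] = {}
    selected = np.zeros(len(expr.values), dtype=bool)
    for ct_a, ct_b in itertools.combinations(cts, 2):
        a = expr.values[expr.columns_of(ct_a)].to_numpy(float)
        b = expr.values[expr.columns_of(ct_b)].to_numpy(float)
        log2fc = a.mean(axis=1) - b.mean(axis=1)
        pvals = _welch_t(a, b)
        pair = f"{ct_a}{PAIR_SEP}{ct_b}"
        stats_cols[f"log2fc_{pair}"] = pd.Series(log2fc, index=expr.values.index)
        stats_cols[f"p_{pair}"] = pd.Series(pvals, index=expr.values.index)
        selected |= (np.abs(log2fc) >= fc_threshold) & (pvals < alpha)
    table = pd.DataFrame(stats_cols)
    return DEGeneSet(table=table.loc[selected])


def _uncentered_distance_to(
    centroid: np.ndarray, rows: np.ndarray
) -> np.ndarray:
    """1 - uncentered correlation between a centroid and each row."""
    num = rows @ centroid
    denom = np.linalg.norm(rows, axis=1) * np.linalg.norm(centroid)
    denom = np.where(denom == 0, 1.0, denom)
    return 1.0 - num / denom


@dataclass
class GeneClustering:
    """Agglomeration history plus the 2-way root partition."""

    genes: list[str]
    merges: list[tuple[int, int, float]]  # (cluster_i, cluster_j, distance)
    partition: pd.Series = field(default=None)  # gene -> 0 / 1 (root branches)


def hierarchical_cluster_genes(expr_values: pd.DataFrame) -> GeneClustering:
    """Centroid-linkage clustering on 1 - uncentered correlation.

    Rows are mean-centered first; cluster centroids are means of member
    rows of the centered matrix. Deterministic: equal minimum distances
    merge the lexicographically smallest active (i, j) pair.
    """
    n = len(expr_values)
    if n < 2:
        raise ValueError("need >= 2 genes to cluster")
    genes = list(expr_values.index)
    x = expr_values.to_numpy(float)
    x = x - x.mean(axis=1, keepdims=True)
    centroids = list(x)
    members: dict[int, list[int]] = {i: [i] for i in range(n)}
    dist = np.full((n, n), np.inf)
    for i in range(n):
        dist[i, i + 1:] = _uncentered_distance_to(x[i], x[i + 1:])
    merges: list[tuple[int, int, float]] = []
    active = set(range(n))
    last_pair = (0, 0)
    for _ in range(n - 1):
        flat = int(np.argmin(dist))  # row-major: first hit is smallest (i, j)
        i, j = divmod(flat, dist.shape[1])
        d = float(dist[i, j])
        merges.append((i, j, d))
        # merged cluster replaces slot i; slot j retires
        members[i] = members[i] + members[j]
        centroids[i] = x[members[i]].mean(axis=0)
        active.discard(j)
        dist[j, :] = np.inf
        dist[:, j] = np.inf
        others = np.array(sorted(active - {i}), dtype=int)
        if len(others):
            rows = np.stack([centroids[k] for k in others])
            new_d = _uncentered_distance_to(centroids[i], rows)
            lo = others < i
            dist[others[lo], i] = new_d[lo]
            dist[i, others[~lo]] = new_d[~lo]
        last_pair = (i, j)
    left, right = last_pair
    labels = pd.Series(0, index=pd.Index(genes, name="gene"), dtype=int)
    labels.iloc[members[right]] = 1
    return GeneClustering(genes=genes, merges=merges, partition=labels)


def assign_expression_classes(
    clustering: GeneClustering,
    expr: ExpressionTable,
) -> pd.Series:
    """Label the two root branches as class I (up in MASC+ESC) and II.

    The branch whose genes average higher in MASC and ESC than in SSC is
    class I. Errors if both branches point the same way.
    """
    vals = expr.values.loc[clustering.partition.index]
    ssc = vals[expr.columns_of("SSC")].to_numpy(float).mean(axis=1)
    other_cols = expr.columns_of("MASC") + expr.columns_of("ESC")
    other = vals[other_cols].to_numpy(float).mean(axis=1)
    contrast = other - ssc
    scores = {
        branch: contrast[(clustering.partition == branch).to_numpy()].mean()
        for branch in (0, 1)
    }
    if not (max(scores.values()) > 0 > min(scores.values())):
        raise ValueError(
            "both branches shift the same way between SSC and MASC/ESC; "
            "classes are undefined"
        )
    class_i_branch = max(scores, key=scores.get)
    return clustering.partition.map(
        lambda b: "I" if b == class_i_branch else "II"
    ).rename("class")


def read_expression_tsv(
    path, groups_path=None, sample_groups: Mapping[str, str] | None = None
) -> ExpressionTable:
    """Load a gene x sample TSV (header = sample ids, first column = gene).

    The sample -> cell type map comes either from a two-column sidecar TSV
    (sample, cell_type) or an explicit mapping.
    """
    values = pd.read_csv(path, sep="\t", index_col=0)
    if sample_groups is None:
        if groups_path is None:
            raise ValueError("need groups_path or sample_groups")
        gdf = pd.read_csv(groups_path, sep="\t")
        sample_groups = dict(zip(gdf.iloc[:, 0].astype(str), gdf.iloc[:, 1].astype(str)))
    return ExpressionTable(values=values, sample_groups=dict(sample_groups))
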