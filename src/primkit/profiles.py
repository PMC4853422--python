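"""TSS-centered read-density matrices, profile k-means, and group statistics.

Profiles are binned reads-per-million mean depths in a window around each
gene's TSS (default +/- 2 kb in 100-bp bins). Minus-strand genes have their
bins reversed so bin 0 is always the most upstream position. Profile
clustering concatenates all (sample, mark) blocks, scales each block by its
global mean, and runs seeded k-means with restarts. Group comparisons use
the two-sided Wilcoxon rank-sum test on per-gene promoter-mean signal.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.cluster import KMeans

from .intervals import CoverageTrack
from .promoters import PromoterSet


@dataclass
class ProfileMatrix:
    """Per (sample, mark): genes x bins matrix of normalized mean depth."""

    blocks: dict[tuple[str, str], pd.DataFrame]
    half_width: int
    bin_width: int

    @property
    def genes(self) -> pd.Index:
        return next(iter(self.blocks.values())).index

    @property
    def n_bins(self) -> int:
        return 2 * self.half_width // self.bin_width


@dataclass
class ProfileClusters:
    labels: pd.Series  # gene -> cluster index
    k: int
    sizes: dict[int, int]
    seed: int
    degenerate: bool  # fewer distinct clusters than k, or duplicate centroids


def tss_profile_matrix(
    tracks: Mapping[tuple[str, str], CoverageTrack],
    promoters: PromoterSet,
    half_width: int = 2000,
    bin_width: int = 100,
) -> ProfileMatrix:
    """Binned RPM depth in [TSS - half_width, TSS + half_width) per gene.

    `tracks` maps (sample_id, mark) -> CoverageTrack. Bins are oriented
    5' -> 3': minus-strand rows are reversed.
    """
    if (2 * half_width) % bin_width:
        raise ValueError("bin_width must divide 2 * half_width")
    n_bins = 2 * half_width // bin_width
    genes = promoters.genes
    bin_labels = [(-half_width + i * bin_width) for i in range(n_bins)]
    blocks: dict[tuple[str, str], pd.DataFrame] = {}
    for key, track in tracks.items():
        mat = np.zeros((len(genes), n_bins))
        scale = 1e6 / track.library_size
        for gi, gene in enumerate(genes):
            p = promoters[gene]
            row = track.binned_means(
                p.interval.chrom, p.tss - half_width, p.tss + half_width, bin_width
            )
            if p.strand == "-":
                row = row[::-1]
            mat[gi] = row * scale
        blocks[key] = pd.DataFrame(
            mat, index=pd.Index(genes, name="gene"), columns=bin_labels
        )
    return ProfileMatrix(blocks=blocks, half_width=half_width, bin_width=bin_width)


def kmeans_profile_clusters(
    profiles: ProfileMatrix,
    k: int,
    seed: int,
    restarts: int = 100,
) -> ProfileClusters:
    """Best-inertia k-means over `restarts` seeded initializations.

    Feature vector per gene = concatenation of all (sample, mark) blocks,
    each scaled by its global mean (left unscaled when the mean is 0).
    """
    genes = profiles.genes
    if k > len(genes):
        raise ValueError(f"k={k} exceeds gene count {len(genes)}")
    parts = []
    for key in sorted(profiles.blocks):
        block = profiles.blocks[key].loc[genes].to_numpy(float)
        mean = block.mean()
        parts.append(block / mean if mean > 0 else block)
    x = np.hstack(parts)
    km = KMeans(n_clusters=k, n_init=restarts, random_state=seed)
    labels = km.fit_predict(x)
    sizes = {int(c): int((labels == c).sum()) for c in range(k)}
    distinct_centroids = len(np.unique(np.round(km.cluster_centers_, 12), axis=0))
    degenerate = (min(sizes.values()) == 0) or (distinct_centroids < k)
    return ProfileClusters(
        labels=pd.Series(labels, index=genes, name="cluster"),
        k=k,
        sizes=sizes,
        seed=seed,
        degenerate=degenerate,
    )


def profile_group_stats(
    profile: pd.DataFrame,
    groups: Mapping[str, Sequence[str]],
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Box statistics per gene group and pairwise rank-sum p-values.

    The per-gene statistic is the mean over bins (promoter-mean signal).
    Groups must be disjoint. Pairs where either group has < 3 genes get a
    NaN p-value (test skipped) with a notice in the stats frame.
    """
    names = list(groups)
    seen: set[str] = set()
    for name in names:
        dup = seen & set(groups[name])
        if dup:
            raise ValueError(f"groups are not disjoint: {sorted(dup)[:3]}...")
        seen |= set(groups[name])
    per_gene = profile.mean(axis=1)
    values = {name: per_gene.loc[list(groups[name])].to_numpy(float) for name in names}
    rows = []
    for name in names:
        v = values[name]
        if len(v) == 0:
            rows.append({"group": name, "n": 0})
            continue
        q1, med, q3 = np.percentile(v, [25, 50, 75])
        iqr = q3 - q1
        inliers = v[(v >= q1 - 1.5 * iqr) & (v <= q3 + 1.5 * iqr)]
        rows.append(
            {
                "group": name,
                "n": len(v),
                "median": med,
                "q1": q1,
                "q3": q3,
                "whisker_lo": inliers.min(),
                "whisker_hi": inliers.max(),
                "test_skipped": len(v) < 3,
            }
        )
    stats_df = pd.DataFrame(rows).set_index("group")
    pvals = pd.DataFrame(np.nan, index=names, columns=names)
    for i, a in enumerate(names):
        for b in names[i + 1:]:
            if len(values[a]) < 3 or len(values[b]) < 3:
                continue
            res = stats.mannwhitneyu(
                values[a], values[b], alternative="two-sided", method="auto"
            )
            pvals.loc[a, b] = pvals.loc[b, a] = float(res.pvalue)
    return stats_df, pvals
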