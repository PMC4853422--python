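"""PRIM-space comparisons across cell types.

Covers sample-level PCA on PRIM matrices, pairwise PRIM correlation, the
bivalent fraction of K27me3-marked promoters, per-cell-type active/repressive
PRIM cutoffs, the six-category promoter transition taxonomy between SSC and
MASC, and the one-sided Fisher test for direction bias.

Promoter status in a cell type is derived from (state, PRIM, cutoff):

    active      state != NA and PRIM >  cutoff
    repressive  state != NA and PRIM <= cutoff
    unmodified  state == NA

The transition decision table, per expression class:

    class I  (up in MASC/ESC):
        Stable_I    repressive(SSC) and repressive(MASC)
        Active      repressive(SSC) and active(MASC) and MASC state K4-only
        Modified    unmodified(SSC) and MASC state != NA
        Other       anything else
    class II (down in MASC/ESC):
        Repressive  active(SSC) and repressive(MASC) and MASC state carries K27me3
        Stable_II   repressive(SSC) and repressive(MASC)
        Unmodified  SSC state != NA and MASC state == NA
        Other       anything else
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.decomposition import PCA

from .promoters import STATE_BIVALENT, STATE_K27_ONLY, STATE_K4_ONLY

CLASS_I_CATEGORIES = ("Stable_I", "Active", "Modified", "Other")
CLASS_II_CATEGORIES = ("Repressive", "Stable_II", "Unmodified", "Other")


class UndefinedStatistic(ValueError):
    """Raised when a ratio statistic has an empty denominator."""


@dataclass(frozen=True)
class PrimCutoff:
    """Per-cell-type threshold separating active from repressive promoters."""

    threshold: float
    quality: float  # max Youden's J, in [0, 1]


@dataclass(frozen=True)
class TransitionCall:
    gene_id: str
    expr_class: str  # "I" or "II"
    category: str


@dataclass(frozen=True)
class PcaResult:
    coordinates: pd.DataFrame  # samples x 3
    variance_fractions: np.ndarray  # length 3, non-increasing


def pca_on_prim(prim_matrix: pd.DataFrame) -> PcaResult:
    """Project samples onto the top 3 components of the PRIM matrix.

    `prim_matrix` is promoters x samples; rows with any undefined PRIM are
    dropped (intersection of modified promoters), rows are mean-centered,
    and samples are the observations. Deterministic up to component sign.
    """
    if prim_matrix.shape[1] < 3:
        raise ValueError("PCA requires >= 3 samples")
    common = prim_matrix.dropna(axis=0, how="any")
    if common.empty:
        raise ValueError("no promoter has defined PRIM in every sample")
    x = common.to_numpy().T  # samples x promoters
    n_comp = min(3, x.shape[0], x.shape[1])
    pca = PCA(n_components=n_comp, svd_solver="full")
    coords = pca.fit_transform(x)
    coords3 = np.zeros((x.shape[0], 3))
    coords3[:, :n_comp] = coords
    frac3 = np.zeros(3)
    frac3[:n_comp] = pca.explained_variance_ratio_
    return PcaResult(
        coordinates=pd.DataFrame(
            coords3, index=prim_matrix.columns, columns=["PC1", "PC2", "PC3"]
        ),
        variance_fractions=frac3,
    )


def correlate_prim(sample_a: pd.Series, sample_b: pd.Series) -> float:
    """Pearson r over genes with defined PRIM in both samples."""
    joined = pd.concat([sample_a, sample_b], axis=1, join="inner").dropna()
    if len(joined) < 3:
        raise ValueError("need >= 3 genes with defined PRIM in both samples")
    r, _ = stats.pearsonr(joined.iloc[:, 0], joined.iloc[:, 1])
    return float(r)


def bivalent_fraction_of_k27(state_column: pd.Series) -> float:
    """count(state=0) / count(state in {0, -1})."""
    bivalent = int((state_column == STATE_BIVALENT).sum())
    k27_marked = bivalent + int((state_column == STATE_K27_ONLY).sum())
    if k27_marked == 0:
        raise UndefinedStatistic("no K27me3-marked promoters")
    return bivalent / k27_marked


def derive_prim_cutoff(
    prim_column: pd.Series, state_column: pd.Series
) -> PrimCutoff:
    """Youden-optimal threshold for "active iff PRIM > c".

    Labels: active = univalent K4me3 (state 1); repressive = any
    K27me3-containing state (0 or -1). Candidate thresholds are midpoints
    of adjacent sorted unique PRIM values; ties take the smallest c.
    """
    df = pd.DataFrame({"prim": prim_column, "state": state_column}).dropna()
    active = df.loc[df["state"] == STATE_K4_ONLY, "prim"].to_numpy(float)
    repressive = df.loc[
        df["state"].isin([STATE_BIVALENT, STATE_K27_ONLY]), "prim"
    ].to_numpy(float)
    if len(active) == 0 or len(repressive) == 0:
        raise ValueError("need both active- and repressive-labeled promoters")
    uniq = np.unique(np.concatenate([active, repressive]))
    if len(uniq) < 2:
        raise ValueError("all PRIM values identical; no threshold lies between")
    candidates = (uniq[:-1] + uniq[1:]) / 2.0
    tpr = (active[None, :] > candidates[:, None]).mean(axis=1)
    fpr = (repressive[None, :] > candidates[:, None]).mean(axis=1)
    j = tpr - fpr
    best = int(np.argmax(j))  # argmax takes the first, i.e. smallest c
    return PrimCutoff(threshold=float(candidates[best]), quality=float(j[best]))


def _status(state, prim: float, cutoff: float) -> str:
    if pd.isna(state):
        if not pd.isna(prim):
            raise ValueError("PRIM defined where state is NA: inconsistent tables")
        return "unmodified"
    if pd.isna(prim):
        raise ValueError("state defined where PRIM is NA: inconsistent tables")
    return "active" if prim > cutoff else "repressive"


def classify_transition(
    gene: str,
    expr_class: str,
    state_ssc,
    prim_ssc: float,
    state_masc,
    prim_masc: float,
    cutoffs: dict[str, PrimCutoff],
) -> TransitionCall:
    """Assign a gene to the SSC->MASC promoter chromatin transition taxonomy."""
    if expr_class not in ("I", "II"):
        raise ValueError(f"expression class must be 'I' or 'II', got {expr_class!r}")
    s_ssc = _status(state_ssc, prim_ssc, cutoffs["SSC"].threshold)
    s_masc = _status(state_masc, prim_masc, cutoffs["MASC"].threshold)
    if expr_class == "I":
        if s_ssc == "repressive" and s_masc == "repressive":
            cat = "Stable_I"
        elif s_ssc == "repressive" and s_masc == "active" and state_masc == STATE_K4_ONLY:
            cat = "Active"
        elif s_ssc == "unmodified" and not pd.isna(state_masc):
            cat = "Modified"
        else:
            cat = "Other"
    else:
        if (
            s_ssc == "active"
            and s_masc == "repressive"
            and state_masc in (STATE_BIVALENT, STATE_K27_ONLY)
        ):
            cat = "Repressive"
        elif s_ssc == "repressive" and s_masc == "repressive":
            cat = "Stable_II"
        elif not pd.isna(state_ssc) and pd.isna(state_masc):
            cat = "Unmodified"
        else:
            cat = "Other"
    return TransitionCall(gene_id=gene, expr_class=expr_class, category=cat)


def classify_transitions(
    expr_classes: pd.Series,
    states: pd.DataFrame,
    prim: pd.DataFrame,
    cutoffs: dict[str, PrimCutoff],
) -> pd.Series:
    """Vector form of classify_transition over a gene table.

    `states` and `prim` are gene x cell-type frames containing at least the
    SSC and MASC columns; `expr_classes` maps gene -> "I"/"II".
    """
    out = {}
    for gene, cls in expr_classes.items():
        call = classify_transition(
            gene,
            cls,
            states.at[gene, "SSC"],
            prim.at[gene, "SSC"],
            states.at[gene, "MASC"],
            prim.at[gene, "MASC"],
            cutoffs,
        )
        out[gene] = call.category
    return pd.Series(out, name="category")


def direction_bias_test(
    group_a_updown: tuple[int, int], group_b_updown: tuple[int, int]
) -> float:
    """One-sided Fisher's exact test for enrichment of "increase" in group a.

    Each argument is (n_increase, n_decrease) for one gene group; the
    p-value is the exact hypergeometric tail probability.
    """
    table = np.array([group_a_updown, group_b_updown])
    if (table < 0).any():
        raise ValueError("counts must be non-negative")
    _, p = stats.fisher_exact(table, alternative="greater")
    return float(p)
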