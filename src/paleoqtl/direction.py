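"""Regulatory directionality of derived eQTLs and tissue clustering.

Slopes are re-oriented so they always describe the dosage effect of the
focal allele (the derived allele, or the ancestral allele in the
frequency-matched control set); eQTL tables report the effect of the ALT
allele, so rows where the focal allele is REF have their slope negated.
The pooled up/down count is tested against the 50/50 null with a one-degree
chi-square goodness-of-fit, and per-tissue binomial z residuals identify
which tissues drive any skew.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

logger = logging.getLogger(__name__)

__all__ = [
    "DirectionTable", "build_direction_table", "direction_test",
    "build_control_set", "orient_slopes", "tissue_clustering",
]


@dataclass
class DirectionTable:
    """Per-tissue counts of up- and down-regulating eQTLs for one subset."""

    counts: pd.DataFrame  # index: tissue; columns: up, down
    subset: str
    n_zero_slopes: int = 0

    @property
    def total_up(self) -> int:
        return int(self.counts["up"].sum())

    @property
    def total_down(self) -> int:
        return int(self.counts["down"].sum())


def orient_slopes(eqtls: pd.DataFrame, classified: pd.DataFrame,
                  focal: str = "derived") -> pd.Series:
    """Slope of each eQTL row re-signed to the focal allele's dosage effect.

    ``classified`` supplies ``rsid``, ``ref``, ``alt`` and
    ``ancestral_allele``; rows whose focal allele is REF get their
    ALT-dosage slope negated. Rows with unresolved ancestral state are NaN.
    """
    if focal not in {"derived", "ancestral"}:
        raise ValueError(f"focal must be 'derived' or 'ancestral', got {focal!r}")
    anc = classified.set_index("rsid")[["ref", "alt", "ancestral_allele"]]
    anc = anc[~anc.index.duplicated()]
    merged = eqtls.join(anc, on="rsid", rsuffix="_cat")
    anc_allele = merged["ancestral_allele"]
    resolved = (anc_allele == merged["ref"]) | (anc_allele == merged["alt"])
    # focal allele is ALT iff (derived and ancestral==ref) or (ancestral and ancestral==alt)
    if focal == "derived":
        focal_is_alt = anc_allele == merged["ref"]
    else:
        focal_is_alt = anc_allele == merged["alt"]
    sign = np.where(focal_is_alt, 1.0, -1.0)
    out = pd.Series(np.where(resolved, merged["slope"] * sign, np.nan),
                    index=eqtls.index, name="oriented_slope")
    return out


def build_direction_table(eqtls: pd.DataFrame, oriented: pd.Series,
                          subset: str) -> DirectionTable:
    """Tabulate up/down counts per tissue from oriented slopes.

    Exactly-zero slopes are counted separately and excluded from the
    binary test.
    """
    ok = oriented.notna()
    nonzero = ok & (oriented != 0)
    n_zero = int((ok & (oriented == 0)).sum())
    if n_zero:
        logger.info("%d zero-slope eQTL(s) excluded from the direction test", n_zero)
    df = pd.DataFrame({"tissue": eqtls.loc[nonzero, "tissue"],
                       "up": (oriented[nonzero] > 0).to_numpy()})
    counts = df.groupby("tissue")["up"].agg(up="sum", total="count")
    counts["down"] = counts["total"] - counts["up"]
    return DirectionTable(counts=counts[["up", "down"]].astype(int), subset=subset,
                          n_zero_slopes=n_zero)


@dataclass
class DirectionTestResult:
    statistic: float
    pvalue: float
    n_up: int
    n_down: int
    tissue_residuals: pd.Series
    flagged_tissues: list
    subset: str


def direction_test(table: DirectionTable, alpha: float = 0.05) -> DirectionTestResult:
    """Pooled chi-square goodness-of-fit against the 50% up / 50% down null.

    The statistic on pooled counts (u, d) is (u−m)²/m + (d−m)²/m with
    m = (u+d)/2. Per-tissue residuals are binomial z-scores
    (up_t − n_t/2)/sqrt(n_t/4); tissues beyond the two-sided normal
    critical value are flagged as skewed.
    """
    u, d = table.total_up, table.total_down
    if u + d == 0:
        raise ValueError("no nonzero slopes: direction test undefined")
    statistic, pvalue = stats.chisquare([u, d])
    n_t = table.counts["up"] + table.counts["down"]
    with np.errstate(divide="ignore", invalid="ignore"):
        resid = (table.counts["up"] - n_t / 2) / np.sqrt(n_t / 4)
    crit = stats.norm.ppf(1 - alpha / 2)
    flagged = [t for t, r in resid.items() if np.isfinite(r) and abs(r) > crit]
    return DirectionTestResult(
        statistic=float(statistic), pvalue=float(pvalue), n_up=u, n_down=d,
        tissue_residuals=resid.rename("z"), flagged_tissues=flagged,
        subset=table.subset,
    )


def build_control_set(classified: pd.DataFrame, eqtls: pd.DataFrame,
                      threshold: float = 0.90) -> DirectionTable:
    """Direction table for the major-ancestral-allele control.

    Mirror selection of the derived-HF set: variants whose *ancestral*
    allele is major at >= threshold global frequency. Orientation then
    refers to the ancestral allele's dosage effect, discarding the
    possibility that any skew is an artifact of a frequency cutoff on
    derived alleles.
    """
    cl = classified.loc[classified["ancestral_resolved"]].copy()
    anc_is_alt = cl["ancestral_allele"] == cl["alt"]
    af_anc = np.where(anc_is_alt, cl["af_global"], 1.0 - cl["af_global"])
    control = cl.loc[af_anc >= threshold]
    if len(control) == 0:
        warnings.warn("empty major-ancestral control set", stacklevel=2)
    ids = set(control["rsid"].dropna())
    sub = eqtls.loc[eqtls["qval_pass"] & eqtls["rsid"].isin(ids)]
    oriented = orient_slopes(sub, classified, focal="ancestral")
    return build_direction_table(sub, oriented, subset="major-ancestral-control")


def tissue_clustering(
    eqtls: pd.DataFrame,
    oriented: pd.Series | None = None,
    method: str = "complete",
):
    """Hierarchical clustering of tissues by mean effect size per gene.

    Builds the tissue x gene matrix of mean (oriented, if given) slopes,
    computes pairwise Euclidean distances over genes shared by each tissue
    pair (missing entries dropped pairwise, rescaled to the full gene
    count), and returns ``(linkage_matrix, tissue_labels, distance_matrix)``
    from scipy's agglomerative clustering.
    """
    df = eqtls.copy()
    df["effect"] = oriented if oriented is not None else df["slope"]
    df = df.dropna(subset=["effect"])
    mat = df.pivot_table(index="tissue", columns="gene_id", values="effect",
                         aggfunc="mean")
    empty = mat.isna().all(axis=1)
    if empty.any():
        warnings.warn(f"tissue(s) without eQTLs excluded: {list(mat.index[empty])}",
                      stacklevel=2)
        mat = mat.loc[~empty]
    if mat.shape[0] < 2:
        raise ValueError("need at least two tissues with eQTLs to cluster")

    tissues = list(mat.index)
    vals = mat.to_numpy()
    k = len(tissues)
    dist = np.zeros((k, k))
    for i in range(k):
        for j in range(i + 1, k):
            both = ~np.isnan(vals[i]) & ~np.isnan(vals[j])
            if both.sum() == 0:
                d = np.nan
            else:
                diff = vals[i, both] - vals[j, both]
                # rescale pairwise-complete distance to the full gene count
                d = np.sqrt((diff ** 2).mean() * vals.shape[1])
            dist[i, j] = dist[j, i] = d
    if np.isnan(dist).any():
        finite = dist[np.isfinite(dist)]
        dist = np.nan_to_num(dist, nan=(finite.max() * 2 if len(finite) else 1.0))
    linkage = hierarchy.linkage(squareform(dist, checks=False), method=method)
    return linkage, tissues, dist


def linkage_to_newick(linkage: np.ndarray, labels: list[str]) -> str:
    """Serialise a scipy linkage matrix as a Newick string with branch lengths."""
    tree = hierarchy.to_tree(linkage)

    def walk(node, parent_height) -> str:
        length = max(parent_height - node.dist, 0.0)
        if node.is_leaf():
            return f"{labels[node.id]}:{length:.6g}"
        left = walk(node.left, node.dist)
        right = walk(node.right, node.dist)
        return f"({left},{right}):{length:.6g}"

    return walk(tree, tree.dist) + ";"
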