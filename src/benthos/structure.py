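"""Community structure: dissimilarity, clustering, ordination, group tests,
and dominance scoring.

Bray-Curtis dissimilarity on log(x+1) densities feeds group-average (UPGMA)
clustering with a flat cut at a similarity level, principal coordinate
analysis, and PERMANOVA. Dominance degree Y = (relative abundance) x
(occurrence frequency); species with Y >= 0.02 are termed dominant.
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist, squareform
from scipy.stats import kruskal
from skbio import DistanceMatrix
from skbio.stats.distance import permanova as _skbio_permanova

from .core_io import BenthosError, SampleTable, log_transform


def bray_curtis(table: SampleTable, log_base: float | None = 10.0) -> DistanceMatrix:
    """Bray-Curtis dissimilarity between sites, optionally on log(x+1) data."""
    df = log_transform(table.data, log_base) if log_base else table.data
    d = pdist(df.to_numpy(float), metric="braycurtis")
    d = np.nan_to_num(d, nan=0.0)  # two all-zero sites are identical
    return DistanceMatrix(squareform(d), ids=list(df.index))


def jaccard(table: SampleTable) -> DistanceMatrix:
    """Presence/absence Jaccard dissimilarity between sites."""
    pa = (table.data.to_numpy(float) > 0)
    d = pdist(pa, metric="jaccard")
    return DistanceMatrix(squareform(np.nan_to_num(d, nan=0.0)), ids=table.sites)


def upgma_cluster(
    dm: DistanceMatrix,
    similarity_cut: float = 0.30,
    n_groups: int | None = None,
) -> tuple[np.ndarray, pd.Series]:
    """Group-average (UPGMA) clustering with a flat cut.

    Groups are formed at dissimilarity 1 - similarity_cut (default: units
    more than 30% similar cluster together); ``n_groups`` overrides the cut
    with a fixed number of clusters. Returns the scipy linkage matrix and a
    per-unit integer label series.
    """
    ids = list(dm.ids)
    if len(ids) < 2:
        raise BenthosError("need at least 2 units to cluster")
    z = hierarchy.linkage(squareform(dm.data, checks=False), method="average")
    if n_groups is not None:
        labels = hierarchy.fcluster(z, t=n_groups, criterion="maxclust")
    else:
        labels = hierarchy.fcluster(z, t=1.0 - similarity_cut, criterion="distance")
    return z, pd.Series(labels, index=ids, name="cluster")


def linkage_to_newick(z: np.ndarray, ids) -> str:
    """Dendrogram as a Newick string (branch lengths from merge heights)."""
    tree = hierarchy.to_tree(z)

    def rec(node, parent_height):
        length = parent_height - node.dist
        if node.is_leaf():
            return f"{ids[node.id]}:{length:.6g}"
        left = rec(node.left, node.dist)
        right = rec(node.right, node.dist)
        return f"({left},{right}):{length:.6g}"

    return f"({rec(tree.left, tree.dist)},{rec(tree.right, tree.dist)});"


def pcoa_ordination(dm: DistanceMatrix) -> dict:
    """Principal coordinates of a dissimilarity matrix.

    Gower double-centering followed by an eigendecomposition. Bray-Curtis is
    a semimetric, so negative eigenvalues can occur: they are reported in
    full and excluded from the proportion-explained denominator; coordinates
    span the positive axes only.
    """
    d2 = dm.data.astype(float) ** 2
    n = d2.shape[0]
    centering = np.eye(n) - np.ones((n, n)) / n
    gower = -0.5 * centering @ d2 @ centering
    eigvals, eigvecs = np.linalg.eigh(gower)
    order = np.argsort(eigvals)[::-1]
    eigvals, eigvecs = eigvals[order], eigvecs[:, order]
    pos = eigvals > 1e-12 * max(1.0, abs(eigvals[0]))
    coords = eigvecs[:, pos] * np.sqrt(eigvals[pos])
    axes = [f"PCo{i + 1}" for i in range(int(pos.sum()))]
    return {
        "coordinates": pd.DataFrame(coords, index=list(dm.ids), columns=axes),
        "eigenvalues": eigvals,
        "negative_eigenvalues": eigvals[eigvals < 0],
        "proportion_explained": eigvals[pos] / eigvals[pos].sum(),
    }


def group_centroids(coordinates: pd.DataFrame, labels: pd.Series) -> pd.DataFrame:
    """Arithmetic-mean centroid of each group in ordination space."""
    df = coordinates.copy()
    df["__g"] = labels.reindex(df.index)
    return df.groupby("__g").mean()


def permanova_test(
    dm: DistanceMatrix,
    labels: pd.Series,
    permutations: int = 999,
    seed: int = 0,
) -> dict:
    """PERMANOVA pseudo-F and permutation p-value for a grouping.

    p = (1 + #{F_perm >= F_obs}) / (1 + n_perm), with seeded label
    permutations. Every group must have at least 2 members.
    """
    grouping = labels.reindex(list(dm.ids))
    counts = grouping.value_counts()
    if (counts < 2).any():
        small = list(counts.index[counts < 2])
        raise BenthosError(f"groups with < 2 members: {small}")
    res = _skbio_permanova(dm, grouping.to_numpy(), permutations=permutations, seed=seed)
    return {
        "pseudo_F": float(res["test statistic"]),
        "p_value": float(res["p-value"]),
        "n_permutations": int(res["number of permutations"]),
        "n_groups": int(counts.size),
    }


def axis_group_tests(coordinates: pd.DataFrame, labels: pd.Series, n_axes: int = 2) -> pd.DataFrame:
    """Kruskal-Wallis comparison of groups along each of the first axes."""
    lab = labels.reindex(coordinates.index)
    rows = []
    for ax in coordinates.columns[:n_axes]:
        groups = [coordinates.loc[lab == g, ax].to_numpy() for g in lab.unique()]
        if len(groups) < 2:
            raise BenthosError("need at least two groups")
        h, p = kruskal(*groups)
        rows.append({"axis": ax, "H": float(h), "p_value": float(p)})
    return pd.DataFrame(rows).set_index("axis")


def dominance(table: SampleTable, threshold: float = 0.02) -> pd.DataFrame:
    """Dominance degree per species within a group of sites.

    Y = (pooled relative abundance) x (fraction of the group's sites where
    the species occurs); the dominant flag marks Y >= threshold.
    """
    pooled = table.data.sum(axis=0)
    total = pooled.sum()
    if total <= 0:
        raise BenthosError("empty group: no abundance")
    rel = pooled / total
    freq = (table.data > 0).mean(axis=0)
    y = rel * freq
    return pd.DataFrame(
        {
            "relative_abundance": rel,
            "occurrence_frequency": freq,
            "Y": y,
            "dominant": y >= threshold,
        }
    ).sort_values("Y", ascending=False)
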