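"""Community-environment association and group comparisons.

Kruskal-Wallis with Wilcoxon rank-sum post hoc (BH-adjusted by default),
Pearson screening of environmental parameters, the Mantel test between a
biological and an environmental distance matrix, and redundancy analysis
(RDA) of dominant-species densities on environmental predictors.

RDA here is the classical two-step procedure: z-score the predictors,
column-center the (log-transformed) response, fit multivariate least
squares, and eigen-decompose the fitted values; axis proportions are taken
relative to the total response variance, so constrained + unconstrained
variance reconstructs the total exactly.
"""

from __future__ import annotations

import itertools

import numpy as np
import pandas as pd
from scipy import stats
from skbio import DistanceMatrix
from skbio.stats.distance import mantel as _skbio_mantel
from statsmodels.stats.multitest import multipletests

from .core_io import BenthosError, EnvironmentTable, SampleTable, log_transform


def kruskal_wallis(values: pd.Series, labels: pd.Series) -> dict:
    """Rank-based H test (tie-corrected) that any group differs."""
    lab = labels.reindex(values.index)
    groups = [values[lab == g].to_numpy(float) for g in lab.dropna().unique()]
    if len(groups) < 2:
        raise BenthosError("need at least two groups")
    h, p = stats.kruskal(*groups)
    return {"H": float(h), "p_value": float(p), "n_groups": len(groups)}


def pairwise_wilcoxon(
    values: pd.Series,
    labels: pd.Series,
    adjust: str = "fdr_bh",
) -> pd.DataFrame:
    """Post hoc two-sided Wilcoxon rank-sum tests for all group pairs.

    Exact null distribution where sample sizes permit (no ties), normal
    approximation otherwise; p-values adjusted across pairs (``adjust="none"``
    disables correction).
    """
    lab = labels.reindex(values.index)
    names = list(lab.dropna().unique())
    pairs = list(itertools.combinations(names, 2))
    raw = []
    for a, b in pairs:
        _, p = stats.mannwhitneyu(
            values[lab == a], values[lab == b], alternative="two-sided"
        )
        raw.append(p)
    adj = raw if adjust == "none" else list(multipletests(raw, method=adjust)[1])
    out = pd.DataFrame(np.nan, index=names, columns=names)
    for (a, b), p in zip(pairs, adj):
        out.loc[a, b] = out.loc[b, a] = p
    return out


def mantel_test(
    d1: DistanceMatrix,
    d2: DistanceMatrix,
    method: str = "spearman",
    permutations: int = 999,
    seed: int = 0,
) -> dict:
    """Mantel correlation between two distance matrices over matched units."""
    if list(d1.ids) != list(d2.ids):
        d2 = d2.filter(d1.ids)
    r, p, n = _skbio_mantel(d1, d2, method=method, permutations=permutations, seed=seed)
    return {"r": float(r), "p_value": float(p), "n_units": int(n),
            "method": method, "n_permutations": permutations}


def environment_distance(env: EnvironmentTable, parameters=None) -> DistanceMatrix:
    """Euclidean distance on z-scored environmental parameters."""
    df = env.data[list(parameters)] if parameters else env.data
    x = df.to_numpy(float)
    sd = x.std(axis=0, ddof=1)
    keep = sd > 0
    z = (x[:, keep] - x[:, keep].mean(axis=0)) / sd[keep]
    from scipy.spatial.distance import pdist, squareform

    return DistanceMatrix(squareform(pdist(z)), ids=list(df.index))


def pearson_screen(env: EnvironmentTable, log_base: float | None = 10.0) -> dict:
    """Pairwise Pearson correlation of environmental parameters.

    Columns are log(x+1) transformed when all their values are non-negative;
    p-values are BH-adjusted over distinct pairs.
    """
    df = env.data.copy()
    if log_base:
        for c in df.columns:
            if (df[c] >= 0).all():
                df[c] = np.log1p(df[c]) / np.log(log_base)
    cols = list(df.columns)
    k = len(cols)
    r = pd.DataFrame(np.eye(k), index=cols, columns=cols)
    p = pd.DataFrame(np.zeros((k, k)), index=cols, columns=cols)
    raw, pairs = [], []
    for i, j in itertools.combinations(range(k), 2):
        ri, pi = stats.pearsonr(df.iloc[:, i], df.iloc[:, j])
        r.iloc[i, j] = r.iloc[j, i] = ri
        p.iloc[i, j] = p.iloc[j, i] = pi
        raw.append(pi)
        pairs.append((i, j))
    p_adj = p.copy()
    if raw:
        adj = multipletests(raw, method="fdr_bh")[1]
        for (i, j), a in zip(pairs, adj):
            p_adj.iloc[i, j] = p_adj.iloc[j, i] = a
    return {"r": r, "p": p, "p_adj": p_adj}


def rda(
    response: SampleTable,
    explanatory: EnvironmentTable,
    parameters=None,
    log_base: float | None = 10.0,
) -> dict:
    """Redundancy analysis of a community table on environmental predictors.

    Returns unit (site) scores and species scores on the constrained axes,
    predictor loadings (correlation of each z-scored predictor with the unit
    scores), the proportion of total response variance per constrained axis,
    and the total constrained proportion.
    """
    x_df = explanatory.data[list(parameters)] if parameters else explanatory.data
    x_df = x_df.loc[response.sites]
    y_df = log_transform(response.data, log_base) if log_base else response.data

    n = len(y_df)
    x = x_df.to_numpy(float)
    sd = x.std(axis=0, ddof=1)
    dropped = [c for c, s in zip(x_df.columns, sd) if s == 0]
    keep = sd > 0
    x = (x[:, keep] - x[:, keep].mean(axis=0)) / sd[keep]
    x_cols = [c for c, k in zip(x_df.columns, keep) if k]
    if x.shape[1] > n - 1:
        raise BenthosError("more explanatory variables than units - 1")
    # drop exactly collinear predictors
    if x.shape[1] > 1:
        rank = np.linalg.matrix_rank(x)
        while rank < x.shape[1]:
            x = x[:, :-1]
            dropped.append(x_cols.pop())
            rank = np.linalg.matrix_rank(x)

    y = y_df.to_numpy(float)
    y = y - y.mean(axis=0)
    beta, *_ = np.linalg.lstsq(x, y, rcond=None)
    fitted = x @ beta
    # constrained axes from the SVD of the fitted matrix
    u, s, vt = np.linalg.svd(fitted, full_matrices=False)
    eig = s**2 / (n - 1)
    total_var = (y**2).sum() / (n - 1)
    pos = eig > max(eig.max(), 1.0) * 1e-12 if eig.size else np.array([], bool)
    eig = eig[pos]
    axes = [f"RDA{i + 1}" for i in range(eig.size)]
    site_scores = pd.DataFrame(
        u[:, pos] * s[pos], index=y_df.index, columns=axes
    )
    species_scores = pd.DataFrame(vt[pos].T, index=y_df.columns, columns=axes)
    if eig.size:
        loadings = pd.DataFrame(
            np.corrcoef(np.hstack([x, site_scores.to_numpy()]), rowvar=False)[
                : x.shape[1], x.shape[1]:
            ],
            index=x_cols,
            columns=axes,
        )
    else:  # nothing constrained: no axes to correlate with
        loadings = pd.DataFrame(index=x_cols, columns=axes, dtype=float)
    constrained = float(eig.sum() / total_var) if total_var > 0 else np.nan
    return {
        "site_scores": site_scores,
        "species_scores": species_scores,
        "loadings": loadings,
        "eigenvalues": eig,
        "proportion_explained": eig / total_var,
        "total_constrained_proportion": constrained,
        "total_variance": total_var,
        "dropped_predictors": dropped,
    }
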