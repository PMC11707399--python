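"""Phylogenetic-diversity indices with a randomization null for NRI.

Eight indices per unit: Faith's PD (branch-length sum of the minimal rooted
subtree spanning the present tips), mean pairwise distance MPD, mean nearest
taxon distance MNTD, the net relatedness index NRI (a standardized effect
size of MPD under a tip-label-shuffle null), and the phylogenetic species
variability family PSV / PSR / PSE / PSC of Helmus-style community
phylogenetics.

The PSV family is computed from the tip correlation matrix
``C_ij = V_ij / sqrt(V_ii V_jj)`` where ``V_ij`` is the shared root-to-tip
branch length of tips i and j (depth of their most recent common ancestor)
and ``V_ii`` the tip's depth; on an ultrametric tree this is the classical
phylogenetic correlation. The tree therefore need not be ultrametric.

Species absent from the tree are excluded fail-soft; the coverage fraction
is recorded on the output (see ``core_io.reconcile_tree``).
"""

from __future__ import annotations

import math
import warnings

import numpy as np
import pandas as pd
from skbio import TreeNode
from skbio.diversity.alpha import faith_pd as _skbio_faith_pd

from .core_io import SampleTable, reconcile_tree

PHYLO_INDICES = ("PD", "MPD", "MNTD", "NRI", "PSV", "PSR", "PSE", "PSC")


class TreeContext:
    """Precomputed tip registry, patristic matrix and correlation matrix."""

    def __init__(self, tree: TreeNode):
        self.tree = tree
        dm = tree.tip_tip_distances()
        self.tips = list(dm.ids)
        self.index = {t: i for i, t in enumerate(self.tips)}
        self.patristic = np.asarray(dm.data, float)
        depths = np.array(
            [tree.find(t).accumulate_to_ancestor(tree) for t in self.tips], float
        )
        self.depths = depths
        # V_ij = depth of MRCA = (depth_i + depth_j - d_ij) / 2
        v = (depths[:, None] + depths[None, :] - self.patristic) / 2.0
        with np.errstate(invalid="ignore", divide="ignore"):
            self.corr = v / np.sqrt(np.outer(depths, depths))
        np.fill_diagonal(self.corr, 1.0)
        self.total_branch_length = float(
            sum(n.length or 0.0 for n in tree.traverse(include_self=False))
        )

    def idx(self, species) -> np.ndarray:
        return np.array([self.index[s] for s in species], int)


def faith_pd(present_species, ctx: TreeContext) -> float:
    """Faith's PD: branch length of the minimal subtree joining tips + root."""
    present = [s for s in present_species if s in ctx.index]
    if not present:
        return math.nan
    counts = np.zeros(len(ctx.tips))
    counts[ctx.idx(present)] = 1
    return float(_skbio_faith_pd(counts, taxa=ctx.tips, tree=ctx.tree))


def mpd(present_species, ctx: TreeContext, abundances=None) -> float:
    """Mean pairwise patristic distance over distinct present tips.

    With ``abundances`` the mean is abundance-weighted over ordered pairs.
    """
    ix = ctx.idx([s for s in present_species if s in ctx.index])
    if ix.size < 2:
        return math.nan
    sub = ctx.patristic[np.ix_(ix, ix)]
    if abundances is None:
        return float(sub[np.triu_indices(ix.size, k=1)].mean())
    w = np.asarray(abundances, float)
    w = w / w.sum()
    outer = np.outer(w, w)
    np.fill_diagonal(outer, 0.0)
    return float((sub * outer).sum() / outer.sum())


def mntd(present_species, ctx: TreeContext) -> float:
    """Mean distance from each present tip to its nearest present neighbour."""
    ix = ctx.idx([s for s in present_species if s in ctx.index])
    if ix.size < 2:
        return math.nan
    sub = ctx.patristic[np.ix_(ix, ix)].copy()
    np.fill_diagonal(sub, np.inf)
    return float(sub.min(axis=1).mean())


def nri(
    present_species,
    ctx: TreeContext,
    n_null: int = 999,
    seed: int = 0,
) -> float:
    """Net relatedness index: -(MPD_obs - mean MPD_null) / sd MPD_null.

    Null model: shuffle tip labels over the whole tree, i.e. redraw the same
    richness uniformly from all tips, ``n_null`` times (seeded). Positive
    values indicate phylogenetic clustering.
    """
    if n_null < 99:
        raise ValueError("n_null must be >= 99")
    present = [s for s in present_species if s in ctx.index]
    k = len(present)
    if k < 2:
        return math.nan
    obs = mpd(present, ctx)
    rng = np.random.default_rng(seed)
    n_tips = len(ctx.tips)
    # vectorized k-subsets: argpartition of random keys per draw
    keys = rng.random((n_null, n_tips))
    draws = np.argpartition(keys, k - 1, axis=1)[:, :k]
    iu = np.triu_indices(k, k=1)
    sub = ctx.patristic[draws[:, :, None], draws[:, None, :]]
    null = sub[:, iu[0], iu[1]].mean(axis=1)
    sd = float(null.std(ddof=1))
    mean = float(null.mean())
    tol = 1e-10 * max(1.0, abs(mean))
    if sd <= tol:
        # degenerate null: the shuffle cannot move MPD (e.g. all tips present)
        return 0.0 if abs(obs - mean) <= tol else math.nan
    return float(-(obs - mean) / sd)


def psv_family(abundance_row: pd.Series, ctx: TreeContext) -> dict:
    """PSV, PSR, PSE, PSC from the tip correlation matrix.

    PSV = 1 - mean off-diagonal correlation among present tips; PSR = PSV x S;
    PSE generalizes PSV to individuals (equals PSV at equal abundances);
    PSC = 1 - mean over present tips of their maximal off-diagonal
    correlation (nearest-relative clustering).
    """
    row = abundance_row[abundance_row > 0]
    present = [s for s in row.index if s in ctx.index]
    out = {"PSV": math.nan, "PSR": math.nan, "PSE": math.nan, "PSC": math.nan}
    s = len(present)
    if s < 2:
        return out
    ix = ctx.idx(present)
    c = ctx.corr[np.ix_(ix, ix)]
    off_sum = float(c.sum() - np.trace(c))
    psv = (s * s - (s + off_sum)) / (s * (s - 1))
    m = row[present].to_numpy(float)
    n_tot = m.sum()
    pse = float((n_tot**2 - m @ c @ m) / (n_tot**2 - (m**2).sum()))
    c_off = c.copy()
    np.fill_diagonal(c_off, -np.inf)
    psc = 1.0 - float(c_off.max(axis=1).mean())
    out.update(PSV=float(psv), PSR=float(psv * s), PSE=pse, PSC=psc)
    return out


def phylo_table(
    abundance: SampleTable,
    tree: TreeNode,
    n_null: int = 999,
    seed: int = 0,
) -> pd.DataFrame:
    """Per-site table of the eight phylogenetic indices.

    Species missing from the tree are dropped from the computation; the
    coverage fraction is stored in ``df.attrs['tree_coverage']`` and a
    warning is emitted when it is below 1.
    """
    recon = reconcile_tree(abundance, tree)
    if recon["missing_from_tree"]:
        warnings.warn(
            f"{len(recon['missing_from_tree'])} species absent from tree; "
            f"coverage {recon['coverage_fraction']:.3f}",
            stacklevel=2,
        )
    ctx = TreeContext(tree)
    rows = {}
    for i, site in enumerate(abundance.sites):
        row = abundance.data.loc[site]
        present = [s for s in row.index[row > 0] if s in ctx.index]
        rec = {
            "PD": faith_pd(present, ctx),
            "MPD": mpd(present, ctx),
            "MNTD": mntd(present, ctx),
            "NRI": nri(present, ctx, n_null, seed + i) if len(present) >= 2 else math.nan,
        }
        rec.update(psv_family(row, ctx))
        rows[site] = rec
    df = pd.DataFrame.from_dict(rows, orient="index")[list(PHYLO_INDICES)]
    df.index.name = "site"
    df.attrs["tree_coverage"] = recon["coverage_fraction"]
    df.attrs["n_null"] = n_null
    return df
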