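"""Co-occurrence networks and community-stability indices.

Per community group: species occurring in at least a minimum fraction of the
group's sites are correlated pairwise (Spearman by default) across sites on
log(x+1) densities; edges keep pairs with |rho| >= rho_min and
Benjamini-Hochberg adjusted p < alpha. All construction parameters are
embedded in the graph so a network artifact is self-describing.

Stability indices: ICV (inverse coefficient of variation of total community
density across sites), cohesion (abundance-weighted mean positive/negative
pairwise association), AVD (average variation degree: mean |z| of species
densities across the group's sites), robustness to random or targeted node
removal with isolation counted as secondary extinction, and vulnerability
(the worst single-node drop in global efficiency).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd
import networkx as nx
from scipy import stats
from scipy.sparse.csgraph import shortest_path
from statsmodels.stats.multitest import multipletests

from .core_io import BenthosError, SampleTable, log_transform

#: the eight stability indices
STABILITY_INDICES = (
    "ICV", "C_pos", "C_neg", "C_total", "AVD",
    "Robustness_R", "Robustness_Y", "Vulnerability",
)

#: above this many nodes, modularity search switches from exact to greedy
EXACT_MODULARITY_MAX_NODES = 10


# ---------------------------------------------------------------------------
# construction
# ---------------------------------------------------------------------------

def correlation_matrix(
    table: SampleTable,
    method: str = "spearman",
    log_base: float = 10.0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Pairwise correlation (and p-values) of species across a group's sites."""
    df = log_transform(table.data, log_base) if log_base else table.data
    x = df.to_numpy(float)
    n_sp = x.shape[1]
    if method == "spearman":
        res = stats.spearmanr(x)
        rho, p = np.atleast_2d(res.statistic), np.atleast_2d(res.pvalue)
    elif method == "pearson":
        rho = np.corrcoef(x, rowvar=False)
        # t-test p-values
        n = x.shape[0]
        with np.errstate(divide="ignore", invalid="ignore"):
            t = rho * np.sqrt((n - 2) / (1 - rho**2))
        p = 2 * stats.t.sf(np.abs(t), df=n - 2)
    else:
        raise BenthosError(f"unknown correlation method {method!r}")
    if rho.shape != (n_sp, n_sp):  # spearmanr collapses for 2 columns
        r = float(np.asarray(res.statistic).reshape(()))
        pv = float(np.asarray(res.pvalue).reshape(()))
        rho = np.array([[1.0, r], [r, 1.0]])
        p = np.array([[0.0, pv], [pv, 0.0]])
    cols = df.columns
    return (
        pd.DataFrame(rho, index=cols, columns=cols),
        pd.DataFrame(p, index=cols, columns=cols),
    )


def build_network(
    table: SampleTable,
    min_occurrence: float = 0.2,
    corr_method: str = "spearman",
    rho_min: float = 0.6,
    alpha: float = 0.05,
    mt_correction: str = "fdr_bh",
    log_base: float = 10.0,
    seed: int = 0,
) -> nx.Graph:
    """Signed, weighted co-occurrence graph for one community group."""
    n_sites = len(table.sites)
    if n_sites < 4:
        raise BenthosError("need at least 4 sites to build a network")
    occ = (table.data > 0).mean(axis=0)
    keep = [s for s in table.species if occ[s] >= min_occurrence]
    # zero-variance species carry no rank information
    keep = [s for s in keep if table.data[s].nunique() > 1]
    g = nx.Graph(
        min_occurrence=min_occurrence, corr_method=corr_method,
        rho_min=rho_min, alpha=alpha, mt_correction=mt_correction,
        log_base=log_base, seed=seed, n_sites=n_sites,
    )
    g.add_nodes_from(keep)
    if len(keep) < 2:
        return g
    sub = SampleTable(table.data[keep], table.kind)
    rho, pval = correlation_matrix(sub, corr_method, log_base)
    iu = np.triu_indices(len(keep), k=1)
    p_flat = pval.to_numpy()[iu]
    if mt_correction and mt_correction != "none":
        p_adj = multipletests(p_flat, method=mt_correction)[1]
    else:
        p_adj = p_flat
    r_flat = rho.to_numpy()[iu]
    for (i, j, r, p_raw, p_a) in zip(iu[0], iu[1], r_flat, p_flat, p_adj):
        if np.isfinite(r) and abs(r) >= rho_min and p_a < alpha:
            g.add_edge(
                keep[i], keep[j],
                rho=float(r), sign=1 if r > 0 else -1,
                weight=float(abs(r)), p=float(p_raw), p_adj=float(p_a),
            )
    return g


# ---------------------------------------------------------------------------
# topology
# ---------------------------------------------------------------------------

@dataclass
class NetworkTopology:
    n_nodes: int
    n_edges: int
    n_components: int
    avg_degree: float
    avg_path_length: float
    clustering: float
    modularity: float

    def as_dict(self) -> dict:
        return asdict(self)


def _set_partitions(items):
    """All partitions of a list into non-empty blocks (restricted-growth)."""
    if not items:
        yield []
        return
    first, rest = items[0], items[1:]
    for part in _set_partitions(rest):
        for i in range(len(part)):
            yield part[:i] + [[first] + part[i]] + part[i + 1:]
        yield [[first]] + part


def best_partition(graph: nx.Graph, weight: str = "weight", seed: int = 0) -> list[set]:
    """Modularity-maximizing partition: exact enumeration on small graphs,
    greedy (Clauset-Newman-Moore) beyond ``EXACT_MODULARITY_MAX_NODES``."""
    nodes = list(graph.nodes)
    if graph.number_of_edges() == 0:
        return [{n} for n in nodes]
    if len(nodes) <= EXACT_MODULARITY_MAX_NODES:
        best, best_q = None, -np.inf
        for part in _set_partitions(nodes):
            q = nx.community.modularity(graph, part, weight=weight)
            if q > best_q + 1e-12:
                best, best_q = part, q
        return [set(b) for b in best]
    comms = nx.community.greedy_modularity_communities(graph, weight=weight)
    return [set(c) for c in comms]


def _adjacency(graph: nx.Graph) -> tuple[list, np.ndarray]:
    nodes = list(graph.nodes)
    a = nx.to_numpy_array(graph, nodelist=nodes, weight=None)
    return nodes, a.astype(bool)


def _mean_local_clustering(a: np.ndarray) -> float:
    """Mean local clustering coefficient from the boolean adjacency matrix.

    Degree-<2 nodes contribute 0, matching the unweighted convention.
    """
    af = a.astype(float)
    triangles = np.einsum("ij,jk,ki->i", af, af, af)  # 2 x closed triples
    deg = af.sum(axis=1)
    denom = deg * (deg - 1)
    local = np.where(denom > 0, triangles / np.where(denom > 0, denom, 1.0), 0.0)
    return float(local.mean())


def topology(graph: nx.Graph, seed: int = 0) -> NetworkTopology:
    """Average degree, path length (largest component), clustering, modularity."""
    n, e = graph.number_of_nodes(), graph.number_of_edges()
    if n == 0:
        return NetworkTopology(0, 0, 0, math.nan, math.nan, math.nan, math.nan)
    d = 2.0 * e / n
    nodes, a = _adjacency(graph)
    comps = list(nx.connected_components(graph))
    n_comps = len(comps)
    if e == 0:
        return NetworkTopology(n, 0, n_comps, d, math.nan, 0.0, math.nan)
    sp = shortest_path(a, method="D", unweighted=True, directed=False)
    giant = max(comps, key=len)
    if len(giant) > 1:
        pos = {v: i for i, v in enumerate(nodes)}
        ix = np.array([pos[v] for v in giant])
        block = sp[np.ix_(ix, ix)]
        off = ~np.eye(len(ix), dtype=bool)
        l = float(block[off].mean())
    else:
        l = math.nan
    c = _mean_local_clustering(a)
    part = best_partition(graph, seed=seed)
    m = nx.community.modularity(graph, part, weight="weight")
    return NetworkTopology(n, e, n_comps, d, l, c, float(m))


# ---------------------------------------------------------------------------
# stability indices
# ---------------------------------------------------------------------------

def icv(table: SampleTable) -> float:
    """Inverse coefficient of variation of total community density.

    mean / sd (ddof=1) of per-site totals; degenerate zero-variance groups
    return NaN rather than infinity.
    """
    totals = table.data.sum(axis=1).to_numpy(float)
    if totals.size < 2:
        return math.nan
    sd = totals.std(ddof=1)
    if sd == 0.0:
        return math.nan
    return float(totals.mean() / sd)


def cohesion(
    table: SampleTable,
    corr_method: str = "spearman",
    log_base: float = 10.0,
) -> pd.DataFrame:
    """Per-site positive and negative cohesion.

    connectedness+-(j) = mean of the positive (resp. negative) pairwise
    correlations of species j with all other species (0 if none); per site,
    C_pos = sum_j relabund_j * conn+(j) and C_neg likewise over conn-(j);
    C_total = C_pos + |C_neg|.
    """
    present = [s for s in table.species if table.data[s].sum() > 0]
    df = table.data[present]
    n_sp = len(present)
    conn_pos = np.zeros(n_sp)
    conn_neg = np.zeros(n_sp)
    if n_sp >= 2:
        rho, _ = correlation_matrix(
            SampleTable(df, table.kind), corr_method, log_base
        )
        r = rho.to_numpy(float)
        np.fill_diagonal(r, np.nan)
        for j in range(n_sp):
            row = r[j]
            pos = row[np.isfinite(row) & (row > 0)]
            neg = row[np.isfinite(row) & (row < 0)]
            conn_pos[j] = pos.mean() if pos.size else 0.0
            conn_neg[j] = neg.mean() if neg.size else 0.0
    rel = df.div(df.sum(axis=1).replace(0.0, np.nan), axis=0).fillna(0.0)
    c_pos = rel.to_numpy() @ conn_pos
    c_neg = rel.to_numpy() @ conn_neg
    out = pd.DataFrame(
        {"C_pos": c_pos, "C_neg": c_neg, "C_total": c_pos + np.abs(c_neg)},
        index=df.index,
    )
    return out


def avd(table: SampleTable) -> float:
    """Average variation degree: mean |z| of species densities across sites.

    Species with zero variance across the group's sites are excluded; the
    normalizer is n_sites x n_retained_species.
    """
    x = table.data.to_numpy(float)
    sd = x.std(axis=0, ddof=1)
    keep = sd > 0
    if not keep.any():
        return math.nan
    z = (x[:, keep] - x[:, keep].mean(axis=0)) / sd[keep]
    return float(np.abs(z).sum() / (x.shape[0] * keep.sum()))


def _surviving_fraction(a: np.ndarray, keep: np.ndarray) -> float:
    """Fraction of nodes left after removal plus secondary extinction.

    Secondary extinction = isolation: a survivor persists only if it keeps at
    least one surviving neighbour. Removing an isolated node cannot isolate
    others, so a single pass suffices.
    """
    n = a.shape[0]
    alive = int((a[keep][:, keep]).any(axis=1).sum())
    return alive / n


def robustness_random(
    graph: nx.Graph,
    removal_fraction: float = 0.5,
    reps: int = 1000,
    seed: int = 0,
) -> float:
    """Mean surviving fraction after removing floor(f*N) random nodes."""
    n = graph.number_of_nodes()
    if n == 0:
        return math.nan
    k = int(removal_fraction * n)
    _, a = _adjacency(graph)
    rng = np.random.default_rng(seed)
    total = 0.0
    for _ in range(reps):
        keep = np.ones(n, bool)
        keep[rng.choice(n, size=k, replace=False)] = False
        total += _surviving_fraction(a, keep)
    return total / reps


def robustness_targeted(graph: nx.Graph, remove_set) -> float:
    """Surviving fraction after removing a designated (dominant) node set."""
    n = graph.number_of_nodes()
    if n == 0:
        return math.nan
    nodes, a = _adjacency(graph)
    removed = set(remove_set)
    keep = np.array([v not in removed for v in nodes])
    return _surviving_fraction(a, keep)


def _global_efficiency(a: np.ndarray) -> float:
    """Mean over ordered node pairs of 1/shortest-path (0 if disconnected)."""
    n = a.shape[0]
    if n < 2:
        return 0.0
    sp = shortest_path(a, method="D", unweighted=True, directed=False)
    with np.errstate(divide="ignore"):
        inv = 1.0 / sp
    np.fill_diagonal(inv, 0.0)
    return float(inv[np.isfinite(inv)].sum() / (n * (n - 1)))


def vulnerability(graph: nx.Graph) -> float:
    """Worst relative drop in global efficiency from one node's deletion.

    E(G) is the mean over ordered node pairs of 1/shortest-path-length
    (0 for disconnected pairs); each E(G \\ i) is taken over the reduced node
    set. Needs at least 3 nodes.
    """
    n = graph.number_of_nodes()
    if n < 3:
        return math.nan
    _, a = _adjacency(graph)
    e_full = _global_efficiency(a)
    if e_full == 0.0:
        return math.nan
    worst = -np.inf
    keep = np.ones(n, bool)
    for i in range(n):
        keep[i] = False
        e_i = _global_efficiency(a[keep][:, keep])
        keep[i] = True
        worst = max(worst, (e_full - e_i) / e_full)
    return float(worst)


def stability_record(
    table: SampleTable,
    graph: nx.Graph,
    dominant_species=(),
    removal_fraction: float = 0.5,
    reps: int = 1000,
    corr_method: str = "spearman",
    log_base: float = 10.0,
    seed: int = 0,
) -> dict:
    """The eight stability indices for one community group."""
    coh = cohesion(table, corr_method, log_base)
    c_pos = float(coh["C_pos"].mean())
    c_neg = float(coh["C_neg"].mean())
    return {
        "ICV": icv(table),
        "C_pos": c_pos,
        "C_neg": c_neg,
        "C_total": c_pos + abs(c_neg),
        "AVD": avd(table),
        "Robustness_R": robustness_random(graph, removal_fraction, reps, seed),
        "Robustness_Y": robustness_targeted(graph, dominant_species),
        "Vulnerability": vulnerability(graph),
    }
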