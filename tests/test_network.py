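import itertools
import math

import networkx as nx
import numpy as np
import pandas as pd
import pytest

from benthos.core_io import SampleTable
from benthos.network import (
    avd,
    best_partition,
    build_network,
    cohesion,
    icv,
    robustness_random,
    robustness_targeted,
    stability_record,
    topology,
    vulnerability,
)

from conftest import random_table


def table_from(vals, prefix_s="s", prefix_sp="sp") -> SampleTable:
    vals = np.asarray(vals, float)
    return SampleTable(
        pd.DataFrame(
            vals,
            index=[f"{prefix_s}{i}" for i in range(vals.shape[0])],
            columns=[f"{prefix_sp}{j}" for j in range(vals.shape[1])],
        )
    )


# ---------------------------------------------------------------------------
# independent oracles (deliberately written from scratch)
# ---------------------------------------------------------------------------

def floyd_warshall_path_length(g: nx.Graph) -> float:
    nodes = list(max(nx.connected_components(g), key=len))
    n = len(nodes)
    idx = {v: i for i, v in enumerate(nodes)}
    d = np.full((n, n), np.inf)
    np.fill_diagonal(d, 0.0)
    for u, v in g.edges:
        if u in idx and v in idx:
            d[idx[u], idx[v]] = d[idx[v], idx[u]] = 1.0
    for k in range(n):
        d = np.minimum(d, d[:, [k]] + d[[k], :])
    off = d[~np.eye(n, dtype=bool)]
    return float(off.mean())


def triangle_clustering(g: nx.Graph) -> float:
    vals = []
    for v in g.nodes:
        nbrs = list(g.neighbors(v))
        k = len(nbrs)
        if k < 2:
            vals.append(0.0)
            continue
        links = sum(1 for a, b in itertools.combinations(nbrs, 2) if g.has_edge(a, b))
        vals.append(2.0 * links / (k * (k - 1)))
    return float(np.mean(vals))


def modularity_of(g: nx.Graph, blocks) -> float:
    m = g.number_of_edges()
    deg = dict(g.degree())
    q = 0.0
    for block in blocks:
        for a in block:
            for b in block:
                q += (1.0 if g.has_edge(a, b) and a != b else 0.0) - deg[a] * deg[b] / (2.0 * m)
    return q / (2.0 * m)


def partitions(collection):
    if len(collection) == 1:
        yield [collection]
        return
    first, rest = collection[0], collection[1:]
    for smaller in partitions(rest):
        for i, subset in enumerate(smaller):
            yield smaller[:i] + [[first] + subset] + smaller[i + 1:]
        yield [[first]] + smaller


def max_modularity_bruteforce(g: nx.Graph) -> float:
    return max(modularity_of(g, p) for p in partitions(list(g.nodes)))


def exhaustive_robustness(g: nx.Graph, k: int) -> tuple[float, float]:
    """Exact mean and sd of the surviving fraction over all k-subsets."""
    nodes = list(g.nodes)
    n = len(nodes)
    fracs = []
    for removed in itertools.combinations(nodes, k):
        removed = set(removed)
        alive = sum(
            1 for v in nodes
            if v not in removed and any(u not in removed for u in g.neighbors(v))
        )
        fracs.append(alive / n)
    return float(np.mean(fracs)), float(np.std(fracs))


def efficiency_oracle(g: nx.Graph) -> float:
    nodes = list(g.nodes)
    n = len(nodes)
    if n < 2:
        return 0.0
    total = 0.0
    for s in nodes:
        lengths = nx.single_source_shortest_path_length(g, s)
        total += sum(1.0 / l for t, l in lengths.items() if t != s)
    return total / (n * (n - 1))


def vulnerability_oracle(g: nx.Graph) -> float:
    e0 = efficiency_oracle(g)
    drops = []
    for v in g.nodes:
        sub = g.subgraph([u for u in g.nodes if u != v])
        drops.append((e0 - efficiency_oracle(sub)) / e0)
    return max(drops)


def random_graph(rng, n_min=4, n_max=8) -> nx.Graph:
    n = int(rng.integers(n_min, n_max + 1))
    p = rng.uniform(0.25, 0.9)
    g = nx.gnp_random_graph(n, p, seed=int(rng.integers(2**31)))
    while g.number_of_edges() == 0:
        g = nx.gnp_random_graph(n, 0.5, seed=int(rng.integers(2**31)))
    nx.set_edge_attributes(g, 1.0, "weight")
    return g


# ---------------------------------------------------------------------------
# construction
# ---------------------------------------------------------------------------

class TestBuildNetwork:
    def test_perfectly_covarying_pair_gets_positive_unit_edge(self, rng):
        x = rng.gamma(2.0, 10.0, 10)
        table = table_from(np.column_stack([x, 2 * x, x.max() + 1.0 - x]))
        g = build_network(table, rho_min=0.6, alpha=0.05)
        assert g.has_edge("sp0", "sp1")
        e = g.edges["sp0", "sp1"]
        assert e["sign"] == 1 and e["weight"] == pytest.approx(1.0)
        assert g.edges["sp0", "sp2"]["sign"] == -1

    def test_rare_species_filtered_by_occurrence(self, rng):
        vals = rng.gamma(2.0, 10.0, (10, 3))
        vals[:, 2] = 0.0
        vals[0, 2] = 5.0  # present at 10% of sites only
        g = build_network(table_from(vals), min_occurrence=0.2)
        assert "sp2" not in g.nodes

    def test_needs_four_sites(self, rng):
        with pytest.raises(Exception, match="4 sites"):
            build_network(random_table(rng, n_sites=3))

    def test_independent_noise_false_positive_rate(self):
        """Retained-edge fraction stays below alpha on pure noise."""
        rng = np.random.default_rng(7)
        retained = tested = 0
        for _ in range(10):
            vals = rng.gamma(1.0, 10.0, (20, 10))  # 45 pairs per draw
            g = build_network(table_from(vals), rho_min=0.0, alpha=0.05)
            n = g.number_of_nodes()
            tested += n * (n - 1) // 2
            retained += g.number_of_edges()
        assert tested >= 400
        assert retained / tested <= 0.05

    def test_parameters_embedded_in_artifact(self, rng):
        g = build_network(random_table(rng), rho_min=0.7, alpha=0.01)
        assert g.graph["rho_min"] == 0.7
        assert g.graph["alpha"] == 0.01


# ---------------------------------------------------------------------------
# topology
# ---------------------------------------------------------------------------

class TestTopology:
    def test_triangle(self):
        g = nx.complete_graph(3)
        nx.set_edge_attributes(g, 1.0, "weight")
        t = topology(g)
        assert t.avg_degree == pytest.approx(2.0)
        assert t.avg_path_length == pytest.approx(1.0)
        assert t.clustering == pytest.approx(1.0)

    def test_three_node_path(self):
        g = nx.path_graph(3)
        nx.set_edge_attributes(g, 1.0, "weight")
        t = topology(g)
        assert t.avg_path_length == pytest.approx(4.0 / 3.0)
        assert t.clustering == pytest.approx(0.0)

    def test_two_disjoint_triangles_hit_modularity_maximum(self):
        g = nx.disjoint_union(nx.complete_graph(3), nx.complete_graph(3))
        nx.set_edge_attributes(g, 1.0, "weight")
        t = topology(g)
        assert t.n_components == 2
        assert t.modularity == pytest.approx(max_modularity_bruteforce(g), abs=1e-12)

    def test_empty_and_edgeless_networks(self):
        t = topology(nx.Graph())
        assert t.n_nodes == 0 and math.isnan(t.avg_degree)
        g = nx.empty_graph(4)
        t = topology(g)
        assert t.avg_degree == 0.0 and math.isnan(t.avg_path_length)

    def test_oracle_battery_small_graphs(self):
        """l, c, m match independent enumeration on random graphs <= 8 nodes."""
        rng = np.random.default_rng(3)
        for _ in range(60):
            g = random_graph(rng)
            t = topology(g)
            assert t.avg_path_length == pytest.approx(
                floyd_warshall_path_length(g), abs=1e-9
            )
            assert t.clustering == pytest.approx(triangle_clustering(g), abs=1e-9)
            assert t.modularity == pytest.approx(
                max_modularity_bruteforce(g), abs=1e-9
            )

    def test_greedy_partition_used_beyond_exact_limit(self):
        g = nx.connected_caveman_graph(4, 4)  # 16 nodes
        nx.set_edge_attributes(g, 1.0, "weight")
        part = best_partition(g)
        assert len(part) == 4


# ---------------------------------------------------------------------------
# stability indices
# ---------------------------------------------------------------------------

class TestICV:
    def test_constant_totals_missing(self):
        assert math.isnan(icv(table_from([[10.0], [10.0], [10.0]])))

    def test_two_site_hand_value(self):
        assert icv(table_from([[8.0], [12.0]])) == pytest.approx(3.535534, abs=1e-6)

    def test_scale_invariance(self, rng):
        t = random_table(rng)
        scaled = SampleTable(t.data * 7.3)
        assert icv(scaled) == pytest.approx(icv(t))


class TestCohesion:
    def test_uncorrelated_species_give_zero(self, rng):
        # two species, one constant: no rank correlation possible
        vals = np.column_stack([rng.gamma(2.0, 5.0, 8), np.full(8, 3.0)])
        out = cohesion(table_from(vals))
        assert np.allclose(out["C_pos"], 0.0)
        assert np.allclose(out["C_neg"], 0.0)

    def test_perfect_pair_equal_share(self, rng):
        x = rng.gamma(2.0, 5.0, 10)
        out = cohesion(table_from(np.column_stack([x, x])))
        assert np.allclose(out["C_pos"], 1.0)
        assert np.allclose(out["C_neg"], 0.0)
        assert np.allclose(out["C_total"], 1.0)

    def test_four_species_hand_oracle(self, rng):
        """Weighted sums match an explicitly looped spreadsheet computation."""
        from scipy.stats import spearmanr

        vals = rng.gamma(2.0, 10.0, (9, 4))
        table = table_from(vals)
        out = cohesion(table, log_base=10.0)

        logged = np.log1p(vals) / np.log(10.0)
        rho = spearmanr(logged).statistic
        conn_pos, conn_neg = np.zeros(4), np.zeros(4)
        for j in range(4):
            others = [rho[j, k] for k in range(4) if k != j]
            pos = [r for r in others if r > 0]
            neg = [r for r in others if r < 0]
            conn_pos[j] = np.mean(pos) if pos else 0.0
            conn_neg[j] = np.mean(neg) if neg else 0.0
        for i in range(9):
            rel = vals[i] / vals[i].sum()
            assert out["C_pos"].iloc[i] == pytest.approx(float(rel @ conn_pos))
            assert out["C_neg"].iloc[i] == pytest.approx(float(rel @ conn_neg))

    def test_cohesion_bounded_by_extreme_correlations(self, rng):
        from scipy.stats import spearmanr

        vals = rng.gamma(2.0, 10.0, (12, 6))
        out = cohesion(table_from(vals))
        logged = np.log1p(vals) / np.log(10.0)
        rho = spearmanr(logged).statistic
        off = rho[~np.eye(6, dtype=bool)]
        assert out["C_pos"].max() <= max(off.max(), 0.0) + 1e-12
        assert abs(out["C_neg"].min()) <= abs(min(off.min(), 0.0)) + 1e-12


class TestAVD:
    def test_constant_species_excluded(self):
        vals = np.array([[5.0, 1.0], [5.0, 3.0], [5.0, 2.0]])
        with_const = avd(table_from(vals))
        without = avd(table_from(vals[:, [1]]))
        assert with_const == pytest.approx(without)

    def test_two_sites_hand_value(self):
        assert avd(table_from([[0.0], [2.0]])) == pytest.approx(0.707107, abs=1e-6)

    def test_standard_normal_limit(self):
        """Mean |z| of N(0,1) data converges to sqrt(2/pi)."""
        rng = np.random.default_rng(0)
        vals = rng.normal(10.0, 1.0, (10_000, 4)).clip(min=0.0)
        assert avd(table_from(vals)) == pytest.approx(math.sqrt(2 / math.pi), abs=0.02)

    def test_all_constant_missing(self):
        assert math.isnan(avd(table_from([[1.0, 2.0], [1.0, 2.0]])))


class TestRobustness:
    def test_complete_graph_half_removal(self):
        g = nx.complete_graph(10)
        assert robustness_random(g, 0.5, reps=50, seed=0) == pytest.approx(0.5)

    def test_star_loses_everything_without_hub(self):
        g = nx.star_graph(9)  # node 0 is the hub
        assert robustness_targeted(g, {0}) == pytest.approx(0.0)

    def test_targeted_removal_of_leaf_keeps_core(self):
        g = nx.star_graph(9)
        assert robustness_targeted(g, {5}) == pytest.approx(0.9)

    def test_monte_carlo_matches_exhaustive_average(self):
        rng = np.random.default_rng(11)
        for _ in range(8):
            g = random_graph(rng)
            k = g.number_of_nodes() // 2
            exact_mean, exact_sd = exhaustive_robustness(g, k)
            mc = robustness_random(g, 0.5, reps=2000, seed=5)
            tol = 4.0 * exact_sd / math.sqrt(2000) + 1e-9
            assert abs(mc - exact_mean) <= tol

    def test_convergence_spread_shrinks_with_reps(self):
        g = nx.gnp_random_graph(12, 0.3, seed=3)
        spread = []
        for reps in (250, 1000):
            vals = [robustness_random(g, 0.5, reps=reps, seed=s) for s in range(12)]
            spread.append(np.std(vals))
        assert spread[1] < spread[0]


class TestVulnerability:
    def test_path_graph_collapses_at_middle(self):
        assert vulnerability(nx.path_graph(3)) == pytest.approx(1.0)

    def test_complete_graph_immune(self):
        assert vulnerability(nx.complete_graph(4)) == pytest.approx(0.0)

    def test_matches_exhaustive_single_deletions(self):
        rng = np.random.default_rng(23)
        for _ in range(40):
            g = random_graph(rng)
            assert vulnerability(g) == pytest.approx(vulnerability_oracle(g), abs=1e-9)

    def test_too_small_graph_missing(self):
        assert math.isnan(vulnerability(nx.path_graph(2)))


class TestStabilityRecord:
    def test_record_is_complete_and_consistent(self, rng):
        table = random_table(rng, n_sites=10, n_species=8)
        g = build_network(table, rho_min=0.4)
        rec = stability_record(table, g, dominant_species=["sp0"], reps=100, seed=0)
        assert set(rec) == {
            "ICV", "C_pos", "C_neg", "C_total", "AVD",
            "Robustness_R", "Robustness_Y", "Vulnerability",
        }
        assert rec["C_total"] == pytest.approx(rec["C_pos"] + abs(rec["C_neg"]))
        assert rec["C_neg"] <= 0.0
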