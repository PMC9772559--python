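"""Network construction and stability, checked against brute-force oracles.

Every topology quantity (clustering, path distance, modularity, Zi-Pi,
efficiency-based vulnerability) is recomputed here from first principles
on small graphs and compared with the package implementation.
"""

import itertools

import networkx as nx
import numpy as np
import pandas as pd
import pytest

from soilmicro.io_core import AbundanceTable
from soilmicro.metabolic import GeneAbundance
from soilmicro.network import (
    CoNetwork,
    build_network,
    correlation_matrix,
    edge_domain_ratios,
    filter_taxa,
    highest_degree_node,
    rmt_threshold,
    robustness,
    taxon_gene_network,
    topology,
    vulnerability,
    zi_pi,
)


# ---------------------------------------------------------------------------
# brute-force oracles


def bf_shortest_paths(adj: np.ndarray) -> np.ndarray:
    """Floyd-Warshall on a 0/1 adjacency matrix."""
    n = adj.shape[0]
    dist = np.where(adj > 0, 1.0, np.inf)
    np.fill_diagonal(dist, 0.0)
    for k in range(n):
        for i in range(n):
            for j in range(n):
                dist[i, j] = min(dist[i, j], dist[i, k] + dist[k, j])
    return dist


def bf_avg_clustering(adj: np.ndarray) -> float:
    n = adj.shape[0]
    ccs = []
    for i in range(n):
        nbrs = np.where(adj[i] > 0)[0]
        k = len(nbrs)
        if k < 2:
            ccs.append(0.0)
            continue
        links = sum(adj[u, v] > 0 for u, v in itertools.combinations(nbrs, 2))
        ccs.append(2 * links / (k * (k - 1)))
    return float(np.mean(ccs))


def bf_gd(adj: np.ndarray) -> float:
    dist = bf_shortest_paths(adj)
    iu = np.triu_indices(adj.shape[0], k=1)
    finite = dist[iu][np.isfinite(dist[iu])]
    return float(finite.mean())


def bf_modularity(adj: np.ndarray, labels: np.ndarray) -> float:
    two_m = adj.sum()
    k = adj.sum(axis=1)
    q = 0.0
    n = adj.shape[0]
    for i in range(n):
        for j in range(n):
            if labels[i] == labels[j]:
                q += adj[i, j] - k[i] * k[j] / two_m
    return q / two_m


def bf_efficiency(adj: np.ndarray) -> float:
    n = adj.shape[0]
    if n < 2:
        return 0.0
    dist = bf_shortest_paths(adj)
    with np.errstate(divide="ignore"):
        inv = 1.0 / dist
    inv[~np.isfinite(inv)] = 0.0
    np.fill_diagonal(inv, 0.0)
    return float(inv.sum() / (n * (n - 1)))


def bf_vulnerability(adj: np.ndarray) -> float:
    e = bf_efficiency(adj)
    worst = -np.inf
    for i in range(adj.shape[0]):
        keep = np.arange(adj.shape[0]) != i
        worst = max(worst, (e - bf_efficiency(adj[np.ix_(keep, keep)])) / e)
    return float(worst)


def bf_zi_pi(adj: np.ndarray, labels: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    n = adj.shape[0]
    zi = np.zeros(n)
    pi = np.zeros(n)
    for i in range(n):
        within = [adj[j] @ (labels == labels[j]) for j in range(n) if labels[j] == labels[i]]
        mine = adj[i] @ (labels == labels[i])
        sd = np.std(within)
        zi[i] = (mine - np.mean(within)) / sd if sd > 0 else 0.0
        k = adj[i].sum()
        if k > 0:
            pi[i] = 1 - sum(
                (adj[i] @ (labels == m) / k) ** 2 for m in np.unique(labels)
            )
    return zi, pi


def net_from_edges(edges, all_nodes=None, weight=0.9):
    """Build a CoNetwork from an explicit edge list via a synthetic corr matrix."""
    nodes = sorted({n for e in edges for n in e} | set(all_nodes or []))
    idx = {n: i for i, n in enumerate(nodes)}
    r = np.eye(len(nodes))
    for u, v in edges:
        r[idx[u], idx[v]] = r[idx[v], idx[u]] = weight
    return build_network(pd.DataFrame(r, index=nodes, columns=nodes), threshold=0.8)


def adjacency_of(network: CoNetwork) -> tuple[np.ndarray, list]:
    nodes = list(network.graph.nodes)
    adj = nx.to_numpy_array(network.graph, nodelist=nodes, weight=None)
    return adj, nodes


# ---------------------------------------------------------------------------
# filtering and correlations


class TestFilterTaxa:
    def _table_with_fractions(self):
        # one sample of 100000 reads: fractions are exact
        counts = np.array([[20, 5, 10, 99965]])
        return AbundanceTable(("s1",), ("a", "b", "c", "big"), counts)

    def test_boundary_rules(self):
        table = self._table_with_fractions()
        kept = filter_taxa(table, 0.0001)
        assert "a" in kept.taxon_ids        # 0.02% retained
        assert "b" not in kept.taxon_ids    # 0.005% removed
        assert "c" not in kept.taxon_ids    # exactly 0.01% removed (strict)

    def test_empty_result_advises(self):
        table = AbundanceTable(("s1",), ("a",), np.array([[10]]))
        with pytest.raises(ValueError, match="threshold"):
            filter_taxa(table, 2.0)


class TestCorrelationMatrix:
    def _table(self, data):
        data = np.asarray(data)
        return AbundanceTable(
            tuple(f"s{i}" for i in range(data.shape[0])),
            tuple(f"t{j}" for j in range(data.shape[1])),
            data,
        )

    def test_unit_diagonal_and_proportional_pair(self):
        table = self._table([[10, 20, 5], [20, 40, 3], [40, 80, 9], [80, 160, 2]])
        r = correlation_matrix(table)
        assert r.loc["t0", "t0"] == pytest.approx(1.0)
        # t1 = 2 * t0 -> identical relative-abundance profiles after log
        assert r.loc["t0", "t1"] == pytest.approx(1.0)

    def test_matches_direct_pearson_on_log_abundances(self):
        data = np.array([[10, 5, 100], [20, 3, 80], [5, 9, 120], [15, 2, 90]])
        table = self._table(data)
        r = correlation_matrix(table)
        ra = data / data.sum(axis=1, keepdims=True)
        logged = np.log10(ra)
        expected = np.corrcoef(logged[:, 0], logged[:, 1])[0, 1]
        assert r.loc["t0", "t1"] == pytest.approx(expected)

    def test_zero_variance_taxon_dropped(self):
        data = np.array([[10, 5], [10, 3], [10, 9], [10, 2]])
        # t0 has constant relative abundance only if totals equal; force it
        data = np.array([[10, 5], [10, 5], [10, 5], [10, 5]])
        r = correlation_matrix(self._table(data))
        assert r.shape[0] < 2 or not r.isna().any().any()

    def test_too_few_samples_rejected(self):
        with pytest.raises(ValueError, match="4 samples"):
            correlation_matrix(self._table([[1, 2], [3, 4], [5, 6]]))


class TestRMTThreshold:
    def test_noise_matrix_low_threshold(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=(60, 80))  # independent data -> weak correlations
        r = np.corrcoef(x, rowvar=False)
        s = rmt_threshold(r)
        assert s <= 0.5

    def test_block_structure_preserved(self):
        rng = np.random.default_rng(1)
        base = rng.normal(size=(40, 4))
        noise = rng.normal(scale=0.4, size=(40, 40))
        x = np.repeat(base, 10, axis=1) + noise  # 4 modules of 10 taxa
        r = np.corrcoef(x, rowvar=False)
        within = np.median([r[i, j] for b in range(4) for i in range(b * 10, b * 10 + 10)
                            for j in range(i + 1, b * 10 + 10)])
        s = rmt_threshold(r)
        assert s < within  # threshold keeps within-block edges

    def test_degenerate_spectrum_falls_back(self, caplog):
        r = np.eye(25)
        s = rmt_threshold(r, fallback=0.80)
        assert s == pytest.approx(0.80)

    def test_too_small_matrix_rejected(self):
        with pytest.raises(ValueError, match="20 taxa"):
            rmt_threshold(np.eye(10))


# ---------------------------------------------------------------------------
# construction and topology


class TestBuildNetwork:
    def test_single_positive_edge(self):
        r = pd.DataFrame([[1, 0.9], [0.9, 1]], index=["a", "b"], columns=["a", "b"])
        net = build_network(r, 0.8)
        assert net.n_edges == 1
        assert net.graph["a"]["b"]["sign"] == 1

    def test_negative_edge_sign(self):
        r = pd.DataFrame([[1, -0.9], [-0.9, 1]], index=["a", "b"], columns=["a", "b"])
        net = build_network(r, 0.8)
        assert net.graph["a"]["b"]["sign"] == -1

    def test_disconnected_triangles_give_two_modules(self):
        edges = [("a", "b"), ("b", "c"), ("a", "c"), ("x", "y"), ("y", "z"), ("x", "z")]
        net = net_from_edges(edges)
        assert len(set(net.modules.values())) == 2

    def test_isolated_nodes_dropped(self):
        r = np.eye(3)
        r[0, 1] = r[1, 0] = 0.9
        df = pd.DataFrame(r, index=list("abc"), columns=list("abc"))
        net = build_network(df, 0.8)
        assert "c" not in net.graph

    def test_edgeless_rejected(self):
        df = pd.DataFrame(np.eye(3), index=list("abc"), columns=list("abc"))
        with pytest.raises(ValueError, match="no edges"):
            build_network(df, 0.8)


class TestTopology:
    def test_complete_graph_k4(self):
        net = net_from_edges([(f"n{i}", f"n{j}") for i in range(4) for j in range(i + 1, 4)])
        topo = topology(net)
        assert topo.avg_clustering == pytest.approx(1.0)
        assert topo.avg_path_distance == pytest.approx(1.0)
        assert topo.positive_fraction == pytest.approx(1.0)

    def test_path_graph_hand_computed(self):
        net = net_from_edges([("a", "b"), ("b", "c")])
        topo = topology(net)
        assert topo.avg_clustering == pytest.approx(0.0)
        assert topo.avg_path_distance == pytest.approx((1 + 1 + 2) / 3)

    @pytest.mark.parametrize("seed", [0, 1, 2, 3, 4])
    def test_matches_brute_force_on_random_graphs(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(6, 13))
        g = nx.gnp_random_graph(n, 0.45, seed=seed)
        if g.number_of_edges() == 0:
            pytest.skip("empty random graph")
        edges = [(f"n{u}", f"n{v}") for u, v in g.edges]
        net = net_from_edges(edges, all_nodes=[f"n{i}" for i in range(n)])
        adj, nodes = adjacency_of(net)
        topo = topology(net)
        assert topo.avg_clustering == pytest.approx(bf_avg_clustering(adj))
        assert topo.avg_path_distance == pytest.approx(bf_gd(adj))
        labels = np.array([net.modules[x] for x in nodes])
        assert topo.modularity == pytest.approx(bf_modularity(adj, labels))


class TestZiPi:
    def test_all_links_inside_module_pi_zero(self):
        net = net_from_edges([("a", "b"), ("b", "c"), ("a", "c")])
        roles = {r.node: r for r in zi_pi(net)}
        assert all(r.pi == pytest.approx(0.0) for r in roles.values())

    def test_even_split_pi_half(self):
        # two triangles joined by one node's two bridges
        edges = [("a", "b"), ("b", "c"), ("a", "c"), ("x", "y"), ("y", "z"), ("x", "z"),
                 ("hub", "a"), ("hub", "x")]
        net = net_from_edges(edges)
        roles = {r.node: r for r in zi_pi(net)}
        assert roles["hub"].pi == pytest.approx(0.5)

    def test_uniform_within_degree_gives_zero_zi(self):
        net = net_from_edges([(f"n{i}", f"n{j}") for i in range(4) for j in range(i + 1, 4)])
        assert all(r.zi == 0.0 for r in zi_pi(net))

    def test_degree_conservation_and_brute_force(self):
        rng = np.random.default_rng(7)
        g = nx.gnp_random_graph(11, 0.4, seed=7)
        edges = [(f"n{u}", f"n{v}") for u, v in g.edges]
        net = net_from_edges(edges)
        adj, nodes = adjacency_of(net)
        labels = np.array([net.modules[x] for x in nodes])
        zi_bf, pi_bf = bf_zi_pi(adj, labels)
        roles = {r.node: r for r in zi_pi(net)}
        for i, x in enumerate(nodes):
            assert roles[x].zi == pytest.approx(zi_bf[i])
            assert roles[x].pi == pytest.approx(pi_bf[i])

    def test_keystone_set_shrinks_with_thresholds(self):
        rng = np.random.default_rng(3)
        g = nx.gnp_random_graph(12, 0.5, seed=3)
        net = net_from_edges([(f"n{u}", f"n{v}") for u, v in g.edges])
        roles = zi_pi(net)
        loose = {r.node for r in roles if r.zi >= 1.0 or r.pi >= 0.3}
        strict = {r.node for r in roles if r.zi >= 2.5 or r.pi >= 0.62}
        assert strict <= loose


class TestRobustness:
    def test_complete_k10_exactly_half_zero_variance(self):
        net = net_from_edges(
            [(f"n{i}", f"n{j}") for i in range(10) for j in range(i + 1, 10)]
        )
        mean, sd = robustness(net, 0.5, iterations=50, seed=0)
        assert mean == pytest.approx(0.5)
        assert sd == pytest.approx(0.0)

    def test_star_graph_matches_enumeration(self):
        # hub + 9 leaves; removing 5 of 10 nodes: hub removed (p=1/2) -> total
        # collapse; hub kept -> hub + 4 leaves survive.  Expected mean 0.25.
        net = net_from_edges([("hub", f"leaf{i}") for i in range(9)])
        mean, _ = robustness(net, 0.5, iterations=800, seed=1)
        assert mean == pytest.approx(0.25, abs=0.02)
        assert mean < 0.5

    def test_seeded_reproducibility(self):
        net = net_from_edges([("a", "b"), ("b", "c"), ("c", "d"), ("d", "a")])
        assert robustness(net, 0.5, 20, seed=5) == robustness(net, 0.5, 20, seed=5)


class TestVulnerability:
    def test_complete_graph_zero(self):
        net = net_from_edges([(f"n{i}", f"n{j}") for i in range(4) for j in range(i + 1, 4)])
        assert vulnerability(net) == pytest.approx(0.0)

    def test_path_cut_vertex(self):
        net = net_from_edges([("a", "b"), ("b", "c")])
        # removing b disconnects everything: V_b = (E - 0)/E = 1
        assert vulnerability(net) == pytest.approx(1.0)

    def test_star_hub_is_maximal_and_matches_brute_force(self):
        net = net_from_edges([("hub", f"l{i}") for i in range(5)])
        adj, nodes = adjacency_of(net)
        assert vulnerability(net) == pytest.approx(bf_vulnerability(adj))

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_matches_brute_force_on_random_graphs(self, seed):
        g = nx.gnp_random_graph(9, 0.35, seed=seed)
        if g.number_of_edges() == 0:
            pytest.skip("empty graph")
        net = net_from_edges([(f"n{u}", f"n{v}") for u, v in g.edges])
        adj, _ = adjacency_of(net)
        assert vulnerability(net) == pytest.approx(bf_vulnerability(adj))

    def test_cut_vertex_strictly_positive(self):
        net = net_from_edges([("a", "b"), ("b", "c"), ("a", "c"), ("c", "d"), ("d", "e"), ("e", "c")])
        assert vulnerability(net) > 0


class TestDomainRatios:
    def _tagged_net(self, edges, domains, signs=None):
        g = nx.Graph()
        for k, (u, v) in enumerate(edges):
            s = 1 if signs is None else signs[k]
            g.add_edge(u, v, weight=0.9 * s, sign=s)
        modules = {n: 0 for n in g}
        return CoNetwork(g, 0.8, modules, domains)

    def test_all_positive_mixed(self):
        net = self._tagged_net(
            [("b1", "b2"), ("f1", "f2"), ("b1", "f1")],
            {"b1": "bacteria", "b2": "bacteria", "f1": "fungi", "f2": "fungi"},
        )
        ratios = edge_domain_ratios(net)
        assert ratios == {"B-B": 1.0, "F-F": 1.0, "B-F": 1.0}

    def test_missing_classes_undefined(self):
        net = self._tagged_net(
            [("b1", "b2")], {"b1": "bacteria", "b2": "bacteria"}
        )
        ratios = edge_domain_ratios(net)
        assert ratios["B-B"] == 1.0
        assert np.isnan(ratios["F-F"]) and np.isnan(ratios["B-F"])

    def test_hand_counted_six_edge_toy(self):
        domains = {"b1": "bacteria", "b2": "bacteria", "b3": "bacteria",
                   "f1": "fungi", "f2": "fungi"}
        edges = [("b1", "b2"), ("b2", "b3"), ("b1", "b3"),
                 ("f1", "f2"), ("b1", "f1"), ("b2", "f2")]
        signs = [1, 1, -1, -1, 1, -1]
        net = self._tagged_net(edges, domains, signs)
        ratios = edge_domain_ratios(net)
        assert ratios["B-B"] == pytest.approx(2 / 3)
        assert ratios["F-F"] == pytest.approx(0.0)
        assert ratios["B-F"] == pytest.approx(1 / 2)


class TestTaxonGeneNetwork:
    def _inputs(self):
        rng = np.random.default_rng(0)
        base = rng.lognormal(0, 0.5, size=8)
        counts = np.column_stack([
            (base * 300).astype(int) + 1,          # genus g0
            ((1 / base) * 200).astype(int) + 1,    # genus g1, anti-correlated
            rng.integers(50, 60, 8),
        ])
        table = AbundanceTable(tuple(f"s{i}" for i in range(8)), ("g0", "g1", "gX"), counts)
        copies = pd.DataFrame(
            {f"s{i}": [base[i] * 1e4, 5e4] for i in range(8)},
            index=["geneA", "geneB"],
        )
        genes = GeneAbundance(copies, {"geneA": "C", "geneB": "N"})
        return table, genes

    def test_proportional_gene_positive_edge(self):
        table, genes = self._inputs()
        net = taxon_gene_network(table, genes, threshold=0.8)
        assert net.graph.has_edge("g0", "geneA")
        assert net.graph["g0"]["geneA"]["sign"] == 1

    def test_anticorrelated_excluded_by_default_kept_with_all(self):
        table, genes = self._inputs()
        net = taxon_gene_network(table, genes, threshold=0.8)
        assert not net.graph.has_edge("g1", "geneA")
        net_all = taxon_gene_network(table, genes, threshold=0.8, keep="all")
        assert net_all.graph.has_edge("g1", "geneA")
        assert net_all.graph["g1"]["geneA"]["sign"] == -1

    def test_highest_degree_taxon_reported(self):
        table, genes = self._inputs()
        net = taxon_gene_network(table, genes, threshold=0.8, keep="all")
        top = highest_degree_node(net, domain="taxon")
        assert net.domains[top] == "taxon"
        taxon_degrees = [
            net.graph.degree(n) for n in net.graph if net.domains[n] == "taxon"
        ]
        assert net.graph.degree(top) == max(taxon_degrees)

    def test_too_few_shared_samples_rejected(self):
        table, genes = self._inputs()
        small = table.select_samples(["s0", "s1", "s2"])
        with pytest.raises(ValueError, match="shared"):
            taxon_gene_network(small, genes, threshold=0.8)
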