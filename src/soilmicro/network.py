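"""Co-occurrence network construction, topology, keystones and stability.

Networks are built MENA-style: taxa above a 0.01% mean relative-abundance
filter are correlated (Pearson, on log10 relative abundances with
half-minimum zero replacement), the similarity threshold s* is chosen by a
random-matrix-theory scan (smallest threshold whose nearest-neighbour
eigenvalue spacing distribution is Poisson-consistent), and edges keep
their correlation sign.  Downstream: topology indices (avgCC, GD,
modularity), Zi-Pi keystone roles, robustness under random 50% node removal
and vulnerability as maximal global-efficiency loss, interdomain
(bacteria-fungi) edge accounting, and bipartite taxon-gene networks.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field
from typing import Mapping

import networkx as nx
import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy import stats
from scipy.sparse import csgraph

from .io_core import AbundanceTable
from .metabolic import GeneAbundance

logger = logging.getLogger("soilmicro")

__all__ = [
    "CoNetwork",
    "TopologyReport",
    "NodeRole",
    "StabilityReport",
    "filter_taxa",
    "correlation_matrix",
    "rmt_threshold",
    "build_network",
    "topology",
    "zi_pi",
    "robustness",
    "vulnerability",
    "edge_domain_ratios",
    "taxon_gene_network",
]

# Guimera-Amaral role cutoffs used to flag keystone taxa
ZI_CUTOFF = 2.5
PI_CUTOFF = 0.62


@dataclass
class CoNetwork:
    """Signed, thresholded correlation graph with a module partition."""

    graph: nx.Graph
    threshold: float
    modules: dict[str, int]
    domains: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if any(u == v for u, v in self.graph.edges):
            raise ValueError("self-loops are not allowed")
        for u, v, d in self.graph.edges(data=True):
            if abs(d["weight"]) < self.threshold - 1e-12:
                raise ValueError(
                    f"edge ({u},{v}) weight {d['weight']} below threshold {self.threshold}"
                )
        uncovered = {n for n in self.graph if self.graph.degree(n) > 0} - set(self.modules)
        if uncovered:
            raise ValueError(f"non-isolated nodes without module: {sorted(uncovered)[:5]}")

    @property
    def n_nodes(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    def positive_fraction(self) -> float:
        signs = [d["sign"] for _, _, d in self.graph.edges(data=True)]
        return float(np.mean([s > 0 for s in signs])) if signs else float("nan")


@dataclass(frozen=True)
class TopologyReport:
    n_nodes: int
    n_edges: int
    positive_fraction: float
    avg_clustering: float
    avg_path_distance: float
    modularity: float

    def to_dict(self) -> dict[str, float]:
        return {
            "nodes": self.n_nodes,
            "edges": self.n_edges,
            "positive_fraction": self.positive_fraction,
            "avgCC": self.avg_clustering,
            "GD": self.avg_path_distance,
            "modularity": self.modularity,
        }


@dataclass(frozen=True)
class NodeRole:
    node: str
    zi: float
    pi: float
    role: str
    keystone: bool


@dataclass(frozen=True)
class StabilityReport:
    robustness_mean: float
    robustness_sd: float
    vulnerability: float
    iterations: int
    removal_fraction: float
    seed: int | None


# ---------------------------------------------------------------------------
# construction


def filter_taxa(
    table: AbundanceTable, min_mean_relative_abundance: float = 0.0001
) -> AbundanceTable:
    """Keep taxa with mean relative abundance strictly above the cutoff."""
    mean_ra = table.mean_relative_abundance()
    keep = [t for t, p in zip(table.taxon_ids, mean_ra) if p > min_mean_relative_abundance]
    if not keep:
        raise ValueError(
            f"no taxa above mean relative abundance {min_mean_relative_abundance}; "
            "lower the threshold"
        )
    return table.select_taxa(keep)


def correlation_matrix(table: AbundanceTable) -> pd.DataFrame:
    """Pearson correlations between taxa on log10 relative abundances.

    Zeros are replaced by half the smallest positive relative abundance in
    the table before the log; taxa with zero variance across samples are
    dropped with a warning (their correlation is undefined).
    """
    if table.n_samples < 4:
        raise ValueError("need >= 4 samples for meaningful correlations")
    ra = table.relative_abundance()
    positive = ra[ra > 0]
    if positive.size == 0:
        raise ValueError("table has no positive counts")
    ra = np.where(ra > 0, ra, positive.min() / 2.0)
    logged = np.log10(ra)
    keep = logged.std(axis=0) > 0
    if not keep.all():
        dropped = [t for t, k in zip(table.taxon_ids, keep) if not k]
        logger.warning("dropping %d zero-variance taxa: %s", len(dropped), dropped[:5])
    taxa = [t for t, k in zip(table.taxon_ids, keep) if k]
    r = np.corrcoef(logged[:, keep], rowvar=False)
    np.fill_diagonal(r, 1.0)
    return pd.DataFrame(r, index=taxa, columns=taxa)


def _nnsd_poisson_pvalue(eigvals: np.ndarray, n_bins: int | None = None) -> float | None:
    """Chi-square goodness of fit of the NNSD against the Poisson form e^-s.

    Eigenvalues are unfolded by a smooth (polynomial) fit to the empirical
    spectral CDF, so mean spacing is 1.  Returns None when the spectrum is
    too degenerate to test.
    """
    lam = np.sort(eigvals)
    uniq = lam[np.concatenate(([True], np.diff(lam) > 1e-8))]
    n = uniq.size
    if n < 30:
        return None
    cdf = (np.arange(n) + 0.5) / n
    scale = uniq[-1] - uniq[0]
    if scale <= 0:
        return None
    x = (uniq - uniq[0]) / scale
    coeff = np.polyfit(x, cdf, deg=5)
    unfolded = n * np.polyval(coeff, x)
    spacings = np.diff(np.sort(unfolded))
    spacings = spacings[spacings > 0]
    if spacings.size < 20:
        return None
    spacings = spacings / spacings.mean()
    if n_bins is None:
        n_bins = int(np.clip(spacings.size // 10, 4, 10))
    # equal-probability bins under Exp(1)
    edges = np.append(-np.log(1.0 - np.arange(n_bins) / n_bins), np.inf)
    observed, _ = np.histogram(spacings, bins=edges)
    expected = spacings.size / n_bins
    chi2 = float(np.sum((observed - expected) ** 2 / expected))
    return float(stats.chi2.sf(chi2, df=n_bins - 1))


def rmt_threshold(
    corr: pd.DataFrame | np.ndarray,
    scan_min: float = 0.30,
    scan_max: float = 0.95,
    scan_step: float = 0.01,
    alpha: float = 0.05,
    fallback: float = 0.80,
) -> float:
    """Random-matrix-theory similarity threshold.

    Scans candidate thresholds; at each, entries with |r| below the
    candidate are zeroed and the nearest-neighbour spacing distribution of
    the eigenvalue spectrum is tested against the Poisson form.  The
    smallest Poisson-consistent threshold (p > alpha) is returned; if the
    scan is exhausted or every spectrum is degenerate, the configured
    fallback is returned with a warning.
    """
    r = corr.to_numpy() if isinstance(corr, pd.DataFrame) else np.asarray(corr, dtype=float)
    if r.shape[0] < 20:
        raise ValueError(f"need >= 20 taxa for a meaningful spectrum, got {r.shape[0]}")
    thresholds = np.arange(scan_min, scan_max + scan_step / 2, scan_step)
    for s in thresholds:
        m = np.where(np.abs(r) >= s, r, 0.0)
        np.fill_diagonal(m, 1.0)
        eig = np.linalg.eigvalsh(m)
        p = _nnsd_poisson_pvalue(eig)
        if p is not None and p > alpha:
            return float(round(s, 10))
    logger.warning(
        "RMT scan [%g, %g] found no Poisson-consistent threshold; using fallback %g",
        scan_min, scan_max, fallback,
    )
    return float(fallback)


def build_network(
    corr: pd.DataFrame,
    threshold: float,
    domains: Mapping[str, str] | None = None,
) -> CoNetwork:
    """Thresholded signed graph with greedy-modularity module partition.

    Edges keep the correlation as ``weight`` and its sign as ``sign``;
    isolated nodes are dropped.  Community detection is deterministic
    (greedy modularity maximisation), so networks are reproducible.
    """
    if not 0 < threshold < 1:
        raise ValueError(f"threshold must lie in (0, 1), got {threshold}")
    r = corr.to_numpy()
    taxa = list(corr.index)
    g = nx.Graph()
    for i, j in zip(*np.where(np.triu(np.abs(r) >= threshold, k=1))):
        w = float(r[i, j])
        g.add_edge(taxa[i], taxa[j], weight=w, sign=1 if w > 0 else -1)
    if g.number_of_edges() == 0:
        raise ValueError(f"no edges at threshold {threshold}; graph would be empty")
    modules = _detect_modules(g)
    dom = {n: domains[n] for n in g if domains and n in domains} if domains else {}
    return CoNetwork(g, threshold, modules, dom)


def _detect_modules(g: nx.Graph) -> dict[str, int]:
    """Greedy-modularity partition with a canonical, hash-independent order.

    Communities come back as frozensets; module ids are assigned by
    (size desc, smallest member) and members enumerated sorted, so the
    partition and all downstream iteration orders are reproducible across
    processes.
    """
    communities = [
        sorted(c, key=str)
        for c in nx.community.greedy_modularity_communities(g, weight=None)
    ]
    communities.sort(key=lambda c: (-len(c), str(c[0])))
    return {n: k for k, comm in enumerate(communities) for n in comm}


# ---------------------------------------------------------------------------
# topology


def topology(network: CoNetwork) -> TopologyReport:
    """avgCC, GD (mean shortest path over connected pairs), modularity."""
    g = network.graph
    if g.number_of_edges() == 0:
        raise ValueError("network has no edges")
    avg_cc = float(np.mean(list(nx.clustering(g).values())))
    total, n_pairs = 0.0, 0
    components = list(nx.connected_components(g))
    if len(components) > 1:
        logger.info(
            "graph is disconnected (%d components); GD averaged over connected pairs",
            len(components),
        )
    for comp in components:
        if len(comp) < 2:
            continue
        for _, dists in nx.all_pairs_shortest_path_length(g.subgraph(comp)):
            total += sum(dists.values())
            n_pairs += len(dists) - 1
    gd = total / n_pairs if n_pairs else float("nan")
    communities: dict[int, list] = {}
    for n, m in network.modules.items():  # modules dict is canonically ordered
        communities.setdefault(m, []).append(n)
    # unweighted modularity (MENA convention); integer sums are exact
    mod = float(nx.community.modularity(g, communities.values(), weight=None))
    return TopologyReport(
        n_nodes=g.number_of_nodes(),
        n_edges=g.number_of_edges(),
        positive_fraction=network.positive_fraction(),
        avg_clustering=avg_cc,
        avg_path_distance=float(gd),
        modularity=mod,
    )


# ---------------------------------------------------------------------------
# Zi-Pi keystone roles


def zi_pi(network: CoNetwork) -> list[NodeRole]:
    """Within-module degree z-score and among-module connectivity.

    Zi standardises a node's within-module degree against its module
    (modules with no degree variance give Zi = 0); Pi = 1 - sum over
    modules of (k_i,m / k_i)^2.  Nodes with Zi >= 2.5 are module/network
    hubs, Pi >= 0.62 connectors; either flags a keystone.
    """
    g, modules = network.graph, network.modules
    if not modules:
        raise ValueError("module partition required; run build_network first")
    within_degree = {
        n: sum(1 for nb in g.neighbors(n) if modules[nb] == modules[n]) for n in modules
    }
    by_module: dict[int, list[int]] = {}
    for n, m in modules.items():
        by_module.setdefault(m, []).append(within_degree[n])
    mod_mean = {m: float(np.mean(v)) for m, v in by_module.items()}
    mod_sd = {m: float(np.std(v)) for m, v in by_module.items()}
    roles = []
    for n in modules:
        sd = mod_sd[modules[n]]
        zi = (within_degree[n] - mod_mean[modules[n]]) / sd if sd > 0 else 0.0
        k = g.degree(n)
        k_by_mod: dict[int, int] = {}
        for nb in g.neighbors(n):
            k_by_mod[modules[nb]] = k_by_mod.get(modules[nb], 0) + 1
        pi = 1.0 - sum((km / k) ** 2 for km in k_by_mod.values()) if k > 0 else 0.0
        hub, connector = zi >= ZI_CUTOFF, pi >= PI_CUTOFF
        role = (
            "network hub" if hub and connector
            else "module hub" if hub
            else "connector" if connector
            else "peripheral"
        )
        roles.append(NodeRole(n, float(zi), float(pi), role, hub or connector))
    return roles


# ---------------------------------------------------------------------------
# stability


def robustness(
    network: CoNetwork,
    removal_fraction: float = 0.5,
    iterations: int = 100,
    seed: int | None = None,
) -> tuple[float, float]:
    """Surviving node fraction after random removal with secondary pruning.

    Each iteration removes ``floor(f * n)`` uniformly chosen nodes, then
    repeatedly deletes survivors left without any edge; robustness is the
    surviving fraction of the original n.  Returns (mean, sd) over
    iterations.
    """
    g = network.graph
    n = g.number_of_nodes()
    if n < 4:
        raise ValueError("need >= 4 nodes")
    if g.number_of_edges() == 0:
        raise ValueError("network has no edges")
    rng = np.random.default_rng(seed)
    nodes = np.array(list(g.nodes))
    n_remove = int(np.floor(removal_fraction * n))
    fractions = np.empty(iterations)
    for it in range(iterations):
        removed = rng.choice(nodes, size=n_remove, replace=False)
        h = g.copy()
        h.remove_nodes_from(removed)
        while True:
            dead = [x for x, d in h.degree() if d == 0]
            if not dead:
                break
            h.remove_nodes_from(dead)
        fractions[it] = h.number_of_nodes() / n
    return float(fractions.mean()), float(fractions.std(ddof=1 if iterations > 1 else 0))


def _efficiency_from_adjacency(adj: "sp.spmatrix") -> float:
    """Mean over ordered node pairs of 1/shortest-path (0 if disconnected)."""
    n = adj.shape[0]
    if n < 2:
        return 0.0
    dist = csgraph.shortest_path(adj, method="D", unweighted=True, directed=False)
    with np.errstate(divide="ignore"):
        inv = 1.0 / dist
    inv[~np.isfinite(inv)] = 0.0
    np.fill_diagonal(inv, 0.0)
    return float(inv.sum() / (n * (n - 1)))


def _global_efficiency(g: nx.Graph) -> float:
    return _efficiency_from_adjacency(nx.to_scipy_sparse_array(g, weight=None))


def vulnerability(network: CoNetwork) -> float:
    """Maximal relative global-efficiency loss over single-node deletions.

    V_i = (E - E_-i) / E with E the mean inverse shortest-path length over
    ordered pairs; the network's vulnerability is max_i V_i.
    """
    g = network.graph
    n = g.number_of_nodes()
    if n < 3:
        raise ValueError("need >= 3 nodes")
    adj = nx.to_scipy_sparse_array(g, weight=None, format="csr")
    e_full = _efficiency_from_adjacency(adj)
    if e_full == 0:
        raise ValueError("graph has no connected pairs")
    worst = -np.inf
    for i in range(n):
        keep = np.arange(n) != i
        worst = max(
            worst, (e_full - _efficiency_from_adjacency(adj[keep][:, keep])) / e_full
        )
    return float(worst)


def stability(
    network: CoNetwork,
    removal_fraction: float = 0.5,
    iterations: int = 100,
    seed: int | None = None,
) -> StabilityReport:
    """Bundle robustness and vulnerability into one report."""
    rob_mean, rob_sd = robustness(network, removal_fraction, iterations, seed)
    return StabilityReport(
        rob_mean, rob_sd, vulnerability(network), iterations, removal_fraction, seed
    )


# ---------------------------------------------------------------------------
# interdomain accounting and taxon-gene networks


def edge_domain_ratios(network: CoNetwork) -> dict[str, float]:
    """Positive-edge fraction within B-B, F-F and B-F edge classes.

    Nodes must carry domain tags ('bacteria' or 'fungi'); classes without
    edges come back as NaN (undefined).
    """
    if not network.domains:
        raise ValueError("network has no domain tags")
    counts = {"B-B": [0, 0], "F-F": [0, 0], "B-F": [0, 0]}
    key = {"bacteria": "B", "fungi": "F"}
    for u, v, d in network.graph.edges(data=True):
        du, dv = key.get(network.domains.get(u, "")), key.get(network.domains.get(v, ""))
        if du is None or dv is None:
            continue
        cls = f"{du}-{dv}" if du == dv else "B-F"
        counts[cls][1] += 1
        if d["sign"] > 0:
            counts[cls][0] += 1
    return {
        cls: (pos / tot if tot else float("nan")) for cls, (pos, tot) in counts.items()
    }


def taxon_gene_network(
    taxa_table: AbundanceTable,
    genes: GeneAbundance,
    threshold: float,
    keep: str = "positive",
) -> CoNetwork:
    """Bipartite co-occurrence network between taxa and functional genes.

    Taxon abundances are log10 relative abundances and gene copies log10
    with half-minimum zero replacement, matching the taxon-taxon networks.
    By default only positive correlations at or above the threshold become
    edges (``keep='all'`` retains negative ones too).
    """
    if keep not in ("positive", "all"):
        raise ValueError("keep must be 'positive' or 'all'")
    shared = [s for s in taxa_table.sample_ids if s in genes.copies.columns]
    if len(shared) < 4:
        raise ValueError(f"need >= 4 shared samples, got {len(shared)}")
    sub = taxa_table.select_samples(shared)
    ra = sub.relative_abundance()
    ra = np.where(ra > 0, ra, ra[ra > 0].min() / 2.0)
    taxa_log = np.log10(ra)
    gm = genes.copies[shared].to_numpy(dtype=float).T  # samples x genes
    pos = gm[gm > 0]
    if pos.size == 0:
        raise ValueError("gene abundance matrix is all zero")
    gene_log = np.log10(np.where(gm > 0, gm, pos.min() / 2.0))
    taxa_ok = taxa_log.std(axis=0) > 0
    gene_ok = gene_log.std(axis=0) > 0
    taxa_ids = [t for t, k in zip(sub.taxon_ids, taxa_ok) if k]
    gene_ids = [g for g, k in zip(genes.copies.index, gene_ok) if k]
    tl, gl = taxa_log[:, taxa_ok], gene_log[:, gene_ok]
    tl = (tl - tl.mean(0)) / tl.std(0)
    gl = (gl - gl.mean(0)) / gl.std(0)
    r = tl.T @ gl / tl.shape[0]  # taxa x genes Pearson
    g = nx.Graph()
    for i, j in itertools.product(range(len(taxa_ids)), range(len(gene_ids))):
        w = float(r[i, j])
        if (keep == "positive" and w >= threshold) or (
            keep == "all" and abs(w) >= threshold
        ):
            g.add_edge(taxa_ids[i], gene_ids[j], weight=w, sign=1 if w > 0 else -1)
    if g.number_of_edges() == 0:
        raise ValueError(f"no taxon-gene edges at threshold {threshold}")
    modules = _detect_modules(g)
    domains = {n: ("gene" if n in set(gene_ids) else "taxon") for n in g}
    return CoNetwork(g, threshold, modules, domains)


def highest_degree_node(network: CoNetwork, domain: str | None = None) -> str:
    """Node with the most edges, optionally restricted to one domain tag."""
    nodes = [
        n for n in network.graph
        if domain is None or network.domains.get(n) == domain
    ]
    if not nodes:
        raise ValueError(f"no nodes with domain {domain!r}")
    return max(nodes, key=lambda n: (network.graph.degree(n), str(n)))
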