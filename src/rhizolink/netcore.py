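"""Core-microbiome identification via co-occurrence network centrality.

The procedure mirrors common practice in rhizosphere studies: (1) filter
core *candidates* by prevalence (present in >= 75% of samples) and mean
relative abundance (> 0.01%); (2) estimate pairwise taxon correlations,
either rank-based (Spearman) or compositional (SparCC); (3) keep edges
with |r| above a threshold and p below a cutoff; (4) summarize the graph
(degree, path length, clustering, modularity); (5) rank candidates by a
composite of degree, closeness and betweenness centrality and call the
top-k the core taxa.

Spearman is the default estimator for the core pipeline; SparCC is
selectable for compositionally-aware correlation on count tables.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from .tables_io import TaxonAbundanceTable, to_relative

__all__ = [
    "CorrelationMatrix",
    "CooccurrenceNetwork",
    "NetworkStats",
    "CoreTaxaRanking",
    "core_candidates",
    "spearman_matrix",
    "sparcc_matrix",
    "build_network",
    "network_stats",
    "centralities",
    "rank_core_taxa",
]


@dataclass
class CorrelationMatrix:
    taxon_ids: list[str]
    r: np.ndarray  # symmetric, diagonal 1
    p: np.ndarray  # symmetric, diagonal ignored
    method: str
    flagged: list[str] = field(default_factory=list)  # taxa with undefined correlations

    def __post_init__(self) -> None:
        r = np.asarray(self.r, dtype=float)
        if not np.allclose(r, r.T, atol=1e-10):
            raise ValueError("correlation matrix must be symmetric")
        if (np.abs(r) > 1 + 1e-9).any():
            raise ValueError("correlations must lie in [-1, 1]")
        self.r = np.clip((r + r.T) / 2.0, -1.0, 1.0)
        np.fill_diagonal(self.r, 1.0)
        self.p = np.asarray(self.p, dtype=float)


@dataclass
class CooccurrenceNetwork:
    graph: nx.Graph  # nodes = taxa; edges carry r and p
    r_min: float
    p_max: float

    @property
    def n_nodes(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    def edge_table(self) -> pd.DataFrame:
        rows = [
            {"taxon_a": a, "taxon_b": b, "r": d["r"], "p": d["p"]}
            for a, b, d in self.graph.edges(data=True)
        ]
        return pd.DataFrame(rows, columns=["taxon_a", "taxon_b", "r", "p"])


@dataclass
class NetworkStats:
    n_nodes: int
    n_edges: int
    average_degree: float
    average_path_length: float
    clustering_coefficient: float
    global_transitivity: float
    modularity: float
    n_components: int

    def to_dict(self) -> dict:
        return dict(self.__dict__)


@dataclass
class CoreTaxaRanking:
    table: pd.DataFrame  # index taxon; degree, closeness, betweenness, composite_rank
    selected: list[str]
    k: int


def core_candidates(
    table: TaxonAbundanceTable,
    prevalence_min: float = 0.75,
    abundance_min: float = 1e-4,
) -> list[str]:
    """Core-candidate taxa: prevalence >= prevalence_min (inclusive) AND
    mean relative abundance strictly > abundance_min.

    Prevalence is the fraction of samples where the taxon is detected
    (abundance > 0); abundance_min defaults to 0.01% on the fraction scale.
    """
    rel = to_relative(table)
    v = rel.values
    prevalence = (v > 0).mean(axis=1)
    mean_abund = v.mean(axis=1)
    keep = (prevalence >= prevalence_min) & (mean_abund > abundance_min)
    result = [t for t, k in zip(rel.taxon_ids, keep) if k]
    if not result:
        warnings.warn("no taxa pass the core-candidate filters", RuntimeWarning)
    return result


def spearman_matrix(
    table: TaxonAbundanceTable, taxa_subset: list[str] | None = None
) -> CorrelationMatrix:
    """Pairwise Spearman correlations (average-rank ties) with two-sided
    t-distribution p-values; |r| = 1 gets p = 0.

    Constant taxon vectors have undefined correlation; these get r = 0,
    p = 1 and are listed in ``flagged``.
    """
    # subset the raw matrix: a taxon subset of a relative table is no
    # longer compositional, so bypass the table-level invariants
    data = table.data if taxa_subset is None else table.data.loc[list(taxa_subset)]
    taxon_ids = list(data.index)
    if len(taxon_ids) < 2:
        raise ValueError("need at least 2 taxa for a correlation matrix")
    if data.shape[1] < 4:
        raise ValueError("need at least 4 samples for Spearman correlations")
    x = data.to_numpy(dtype=float)  # taxa x samples
    n = data.shape[1]
    constant = np.array([np.all(row == row[0]) for row in x])
    ranks = np.vstack([stats.rankdata(row) for row in x])
    z = ranks - ranks.mean(axis=1, keepdims=True)
    norm = np.sqrt((z**2).sum(axis=1))
    norm_safe = np.where(norm == 0, 1.0, norm)
    r = (z @ z.T) / np.outer(norm_safe, norm_safe)
    r = np.clip(r, -1.0, 1.0)
    r[constant, :] = 0.0
    r[:, constant] = 0.0
    np.fill_diagonal(r, 1.0)

    with np.errstate(divide="ignore", invalid="ignore"):
        t = r * np.sqrt((n - 2) / (1.0 - r**2))
    p = 2.0 * stats.t.sf(np.abs(t), df=n - 2)
    p[np.abs(r) >= 1.0] = 0.0
    p[constant, :] = 1.0
    p[:, constant] = 1.0
    np.fill_diagonal(p, 0.0)
    flagged = [t_ for t_, c in zip(taxon_ids, constant) if c]
    return CorrelationMatrix(taxon_ids, r, p, method="spearman", flagged=flagged)


def _sparcc_rho(frac: np.ndarray, exclusion_threshold: float, max_exclusions: int) -> np.ndarray:
    """One SparCC basis-correlation estimate from a fraction matrix.

    ``frac`` is taxa x samples, strictly positive. Basis variances solve
    the linear system M w = t_rowsum with M = (D-1) on the diagonal and 1
    off-diagonal (the sparsity approximation); strongly correlated pairs
    are iteratively excluded from the system and re-solved.
    """
    logf = np.log(frac)
    d = logf.shape[0]
    # variation matrix t_ij = Var(log f_i - log f_j)
    var = logf.var(axis=1, ddof=1)
    cov = np.cov(logf)
    t = var[:, None] + var[None, :] - 2.0 * cov
    np.fill_diagonal(t, 0.0)

    m = np.ones((d, d)) + np.diag(np.full(d, d - 2.0))
    t_work = t.copy()
    excluded = np.zeros((d, d), dtype=bool)

    def solve_rho():
        omega = np.linalg.solve(m, t_work.sum(axis=1))
        omega = np.clip(omega, 1e-12, None)
        rho = (omega[:, None] + omega[None, :] - t) / (2.0 * np.sqrt(np.outer(omega, omega)))
        return np.clip(rho, -1.0, 1.0)

    rho = solve_rho()
    for _ in range(max_exclusions):
        cand = np.abs(rho.copy())
        np.fill_diagonal(cand, 0.0)
        cand[excluded] = 0.0
        i, j = np.unravel_index(np.argmax(cand), cand.shape)
        if cand[i, j] <= exclusion_threshold:
            break
        excluded[i, j] = excluded[j, i] = True
        m[i, i] -= 1.0
        m[j, j] -= 1.0
        t_work[i, j] = t_work[j, i] = 0.0
        rho = solve_rho()
    np.fill_diagonal(rho, 1.0)
    return rho


def sparcc_matrix(
    table: TaxonAbundanceTable,
    n_dirichlet: int = 20,
    exclusion_threshold: float = 0.1,
    max_exclusions: int = 10,
    n_perm: int = 99,
    seed: int = 0,
) -> CorrelationMatrix:
    """SparCC compositional correlations on a counts table.

    Per Dirichlet draw (pseudocount 1) the basis correlations are
    estimated from log-ratio variances under the sparsity assumption and
    averaged over draws. p-values come from a permutation null in which
    each taxon's counts are independently shuffled across samples and the
    matrix recomputed (single posterior draw per permutation, for cost);
    set ``n_perm=0`` to skip p-values (p = 0, threshold on r only).
    """
    if table.kind != "counts":
        raise ValueError("SparCC requires a counts table")
    if table.n_taxa < 25:
        raise ValueError("SparCC sparsity assumption needs >= 25 taxa")
    if table.n_samples < 10:
        raise ValueError("SparCC needs >= 10 samples")
    rng = np.random.default_rng(seed)
    counts = table.values  # taxa x samples
    d, n = counts.shape

    def estimate(c):
        rhos = np.zeros((d, d))
        for _ in range(n_dirichlet):
            # posterior fractions per sample: Dirichlet(counts + 1)
            g = rng.gamma(c + 1.0)
            frac = g / g.sum(axis=0, keepdims=True)
            rhos += _sparcc_rho(frac, exclusion_threshold, max_exclusions)
        return rhos / n_dirichlet

    rho = estimate(counts)

    if n_perm > 0:
        exceed = np.zeros((d, d))
        for _ in range(n_perm):
            perm = np.vstack([rng.permutation(row) for row in counts])
            g = rng.gamma(perm + 1.0)
            frac = g / g.sum(axis=0, keepdims=True)
            rho_null = _sparcc_rho(frac, exclusion_threshold, max_exclusions)
            exceed += np.abs(rho_null) >= np.abs(rho)
        p = (1.0 + exceed) / (n_perm + 1.0)
    else:
        p = np.zeros((d, d))
    np.fill_diagonal(p, 0.0)
    return CorrelationMatrix(table.taxon_ids, rho, p, method="sparcc")


def build_network(
    corr: CorrelationMatrix, r_min: float = 0.6, p_max: float = 0.05
) -> CooccurrenceNetwork:
    """Undirected co-occurrence network: edge iff |r| > r_min and p < p_max.

    Taxa left without any surviving edge are dropped from the graph.
    """
    g = nx.Graph()
    ids = corr.taxon_ids
    n = len(ids)
    for i in range(n):
        for j in range(i + 1, n):
            if abs(corr.r[i, j]) > r_min and corr.p[i, j] < p_max:
                g.add_edge(ids[i], ids[j], r=float(corr.r[i, j]), p=float(corr.p[i, j]))
    return CooccurrenceNetwork(graph=g, r_min=r_min, p_max=p_max)


def network_stats(net: CooccurrenceNetwork | nx.Graph) -> NetworkStats:
    """Topology summary: average degree 2E/N, mean shortest-path length over
    connected pairs, mean local clustering (degree<2 nodes contribute 0;
    global transitivity also reported), and Newman modularity of the
    deterministic greedy (CNM) partition.
    """
    g = net.graph if isinstance(net, CooccurrenceNetwork) else net
    n = g.number_of_nodes()
    if n == 0:
        raise ValueError("network is empty")
    e = g.number_of_edges()
    avg_degree = 2.0 * e / n

    # mean shortest-path length over connected pairs only
    total, pairs = 0, 0
    for comp in nx.connected_components(g):
        sub = g.subgraph(comp)
        for _, lengths in nx.all_pairs_shortest_path_length(sub):
            total += sum(lengths.values())
            pairs += len(lengths) - 1
    apl = total / pairs if pairs else 0.0

    clustering = nx.average_clustering(g)
    transitivity = nx.transitivity(g)

    if e == 0:
        q = 0.0
    else:
        # canonicalize node order so the greedy (CNM) agglomeration, whose
        # delta-Q ties are broken by node index, is reproducible and
        # independent of graph construction order
        order = sorted(g.nodes, key=str)
        canon = nx.Graph()
        canon.add_nodes_from(range(len(order)))
        index = {v: i for i, v in enumerate(order)}
        canon.add_edges_from((index[a], index[b]) for a, b in g.edges)
        communities = nx.community.greedy_modularity_communities(canon)
        q = nx.community.modularity(canon, communities)

    return NetworkStats(
        n_nodes=n,
        n_edges=e,
        average_degree=avg_degree,
        average_path_length=apl,
        clustering_coefficient=clustering,
        global_transitivity=transitivity,
        modularity=float(q),
        n_components=nx.number_connected_components(g),
    )


def centralities(net: CooccurrenceNetwork | nx.Graph) -> pd.DataFrame:
    """Degree (raw counts), Wasserman-Faust closeness (component-scaled),
    and betweenness (normalized by (n-1)(n-2)/2) per node."""
    g = net.graph if isinstance(net, CooccurrenceNetwork) else net
    if g.number_of_nodes() == 0:
        raise ValueError("network is empty")
    if g.number_of_nodes() == 1:
        node = next(iter(g.nodes))
        return pd.DataFrame(
            {"degree": [0], "closeness": [0.0], "betweenness": [0.0]}, index=[node]
        )
    deg = dict(g.degree())
    clo = nx.closeness_centrality(g, wf_improved=True)
    bet = nx.betweenness_centrality(g, normalized=True)
    nodes = sorted(g.nodes)
    return pd.DataFrame(
        {
            "degree": [deg[v] for v in nodes],
            "closeness": [clo[v] for v in nodes],
            "betweenness": [bet[v] for v in nodes],
        },
        index=nodes,
    )


def rank_core_taxa(net: CooccurrenceNetwork | nx.Graph, k: int = 5) -> CoreTaxaRanking:
    """Rank candidate taxa by the mean of their three centrality rank
    positions (average ties) and select the top k.

    Ties in the composite are broken by degree, then closeness, then
    betweenness, then lexicographic taxon id.
    """
    cent = centralities(net)
    if len(cent) < k:
        warnings.warn(
            f"only {len(cent)} nodes available; returning all", RuntimeWarning
        )
    ranks = pd.DataFrame(index=cent.index)
    for col in ("degree", "closeness", "betweenness"):
        # rank 1 = most central; average ties
        ranks[col] = stats.rankdata(-cent[col].to_numpy(), method="average")
    cent = cent.copy()
    cent["composite_rank"] = ranks.mean(axis=1)
    ordered = cent.sort_values(
        by=["composite_rank", "degree", "closeness", "betweenness"],
        ascending=[True, False, False, False],
        kind="mergesort",  # stable; index (lexicographic) is the last tiebreak
    )
    # enforce lexicographic final tie-break explicitly
    ordered = ordered.reset_index(names="taxon")
    ordered = ordered.sort_values(
        by=["composite_rank", "degree", "closeness", "betweenness", "taxon"],
        ascending=[True, False, False, False, True],
        kind="mergesort",
    ).set_index("taxon")
    selected = list(ordered.index[: min(k, len(ordered))])
    return CoreTaxaRanking(table=ordered, selected=selected, k=k)
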