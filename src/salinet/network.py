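"""Co-occurrence networks and their random-graph null comparison.

Pipeline: prevalence-filter the OTU table, test all pairwise Spearman
correlations (BH-adjusted), keep robust significant edges, build a
simple undirected graph, summarise its topology, and compare the
observed metrics against an ensemble of Erdős–Rényi G(N, L) graphs with
identical node and edge counts.  Environment–OTU networks reuse the same
correlation machinery with environmental variables as typed nodes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .datatypes import OtuTable, SalinetError, TaxonomyTable

DEFAULT_RHO_MIN = 0.6
DEFAULT_Q_MAX = 0.05


def prevalence_filter(table: OtuTable, min_prevalence: float = 0.25) -> OtuTable:
    """Keep OTUs occurring in at least ``min_prevalence`` of samples."""
    if not 0 < min_prevalence <= 1:
        raise SalinetError("min_prevalence must be in (0, 1]")
    frac = table.occupancy() / table.n_samples
    keep = frac.index[frac >= min_prevalence].tolist()
    if not keep:
        raise SalinetError("no OTUs pass the prevalence filter; lower the threshold")
    return table.select_otus(keep)


def _spearman_matrix(data: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Spearman rho and t-approximation p-values for all column pairs."""
    n, p = data.shape
    rho, pval = stats.spearmanr(data)
    if p == 2:  # spearmanr returns scalars for two columns
        rho = np.array([[1.0, rho], [rho, 1.0]])
        pval = np.array([[0.0, pval], [pval, 0.0]])
    return np.asarray(rho), np.asarray(pval)


def spearman_edges(
    table: OtuTable,
    rho_min: float = DEFAULT_RHO_MIN,
    q_max: float = DEFAULT_Q_MAX,
) -> pd.DataFrame:
    """All-pairs Spearman correlations with BH control, thresholded.

    Returns the edge table (source, target, rho, p, q, sign) of pairs
    with ``|rho| > rho_min`` and BH-adjusted ``q < q_max``.  The BH
    family is every tested pair in this table.  Constant OTU vectors
    have undefined rank correlations; their pairs are excluded with a
    warning.
    """
    if table.n_samples < 4:
        raise SalinetError("need at least 4 samples for meaningful correlation p-values")
    counts = table.counts.to_numpy(dtype=float)
    otus = np.array(table.otu_ids)
    constant = counts.std(axis=0) == 0
    if constant.any():
        warnings.warn(
            f"excluding constant OTUs from correlation: {otus[constant].tolist()}", UserWarning
        )
        counts = counts[:, ~constant]
        otus = otus[~constant]
    rho, pval = _spearman_matrix(counts)
    iu = np.triu_indices(len(otus), 1)
    rho_flat, p_flat = rho[iu], pval[iu]
    ok = np.isfinite(rho_flat) & np.isfinite(p_flat)
    q_flat = np.full_like(p_flat, np.nan)
    if ok.any():
        _, q_ok, _, _ = multipletests(p_flat[ok], method="fdr_bh")
        q_flat[ok] = q_ok
    edges = pd.DataFrame(
        {
            "source": otus[iu[0]],
            "target": otus[iu[1]],
            "rho": rho_flat,
            "p": p_flat,
            "q": q_flat,
        }
    )
    edges = edges[ok]
    edges["sign"] = np.where(edges["rho"] > 0, "positive", "negative")
    kept = edges[(edges["rho"].abs() > rho_min) & (edges["q"] < q_max)]
    return kept.reset_index(drop=True)


def build_network(edges: pd.DataFrame, taxonomy: TaxonomyTable | None = None) -> nx.Graph:
    """Simple undirected graph from an edge table (isolates excluded)."""
    g = nx.Graph()
    for rec in edges.itertuples(index=False):
        if rec.source == rec.target:
            continue
        g.add_edge(rec.source, rec.target, rho=float(rec.rho), sign=rec.sign)
    if taxonomy is not None:
        for node in g.nodes:
            if node in taxonomy.data.index:
                g.nodes[node]["order"] = taxonomy.data.loc[node, "order"]
                g.nodes[node]["functional_group"] = taxonomy.data.loc[node, "functional_group"]
                g.nodes[node]["type"] = "OTU"
    return g


@dataclass
class TopologySummary:
    n_nodes: int
    n_links: int
    avg_degree: float
    avg_clustering: float
    avg_path_distance: float
    diameter: int
    modularity: float
    connectance: float
    centralization_degree: float
    centralization_betweenness: float
    power_law_r2: float
    n_positive: int
    n_negative: int


def _power_law_r2(degrees: list[int]) -> float:
    """R^2 of the log-log least-squares fit of degree frequency."""
    values, counts = np.unique([d for d in degrees if d > 0], return_counts=True)
    if len(values) < 2:
        return float("nan")
    x, y = np.log(values), np.log(counts)
    slope, intercept = np.polyfit(x, y, 1)
    fitted = slope * x + intercept
    ss_res = np.sum((y - fitted) ** 2)
    ss_tot = np.sum((y - y.mean()) ** 2)
    if ss_tot == 0:
        return float("nan")
    return float(1.0 - ss_res / ss_tot)


def _centralization_degree(g: nx.Graph) -> float:
    n = g.number_of_nodes()
    if n < 3:
        return 0.0
    degs = np.array([d for _, d in g.degree()])
    return float((degs.max() - degs).sum() / ((n - 1) * (n - 2)))


def _centralization_betweenness(g: nx.Graph) -> float:
    n = g.number_of_nodes()
    if n < 3:
        return 0.0
    bet = np.array(list(nx.betweenness_centrality(g, normalized=True).values()))
    return float((bet.max() - bet).sum() / (n - 1))


def _mean_shortest_path(g: nx.Graph) -> tuple[float, int]:
    """Mean shortest-path length over connected pairs, and the diameter
    of the largest component."""
    total, pairs = 0.0, 0
    for comp in nx.connected_components(g):
        sub = g.subgraph(comp)
        if len(comp) < 2:
            continue
        for _, lengths in nx.all_pairs_shortest_path_length(sub):
            total += sum(lengths.values())
            pairs += len(lengths) - 1
    gd = total / pairs if pairs else float("nan")
    largest = max(nx.connected_components(g), key=len)
    diam = nx.diameter(g.subgraph(largest)) if len(largest) > 1 else 0
    return gd, diam


def modularity_greedy(g: nx.Graph, resolution: float = 1.0) -> tuple[float, list[set]]:
    """Greedy (CNM) modularity maximisation; deterministic given the graph."""
    communities = list(nx.community.greedy_modularity_communities(g, resolution=resolution))
    q = nx.community.modularity(g, communities, resolution=resolution)
    return float(q), communities


def topology(g: nx.Graph, resolution: float = 1.0) -> TopologySummary:
    """Full topological summary of a co-occurrence network.

    ``avg_degree = 2L/N`` and ``connectance = 2L/(N(N-1))`` are closed
    forms; the path metrics are averaged over reachable pairs only, with
    the diameter taken on the largest connected component.
    """
    n, l = g.number_of_nodes(), g.number_of_edges()
    if n < 2:
        raise SalinetError("topology needs at least 2 nodes")
    gd, diam = _mean_shortest_path(g)
    q, _ = modularity_greedy(g, resolution=resolution)
    signs = [d.get("sign", "positive") for _, _, d in g.edges(data=True)]
    return TopologySummary(
        n_nodes=n,
        n_links=l,
        avg_degree=average_degree(n, l),
        avg_clustering=float(np.mean(list(nx.clustering(g).values()))),
        avg_path_distance=gd,
        diameter=diam,
        modularity=q,
        connectance=connectance(n, l),
        centralization_degree=_centralization_degree(g),
        centralization_betweenness=_centralization_betweenness(g),
        power_law_r2=_power_law_r2([d for _, d in g.degree()]),
        n_positive=sum(s == "positive" for s in signs),
        n_negative=sum(s == "negative" for s in signs),
    )


def average_degree(n_nodes: int, n_links: int) -> float:
    """avgK = 2L/N."""
    if n_nodes < 1:
        raise SalinetError("need at least one node")
    return 2.0 * n_links / n_nodes


def connectance(n_nodes: int, n_links: int) -> float:
    """Realised fraction of possible undirected edges, 2L/(N(N-1))."""
    if n_nodes < 2:
        raise SalinetError("connectance needs at least 2 nodes")
    return 2.0 * n_links / (n_nodes * (n_nodes - 1))


@dataclass
class NullEnsembleSummary:
    n_nodes: int
    n_links: int
    n_graphs: int
    means: dict
    sds: dict
    z_scores: dict  # filled when an observed summary is supplied


def er_null_ensemble(
    n_nodes: int,
    n_links: int,
    n_graphs: int = 10000,
    seed: int | None = 0,
    observed: TopologySummary | None = None,
    metrics: tuple[str, ...] = ("avg_clustering", "avg_path_distance", "modularity"),
) -> NullEnsembleSummary:
    """Erdős–Rényi G(N, L) ensemble statistics for null comparison.

    Each of the ``n_graphs`` null graphs has exactly ``n_nodes`` nodes
    and ``n_links`` uniformly placed edges; average clustering, mean path
    distance and greedy modularity (selectable via ``metrics``) are
    summarised, and z-scores of the observed metrics are reported when an
    observed summary is given.
    """
    max_links = n_nodes * (n_nodes - 1) // 2
    if n_links > max_links:
        raise SalinetError(f"L={n_links} infeasible for N={n_nodes} (max {max_links})")
    known = {"avg_clustering", "avg_path_distance", "modularity"}
    bad = set(metrics) - known
    if bad:
        raise SalinetError(f"unknown null-ensemble metrics: {sorted(bad)}")
    rng = np.random.default_rng(seed)
    values: dict[str, list[float]] = {k: [] for k in metrics}
    for _ in range(n_graphs):
        g = nx.gnm_random_graph(n_nodes, n_links, seed=int(rng.integers(2**31)))
        if "avg_clustering" in values:
            values["avg_clustering"].append(float(np.mean(list(nx.clustering(g).values()))))
        if "avg_path_distance" in values:
            gd, _ = _mean_shortest_path(g)
            values["avg_path_distance"].append(gd)
        if "modularity" in values:
            q, _ = modularity_greedy(g)
            values["modularity"].append(q)
    means = {k: float(np.mean(v)) for k, v in values.items()}
    sds = {k: float(np.std(v, ddof=1)) if n_graphs > 1 else 0.0 for k, v in values.items()}
    z_scores = {}
    if observed is not None:
        for k in values:
            obs = getattr(observed, k)
            z_scores[k] = (obs - means[k]) / sds[k] if sds[k] > 0 else float("nan")
    return NullEnsembleSummary(
        n_nodes=n_nodes, n_links=n_links, n_graphs=n_graphs,
        means=means, sds=sds, z_scores=z_scores,
    )


def degree_proportion_by_taxon(
    g: nx.Graph, taxonomy: TaxonomyTable, rank: str = "order"
) -> pd.Series:
    """Fraction of total degree held by each taxon at ``rank``.

    Nodes without a taxonomy entry at the rank go to "unclassified".
    Fractions sum to 1 on any non-empty network.
    """
    degrees = dict(g.degree())
    total = sum(degrees.values())
    if total == 0:
        raise SalinetError("network has no edges")
    ranks = taxonomy.rank(rank)
    sums: dict[str, float] = {}
    for node, deg in degrees.items():
        taxon = ranks.get(node, "unclassified")
        if pd.isna(taxon):
            taxon = "unclassified"
        sums[taxon] = sums.get(taxon, 0.0) + deg
    return pd.Series(sums).sort_values(ascending=False) / total


def env_otu_network(
    table: OtuTable,
    variables: pd.DataFrame,
    rho_min: float = DEFAULT_RHO_MIN,
    q_max: float = DEFAULT_Q_MAX,
    taxonomy: TaxonomyTable | None = None,
) -> tuple[nx.Graph, pd.Series]:
    """Joint OTU–OTU / OTU–environment correlation network.

    Environmental variables become nodes of type "environment".  BH
    adjustment is applied separately to the OTU–OTU family and to the
    OTU–environment family.  Returns the graph and the per-environment
    node degree.
    """
    variables = variables.loc[table.sample_ids]
    if variables.isna().any().any():
        raise SalinetError("missing values in environmental variables")
    const = variables.columns[variables.std(axis=0) == 0].tolist()
    if const:
        warnings.warn(f"excluding constant variables: {const}", UserWarning)
        variables = variables.drop(columns=const)
    counts = table.counts.to_numpy(dtype=float)
    env = variables.to_numpy(dtype=float)
    otus = np.array(table.otu_ids)
    env_names = np.array(variables.columns)

    otu_edges = spearman_edges(table, rho_min=rho_min, q_max=q_max)

    combined = np.column_stack([counts, env])
    rho, pval = _spearman_matrix(combined)
    n_otu = len(otus)
    rho_oe = rho[:n_otu, n_otu:]
    p_oe = pval[:n_otu, n_otu:]
    flat_r, flat_p = rho_oe.ravel(), p_oe.ravel()
    ok = np.isfinite(flat_r) & np.isfinite(flat_p)
    q = np.full_like(flat_p, np.nan)
    if ok.any():
        _, q_ok, _, _ = multipletests(flat_p[ok], method="fdr_bh")
        q[ok] = q_ok
    ii, jj = np.unravel_index(np.arange(flat_r.size), rho_oe.shape)
    env_edges = pd.DataFrame(
        {
            "source": otus[ii],
            "target": env_names[jj],
            "rho": flat_r,
            "p": flat_p,
            "q": q,
        }
    )
    env_edges = env_edges[ok]
    env_edges["sign"] = np.where(env_edges["rho"] > 0, "positive", "negative")
    env_edges = env_edges[(env_edges["rho"].abs() > rho_min) & (env_edges["q"] < q_max)]

    g = build_network(pd.concat([otu_edges, env_edges], ignore_index=True), taxonomy)
    for name in env_names:
        if name in g:
            g.nodes[name]["type"] = "environment"
    env_degree = pd.Series(
        {name: (g.degree(name) if name in g else 0) for name in env_names}, name="degree"
    ).sort_values(ascending=False)
    return g, env_degree


def write_edge_list(g: nx.Graph, path) -> None:
    """Gephi-compatible TSV edge list (source, target, rho, sign)."""
    rows = [
        {"source": u, "target": v, "rho": d.get("rho", np.nan), "sign": d.get("sign", "")}
        for u, v, d in g.edges(data=True)
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
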