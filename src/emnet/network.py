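"""Signed Spearman co-occurrence networks and derived complexity metrics.

The construction follows the standard amplicon workflow: taxa below a total
relative-abundance floor are discarded, all pairwise Spearman correlations
are computed (tie-corrected rho; calibrated two-sided p, see
:func:`spearman_matrix`), and an undirected signed graph keeps pairs with
|rho| >= r_cut and p <= p_cut.

Per-sample "subnetwork" metrics come from the subgraph induced by the taxa
present in that sample; the Multi-net index is the mean of the z-scored
node number, edge number and betweenness centrality across samples.  Node
roles use the Guimera-Amaral within-module degree z-score (Zi) and
participation coefficient (Pi) with the usual cuts (2.5, 0.62): peripherals,
connectors, module hubs and network hubs; non-peripheral nodes are treated
as keystone taxa.
"""

from __future__ import annotations

import dataclasses
import logging
from functools import lru_cache
from itertools import permutations
from typing import Mapping

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger("emnet")

__all__ = [
    "CooccurrenceNetwork", "filter_by_relative_abundance", "spearman_matrix",
    "build_network", "topology", "sample_subnetworks", "multi_net", "zi_pi",
    "keystone_diversity_correlations", "crosskingdom_table", "biotic_factors",
    "BIOTIC_FACTOR_COLUMNS",
]

ROLE_PERIPHERAL = "peripheral"
ROLE_CONNECTOR = "connector"
ROLE_MODULE_HUB = "module hub"
ROLE_NETWORK_HUB = "network hub"


@dataclasses.dataclass
class CooccurrenceNetwork:
    """Thresholded signed correlation graph plus its construction record."""

    graph: nx.Graph
    params: dict
    provenance: dict

    @property
    def n_nodes(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()


def filter_by_relative_abundance(table: pd.DataFrame,
                                 min_frac: float) -> pd.DataFrame:
    """Keep taxa whose share of the grand total is at least ``min_frac``."""
    if not 0.0 <= min_frac < 1.0:
        raise ValueError("min_frac must lie in [0, 1)")
    totals = table.sum(axis=0)
    grand = totals.sum()
    if grand <= 0:
        raise ValueError("table has no counts")
    keep = totals / grand >= min_frac
    if not keep.any():
        raise ValueError(
            f"abundance filter {min_frac} removed every taxon; lower it")
    out = table.loc[:, keep]
    logger.info("abundance filter %.2g kept %d/%d taxa",
                min_frac, keep.sum(), table.shape[1])
    return out


@lru_cache(maxsize=8)
def _null_abs_rho(n: int, mc_draws: int = 200_000) -> np.ndarray:
    """Sorted |rho| under the permutation null for untied data of size n.

    Exact enumeration up to n = 9; beyond that a fixed-seed Monte-Carlo
    sample of the null (shared by every untied pair of the same n, so it is
    computed once and the pipeline stays deterministic).
    """
    base = np.arange(n, dtype=float)
    base = (base - base.mean()) / base.std()
    if n <= 9:
        perms = np.array(list(permutations(range(n))), dtype=float)
    else:
        rng = np.random.default_rng(890_421)  # fixed: a critical-value table
        perms = np.argsort(rng.random((mc_draws, n)), axis=1).astype(float)
    perms = (perms - perms.mean(axis=1, keepdims=True)) \
        / perms.std(axis=1, keepdims=True)
    return np.sort(np.abs(perms @ base / n))


def _null_tail_p(abs_rho: np.ndarray, null: np.ndarray) -> np.ndarray:
    """P(|rho_null| >= observed), add-one corrected."""
    m = len(null)
    # count of null values >= observed (strict tolerance for float noise)
    idx = np.searchsorted(null, abs_rho - 1e-12, side="left")
    return (1.0 + (m - idx)) / (m + 1.0)


def spearman_matrix(table: pd.DataFrame, p_method: str = "auto"
                    ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """All-pairs Spearman rho with two-sided p-values.

    rho comes from average-ranked data (tie-corrected).  ``p_method``:

    * ``"auto"`` (default) mirrors R's ``cor.test``: pairs of untied
      vectors use the permutation null of rho (exact for n <= 9, a shared
      fixed-seed Monte-Carlo null up to n = 50), tied pairs and larger n
      fall back to the t approximation.  The t approximation is mildly
      anticonservative in the far tail at these sample sizes, which
      matters when edges are thresholded at p <= 0.001.
    * ``"t"`` forces the t approximation everywhere.

    Zero-variance taxa yield NaN rho/p for their pairs; such pairs are
    excluded from edge construction downstream.  Requires >= 4 samples.
    """
    n = len(table)
    if n < 4:
        raise ValueError("need at least 4 samples for Spearman p-values")
    X = table.to_numpy(dtype=float)
    const = X.std(axis=0) == 0
    ranks = pd.DataFrame(X).rank().to_numpy()
    with np.errstate(invalid="ignore", divide="ignore"):
        rho = np.corrcoef(ranks, rowvar=False)
    if rho.ndim == 0:  # single taxon
        rho = np.array([[1.0]])
    rho[const, :] = np.nan
    rho[:, const] = np.nan
    np.fill_diagonal(rho, 1.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        r2 = np.clip(rho, -1.0, 1.0)
        t = r2 * np.sqrt((n - 2) / (1.0 - r2 ** 2))
    p = 2.0 * stats.t.sf(np.abs(t), df=n - 2)
    p[np.isinf(t)] = 0.0
    if p_method == "auto" and n <= 50:
        untied = np.array([len(np.unique(X[:, j])) == n
                           for j in range(X.shape[1])])
        both = np.outer(untied, untied)
        if both.any():
            null = _null_abs_rho(n)
            p[both] = _null_tail_p(np.abs(r2[both]), null)
    elif p_method not in ("auto", "t"):
        raise ValueError(f"unknown p_method {p_method!r}")
    np.fill_diagonal(p, 0.0)
    cols = table.columns
    return (pd.DataFrame(rho, index=cols, columns=cols),
            pd.DataFrame(p, index=cols, columns=cols))


def build_network(table: pd.DataFrame, r_cut: float = 0.6,
                  p_cut: float = 0.001,
                  annotations: pd.DataFrame | None = None,
                  provenance: Mapping | None = None) -> CooccurrenceNetwork:
    """Signed co-occurrence graph from an (already filtered) count table.

    Edges: |rho| >= r_cut and p <= p_cut.  The edge criterion is applied to
    the magnitude because both co-presence (positive) and exclusion
    (negative) correlations are biologically meaningful; the sign is stored
    on each edge.  Isolated taxa are not added as nodes but are counted in
    ``provenance["n_candidate_taxa"]``.
    """
    rho, p = spearman_matrix(table)
    R, P = rho.to_numpy(), p.to_numpy()
    m = len(rho)
    graph = nx.Graph()
    iu = np.triu_indices(m, k=1)
    ok = (~np.isnan(R[iu])) & (np.abs(R[iu]) >= r_cut) & (P[iu] <= p_cut)
    taxa = rho.index.to_numpy()
    for i, j in zip(iu[0][ok], iu[1][ok]):
        graph.add_edge(taxa[i], taxa[j], rho=float(R[i, j]),
                       p_value=float(P[i, j]),
                       sign=1 if R[i, j] > 0 else -1)
    if annotations is not None:
        for node in graph.nodes:
            if node in annotations.index:
                for key, val in annotations.loc[node].items():
                    graph.nodes[node][str(key)] = val
    if graph.number_of_edges() == 0:
        logger.warning("no edge survived |rho|>=%.2f, p<=%.3g", r_cut, p_cut)
    prov = {"n_samples": len(table), "n_candidate_taxa": m,
            "n_isolated": m - graph.number_of_nodes()}
    if provenance:
        prov.update(provenance)
    logger.info("network: %d nodes, %d edges (|rho|>=%.2f, p<=%.3g)",
                graph.number_of_nodes(), graph.number_of_edges(), r_cut, p_cut)
    return CooccurrenceNetwork(
        graph, {"r_cut": r_cut, "p_cut": p_cut}, prov)


def _as_graph(net) -> nx.Graph:
    return net.graph if isinstance(net, CooccurrenceNetwork) else net


def topology(net) -> dict:
    """Whole-network topology summary.

    Path-based metrics average over connected pairs only; eigenvector
    centrality is computed on the largest connected component.  Metrics
    undefined on the given graph (assortativity of a degree-regular graph,
    positive/negative ratio without negative edges) are NaN and listed
    under ``"undefined"``.
    """
    g = _as_graph(net)
    nn, ne = g.number_of_nodes(), g.number_of_edges()
    undefined: list[str] = []
    if nn == 0:
        keys = ["node_num", "edge_num", "positive_edges", "negative_edges",
                "pos_neg_ratio", "average_degree", "average_distance",
                "density", "assortativity", "betweenness_centrality",
                "degree_centrality", "eigenvector_centrality"]
        return {**{k: float("nan") for k in keys},
                "node_num": 0, "edge_num": 0, "undefined": keys}
    signs = [d.get("sign", 1) for _, _, d in g.edges(data=True)]
    pos = sum(1 for s in signs if s > 0)
    neg = ne - pos
    if neg == 0:
        ratio = float("nan")
        undefined.append("pos_neg_ratio")
    else:
        ratio = pos / neg

    # mean shortest-path length over all reachable (ordered) pairs
    total, pairs = 0, 0
    for node, lengths in nx.all_pairs_shortest_path_length(g):
        for other, dist in lengths.items():
            if other != node:
                total += dist
                pairs += 1
    avg_dist = total / pairs if pairs else float("nan")
    if not pairs:
        undefined.append("average_distance")

    degs = np.array([d for _, d in g.degree()], dtype=float)
    if nn > 1 and len(set(degs)) > 1:
        assort = float(nx.degree_assortativity_coefficient(g))
    else:
        assort = float("nan")
        undefined.append("assortativity")

    bet = float(np.mean(list(nx.betweenness_centrality(g).values())))
    degc = float(np.mean(list(nx.degree_centrality(g).values()))) if nn > 1 else float("nan")
    comp = max(nx.connected_components(g), key=len)
    sub = g.subgraph(comp)
    if sub.number_of_nodes() > 1:
        # dense symmetric eigendecomposition: deterministic, unlike the
        # ARPACK route which starts from a random vector
        A = nx.to_numpy_array(sub, weight=None)
        vals, vecs = np.linalg.eigh(A)
        v = np.abs(vecs[:, -1])
        eig = float(np.mean(v / np.linalg.norm(v)))
    else:
        eig = float("nan")
        undefined.append("eigenvector_centrality")

    return {
        "node_num": nn, "edge_num": ne,
        "positive_edges": pos, "negative_edges": neg,
        "pos_neg_ratio": ratio,
        "average_degree": 2.0 * ne / nn,
        "average_distance": avg_dist,
        "density": float(nx.density(g)),
        "assortativity": assort,
        "betweenness_centrality": bet,
        "degree_centrality": degc,
        "eigenvector_centrality": eig,
        "undefined": undefined,
    }


def sample_subnetworks(net, table: pd.DataFrame) -> pd.DataFrame:
    """Induced-subgraph metrics per sample.

    For each sample, the subgraph induced on network taxa with count > 0 in
    that sample; returns node_num, edge_num and mean normalized betweenness
    centrality per sample.  Samples containing no network taxon get zeros.
    """
    g = _as_graph(net)
    nodes = [t for t in g.nodes if t in table.columns]
    rows = []
    for sample in table.index:
        present = [t for t in nodes if table.at[sample, t] > 0]
        sub = g.subgraph(present)
        if sub.number_of_nodes() == 0:
            rows.append({"node_num": 0, "edge_num": 0,
                         "betweenness_centrality": 0.0})
            continue
        bc = nx.betweenness_centrality(sub)
        rows.append({"node_num": sub.number_of_nodes(),
                     "edge_num": sub.number_of_edges(),
                     "betweenness_centrality": float(np.mean(list(bc.values())))})
    return pd.DataFrame(rows, index=table.index)


def multi_net(metrics: pd.DataFrame) -> pd.Series:
    """Single-index multi-complexity per sample.

    Each of node_num, edge_num and betweenness_centrality is z-scored
    across samples (sample SD); the index is the per-sample mean of the
    three z-scores.  A metric constant across samples contributes 0.
    """
    if len(metrics) < 2:
        raise ValueError("multi_net needs at least 2 samples")
    z = pd.DataFrame(index=metrics.index, dtype=float)
    for col in ("node_num", "edge_num", "betweenness_centrality"):
        x = metrics[col].to_numpy(dtype=float)
        sd = x.std(ddof=1)
        if sd == 0:
            logger.info("multi_net: %s constant across samples; z set to 0", col)
            z[col] = 0.0
        else:
            z[col] = (x - x.mean()) / sd
    out = z.mean(axis=1)
    out.name = "multi_net"
    return out


def _communities(g: nx.Graph, method: str, seed: int) -> list[set]:
    if method == "greedy":
        comms = nx.community.greedy_modularity_communities(g)
    elif method == "louvain":
        comms = nx.community.louvain_communities(g, seed=seed)
    else:
        raise ValueError(f"unknown module detection method {method!r}")
    # stable ordering: by smallest member id
    return sorted((set(c) for c in comms), key=lambda c: sorted(map(str, c)))


def zi_pi(net, seed: int = 0, method: str = "greedy",
          zi_cut: float = 2.5, pi_cut: float = 0.62) -> pd.DataFrame:
    """Guimera-Amaral node roles on the unsigned topology.

    Zi = (k_within - mean k_within of the module) / sd (0 when sd = 0 or
    the module is a singleton); Pi = 1 - sum_s (k_is / k_i)^2.  Roles by
    the (zi_cut, pi_cut) grid with boundary values going to the lower
    category: peripheral (Zi <= cut, Pi <= cut), connector (low Zi, high
    Pi), module hub (high Zi, low Pi), network hub (both high).
    """
    g = _as_graph(net)
    if g.number_of_edges() == 0:
        raise ValueError("node roles need a network with at least one edge")
    comms = _communities(g, method, seed)
    module_of = {n: m for m, c in enumerate(comms) for n in c}

    within = {}
    for m, comm in enumerate(comms):
        sub = g.subgraph(comm)
        for n in comm:
            within[n] = sub.degree(n)
    rows = []
    for n in sorted(g.nodes, key=str):
        m = module_of[n]
        comm = comms[m]
        kw = np.array([within[u] for u in comm], dtype=float)
        sd = kw.std()
        zi = (within[n] - kw.mean()) / sd if sd > 0 and len(comm) > 1 else 0.0
        k = g.degree(n)
        by_mod = np.zeros(len(comms))
        for u in g.neighbors(n):
            by_mod[module_of[u]] += 1
        pi = 1.0 - float(((by_mod / k) ** 2).sum()) if k > 0 else 0.0
        hub = zi > zi_cut
        conn = pi > pi_cut
        role = (ROLE_NETWORK_HUB if hub and conn else
                ROLE_MODULE_HUB if hub else
                ROLE_CONNECTOR if conn else ROLE_PERIPHERAL)
        rows.append({"taxon": n, "module": m, "zi": float(zi),
                     "pi": float(pi), "role": role,
                     "singleton_module": len(comm) == 1})
    return pd.DataFrame(rows).set_index("taxon")


def keystone_diversity_correlations(roles: pd.DataFrame, table: pd.DataFrame,
                                    indicators: pd.DataFrame) -> pd.DataFrame:
    """Spearman correlations between keystone relative abundances and
    diversity/topology indicators (long format: taxon x indicator).

    Keystones are all non-peripheral nodes.  Constant abundance or
    indicator vectors yield NaN rho with ``undefined=True``.
    """
    keystones = roles.index[roles["role"] != ROLE_PERIPHERAL]
    if len(keystones) == 0:
        logger.warning("no keystone taxa (all peripheral)")
        return pd.DataFrame(
            columns=["taxon", "indicator", "rho", "p", "undefined"])
    rel = table.div(table.sum(axis=1), axis=0)
    rows = []
    for taxon in keystones:
        if taxon not in rel.columns:
            continue
        x = rel[taxon].to_numpy()
        for ind in indicators.columns:
            y = indicators[ind].to_numpy(dtype=float)
            if np.std(x) == 0 or np.std(y) == 0:
                rows.append({"taxon": taxon, "indicator": ind,
                             "rho": float("nan"), "p": float("nan"),
                             "undefined": True})
                continue
            rho, p = stats.spearmanr(x, y)
            rows.append({"taxon": taxon, "indicator": ind,
                         "rho": float(rho), "p": float(p),
                         "undefined": False})
    return pd.DataFrame(rows)


BIOTIC_FACTOR_COLUMNS = ["Richness", "AD", "Avgdist", "Den", "Assort",
                         "Vnum", "Edgnum", "Cenbet", "Cendeg", "Ceneig"]


def crosskingdom_table(fungal: pd.DataFrame,
                       bacterial: pd.DataFrame) -> pd.DataFrame:
    """Concatenate fungal and bacterial tables on shared samples."""
    common = fungal.index.intersection(bacterial.index)
    if len(common) == 0:
        raise ValueError("no shared samples between tables")
    return pd.concat([fungal.loc[common], bacterial.loc[common]], axis=1)


def biotic_factors(net, fungal: pd.DataFrame,
                   bacterial: pd.DataFrame) -> pd.DataFrame:
    """Per-sample biotic factors from the cross-kingdom network.

    For each sample the subgraph induced on joint-network taxa present in
    that sample is summarized: bacterial richness (from the bacterial table
    alone), average degree (AD), average distance (Avgdist), density (Den),
    degree assortativity (Assort), node and edge numbers (Vnum, Edgnum) and
    mean betweenness/degree/eigenvector centralities (Cenbet, Cendeg,
    Ceneig).  Metrics undefined on a given subgraph are reported as 0 so
    downstream models receive complete columns.
    """
    g = _as_graph(net)
    joint = crosskingdom_table(fungal, bacterial)
    rows = []
    for sample in joint.index:
        present = [t for t in g.nodes
                   if t in joint.columns and joint.at[sample, t] > 0]
        sub = g.subgraph(present)
        t = topology(sub)
        rows.append({
            "Richness": int((bacterial.loc[sample] > 0).sum()),
            "AD": t["average_degree"], "Avgdist": t["average_distance"],
            "Den": t["density"], "Assort": t["assortativity"],
            "Vnum": t["node_num"], "Edgnum": t["edge_num"],
            "Cenbet": t["betweenness_centrality"],
            "Cendeg": t["degree_centrality"],
            "Ceneig": t["eigenvector_centrality"],
        })
    out = pd.DataFrame(rows, index=joint.index)
    return out.fillna(0.0)
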