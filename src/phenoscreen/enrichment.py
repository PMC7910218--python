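"""Offline protein-network and annotation enrichment.

Replaces web-service lookups with local computation on a supplied weighted
edge list and GMT annotation sets: first-shell expansion of a query set
(up to 10 best-connected interactors), interaction enrichment against a
degree-matched sampling null, hypergeometric GO-term enrichment with
Benjamini-Hochberg adjustment, and the plain hypergeometric overlap test.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)

HIGH_CONFIDENCE = 0.7


@dataclass(frozen=True)
class EnrichmentResult:
    query_size: int
    background_size: int
    observed: float
    expected: float
    p_value: float
    method: str
    added_nodes: tuple[str, ...] = ()
    extra: dict = field(default_factory=dict)


def load_network(
    edges: pd.DataFrame, min_score: float = HIGH_CONFIDENCE
) -> nx.Graph:
    """Build an undirected graph keeping edges at or above ``min_score``;
    self-loops are dropped."""
    g = nx.Graph()
    for a, b, s in edges[["node_a", "node_b", "combined_score"]].itertuples(
        index=False
    ):
        if a == b:
            continue
        if s >= min_score:
            g.add_edge(str(a), str(b), score=float(s))
    return g


def add_first_shell(
    network: nx.Graph, query: set[str], max_added: int = 10
) -> tuple[set[str], tuple[str, ...]]:
    """Expand a query set with its best-connected direct interactors.

    Candidates are ranked by number of edges into the query, then summed
    edge score, then lexicographic id (deterministic tie-break). Returns
    (expanded set, added nodes in rank order).
    """
    if not query:
        raise ValueError("empty query set")
    mapped = {q for q in query if q in network}
    dropped = query - mapped
    if dropped:
        logger.warning("%d query ids not in network; dropped", len(dropped))
    if max_added <= 0:
        return set(mapped), ()
    scores: dict[str, tuple[int, float]] = {}
    for q in mapped:
        for nb in network.neighbors(q):
            if nb in mapped:
                continue
            cnt, tot = scores.get(nb, (0, 0.0))
            scores[nb] = (cnt + 1, tot + network[q][nb]["score"])
    ranked = sorted(
        scores.items(), key=lambda kv: (-kv[1][0], -kv[1][1], kv[0])
    )
    added = tuple(n for n, _ in ranked[:max_added])
    return mapped | set(added), added


def _internal_edges(network: nx.Graph, nodes: set[str]) -> int:
    return sum(1 for a, b in network.edges(nodes) if a in nodes and b in nodes)


def ppi_enrichment(
    network: nx.Graph,
    query: set[str],
    n_null: int = 10_000,
    seed: int = 0,
    n_degree_bins: int = 10,
) -> EnrichmentResult:
    """Interaction enrichment of a query set against a degree-matched null.

    The observed statistic is the number of network edges with both ends in
    the query. Null sets are drawn by replacing each query node with a
    random node from the same degree decile of the background; the p-value
    is the add-one fraction of null draws with at least as many internal
    edges.
    """
    mapped = {q for q in query if q in network}
    if len(query) - len(mapped):
        logger.warning(
            "%d query ids absent from network; dropped", len(query) - len(mapped)
        )
    if len(mapped) < 2:
        raise ValueError("need >= 2 mapped query nodes")
    if network.number_of_edges() == 0:
        raise ValueError("network has no edges at this confidence cutoff")

    observed = _internal_edges(network, mapped)
    nodes = sorted(network.nodes)
    degrees = np.array([network.degree(n) for n in nodes], dtype=float)
    # degree-decile bins over the background degree distribution
    edges_quantiles = np.quantile(
        degrees, np.linspace(0, 1, n_degree_bins + 1)[1:-1]
    )
    bins = np.searchsorted(edges_quantiles, degrees, side="right")
    node_bins: dict[int, list[int]] = {}
    for i, b in enumerate(bins):
        node_bins.setdefault(int(b), []).append(i)
    node_index = {n: i for i, n in enumerate(nodes)}
    query_bins = [int(bins[node_index[q]]) for q in sorted(mapped)]

    dense = nx.to_numpy_array(network, nodelist=nodes, weight=None).astype(bool)
    rng = np.random.default_rng(seed)
    # one column of node draws per query slot, sampled within its degree bin
    chosen = np.empty((n_null, len(query_bins)), dtype=np.int64)
    for slot, b in enumerate(query_bins):
        pool = np.asarray(node_bins[b])
        chosen[:, slot] = pool[rng.integers(len(pool), size=n_null)]
    null_counts = np.zeros(n_null, dtype=np.int64)
    m = len(query_bins)
    for i in range(m):
        for j in range(i + 1, m):
            distinct = chosen[:, i] != chosen[:, j]
            null_counts += distinct & dense[chosen[:, i], chosen[:, j]]
    p = float((np.sum(null_counts >= observed) + 1) / (n_null + 1))
    return EnrichmentResult(
        query_size=len(mapped),
        background_size=len(nodes),
        observed=float(observed),
        expected=float(null_counts.mean()),
        p_value=p,
        method="degree-matched-permutation",
    )


def hypergeom_overlap(
    population: int, successes: int, draws: int, observed: int
) -> float:
    """Upper-tail P(X >= observed) for X ~ Hypergeometric(N, K, n)."""
    if not (0 <= observed <= min(successes, draws) <= population):
        raise ValueError(
            f"inconsistent counts N={population} K={successes} "
            f"n={draws} k={observed}"
        )
    if successes > population or draws > population:
        raise ValueError("successes/draws exceed population")
    return float(
        stats.hypergeom.sf(observed - 1, population, successes, draws)
    )


def go_enrichment(
    annotations: dict[str, set[str]],
    query: set[str],
    background: set[str],
    namespace_prefix: str | None = None,
) -> pd.DataFrame:
    """Hypergeometric term enrichment of a query within a background.

    Each annotation set is restricted to the background; the raw upper-tail
    hypergeometric p and the BH-adjusted q are reported per term. Use
    ``namespace_prefix`` (e.g. ``"MF:"``) to restrict to one ontology
    branch, mirroring molecular-function-only testing.
    """
    if not background:
        raise ValueError("empty background")
    if not query <= background:
        raise ValueError("query must be a subset of the background")
    rows = []
    n_bg = len(background)
    n_q = len(query)
    for term, members in sorted(annotations.items()):
        if namespace_prefix and not term.startswith(namespace_prefix):
            continue
        in_bg = members & background
        if not in_bg:
            continue
        k = len(members & query)
        p = hypergeom_overlap(n_bg, len(in_bg), n_q, k)
        rows.append({
            "term": term,
            "term_size": len(in_bg),
            "overlap": k,
            "expected": len(in_bg) * n_q / n_bg,
            "p_value": p,
        })
    result = pd.DataFrame(rows)
    if len(result):
        result["q_value"] = multipletests(result["p_value"], method="fdr_bh")[1]
        result = result.sort_values("p_value", kind="stable").reset_index(drop=True)
    return result
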