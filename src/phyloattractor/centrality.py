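"""Local and global interactome centralities, summarized by phylostratum.

Degree counts direct (one-step) interactions on the confidence-filtered
graph.  Closeness is the raw reciprocal of the sum of hop distances from a
node to every other node it can reach; on disconnected graphs the sum runs
over the node's connected component only, since the formula is undefined for
unreachable pairs.  Betweenness is unweighted shortest-path betweenness with
each unordered pair counted once, endpoints excluded, and fractional credit
shared among equal-length paths (Brandes semantics) by default.

Edge confidence acts only as a filter upstream; path lengths are hop counts.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd

from .netio import InteractionNetwork, StratumMap, N_STRATA

logger = logging.getLogger("phyloattractor")

MEASURES = ("degree", "closeness", "betweenness")


def degree(net: InteractionNetwork) -> dict[str, int]:
    """Unweighted degree per node."""
    return {v: int(d) for v, d in net.graph.degree()}


def closeness(net: InteractionNetwork, normalized: bool = False) -> dict[str, float]:
    """Reciprocal of the summed hop distances to all reachable nodes.

    Isolated nodes get closeness 0 (logged).  With ``normalized=True`` the
    classic (k-1)/sum form is returned instead, where k is the size of the
    node's component; the raw reciprocal is the default.
    """
    g = net.graph
    out: dict[str, float] = {}
    n_isolated = 0
    for v in g:
        dist = nx.single_source_shortest_path_length(g, v)
        total = sum(dist.values())
        if total == 0:
            out[v] = 0.0
            n_isolated += 1
        elif normalized:
            out[v] = (len(dist) - 1) / total
        else:
            out[v] = 1.0 / total
    if n_isolated:
        logger.info("closeness: %d isolated node(s) assigned 0", n_isolated)
    return out


def betweenness(net: InteractionNetwork, tie_policy: str = "fractional") -> dict[str, float]:
    """Shortest-path betweenness, unordered pairs counted once.

    ``tie_policy`` decides how equal-length paths share credit:

    * ``"fractional"`` (default): each pair contributes 1 split across its
      geodesics (Brandes).
    * ``"count-all"``: every geodesic through the node contributes 1, i.e.
      the node's score for a pair (s, t) is the number of s-t geodesics
      passing through it.
    """
    if tie_policy == "fractional":
        return {v: float(b) for v, b in nx.betweenness_centrality(net.graph, normalized=False).items()}
    if tie_policy != "count-all":
        raise ValueError(f"unknown tie_policy {tie_policy!r}")
    return _betweenness_count_all(net.graph)


def _geodesic_counts(g: nx.Graph, nodes: list[str]) -> tuple[np.ndarray, np.ndarray]:
    """All-pairs hop distance D and geodesic count S via per-source BFS."""
    n = len(nodes)
    idx = {v: i for i, v in enumerate(nodes)}
    adj = [[idx[w] for w in g[v]] for v in nodes]
    D = np.full((n, n), np.inf)
    S = np.zeros((n, n))
    for s in range(n):
        D[s, s] = 0
        S[s, s] = 1.0
        frontier = [s]
        d = 0
        while frontier:
            nxt: list[int] = []
            for u in frontier:
                for w in adj[u]:
                    if np.isinf(D[s, w]):
                        D[s, w] = d + 1
                        nxt.append(w)
                    if D[s, w] == d + 1:
                        S[s, w] += S[s, u]
            frontier = nxt
            d += 1
    return D, S


def _betweenness_count_all(g: nx.Graph) -> dict[str, float]:
    nodes = sorted(g.nodes)
    D, S = _geodesic_counts(g, nodes)
    n = len(nodes)
    out = {}
    iu = np.triu_indices(n, k=1)
    for vi, v in enumerate(nodes):
        # paths s-t through v: sigma(s,v)*sigma(v,t) when d(s,v)+d(v,t)=d(s,t)
        through = (D[:, vi][:, None] + D[vi, :][None, :] == D) & np.isfinite(D)
        cnt = np.where(through, S[:, vi][:, None] * S[vi, :][None, :], 0.0)
        cnt[vi, :] = 0.0
        cnt[:, vi] = 0.0
        out[v] = float(cnt[iu].sum())
    return out


@dataclass
class CentralityProfile:
    """Per-node centralities plus per-stratum mean/sem/n summaries."""

    per_node: pd.DataFrame  # index node; columns stratum, degree, closeness, betweenness
    per_stratum: pd.DataFrame  # index stratum; columns <measure>_mean/_sem/_n
    n_unmapped: int = 0


def compute_profile(
    net: InteractionNetwork,
    strata: StratumMap,
    tie_policy: str = "fractional",
    normalized_closeness: bool = False,
) -> CentralityProfile:
    """Compute all three measures and summarize them by stratum."""
    measures = {
        "degree": degree(net),
        "closeness": closeness(net, normalized=normalized_closeness),
        "betweenness": betweenness(net, tie_policy=tie_policy),
    }
    return stratum_summary(measures, strata)


def stratum_summary(
    measures: dict[str, dict[str, float]], strata: StratumMap
) -> CentralityProfile:
    """Summarize per-node measures by stratum (mean, standard error, n).

    Nodes without a stratum assignment are kept in the per-node table with a
    missing stratum but excluded from the per-stratum summary; their count is
    logged.  A stratum with a single node reports sem 0.
    """
    nodes = sorted(set().union(*(m.keys() for m in measures.values())))
    if not any(v in strata for v in nodes):
        raise ValueError("no node has a stratum assignment")
    per_node = pd.DataFrame(index=pd.Index(nodes, name="node"))
    per_node["stratum"] = [strata.entries.get(v, np.nan) for v in nodes]
    for name, vals in measures.items():
        per_node[name] = [vals.get(v, np.nan) for v in nodes]
    n_unmapped = int(per_node["stratum"].isna().sum())
    if n_unmapped:
        logger.info("stratum_summary: %d node(s) without stratum excluded from summary", n_unmapped)

    mapped = per_node.dropna(subset=["stratum"]).copy()
    mapped["stratum"] = mapped["stratum"].astype(int)
    rows = []
    for s in range(1, N_STRATA + 1):
        sub = mapped[mapped["stratum"] == s]
        row: dict[str, float] = {"stratum": s}
        for name in measures:
            x = sub[name].to_numpy(dtype=float)
            row[f"{name}_n"] = len(x)
            row[f"{name}_mean"] = float(np.mean(x)) if len(x) else np.nan
            row[f"{name}_sem"] = (
                float(np.std(x, ddof=1) / np.sqrt(len(x))) if len(x) > 1 else (0.0 if len(x) == 1 else np.nan)
            )
        rows.append(row)
    per_stratum = pd.DataFrame(rows).set_index("stratum")
    return CentralityProfile(per_node=per_node, per_stratum=per_stratum, n_unmapped=n_unmapped)
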