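"""Shared fixtures: tiny hand-built graphs and TSV writers."""

from __future__ import annotations

import networkx as nx
import pytest

from phyloattractor import InteractionNetwork, StratumMap


def make_net(edges, threshold: float = 0.5, score: float = 0.9) -> InteractionNetwork:
    """Build a network from (a, b) or (a, b, score) tuples."""
    g = nx.Graph()
    for e in edges:
        if len(e) == 2:
            a, b = e
            s = score
        else:
            a, b, s = e
        g.add_edge(a, b, score=float(s))
    return InteractionNetwork(graph=g, confidence_threshold=threshold)


@pytest.fixture
def path_net() -> InteractionNetwork:
    """A - B - C."""
    return make_net([("A", "B"), ("B", "C")])


@pytest.fixture
def star_net() -> InteractionNetwork:
    """Star K1,4 with center X."""
    return make_net([("X", f"L{i}") for i in range(4)])


def write_edges_tsv(path, rows, header: str = "protein1\tprotein2\tcombined_score") -> None:
    lines = [header] + [f"{a}\t{b}\t{s}" for a, b, s in rows]
    path.write_text("\n".join(lines) + "\n")


def write_strata_tsv(path, entries: dict) -> None:
    lines = ["gene_id\tstratum"] + [f"{g}\t{s}" for g, s in entries.items()]
    path.write_text("\n".join(lines) + "\n")


@pytest.fixture
def two_stratum_map() -> StratumMap:
    return StratumMap({"A": 17, "B": 1, "C": 1})
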