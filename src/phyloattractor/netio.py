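"""Readers, writers and shared domain types for the interactome analysis.

All components of the pipeline share a single string identifier space: the
protein nodes of the interaction network, the keys of the gene-age (stratum)
map, the rows of expression tables and the gene annotations of the GO-like
DAG must use the same identifiers.  Nodes that are present in the network but
absent from the stratum map are retained in the graph and excluded (with a
logged count) from any per-stratum summary.

File dialects
-------------
* Edge list TSV with header ``protein1\tprotein2\tcombined_score`` (a
  ``score`` header is also accepted).  Scores may be reals in (0, 1] or
  STRING-style integers in (0, 1000]; the scale is auto-detected from the
  maximum value and 0-1000 scores are divided by 1000 (logged).
* Stratum map TSV ``gene_id\tstratum`` with strata in 1..17.
* GO structure as two TSVs: ``term_child\tterm_parent`` edges and
  ``term\tgene`` direct annotations.  A thin adapter for OBO (``is_a`` only)
  is provided for convenience.
"""

from __future__ import annotations

import logging
from collections import deque
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import networkx as nx
import pandas as pd

logger = logging.getLogger("phyloattractor")

#: Names of the 17 evolutionary strata, oldest (cellular organisms) first.
STRATUM_LABELS: dict[int, str] = {
    1: "cellular organisms (Prokaryota)",
    2: "Eukaryota",
    3: "Opisthokonta",
    4: "Metazoa",
    5: "Eumetazoa",
    6: "Bilateria",
    7: "Chordata",
    8: "Vertebrata",
    9: "Euteleostomi",
    10: "Tetrapoda",
    11: "Amniota",
    12: "Mammalia",
    13: "Theria",
    14: "Eutheria",
    15: "Boreoeutheria",
    16: "Primates",
    17: "Hominidae",
}

N_STRATA = 17

#: Strata conventionally called "unicellular" (before Metazoa).
UC_STRATA = (1, 2, 3)


# ---------------------------------------------------------------------------
# Stratum map
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class StratumMap:
    """Gene identifier -> evolutionary stratum (1..17)."""

    entries: Mapping[str, int]
    labels: Mapping[int, str] = field(default_factory=lambda: dict(STRATUM_LABELS))

    def __post_init__(self) -> None:
        bad = {g: s for g, s in self.entries.items() if not 1 <= int(s) <= N_STRATA}
        if bad:
            g, s = next(iter(bad.items()))
            raise ValueError(f"stratum {s} for gene {g!r} outside 1..{N_STRATA}")

    def __len__(self) -> int:
        return len(self.entries)

    def __contains__(self, gene: str) -> bool:
        return gene in self.entries

    def stratum_of(self, gene: str) -> int:
        return int(self.entries[gene])

    def genes_in(self, stratum: int) -> list[str]:
        return sorted(g for g, s in self.entries.items() if int(s) == stratum)

    def counts(self) -> dict[int, int]:
        """Number of mapped genes per stratum (all strata 1..17, zeros kept)."""
        out = {s: 0 for s in range(1, N_STRATA + 1)}
        for s in self.entries.values():
            out[int(s)] += 1
        return out

    def to_series(self) -> pd.Series:
        return pd.Series(dict(self.entries), name="stratum").astype(int)


def read_stratum_map(path: str | Path) -> StratumMap:
    """Read a ``gene_id\tstratum`` TSV into a :class:`StratumMap`.

    Raises on duplicated identifiers and on strata outside 1..17.
    """
    df = pd.read_csv(path, sep="\t", dtype={0: str})
    if df.shape[1] < 2:
        raise ValueError(f"{path}: expected two columns gene_id, stratum")
    genes = df.iloc[:, 0].astype(str)
    dup = genes[genes.duplicated()]
    if not dup.empty:
        raise ValueError(f"{path}: duplicate gene identifier {dup.iloc[0]!r}")
    strata = pd.to_numeric(df.iloc[:, 1], errors="coerce")
    if strata.isna().any():
        line = int(strata.isna().idxmax()) + 2  # +1 header, +1 one-based
        raise ValueError(f"{path}: non-numeric stratum at line {line}")
    return StratumMap(dict(zip(genes, strata.astype(int))))


def write_stratum_map(smap: StratumMap, path: str | Path) -> None:
    df = pd.DataFrame(
        {"gene_id": sorted(smap.entries), "stratum": [smap.entries[g] for g in sorted(smap.entries)]}
    )
    df.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Interaction network
# ---------------------------------------------------------------------------


@dataclass
class InteractionNetwork:
    """Undirected confidence-filtered protein interaction network.

    ``graph`` is a :class:`networkx.Graph` whose edges carry a ``score``
    attribute strictly greater than ``confidence_threshold``.
    """

    graph: nx.Graph
    confidence_threshold: float = 0.5

    @property
    def nodes(self) -> list[str]:
        return sorted(self.graph.nodes)

    def n_nodes(self) -> int:
        return self.graph.number_of_nodes()

    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    def mapped_nodes(self, smap: StratumMap) -> list[str]:
        return [v for v in self.nodes if v in smap]


def read_network(path: str | Path, threshold: float = 0.5) -> InteractionNetwork:
    """Read an edge-list TSV, keeping edges with confidence strictly above
    ``threshold``.

    Self-loops are dropped and symmetric duplicates collapsed (the maximum
    score is kept).  STRING-style 0-1000 integer scores are detected from the
    maximum value and rescaled to 0-1.
    """
    if not 0 <= threshold < 1:
        raise ValueError(f"threshold must be in [0, 1), got {threshold}")
    df = pd.read_csv(path, sep="\t", dtype=str)
    cols = {c.lower(): c for c in df.columns}
    score_col = cols.get("combined_score") or cols.get("score")
    p1 = cols.get("protein1")
    p2 = cols.get("protein2")
    if score_col is None or p1 is None or p2 is None:
        raise ValueError(
            f"{path}: need columns protein1, protein2 and combined_score/score, got {list(df.columns)}"
        )
    scores = pd.to_numeric(df[score_col], errors="coerce")
    bad = scores.isna() | df[p1].isna() | df[p2].isna()
    if bad.any():
        line = int(bad.idxmax()) + 2
        raise ValueError(f"{path}: malformed row at line {line}")
    if scores.max() > 1.0:
        logger.info("%s: scores look STRING-scaled (max %.0f), dividing by 1000", path, scores.max())
        scores = scores / 1000.0

    g = nx.Graph()
    n_self, n_dup, n_low = 0, 0, 0
    for a, b, s in zip(df[p1].astype(str), df[p2].astype(str), scores):
        if a == b:
            n_self += 1
            continue
        if s <= threshold:
            n_low += 1
            continue
        if g.has_edge(a, b):
            n_dup += 1
            if s > g[a][b]["score"]:
                g[a][b]["score"] = float(s)
            continue
        g.add_edge(a, b, score=float(s))
    logger.info(
        "%s: kept %d edges (%d below threshold, %d self-loops, %d duplicates dropped)",
        path, g.number_of_edges(), n_low, n_self, n_dup,
    )
    if g.number_of_edges() == 0:
        raise ValueError("no edges above threshold")
    return InteractionNetwork(graph=g, confidence_threshold=float(threshold))


def write_network(net: InteractionNetwork, path: str | Path) -> None:
    """Write the canonical edge-list TSV (sorted node pairs, sorted rows)."""
    rows = sorted(
        (min(a, b), max(a, b), d["score"]) for a, b, d in net.graph.edges(data=True)
    )
    df = pd.DataFrame(rows, columns=["protein1", "protein2", "combined_score"])
    df.to_csv(path, sep="\t", index=False, float_format="%.9f")


# ---------------------------------------------------------------------------
# Gene-set flags (e.g. ZF-C2H2 / IPR036236)
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class GeneSetFlag:
    """A named gene set, e.g. the zinc-finger C2H2 superfamily members."""

    name: str
    members: frozenset[str]

    def restricted_to(self, universe: Iterable[str]) -> "GeneSetFlag":
        return GeneSetFlag(self.name, frozenset(self.members) & frozenset(universe))


def read_gene_set(path: str | Path, name: str | None = None) -> GeneSetFlag:
    """Read a one-column gene list (no header) into a :class:`GeneSetFlag`."""
    genes = [ln.strip() for ln in Path(path).read_text().splitlines() if ln.strip()]
    return GeneSetFlag(name or Path(path).stem, frozenset(genes))


# ---------------------------------------------------------------------------
# GO-like DAG
# ---------------------------------------------------------------------------


@dataclass
class GODag:
    """A GO-like acyclic term hierarchy with direct gene annotations.

    ``parents`` maps child term -> set of parent terms (``is_a`` semantics);
    ``direct`` maps term -> directly annotated genes.  ``namespaces`` is an
    optional term -> namespace (e.g. ``BP``/``CC``) map.
    """

    terms: set[str]
    parents: dict[str, set[str]]
    direct: dict[str, set[str]]
    namespaces: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for t in self.direct:
            if t not in self.terms:
                raise ValueError(f"annotated term {t!r} not in term set")
        for c, ps in self.parents.items():
            missing = ({c} | set(ps)) - self.terms
            if missing:
                raise ValueError(f"edge references unknown term(s) {sorted(missing)}")

    def children(self) -> dict[str, set[str]]:
        out: dict[str, set[str]] = {t: set() for t in self.terms}
        for c, ps in self.parents.items():
            for p in ps:
                out[p].add(c)
        return out


def read_go(edges_path: str | Path, annot_path: str | Path) -> GODag:
    """Read the two-TSV GO dialect: (term_child, term_parent) + (term, gene)."""
    e = pd.read_csv(edges_path, sep="\t", dtype=str)
    a = pd.read_csv(annot_path, sep="\t", dtype=str)
    parents: dict[str, set[str]] = {}
    terms: set[str] = set()
    for c, p in zip(e.iloc[:, 0], e.iloc[:, 1]):
        terms.update((c, p))
        parents.setdefault(c, set()).add(p)
    direct: dict[str, set[str]] = {}
    for t, g in zip(a.iloc[:, 0], a.iloc[:, 1]):
        terms.add(t)
        direct.setdefault(t, set()).add(g)
    return GODag(terms=terms, parents=parents, direct=direct)


def write_go(dag: GODag, edges_path: str | Path, annot_path: str | Path) -> None:
    rows = sorted((c, p) for c, ps in dag.parents.items() for p in ps)
    pd.DataFrame(rows, columns=["term_child", "term_parent"]).to_csv(
        edges_path, sep="\t", index=False
    )
    arows = sorted((t, g) for t, gs in dag.direct.items() for g in gs)
    pd.DataFrame(arows, columns=["term", "gene"]).to_csv(annot_path, sep="\t", index=False)


def read_obo(path: str | Path, annot_path: str | Path) -> GODag:
    """Adapter: read an OBO ontology (``is_a`` edges only) plus a
    ``term\tgene`` annotation TSV.  Requires :mod:`obonet`."""
    import obonet

    g = obonet.read_obo(path)
    # obonet edges point child -> parent for is_a
    parents: dict[str, set[str]] = {}
    namespaces: dict[str, str] = {}
    for c, p, key in g.edges(keys=True):
        if key == "is_a":
            parents.setdefault(c, set()).add(p)
    for t, data in g.nodes(data=True):
        if "namespace" in data:
            namespaces[t] = data["namespace"]
    a = pd.read_csv(annot_path, sep="\t", dtype=str)
    direct: dict[str, set[str]] = {}
    for t, gene in zip(a.iloc[:, 0], a.iloc[:, 1]):
        direct.setdefault(t, set()).add(gene)
    terms = set(g.nodes) | set(direct)
    return GODag(terms=terms, parents=parents, direct=direct, namespaces=namespaces)


def topological_order(dag: GODag) -> list[str]:
    """Terms ordered children-before-parents; raises on a cycle, naming a
    term that participates in it."""
    children = dag.children()
    # Kahn's algorithm on the child -> parent direction: a term is emitted
    # once all of its children have been emitted.
    pending = {t: len(children[t]) for t in dag.terms}
    ready = deque(sorted(t for t, k in pending.items() if k == 0))
    order: list[str] = []
    while ready:
        t = ready.popleft()
        order.append(t)
        for p in sorted(dag.parents.get(t, ())):
            pending[p] -= 1
            if pending[p] == 0:
                ready.append(p)
    if len(order) != len(dag.terms):
        on_cycle = sorted(t for t, k in pending.items() if k > 0)
        raise ValueError(f"cycle detected in term hierarchy involving {on_cycle[0]!r}")
    return order


def propagate_annotations(dag: GODag) -> dict[str, frozenset[str]]:
    """Propagate direct annotations up the DAG.

    A gene belongs to a term if it is directly annotated to that term or to
    any of its descendants, so every term's propagated set is the union of
    its direct genes and its children's propagated sets (superset property).
    """
    order = topological_order(dag)  # children first
    children = dag.children()
    out: dict[str, frozenset[str]] = {}
    for t in order:
        genes: set[str] = set(dag.direct.get(t, ()))
        for c in children[t]:
            genes |= out[c]
        out[t] = frozenset(genes)
    return out
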