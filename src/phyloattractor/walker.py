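"""Random-walk simulation of attractor dynamics on the interactome.

A walk starts at a uniformly chosen protein of the start stratum (default 17,
the youngest) and at every step moves to a uniformly chosen neighbor;
revisits are allowed.  Only the final node of each walk is tallied, by the
stratum of that endpoint, and tallies are normalized by the number of
stratum-mapped genes present in the filtered network (a per-stratum
gene-count table may be supplied to normalize against an external universe
instead).

On a connected non-bipartite graph the endpoint law of long walks converges
to the degree-proportional stationary distribution pi(v) = deg(v) / 2|E|, so
the normalized per-stratum frequency converges to (mean stratum degree)/2|E|.
This closed form is the primary oracle for the simulation: an old, densely
connected core attracts walk endpoints exactly in proportion to its excess
degree.

Randomness is counter-based: the uniform variates of step ``t`` come from a
Philox stream keyed by (master seed, t), and walk ``i`` reads element ``i``
of each stream.  Tallies are therefore independent of execution order and
identical however the repeats are batched.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .netio import InteractionNetwork, StratumMap, N_STRATA

logger = logging.getLogger("phyloattractor")


@dataclass(frozen=True)
class WalkConfig:
    """Ensemble parameters: 10,000 repeats and start stratum 17 by default."""

    n_repeats: int = 10_000
    walk_length: int = 1000
    start_stratum: int = 17
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_repeats < 1:
            raise ValueError("n_repeats must be >= 1")
        if self.walk_length < 0:
            raise ValueError("walk_length must be >= 0")
        if not 1 <= self.start_stratum <= N_STRATA:
            raise ValueError("start_stratum must be in 1..17")


@dataclass
class WalkEndDistribution:
    """Endpoint tallies per stratum, raw and gene-number-normalized."""

    raw_counts: dict[int, int]
    normalized: dict[int, float]
    config: WalkConfig
    n_dead_end_terminations: int = 0
    n_unmapped_endpoints: int = 0
    stratum_sizes: dict[int, int] = field(default_factory=dict)
    node_counts: dict[str, int] | None = None

    def node_fractions(self) -> dict[str, float]:
        if self.node_counts is None:
            raise ValueError("ensemble was run without keep_node_counts")
        n = self.config.n_repeats
        return {v: c / n for v, c in self.node_counts.items()}

    def endpoint_fractions(self) -> dict[int, float]:
        n = self.config.n_repeats
        return {s: c / n for s, c in self.raw_counts.items()}


def _step_rng(seed: int, step: int) -> np.random.Generator:
    key = np.random.SeedSequence(entropy=int(seed), spawn_key=(int(step),)).generate_state(
        2, dtype=np.uint64
    )
    return np.random.Generator(np.random.Philox(key=key))


def _csr_adjacency(net: InteractionNetwork) -> tuple[list[str], np.ndarray, np.ndarray]:
    """Sorted-node CSR adjacency with sorted neighbor lists (deterministic)."""
    nodes = net.nodes
    idx = {v: i for i, v in enumerate(nodes)}
    indptr = np.zeros(len(nodes) + 1, dtype=np.int64)
    neigh: list[int] = []
    for i, v in enumerate(nodes):
        ns = sorted(idx[w] for w in net.graph[v])
        neigh.extend(ns)
        indptr[i + 1] = len(neigh)
    return nodes, indptr, np.asarray(neigh, dtype=np.int64)


def random_walk(
    net: InteractionNetwork, start: str, length: int, rng: np.random.Generator
) -> str:
    """Walk ``length`` uniform-neighbor steps from ``start``; returns the
    final node.  An isolated start terminates immediately at itself."""
    if start not in net.graph:
        raise ValueError(f"start node {start!r} not in network")
    cur = start
    for _ in range(length):
        nbrs = sorted(net.graph[cur])
        if not nbrs:
            break
        cur = nbrs[int(rng.integers(len(nbrs)))]
    return cur


def run_ensemble(
    net: InteractionNetwork,
    strata: StratumMap,
    cfg: WalkConfig,
    stratum_sizes: dict[int, int] | None = None,
    keep_node_counts: bool = False,
) -> WalkEndDistribution:
    """Run the full walk ensemble and tally endpoints by stratum.

    ``stratum_sizes`` overrides the normalization denominators (e.g. with
    genome-wide per-stratum gene counts); by default the number of
    stratum-mapped nodes present in the network is used.  With
    ``keep_node_counts`` the per-node endpoint tallies are retained too.
    """
    nodes, indptr, neigh = _csr_adjacency(net)
    node_stratum = np.array(
        [strata.entries.get(v, 0) for v in nodes], dtype=np.int64
    )  # 0 = unmapped
    pool = np.flatnonzero(node_stratum == cfg.start_stratum)
    if pool.size == 0:
        raise ValueError(f"no network node in start stratum {cfg.start_stratum}")

    n = cfg.n_repeats
    deg = (indptr[1:] - indptr[:-1]).astype(np.int64)

    u0 = _step_rng(cfg.seed, 0).random(n)
    cur = pool[(u0 * pool.size).astype(np.int64)]
    n_dead = int(np.count_nonzero(deg[cur] == 0))

    for t in range(1, cfg.walk_length + 1):
        u = _step_rng(cfg.seed, t).random(n)
        d = deg[cur]
        offset = (u * d).astype(np.int64)
        pos = np.minimum(indptr[cur] + offset, neigh.size - 1) if neigh.size else np.zeros_like(cur)
        stepped = neigh[pos] if neigh.size else cur
        cur = np.where(d > 0, stepped, cur)

    end_strata = node_stratum[cur]
    counts = np.bincount(end_strata, minlength=N_STRATA + 1)
    raw = {s: int(counts[s]) for s in range(1, N_STRATA + 1)}
    n_unmapped = int(counts[0])

    if stratum_sizes is None:
        present = node_stratum[node_stratum > 0]
        sizes_arr = np.bincount(present, minlength=N_STRATA + 1)
        sizes = {s: int(sizes_arr[s]) for s in range(1, N_STRATA + 1)}
    else:
        sizes = {s: int(stratum_sizes.get(s, 0)) for s in range(1, N_STRATA + 1)}
    normalized = {
        s: (raw[s] / sizes[s] if sizes[s] > 0 else 0.0) for s in range(1, N_STRATA + 1)
    }
    node_counts = None
    if keep_node_counts:
        per_node = np.bincount(cur, minlength=len(nodes))
        node_counts = {v: int(c) for v, c in zip(nodes, per_node)}
    return WalkEndDistribution(
        raw_counts=raw,
        normalized=normalized,
        config=cfg,
        n_dead_end_terminations=n_dead,
        n_unmapped_endpoints=n_unmapped,
        stratum_sizes=sizes,
        node_counts=node_counts,
    )


def stationary_distribution(net: InteractionNetwork) -> dict[str, float]:
    """Closed-form long-walk endpoint law pi(v) = deg(v) / 2|E|."""
    two_m = 2 * net.n_edges()
    return {v: d / two_m for v, d in net.graph.degree()}


def total_variation(p: dict, q: dict) -> float:
    keys = set(p) | set(q)
    return 0.5 * sum(abs(p.get(k, 0.0) - q.get(k, 0.0)) for k in keys)


def length_sweep(
    net: InteractionNetwork,
    strata: StratumMap,
    lengths: list[int],
    cfg: WalkConfig,
    stratum_sizes: dict[int, int] | None = None,
) -> tuple[list[WalkEndDistribution], list[float]]:
    """One ensemble per walk length, with per-length seeds derived stably
    from the master seed.  Returns the distributions and the TV distance
    between successive lengths' endpoint-fraction profiles (convergence
    diagnostic)."""
    if not lengths:
        raise ValueError("lengths must be non-empty")
    dists: list[WalkEndDistribution] = []
    for length in lengths:
        sub_seed = int(
            np.random.SeedSequence(entropy=int(cfg.seed), spawn_key=(int(length), 1)).generate_state(1)[0]
            % (2**31)
        )
        sub = WalkConfig(
            n_repeats=cfg.n_repeats,
            walk_length=int(length),
            start_stratum=cfg.start_stratum,
            seed=sub_seed,
        )
        dists.append(run_ensemble(net, strata, sub, stratum_sizes=stratum_sizes))
    tv = [
        total_variation(a.endpoint_fractions(), b.endpoint_fractions())
        for a, b in zip(dists, dists[1:])
    ]
    for length, d in zip(lengths[1:], tv):
        logger.info("length_sweep: TV to previous length at %d steps = %.4f", length, d)
    return dists, tv
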