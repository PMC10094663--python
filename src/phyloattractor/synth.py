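"""Seed-deterministic generators for study-shaped synthetic data.

Three generators emit the statistical structure the analysis assumes, in the
same TSV dialects the readers consume:

* an age-layered interaction network grown stratum by stratum (oldest
  first), by degree-preferential attachment or duplication-divergence, so
  older strata accumulate degree and form the dense core that the walk and
  centrality analyses are meant to detect;
* a genes x cells expression matrix with two cell groups, a per-stratum
  baseline, and a planted per-stratum group effect delta(s) on the log2
  scale (the "gradual atavism" gradient) under lognormal or
  negative-binomial noise;
* a random GO-like DAG with direct annotations and optional planted terms
  whose genes can be shifted in a value table to plant enrichment signal.

Confidence scores are drawn in (0.5, 1] so fixtures pass the default filter
unchanged; an optional fraction of sub-threshold noise edges exercises it.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

from .expression import ExpressionMatrix
from .netio import GODag, InteractionNetwork, StratumMap, N_STRATA


def _default_counts() -> list[int]:
    return [30] * N_STRATA


@dataclass
class NetworkGenConfig:
    """Age-layered network growth parameters.

    ``n_per_stratum`` lists node counts for strata 1..17 (oldest first, the
    order in which nodes are added).  ``model`` is ``"pa"`` (age-ordered
    degree-preferential attachment, default) or ``"dd"``
    (duplication-divergence).  ``m`` is the number of edges a new node
    attaches under PA; ``divergence`` the per-neighbor drop probability
    under DD.
    """

    n_per_stratum: list[int] = field(default_factory=_default_counts)
    model: str = "pa"
    m: int = 3
    divergence: float = 0.3
    noise_edge_frac: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.n_per_stratum) != N_STRATA:
            raise ValueError(f"n_per_stratum must have {N_STRATA} entries")
        if any(c < 1 for c in self.n_per_stratum):
            raise ValueError("all stratum counts must be >= 1")
        if self.m < 1:
            raise ValueError("m must be >= 1")
        if self.model not in ("pa", "dd"):
            raise ValueError("model must be 'pa' or 'dd'")


def gen_network(cfg: NetworkGenConfig) -> tuple[InteractionNetwork, StratumMap]:
    """Grow the age-layered network; returns the network and its stratum map.

    Nodes enter in stratum order 1 -> 17.  Under PA each newcomer attaches
    ``min(m, existing)`` edges to distinct nodes with probability
    proportional to degree+1; under DD it copies a random template's
    neighborhood, dropping each neighbor with probability ``divergence``
    (falling back to an edge to the template if everything was dropped).
    Earlier strata therefore accumulate degree - the planted core-periphery
    age gradient.
    """
    rng = np.random.default_rng(cfg.seed)
    total = sum(cfg.n_per_stratum)
    names = [f"G{i:05d}" for i in range(total)]
    entries: dict[str, int] = {}
    i = 0
    for s, count in enumerate(cfg.n_per_stratum, start=1):
        for _ in range(count):
            entries[names[i]] = s
            i += 1

    g = nx.Graph()
    g.add_node(names[0])
    deg = np.zeros(total, dtype=np.int64)
    name_idx = {v: i for i, v in enumerate(names)}

    def score() -> float:
        return float(1.0 - 0.5 * rng.random())  # in (0.5, 1]

    for i in range(1, total):
        new = names[i]
        g.add_node(new)
        if cfg.model == "pa":
            k = min(cfg.m, i)
            w = deg[:i] + 1.0
            targets = rng.choice(i, size=k, replace=False, p=w / w.sum())
            for t in targets:
                g.add_edge(new, names[t], score=score())
                deg[t] += 1
                deg[i] += 1
        else:  # duplication-divergence
            t = int(rng.integers(i))
            template = names[t]
            kept = [w for w in sorted(g[template]) if rng.random() >= cfg.divergence]
            if not kept:
                kept = [template]
            for w in kept:
                g.add_edge(new, w, score=score())
                deg[name_idx[w]] += 1
                deg[i] += 1

    if cfg.noise_edge_frac > 0:
        n_noise = int(cfg.noise_edge_frac * g.number_of_edges())
        for _ in range(n_noise):
            a, b = rng.choice(total, size=2, replace=False)
            if not g.has_edge(names[a], names[b]):
                # sub-threshold score: dropped by the default >0.5 filter
                g.add_edge(names[a], names[b], score=float(0.5 * rng.random()))

    return InteractionNetwork(graph=g, confidence_threshold=0.5), StratumMap(entries)


# ---------------------------------------------------------------------------
# Expression
# ---------------------------------------------------------------------------


def _per_stratum(x, default: float) -> np.ndarray:
    """Coerce a scalar, length-17 sequence or callable to a 17-vector."""
    if x is None:
        return np.full(N_STRATA, default)
    if callable(x):
        return np.array([float(x(s)) for s in range(1, N_STRATA + 1)])
    arr = np.asarray(x, dtype=float)
    if arr.ndim == 0:
        return np.full(N_STRATA, float(arr))
    if arr.shape != (N_STRATA,):
        raise ValueError(f"expected scalar or {N_STRATA}-vector")
    return arr


@dataclass
class ExpressionGenConfig:
    """Planted expression structure.

    ``baseline`` and ``delta`` are per-stratum log2-scale vectors (scalar,
    17-sequence or callable of stratum); group A cells are shifted by
    delta(s).  The default baseline declines with stratum age rank,
    emulating higher expression of ancient genes; the default delta is 0
    (null).  Noise is lognormal (sd ``sigma`` on the log2 scale) or
    negative-binomial with ``dispersion``.
    """

    baseline: object = None
    delta: object = None
    noise: str = "lognormal"
    sigma: float = 0.5
    dispersion: float = 5.0
    n_cells: int = 50
    data_kind: str = "intensity"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_cells < 2:
            raise ValueError("n_cells must be >= 2 per group")
        if self.noise not in ("lognormal", "negative-binomial"):
            raise ValueError("noise must be 'lognormal' or 'negative-binomial'")
        if self.dispersion <= 0:
            raise ValueError("dispersion must be > 0")

    def baseline_vector(self) -> np.ndarray:
        if self.baseline is None:
            return np.array([8.0 - 0.15 * (s - 1) for s in range(1, N_STRATA + 1)])
        return _per_stratum(self.baseline, 0.0)

    def delta_vector(self) -> np.ndarray:
        return _per_stratum(self.delta, 0.0)


def gen_expression(cfg: ExpressionGenConfig, strata: StratumMap) -> ExpressionMatrix:
    """Genes x cells matrix with the planted group effect.

    Gene g of stratum s has log2 mean ``baseline[s]`` in group B and
    ``baseline[s] + delta[s]`` in group A.  Lognormal noise adds a normal
    deviate on the log2 scale and exponentiates; negative-binomial draws
    counts with the corresponding linear-scale mean.
    """
    rng = np.random.default_rng(cfg.seed)
    genes = sorted(strata.entries)
    s_idx = np.array([strata.entries[g] - 1 for g in genes])
    base = cfg.baseline_vector()[s_idx]
    delta = cfg.delta_vector()[s_idx]

    n = cfg.n_cells
    cells = [f"a{j:04d}" for j in range(n)] + [f"b{j:04d}" for j in range(n)]
    groups = pd.Series(["group_a"] * n + ["group_b"] * n, index=cells)
    log_mean = base[:, None] + delta[:, None] * np.array([1.0] * n + [0.0] * n)[None, :]

    if cfg.noise == "lognormal":
        X = 2.0 ** (log_mean + rng.normal(0.0, cfg.sigma, size=log_mean.shape))
    else:
        mu = 2.0**log_mean
        r = cfg.dispersion
        X = rng.negative_binomial(r, r / (r + mu)).astype(float)
    return ExpressionMatrix(
        values=pd.DataFrame(X, index=genes, columns=cells),
        groups=groups,
        name="synthetic",
        log_transformed=False,
    )


# ---------------------------------------------------------------------------
# GO DAG
# ---------------------------------------------------------------------------


@dataclass
class GOGenConfig:
    """Random DAG shape and planted enrichment."""

    n_terms: int = 40
    max_depth: int = 4
    annotation_rate: float = 0.01
    n_planted: int = 0
    planted_size: int = 50
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_terms < 1:
            raise ValueError("n_terms must be >= 1")
        if self.max_depth < 1:
            raise ValueError("max_depth must be >= 1")


def gen_go(cfg: GOGenConfig, genes) -> tuple[GODag, dict[str, frozenset[str]]]:
    """Random acyclic term hierarchy with direct annotations.

    Term 0 is the root (depth 0); every other term gets a random depth in
    1..max_depth and 1-2 parents among strictly shallower terms, so the
    result is acyclic by construction.  The last ``n_planted`` terms are
    leaves hanging off the root whose direct annotations are dedicated,
    mutually disjoint samples of ``planted_size`` genes, reserved before any
    random annotation so the planted ground truth is unambiguous; the
    remaining non-root terms annotate each unreserved gene independently
    with probability ``annotation_rate``.  The planted samples are returned
    so a caller can plant a value shift on them.
    """
    rng = np.random.default_rng(cfg.seed)
    genes = sorted(genes)
    names = [f"T{i:04d}" for i in range(cfg.n_terms)]
    depth = {names[0]: 0}
    parents: dict[str, set[str]] = {}
    for i in range(1, cfg.n_terms):
        d = int(rng.integers(1, cfg.max_depth + 1))
        shallower = [t for t in names[:i] if depth[t] < d]
        if not shallower:
            shallower = [names[0]]
            d = 1
        k = min(int(rng.integers(1, 3)), len(shallower))
        ps = rng.choice(len(shallower), size=k, replace=False)
        parents[names[i]] = {shallower[j] for j in ps}
        depth[names[i]] = d

    planted: dict[str, frozenset[str]] = {}
    direct: dict[str, set[str]] = {}
    reserved: set[str] = set()
    if cfg.n_planted:
        if cfg.n_planted * cfg.planted_size > len(genes):
            raise ValueError("not enough genes for the requested planted terms")
        pool = rng.permutation(len(genes))
        for j in range(cfg.n_planted):
            t = names[cfg.n_terms - 1 - j]
            members = frozenset(
                genes[k] for k in pool[j * cfg.planted_size : (j + 1) * cfg.planted_size]
            )
            direct[t] = set(members)
            parents[t] = {names[0]}  # planted leaves hang off the root
            planted[t] = members
            reserved |= members

    free = [g for g in genes if g not in reserved]
    for t in names[1 : cfg.n_terms - cfg.n_planted]:
        mask = rng.random(len(free)) < cfg.annotation_rate
        chosen = {g for g, m in zip(free, mask) if m}
        if chosen:
            direct[t] = chosen
    return GODag(terms=set(names), parents=parents, direct=direct), planted


def apply_planted_shift(values: pd.Series, members, delta: float) -> pd.Series:
    """Return a copy of a value table with ``delta`` added to the listed
    genes (the enrichment generator's planting hook)."""
    out = values.astype(float).copy()
    idx = [g for g in members if g in out.index]
    out.loc[idx] = out.loc[idx] + delta
    return out
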