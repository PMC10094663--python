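"""Monte-Carlo contrast enrichment over a GO-like DAG.

For every term the statistic is the difference between the mean per-gene
value (typically a log2 fold) of the term's DAG-propagated gene set and the
mean over all measured genes ("fold difference").  Significance comes from
random samplings: for a term with k measured genes, ``n_samples`` subsets of
size k are drawn from the measured universe without replacement within a
sample (the pool is fully replaced between samples), and significance comes
from how often a random sample mean reaches the category mean: the
two-tailed p-value is twice the smaller add-one-smoothed tail probability,
capped at 1.  The sampling follows the empirical value distribution, so no
distributional assumption is made.

Category genes stay in the sampling pool, and the baseline universe is the
set of genes present in the value table.  Benjamini-Hochberg q-values are
attached (Benjamini-Yekutieli available behind a flag).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

from .netio import GODag, propagate_annotations

logger = logging.getLogger("phyloattractor")


@dataclass
class ContrastResult:
    term: str
    n_genes: int
    category_mean: float
    total_mean: float
    fold_difference: float
    p_value: float
    q_value: float = np.nan


def _sample_means(
    values: np.ndarray, k: int, n_samples: int, rng: np.random.Generator
) -> np.ndarray:
    """Means of ``n_samples`` size-k subsets drawn without replacement.

    For k*(k-1) <= n the birthday-problem duplicate probability is modest
    and a rejection scheme (redraw rows with duplicate indices) is used;
    otherwise each sample takes the first k entries of a random permutation
    ranking.  Both are deterministic given the generator state.
    """
    n = values.size
    if k > n:
        raise ValueError(f"category size {k} exceeds universe size {n}")
    if k == n:
        return np.full(n_samples, values.mean())
    if k * (k - 1) <= n:
        idx = rng.integers(0, n, size=(n_samples, k))
        while True:
            srt = np.sort(idx, axis=1)
            bad = np.flatnonzero((np.diff(srt, axis=1) == 0).any(axis=1))
            if bad.size == 0:
                break
            idx[bad] = rng.integers(0, n, size=(bad.size, k))
    else:
        keys = rng.random((n_samples, n))
        idx = np.argpartition(keys, k - 1, axis=1)[:, :k]
    return values[idx].mean(axis=1)


def contrast_test(
    values: pd.Series,
    category_genes,
    n_samples: int = 20_000,
    seed: int = 0,
    rng: np.random.Generator | None = None,
) -> ContrastResult:
    """Two-tailed Monte-Carlo contrast of a category mean against the total
    mean of the value table.

    With upper/lower tail counts over the sample means,
    ``p_tail = (1 + #hits) / (1 + n_samples)`` (add-one smoothing, so p is
    never 0) and ``p = min(1, 2 * min(p_upper, p_lower))``.
    """
    vals = values.astype(float)
    genes = [g for g in category_genes if g in vals.index]
    if not genes:
        raise ValueError("category has no measured gene")
    arr = vals.to_numpy()
    total_mean = float(arr.mean())
    cat_mean = float(vals.loc[genes].mean())
    if rng is None:
        rng = np.random.default_rng(seed)
    means = _sample_means(arr, len(genes), n_samples, rng)
    tol = 1e-12 * max(1.0, abs(cat_mean))
    n_hi = int(np.count_nonzero(means >= cat_mean - tol))
    n_lo = int(np.count_nonzero(means <= cat_mean + tol))
    p_hi = (1 + n_hi) / (1 + n_samples)
    p_lo = (1 + n_lo) / (1 + n_samples)
    p = min(1.0, 2.0 * min(p_hi, p_lo))
    return ContrastResult(
        term="",
        n_genes=len(genes),
        category_mean=cat_mean,
        total_mean=total_mean,
        fold_difference=cat_mean - total_mean,
        p_value=p,
    )


def fdr_correct(p_values, method: str = "bh") -> np.ndarray:
    """Benjamini-Hochberg (default) or Benjamini-Yekutieli q-values."""
    p = np.asarray(list(p_values), dtype=float)
    if p.size == 0:
        return p
    mt_method = {"bh": "fdr_bh", "by": "fdr_by"}[method]
    return multipletests(p, method=mt_method)[1]


def run_enrichment(
    values: pd.Series,
    dag: GODag,
    namespace: str | None = None,
    min_size: int = 21,
    n_samples: int = 20_000,
    seed: int = 0,
    fdr_method: str = "bh",
) -> pd.DataFrame:
    """Contrast test for every sufficiently large term of the DAG.

    Annotations are propagated up the DAG first, then intersected with the
    measured genes; terms with fewer than ``min_size`` measured genes are
    dropped (the conventional cutoffs are >20 genes for processes and >10
    for components).  Each term gets an independent random substream derived
    from ``seed``, so results do not depend on term evaluation order.
    Returns a DataFrame sorted by fold_difference (descending) with columns
    term, n_genes, category_mean, total_mean, fold_difference, p, q.
    """
    propagated = propagate_annotations(dag)
    terms = sorted(propagated)
    if namespace is not None:
        terms = [t for t in terms if dag.namespaces.get(t) == namespace]
    vals = values.astype(float)
    measured = frozenset(vals.index)

    results: list[ContrastResult] = []
    for i, t in enumerate(terms):
        genes = propagated[t] & measured
        if len(genes) < min_size:
            continue
        sub = np.random.Generator(
            np.random.Philox(
                key=np.random.SeedSequence(entropy=int(seed), spawn_key=(i,)).generate_state(
                    2, dtype=np.uint64
                )
            )
        )
        res = contrast_test(vals, genes, n_samples=n_samples, rng=sub)
        res.term = t
        results.append(res)
    if not results:
        logger.warning("run_enrichment: no term passes min_size=%d", min_size)
        return pd.DataFrame(
            columns=["term", "n_genes", "category_mean", "total_mean", "fold_difference", "p", "q"]
        )
    q = fdr_correct([r.p_value for r in results], method=fdr_method)
    for r, qv in zip(results, q):
        r.q_value = float(qv)
    df = pd.DataFrame(
        {
            "term": [r.term for r in results],
            "n_genes": [r.n_genes for r in results],
            "category_mean": [r.category_mean for r in results],
            "total_mean": [r.total_mean for r in results],
            "fold_difference": [r.fold_difference for r in results],
            "p": [r.p_value for r in results],
            "q": [r.q_value for r in results],
        }
    )
    return df.sort_values("fold_difference", ascending=False).reset_index(drop=True)
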