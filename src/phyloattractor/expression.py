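"""Expression normalization, group folds and phylostratic profiles.

The workflow mirrors a standard two-group single-cell contrast: quantile
normalization across cells followed by a log2 transform, per-gene group
means, a log2 fold per gene (group A minus group B), and per-stratum or
per-stratum-bin summaries of either expression levels or folds.  Fold
orientation is fixed so that positive means up in the first-named group
(cancer, invasive, polyploid).

An analysis-of-means (ANOM) helper flags strata whose mean deviates from the
grand mean beyond simultaneous decision limits, and a composition helper
reports how a gene set distributes over strata together with the Spearman
rank correlation of that profile against stratum index.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .netio import GeneSetFlag, StratumMap, N_STRATA

logger = logging.getLogger("phyloattractor")

#: Default stratum bins for fold profiles: the ancient peak strata kept
#: separate, then Metazoa-Bilateria, Chordata-Euteleostomi, and the rest.
DEFAULT_BINS: tuple[tuple[int, int], ...] = ((1, 1), (2, 2), (3, 3), (4, 6), (7, 9), (10, 17))


# ---------------------------------------------------------------------------
# Containers
# ---------------------------------------------------------------------------


@dataclass
class ExpressionMatrix:
    """Genes x cells matrix with a two-group cell labeling.

    ``values`` has gene identifiers as the index and cell identifiers as
    columns; ``groups`` maps every cell to its label.  ``log_transformed``
    records whether values are already on the log2 scale.
    """

    values: pd.DataFrame
    groups: pd.Series
    name: str = "dataset"
    log_transformed: bool = False

    def __post_init__(self) -> None:
        missing = set(self.values.columns) - set(self.groups.index)
        if missing:
            raise ValueError(f"cells without group label: {sorted(missing)[:3]}...")
        self.groups = self.groups.loc[self.values.columns]
        counts = self.groups.value_counts()
        if len(counts) != 2:
            raise ValueError(f"expected exactly two cell groups, got {list(counts.index)}")
        if (counts < 2).any():
            raise ValueError("each group needs at least 2 cells")
        if not self.log_transformed and (self.values.to_numpy() < 0).any():
            raise ValueError("negative entries in a pre-log expression matrix")

    @property
    def group_labels(self) -> tuple[str, str]:
        return tuple(sorted(self.groups.unique()))  # type: ignore[return-value]

    def cells_of(self, label: str) -> list[str]:
        return list(self.groups.index[self.groups == label])


@dataclass
class FoldTable:
    """Per-gene log2 contrast (group_a mean - group_b mean) with the group
    means retained.  ``table`` columns: mean_a, mean_b, log2_fold."""

    table: pd.DataFrame
    group_a: str
    group_b: str
    dataset: str = "dataset"

    @property
    def folds(self) -> pd.Series:
        return self.table["log2_fold"]


@dataclass
class StratumProfile:
    """Per-stratum-bin mean/sem/n of a per-gene value (level or fold)."""

    table: pd.DataFrame  # index bin label; columns lo, hi, mean, sem, n
    value_kind: str = "fold"
    zfc2h2_excluded: bool = False
    n_unmapped: int = 0


@dataclass
class ANOMResult:
    """Analysis-of-means decision: per-stratum means against the grand mean
    with simultaneous decision limits at family level alpha."""

    table: pd.DataFrame  # index stratum; mean, n, lower, upper, flagged
    grand_mean: float
    pooled_sd: float
    alpha: float
    h: float
    excluded_strata: list[int] = field(default_factory=list)


# ---------------------------------------------------------------------------
# Normalization
# ---------------------------------------------------------------------------


def quantile_normalize(
    mat: ExpressionMatrix, log2_offset: float = 1.0, data_kind: str = "counts"
) -> ExpressionMatrix:
    """Quantile-normalize cells to a common distribution, then log2.

    Every cell's sorted value vector is replaced by the across-cell mean of
    sorted vectors; ties within a cell receive the mean of the tied
    reference quantiles (rank interpolation).  A log2(x + offset) transform
    follows; for continuous intensity data (``data_kind="intensity"``) the
    offset is skipped.
    """
    if mat.log_transformed:
        raise ValueError("matrix is already log-transformed")
    X = mat.values.to_numpy(dtype=float)
    if (X < 0).any():
        raise ValueError("negative entries")
    n_genes = X.shape[0]
    ref = np.sort(X, axis=0).mean(axis=1)
    out = np.empty_like(X)
    grid = np.arange(1, n_genes + 1, dtype=float)
    for j in range(X.shape[1]):
        ranks = stats.rankdata(X[:, j], method="average")
        out[:, j] = np.interp(ranks, grid, ref)
    offset = 0.0 if data_kind == "intensity" else float(log2_offset)
    if offset == 0.0 and (out <= 0).any():
        raise ValueError("zero values with no log offset; use counts data_kind")
    logged = np.log2(out + offset)
    return ExpressionMatrix(
        values=pd.DataFrame(logged, index=mat.values.index, columns=mat.values.columns),
        groups=mat.groups,
        name=mat.name,
        log_transformed=True,
    )


# ---------------------------------------------------------------------------
# Folds
# ---------------------------------------------------------------------------


def group_fold(mat: ExpressionMatrix, group_a: str, group_b: str) -> FoldTable:
    """log2 fold per gene: mean over ``group_a`` cells minus mean over
    ``group_b`` cells, on an already log-transformed matrix."""
    if not mat.log_transformed:
        raise ValueError("group_fold expects a log-transformed matrix")
    cells_a = mat.cells_of(group_a)
    cells_b = mat.cells_of(group_b)
    if not cells_a or not cells_b:
        raise ValueError(f"empty group among ({group_a!r}, {group_b!r})")
    mean_a = mat.values[cells_a].mean(axis=1)
    mean_b = mat.values[cells_b].mean(axis=1)
    table = pd.DataFrame({"mean_a": mean_a, "mean_b": mean_b, "log2_fold": mean_a - mean_b})
    return FoldTable(table=table, group_a=group_a, group_b=group_b, dataset=mat.name)


def read_fold_table(path, group_a: str = "group_a", group_b: str = "group_b") -> FoldTable:
    """Read a precomputed ``gene\tlog2fold`` TSV (e.g. polyploid/diploid
    pancancer folds), bypassing normalization."""
    df = pd.read_csv(path, sep="\t", dtype={0: str})
    df = df.set_index(df.columns[0])
    folds = pd.to_numeric(df.iloc[:, 0])
    table = pd.DataFrame({"mean_a": np.nan, "mean_b": np.nan, "log2_fold": folds})
    return FoldTable(table=table, group_a=group_a, group_b=group_b)


# ---------------------------------------------------------------------------
# Stratum profiles
# ---------------------------------------------------------------------------


def _check_bins(bins) -> list[tuple[int, int]]:
    bins = [(int(lo), int(hi)) for lo, hi in bins]
    covered = sorted(s for lo, hi in bins for s in range(lo, hi + 1))
    if covered != list(range(1, N_STRATA + 1)):
        raise ValueError(f"bins must partition 1..{N_STRATA}, got {bins}")
    return bins


def stratum_profile(
    values: pd.Series,
    strata: StratumMap,
    bins=DEFAULT_BINS,
    exclude: GeneSetFlag | None = None,
    value_kind: str = "fold",
) -> StratumProfile | tuple[StratumProfile, StratumProfile]:
    """Per-bin mean/sem/n of a per-gene value table.

    Only genes present in both the value table and the stratum map enter;
    missing ones are counted and logged.  With ``exclude`` given, returns a
    pair (profile without the flagged genes, profile with them retained) so
    the two series can be overlaid.  Empty bins are reported with n=0 and
    NaN mean rather than dropped.
    """
    bins = _check_bins(bins)
    if exclude is not None:
        without = stratum_profile(
            values.drop(index=[g for g in exclude.members if g in values.index]),
            strata,
            bins=bins,
            value_kind=value_kind,
        )
        assert isinstance(without, StratumProfile)
        without.zfc2h2_excluded = True
        full = stratum_profile(values, strata, bins=bins, value_kind=value_kind)
        assert isinstance(full, StratumProfile)
        return without, full

    smap = strata.to_series()
    common = values.index.intersection(smap.index)
    n_unmapped = len(values) - len(common)
    if n_unmapped:
        logger.info("stratum_profile: %d gene(s) without stratum excluded", n_unmapped)
    vals = values.loc[common].astype(float)
    gs = smap.loc[common]
    rows = []
    for lo, hi in bins:
        label = f"{lo}" if lo == hi else f"{lo}-{hi}"
        x = vals[(gs >= lo) & (gs <= hi)].to_numpy()
        rows.append(
            {
                "bin": label,
                "lo": lo,
                "hi": hi,
                "n": len(x),
                "mean": float(np.mean(x)) if len(x) else np.nan,
                "sem": float(np.std(x, ddof=1) / np.sqrt(len(x))) if len(x) > 1 else (0.0 if len(x) == 1 else np.nan),
            }
        )
    table = pd.DataFrame(rows).set_index("bin")
    if (table["n"] == 0).any():
        logger.warning("stratum_profile: empty bin(s) %s", list(table.index[table["n"] == 0]))
    return StratumProfile(table=table, value_kind=value_kind, n_unmapped=n_unmapped)


def profile_slope(profile: StratumProfile) -> tuple[float, float]:
    """Weighted least-squares slope of bin means against bin midpoints.

    Returns (slope, standard error); bins with n==0 are skipped.  Used to
    quantify a monotone age gradient in fold or level profiles.
    """
    t = profile.table[profile.table["n"] > 0]
    x = (t["lo"] + t["hi"]).to_numpy(dtype=float) / 2
    y = t["mean"].to_numpy(dtype=float)
    w = t["n"].to_numpy(dtype=float)
    W = np.sum(w)
    xb = np.sum(w * x) / W
    yb = np.sum(w * y) / W
    sxx = np.sum(w * (x - xb) ** 2)
    slope = np.sum(w * (x - xb) * (y - yb)) / sxx
    resid = y - (yb + slope * (x - xb))
    dof = max(len(x) - 2, 1)
    s2 = np.sum(w * resid**2) / dof
    return float(slope), float(np.sqrt(s2 / sxx))


# ---------------------------------------------------------------------------
# Analysis of means
# ---------------------------------------------------------------------------


def anom(
    values: pd.Series,
    strata: StratumMap,
    alpha: float = 0.05,
    method: str = "normal",
    n_sim: int = 2000,
    seed: int = 0,
) -> ANOMResult:
    """Analysis of means over strata at family significance ``alpha``.

    Each stratum mean is compared with the grand mean; decision limits are
    ``grand +- h * pooled_sd * sqrt(1/n_i - 1/N)``.  With
    ``method="normal"`` the critical value h is a Bonferroni-adjusted t
    quantile; ``method="montecarlo"`` calibrates h by permuting stratum
    labels and taking the (1-alpha) quantile of the maximum standardized
    deviation.  Strata with fewer than 2 genes are excluded with a warning.
    """
    smap = strata.to_series()
    common = values.index.intersection(smap.index)
    vals = values.loc[common].astype(float)
    gs = smap.loc[common]

    groups = {s: vals[gs == s].to_numpy() for s in sorted(gs.unique())}
    excluded = [s for s, x in groups.items() if len(x) < 2]
    for s in excluded:
        logger.warning("anom: stratum %d has n<2, excluded", s)
    groups = {s: x for s, x in groups.items() if len(x) >= 2}
    if len(groups) < 2:
        raise ValueError("need at least 2 strata with n >= 2")

    ns = np.array([len(x) for x in groups.values()], dtype=float)
    N = ns.sum()
    k = len(groups)
    all_vals = np.concatenate(list(groups.values()))
    grand = float(all_vals.mean())
    ss_within = sum(float(((x - x.mean()) ** 2).sum()) for x in groups.values())
    pooled_sd = float(np.sqrt(ss_within / (N - k)))

    scale = pooled_sd * np.sqrt(1.0 / ns - 1.0 / N)
    if method == "normal":
        h = float(stats.t.ppf(1 - alpha / (2 * k), df=N - k))
    elif method == "montecarlo":
        rng = np.random.default_rng(seed)
        sizes = ns.astype(int)
        maxima = np.empty(n_sim)
        for b in range(n_sim):
            perm = rng.permutation(all_vals)
            offs = np.concatenate(([0], np.cumsum(sizes)))
            means = np.array([perm[offs[i]: offs[i + 1]].mean() for i in range(k)])
            maxima[b] = np.max(np.abs(means - grand) / scale)
        h = float(np.quantile(maxima, 1 - alpha))
    else:
        raise ValueError(f"unknown method {method!r}")

    rows = []
    for (s, x), sc in zip(groups.items(), scale):
        m = float(x.mean())
        lo, hi = grand - h * sc, grand + h * sc
        rows.append(
            {"stratum": s, "n": len(x), "mean": m, "lower": lo, "upper": hi,
             "flagged": bool(m < lo or m > hi)}
        )
    table = pd.DataFrame(rows).set_index("stratum")
    return ANOMResult(
        table=table, grand_mean=grand, pooled_sd=pooled_sd, alpha=alpha, h=h,
        excluded_strata=excluded,
    )


def plot_anom(result: ANOMResult, path, title: str = "Analysis of means") -> None:
    """Write the classic ANOM decision plot (means, grand mean, limits)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    t = result.table
    fig, ax = plt.subplots(figsize=(7, 4))
    ax.plot(t.index, t["mean"], "o-", color="black", label="stratum mean")
    ax.plot(t.index, t["lower"], "r:", label=f"decision limits (alpha={result.alpha})")
    ax.plot(t.index, t["upper"], "r:")
    ax.axhline(result.grand_mean, color="gray", lw=1, label="grand mean")
    flagged = t[t["flagged"]]
    if not flagged.empty:
        ax.plot(flagged.index, flagged["mean"], "rs", label="flagged")
    ax.set_xlabel("phylostratum")
    ax.set_ylabel("mean value")
    ax.set_title(title)
    ax.legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


# ---------------------------------------------------------------------------
# Gene-set stratum composition
# ---------------------------------------------------------------------------


def stratum_composition(
    gene_set, strata: StratumMap, normalize: str = "set"
) -> tuple[pd.DataFrame, float, float]:
    """Distribution of a gene set over strata and its age trend.

    ``normalize="set"`` reports (set genes in stratum)/(mapped set genes);
    ``normalize="stratum"`` divides instead by the stratum's total gene
    count in the map.  Returns (table, Spearman r, p) where the correlation
    is taken between the per-stratum proportion and the stratum index.
    """
    members = [g for g in gene_set if g in strata]
    if not members:
        raise ValueError("gene set has no stratum-mapped member")
    per = {s: 0 for s in range(1, N_STRATA + 1)}
    for g in members:
        per[strata.stratum_of(g)] += 1
    totals = strata.counts()
    rows = []
    for s in range(1, N_STRATA + 1):
        if normalize == "set":
            prop = per[s] / len(members)
        elif normalize == "stratum":
            prop = per[s] / totals[s] if totals[s] else np.nan
        else:
            raise ValueError(f"unknown normalize {normalize!r}")
        rows.append({"stratum": s, "n_set": per[s], "n_stratum": totals[s], "proportion": prop})
    table = pd.DataFrame(rows).set_index("stratum")
    ok = table["proportion"].notna()
    if ok.sum() < 3:
        raise ValueError("need >= 3 strata with defined proportions")
    r, p = stats.spearmanr(table.index[ok], table.loc[ok, "proportion"])
    return table, float(r), float(p)
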