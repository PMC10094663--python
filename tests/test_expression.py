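"""Normalization, folds, stratum profiles, ANOM and composition."""

from __future__ import annotations

import subprocess
import shutil

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

from phyloattractor import (
    DEFAULT_BINS,
    ExpressionMatrix,
    GeneSetFlag,
    StratumMap,
    anom,
    group_fold,
    profile_slope,
    quantile_normalize,
    stratum_composition,
    stratum_profile,
)


def make_matrix(values, groups=None, log=False):
    df = pd.DataFrame(values)
    df.index = [f"g{i}" for i in range(df.shape[0])]
    df.columns = [f"c{i}" for i in range(df.shape[1])]
    if groups is None:
        half = df.shape[1] // 2
        groups = ["group_a"] * half + ["group_b"] * (df.shape[1] - half)
    return ExpressionMatrix(
        values=df, groups=pd.Series(groups, index=df.columns), log_transformed=log
    )


class TestQuantileNormalize:
    def test_identical_columns_fixed_point(self):
        mat = make_matrix(np.tile([[1.0], [5.0], [3.0], [7.0]], (1, 4)))
        out = quantile_normalize(mat)
        linear = 2.0**out.values - 1
        assert np.allclose(linear, mat.values.to_numpy())

    def test_two_profile_hand_example(self):
        # columns alternate between (1,2,3) and (4,5,6); the across-cell
        # mean of sorted vectors is (2.5, 3.5, 4.5), so every column becomes
        # exactly that on the linear scale
        mat = make_matrix(np.array([[1.0, 4.0, 1.0, 4.0], [2.0, 5.0, 2.0, 5.0], [3.0, 6.0, 3.0, 6.0]]))
        out = quantile_normalize(mat)
        linear = 2.0**out.values.to_numpy() - 1
        expected = np.tile([[2.5], [3.5], [4.5]], (1, 4))
        assert np.allclose(linear, expected)

    def test_columns_share_sorted_values(self):
        rng = np.random.default_rng(0)
        mat = make_matrix(rng.gamma(2.0, 10.0, size=(40, 6)))
        out = quantile_normalize(mat)
        X = out.values.to_numpy()
        ref = np.sort(X[:, 0])
        for j in range(1, X.shape[1]):
            assert np.allclose(np.sort(X[:, j]), ref)

    def test_total_sum_preserved_pre_log(self):
        rng = np.random.default_rng(1)
        mat = make_matrix(rng.gamma(2.0, 10.0, size=(30, 4)))
        out = quantile_normalize(mat)
        linear = 2.0**out.values.to_numpy() - 1
        assert linear.sum() == pytest.approx(mat.values.to_numpy().sum(), rel=1e-9)

    @given(
        arrays(
            np.float64,
            st.tuples(st.integers(3, 12), st.just(4)),
            elements=st.floats(min_value=0.0, max_value=1e4, allow_nan=False),
        )
    )
    @settings(deadline=None, max_examples=40, derandomize=True)
    def test_sorted_column_identity_for_tie_free_matrices(self, X):
        # the identity is exact only for tie-free columns: tied entries
        # receive the mean of their tied reference quantiles (as in limma),
        # which departs from the reference vector itself
        X = X + np.arange(X.size, dtype=float).reshape(X.shape) * 1e-7
        out = quantile_normalize(make_matrix(X))
        Y = out.values.to_numpy()
        ref = np.sort(Y[:, 0])
        for j in range(1, Y.shape[1]):
            assert np.allclose(np.sort(Y[:, j]), ref, atol=1e-9)

    def test_negative_input_rejected(self):
        with pytest.raises(ValueError, match="negative"):
            make_matrix(np.array([[1.0, -2.0, 1.0, 1.0], [3.0, 4.0, 2.0, 2.0]]))

    def test_matches_limma_reference(self, tmp_path):
        """Cross-check against the Bioconductor reference implementation
        (limma::normalizeQuantiles) on a small matrix with ties."""
        if shutil.which("Rscript") is None:
            pytest.skip("Rscript not on PATH")
        rng = np.random.default_rng(3)
        X = np.round(rng.gamma(2.0, 5.0, size=(12, 5)), 1)
        X[3, :] = X[4, :]  # plant ties
        mat = make_matrix(X, groups=["group_a"] * 3 + ["group_b"] * 2)
        out = quantile_normalize(mat)
        mine = 2.0**out.values.to_numpy() - 1

        inp = tmp_path / "x.tsv"
        pd.DataFrame(X).to_csv(inp, sep="\t", index=False, header=False)
        r = subprocess.run(
            [
                "Rscript", "-e",
                "suppressMessages(library(limma));"
                f"x <- as.matrix(read.delim('{inp}', header=FALSE));"
                "y <- normalizeQuantiles(x, ties=TRUE);"
                "write.table(format(y, digits=12), stdout(), sep='\\t',"
                " row.names=FALSE, col.names=FALSE, quote=FALSE)",
            ],
            capture_output=True, text=True, check=True,
        )
        ref = np.array(
            [[float(v) for v in line.split("\t")] for line in r.stdout.strip().splitlines()]
        )
        assert np.allclose(mine, ref, atol=1e-8)


class TestGroupFold:
    def test_identical_groups_fold_zero(self):
        mat = make_matrix(np.tile([[2.0], [3.0]], (1, 4)), log=True)
        ft = group_fold(mat, "group_a", "group_b")
        assert np.allclose(ft.folds.to_numpy(), 0.0)

    def test_twofold_linear_is_one_log2(self):
        # group_a one log2 unit above group_b = 2x linear expression
        vals = np.array([[4.0, 4.0, 3.0, 3.0], [6.0, 6.0, 5.0, 5.0]])
        mat = make_matrix(vals, log=True)
        ft = group_fold(mat, "group_a", "group_b")
        assert np.allclose(ft.folds.to_numpy(), 1.0)

    def test_toy_matrix_matches_spreadsheet_recomputation(self):
        rng = np.random.default_rng(5)
        vals = np.round(rng.uniform(0, 10, size=(4, 6)), 2)
        mat = make_matrix(vals, log=True)
        ft = group_fold(mat, "group_a", "group_b")
        # cell-by-cell recomputation with plain python loops
        for i in range(4):
            ma = sum(vals[i, :3]) / 3
            mb = sum(vals[i, 3:]) / 3
            assert ft.folds.iloc[i] == pytest.approx(ma - mb, abs=1e-12)

    def test_antisymmetric_under_group_swap(self):
        rng = np.random.default_rng(6)
        mat = make_matrix(rng.normal(5, 1, size=(20, 8)), log=True)
        ab = group_fold(mat, "group_a", "group_b").folds
        ba = group_fold(mat, "group_b", "group_a").folds
        assert np.allclose(ab.to_numpy(), -ba.to_numpy())

    def test_not_logged_rejected(self):
        mat = make_matrix(np.ones((4, 4)))
        with pytest.raises(ValueError):
            group_fold(mat, "group_a", "group_b")


class TestStratumProfile:
    def test_two_bin_means(self):
        smap = StratumMap({"g1": 1, "g2": 1, "g3": 17})
        vals = pd.Series({"g1": 1.0, "g2": 3.0, "g3": 2.0})
        prof = stratum_profile(vals, smap, bins=[(1, 16), (17, 17)])
        assert prof.table.loc["1-16", "mean"] == pytest.approx(2.0)
        assert prof.table.loc["17", "mean"] == pytest.approx(2.0)

    def test_bins_must_partition(self):
        smap = StratumMap({"g1": 1})
        with pytest.raises(ValueError):
            stratum_profile(pd.Series({"g1": 1.0}), smap, bins=[(1, 16)])

    def test_exclusion_changes_only_affected_bins(self):
        smap = StratumMap({"g1": 1, "g2": 1, "g3": 10, "g4": 10})
        vals = pd.Series({"g1": 1.0, "g2": 2.0, "g3": 5.0, "g4": 9.0})
        flag = GeneSetFlag("zf", frozenset({"g4"}))
        without, full = stratum_profile(vals, smap, exclude=flag)
        assert without.zfc2h2_excluded and not full.zfc2h2_excluded
        assert without.table.loc["1", "mean"] == full.table.loc["1", "mean"]
        assert without.table.loc["10-17", "mean"] == pytest.approx(5.0)
        assert full.table.loc["10-17", "mean"] == pytest.approx(7.0)

    def test_empty_bin_flagged_not_dropped(self):
        smap = StratumMap({"g1": 1})
        prof = stratum_profile(pd.Series({"g1": 1.0}), smap)
        assert "10-17" in prof.table.index
        assert prof.table.loc["10-17", "n"] == 0
        assert np.isnan(prof.table.loc["10-17", "mean"])

    def test_unmapped_genes_excluded_without_effect(self):
        smap = StratumMap({"g1": 1, "g2": 2})
        vals = pd.Series({"g1": 1.0, "g2": 3.0})
        vals_extra = pd.concat([vals, pd.Series({"zz": 99.0})])
        p1 = stratum_profile(vals, smap)
        p2 = stratum_profile(vals_extra, smap)
        assert p2.n_unmapped == 1
        pd.testing.assert_frame_equal(p1.table, p2.table)

    def test_gene_order_invariance(self):
        smap = StratumMap({f"g{i}": 1 + i % 17 for i in range(60)})
        rng = np.random.default_rng(2)
        vals = pd.Series(rng.normal(size=60), index=[f"g{i}" for i in range(60)])
        p1 = stratum_profile(vals, smap)
        p2 = stratum_profile(vals.sample(frac=1, random_state=1), smap)
        pd.testing.assert_frame_equal(p1.table, p2.table)


class TestANOM:
    def _null_data(self, rng, n_per=60):
        genes = {}
        vals = {}
        for s in range(1, 18):
            for i in range(n_per):
                g = f"s{s}g{i}"
                genes[g] = s
                vals[g] = float(rng.normal())
        return pd.Series(vals), StratumMap(genes)

    def test_null_family_flag_rate_bounded(self):
        """Under a common null distribution, the chance of flagging any
        stratum stays at or below the family alpha (300 simulations)."""
        rng = np.random.default_rng(11)
        n_flagged = 0
        for _ in range(300):
            vals, smap = self._null_data(rng, n_per=30)
            res = anom(vals, smap, alpha=0.05)
            n_flagged += int(res.table["flagged"].any())
        rate = n_flagged / 300
        assert rate <= 0.05 + 2 * np.sqrt(0.05 * 0.95 / 300)

    def test_shifted_stratum_always_flagged(self):
        """A 5-pooled-sd shift of one stratum (n=100) is detected."""
        rng = np.random.default_rng(12)
        for _ in range(20):
            vals, smap = self._null_data(rng, n_per=100)
            shifted = vals.copy()
            idx = [g for g in shifted.index if g.startswith("s9g")]
            shifted.loc[idx] += 5.0
            res = anom(shifted, smap, alpha=0.05)
            assert bool(res.table.loc[9, "flagged"])

    def test_stratum_at_grand_mean_not_flagged(self):
        genes, vals = {}, {}
        for s in (1, 2, 3):
            for i in range(50):
                g = f"s{s}g{i}"
                genes[g] = s
                vals[g] = float((-1) ** i) * (1.0 if s != 2 else 0.5)
        # stratum 2 mean == 0 == grand mean by construction
        res = anom(pd.Series(vals), StratumMap(genes), alpha=0.05)
        assert not bool(res.table.loc[2, "flagged"])

    def test_small_stratum_excluded_with_warning(self):
        genes = {f"g{i}": 1 + (i % 2) for i in range(20)}
        genes["lone"] = 17
        rng = np.random.default_rng(0)
        vals = pd.Series({g: float(rng.normal()) for g in genes})
        res = anom(vals, StratumMap(genes))
        assert res.excluded_strata == [17]
        assert 17 not in res.table.index

    def test_limits_bracket_grand_mean(self):
        rng = np.random.default_rng(13)
        vals, smap = self._null_data(rng, n_per=25)
        res = anom(vals, smap)
        assert (res.table["lower"] <= res.grand_mean).all()
        assert (res.table["upper"] >= res.grand_mean).all()

    def test_montecarlo_h_close_to_normal_h(self):
        rng = np.random.default_rng(14)
        vals, smap = self._null_data(rng, n_per=40)
        res_n = anom(vals, smap, method="normal")
        res_mc = anom(vals, smap, method="montecarlo", n_sim=800, seed=7)
        assert res_mc.h == pytest.approx(res_n.h, rel=0.15)


class TestComposition:
    def _uniform_map(self, n=1700):
        return StratumMap({f"g{i}": 1 + i % 17 for i in range(n)})

    def test_concentrated_set_monotone(self):
        smap = self._uniform_map()
        members = [g for g in smap.entries if smap.stratum_of(g) == 1][:40]
        table, r, p = stratum_composition(members, smap)
        assert table.loc[1, "proportion"] == pytest.approx(1.0)
        assert r < 0

    def test_null_set_uncorrelated(self):
        """A set sampled uniformly from the gene universe shows no age
        trend: mean Spearman r over seeds is near 0 (null sd of r over 17
        strata is ~1/4, so the mean over 25 seeds has sd ~0.05) and the
        trend is rarely significant."""
        smap = self._uniform_map()
        rng = np.random.default_rng(21)
        rs, n_sig = [], 0
        for _ in range(25):
            members = list(rng.choice(sorted(smap.entries), size=500, replace=False))
            _, r, p = stratum_composition(members, smap)
            rs.append(r)
            n_sig += int(p < 0.01)
        assert abs(np.mean(rs)) < 0.2
        assert n_sig <= 2

    def test_planted_geometric_decline_recovered(self):
        smap = self._uniform_map(3400)
        rng = np.random.default_rng(22)
        members = []
        for s in range(1, 18):
            pool = [g for g in smap.entries if smap.stratum_of(g) == s]
            k = max(1, int(120 * 0.7 ** (s - 1)))
            members += list(rng.choice(pool, size=min(k, len(pool)), replace=False))
        _, r, p = stratum_composition(members, smap)
        assert r < -0.8

    def test_stratum_normalized_variant(self):
        smap = StratumMap({"a": 1, "b": 1, "c": 2, "d": 3, "e": 4})
        table, _, _ = stratum_composition(["a", "c", "d"], smap, normalize="stratum")
        assert table.loc[1, "proportion"] == pytest.approx(0.5)
        assert table.loc[2, "proportion"] == pytest.approx(1.0)


class TestGradientRecovery:
    def test_planted_fold_gradient_slope(self):
        """A planted per-stratum fold gradient (slope -0.03 per stratum) is
        recovered by the stratum profile slope within 2 standard errors."""
        from phyloattractor import ExpressionGenConfig, NetworkGenConfig, gen_expression, gen_network

        _, smap = gen_network(NetworkGenConfig(n_per_stratum=[60] * 17, m=2, seed=30))
        cfg = ExpressionGenConfig(
            delta=lambda s: 0.5 - 0.03 * (s - 1), sigma=0.5, n_cells=40, seed=31
        )
        mat = gen_expression(cfg, smap)
        logged = ExpressionMatrix(
            values=np.log2(mat.values + 1), groups=mat.groups, log_transformed=True
        )
        ft = group_fold(logged, "group_a", "group_b")
        prof = stratum_profile(ft.folds, smap)
        slope, se = profile_slope(prof)
        assert abs(slope - (-0.03)) <= 2 * se
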