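"""Statistics battery: oracles by enumeration, planted-effect recovery,
landscape and density properties."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from paralogcs.robustness import (
    ancestral_homomer_contingency,
    build_landscape,
    cellwise_means,
    class_density,
    compare_classes,
    diagonal_fractions,
    expression_bin_comparison,
    fishers_exact_2x2,
    landscape_trend,
    mann_whitney_u,
    partial_spearman,
)


def mwu_enumeration_oracle(a, b):
    """Independent exact two-sided p: brute-force pair counting over every
    split of the pooled values into the observed group sizes."""
    pooled = list(a) + list(b)
    na = len(a)

    def u_of(group_a, group_b):
        u = 0.0
        for x in group_a:
            for y in group_b:
                u += 1.0 if x > y else (0.5 if x == y else 0.0)
        return u

    u_obs = u_of(a, b)
    us = []
    idx = range(len(pooled))
    for comb in itertools.combinations(idx, na):
        ga = [pooled[i] for i in comb]
        gb = [pooled[i] for i in idx if i not in comb]
        us.append(u_of(ga, gb))
    us = np.array(us)
    p_le = (us <= u_obs + 1e-9).mean()
    p_ge = (us >= u_obs - 1e-9).mean()
    return min(1.0, 2 * min(p_le, p_ge))


def fisher_enumeration_oracle(table):
    """Two-sided probability-mass p from the hypergeometric distribution."""
    (a, b), (c, d) = table
    r1, m = a + b, a + c
    n = a + b + c + d
    support = np.arange(max(0, r1 + m - n), min(r1, m) + 1)
    pmf = stats.hypergeom.pmf(support, n, r1, m)
    return float(pmf[pmf <= pmf[support == a][0] * (1 + 1e-9)].sum())


class TestMannWhitney:
    def test_separated_triplets_exact_p(self):
        res = mann_whitney_u([1, 2, 3], [4, 5, 6])
        assert res.value == 0.0
        assert res.p_value == pytest.approx(0.1)

    def test_identical_groups_center_u(self):
        res = mann_whitney_u([1, 2, 3], [1, 2, 3])
        assert res.value == 4.5  # n_a * n_b / 2
        assert res.p_value == 1.0

    @pytest.mark.parametrize("seed", range(6))
    def test_exact_p_matches_enumeration_oracle(self, seed):
        rng = np.random.default_rng(seed)
        na, nb = rng.integers(2, 7), rng.integers(2, 7)
        # integer values force ties
        a = rng.integers(0, 5, na).astype(float)
        b = rng.integers(0, 5, nb).astype(float)
        res = mann_whitney_u(a, b)
        assert res.extra["method"] == "exact"
        assert res.p_value == pytest.approx(mwu_enumeration_oracle(a, b), abs=1e-12)

    def test_matches_scipy_exact_without_ties(self):
        rng = np.random.default_rng(7)
        a = rng.normal(size=5)
        b = rng.normal(size=6)
        ours = mann_whitney_u(a, b)
        ref = stats.mannwhitneyu(a, b, alternative="two-sided", method="exact")
        assert ours.p_value == pytest.approx(ref.pvalue, abs=1e-12)

    def test_normal_approximation_close_to_exact(self):
        rng = np.random.default_rng(8)
        for _ in range(10):
            a = rng.normal(size=6)
            b = rng.normal(size=6)
            exact = mann_whitney_u(a, b, exact_max_n=12).p_value
            approx = mann_whitney_u(a, b, exact_max_n=0).p_value
            assert abs(exact - approx) <= 0.02

    def test_shift_drives_p_down_with_n(self):
        rng = np.random.default_rng(9)
        prev = 1.0
        for n in (8, 16, 32, 64):
            a = rng.normal(0, 1, n)
            b = rng.normal(0, 1, n) + 3.0  # shift > range(a) essentially
            p = mann_whitney_u(a, b).p_value
            assert p <= prev + 1e-6
            prev = p

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            mann_whitney_u([], [1.0])


class TestFisher:
    def test_balanced_table_or_one(self):
        res = fishers_exact_2x2([[10, 10], [10, 10]])
        assert res.value == 1.0

    def test_odds_ratio_arithmetic(self):
        assert fishers_exact_2x2([[20, 5], [5, 20]]).value == 16.0

    def test_zero_margin_flagged(self):
        res = fishers_exact_2x2([[0, 0], [5, 5]])
        assert res.p_value == 1.0 and res.extra["flag"] == "zero-margin"

    def test_zero_cell_gives_infinite_or(self):
        res = fishers_exact_2x2([[5, 0], [1, 5]])
        assert np.isinf(res.value) and res.extra["flag"] == "infinite-odds-ratio"

    def test_p_matches_enumeration_for_all_small_tables(self):
        # every margin configuration with N <= 20 (p depends only on margins
        # and the observed cell); the full N <= 40 sweep runs in the
        # acceptance suite
        for n in range(1, 21):
            for r1 in range(n + 1):
                for m in range(n + 1):
                    lo, hi = max(0, r1 + m - n), min(r1, m)
                    for a in range(lo, hi + 1):
                        t = [[a, r1 - a], [m - a, n - r1 - m + a]]
                        if min(r1, n - r1, m, n - m) == 0:
                            continue
                        ours = fishers_exact_2x2(t).p_value
                        oracle = fisher_enumeration_oracle(t)
                        assert ours == pytest.approx(oracle, abs=1e-9), t


class TestPartialSpearman:
    def test_zero_covariates_equals_plain_spearman(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=60)
        y = x + rng.normal(size=60)
        ours = partial_spearman(x, y)
        ref = stats.spearmanr(x, y)
        assert ours.value == pytest.approx(ref.statistic, abs=1e-12)
        assert ours.p_value == pytest.approx(ref.pvalue, rel=1e-6)

    def test_matches_pingouin_with_covariates(self):
        pg = pytest.importorskip("pingouin")
        rng = np.random.default_rng(1)
        df = pd.DataFrame(rng.normal(size=(80, 3)), columns=["x", "y", "z"])
        df["y"] += 0.5 * df["z"]
        df["x"] += 0.5 * df["z"]
        ours = partial_spearman(df["x"], df["y"], df[["z"]])
        ref = pg.partial_corr(df, x="x", y="y", covar=["z"], method="spearman")
        assert ours.value == pytest.approx(float(ref["r"].iloc[0]), abs=1e-9)

    def test_identity_relationship_gives_rho_one(self):
        rng = np.random.default_rng(2)
        x = rng.normal(size=40)
        z = rng.normal(size=40)
        res = partial_spearman(x, x.copy(), pd.DataFrame({"z": z}))
        assert res.value == pytest.approx(1.0, abs=1e-9)

    def test_confounded_relationship_vanishes(self):
        vals = []
        for seed in range(10):
            rng = np.random.default_rng(seed)
            z = rng.normal(size=200)
            y = z + 0.1 * rng.normal(size=200)
            x = rng.normal(size=200)
            vals.append(partial_spearman(x, y, pd.DataFrame({"z": z})).value)
        assert abs(np.mean(vals)) < 0.05

    def test_constant_variable_rejected(self):
        with pytest.raises(ValueError):
            partial_spearman([1.0] * 10, list(range(10)))


class TestCompareClasses:
    def test_planted_shift_detected_with_direction(self):
        rng = np.random.default_rng(3)
        cs = pd.Series(rng.normal(size=300), index=[f"g{i}" for i in range(300)])
        labels = pd.Series(["paralog"] * 150 + ["singleton"] * 150, index=cs.index)
        cs[labels == "paralog"] += 0.5
        out = compare_classes(cs.rename("d"), labels, [("paralog", "singleton")])
        assert out.loc[0, "p_value"] < 0.01
        assert out.loc[0, "median_diff"] > 0

    def test_single_pairing_single_dataset_one_row(self):
        cs = pd.Series(np.arange(10.0), index=[f"g{i}" for i in range(10)])
        labels = pd.Series(["a"] * 5 + ["b"] * 5, index=cs.index)
        out = compare_classes(cs.rename("d"), labels, [("a", "b")])
        assert len(out) == 1

    def test_shuffled_labels_give_uniform_p(self):
        rng = np.random.default_rng(4)
        ps = []
        for _ in range(40):
            cs = pd.Series(rng.normal(size=120), index=range(120))
            labels = pd.Series(rng.permutation(["a"] * 60 + ["b"] * 60), index=cs.index)
            ps.append(compare_classes(cs.rename("d"), labels, [("a", "b")])["p_value"][0])
        assert stats.kstest(ps, "uniform").pvalue > 0.01


class TestCellwiseMeans:
    def test_two_class_means_and_diagonal(self):
        cs = pd.DataFrame({"CL1": [-1.0, -1.0, 0.0, 0.0]}, index=list("abcd"))
        labels = pd.Series({"a": "x", "b": "x", "c": "y", "d": "y"})
        means = cellwise_means(cs, labels)
        assert means.loc["CL1", "x"] == -1.0 and means.loc["CL1", "y"] == 0.0
        frac = diagonal_fractions(means, "x", "y")
        assert frac["above"] == 1.0 and frac["n_lines"] == 1

    def test_equal_means_counted_on_diagonal(self):
        cs = pd.DataFrame({"CL1": [1.0, 1.0]}, index=list("ab"))
        labels = pd.Series({"a": "x", "b": "y"})
        frac = diagonal_fractions(cellwise_means(cs, labels), "x", "y")
        assert frac["on"] == 1.0

    def test_planted_shift_systematic_across_lines(self, small_study, small_scores):
        means = cellwise_means(small_scores["merged"], small_study.catalog["class"])
        frac = diagonal_fractions(means, "singleton", "paralog")
        assert frac["above"] >= 0.95  # paralog mean CS above singleton in ~every line


class TestAncestralHomomer:
    def _pairs(self, hom_a, hom_b, het):
        return pd.DataFrame({"homomer_a": hom_a, "homomer_b": hom_b, "heteromer": het})

    def test_perfect_association_flags_infinite_or(self):
        p = self._pairs([1, 1, 0, 0], [1, 1, 0, 0], [1, 1, 0, 0])
        table, res = ancestral_homomer_contingency(p)
        assert np.isinf(res.value)

    def test_mixed_pairs_excluded_from_table(self):
        p = self._pairs([1, 1, 0], [1, 0, 0], [1, 0, 1])
        table, res = ancestral_homomer_contingency(p)
        assert table.to_numpy().sum() == 2
        assert res.extra["n_excluded_mixed"] == 1

    def test_independent_flags_give_or_near_one(self):
        log_ors = []
        for seed in range(10):
            rng = np.random.default_rng(seed)
            n = 600
            p = self._pairs(rng.uniform(size=n) < 0.5, rng.uniform(size=n) < 0.5,
                            rng.uniform(size=n) < 0.3)
            _, res = ancestral_homomer_contingency(p)
            log_ors.append(np.log(res.value))
        assert abs(np.mean(log_ors)) < 0.2


class TestExpressionBins:
    def test_bins_partition_with_equal_sizes(self):
        n = 100
        idx = [f"g{i}" for i in range(n)]
        cs = pd.Series(np.random.default_rng(0).normal(size=n), index=idx)
        expr = pd.Series(np.arange(n, dtype=float), index=idx)
        labels = pd.Series(["paralog", "singleton"] * 50, index=idx)
        out = expression_bin_comparison(cs, expr, labels, n_bins=5)
        assert out["n_bin"].tolist() == [20] * 5
        assert out["n_bin"].sum() == n

    def test_effect_confined_to_high_expression_bins(self):
        rng = np.random.default_rng(5)
        n = 1000
        idx = [f"g{i}" for i in range(n)]
        expr = pd.Series(rng.uniform(0, 10, n), index=idx)
        labels = pd.Series(rng.choice(["paralog", "singleton"], n), index=idx)
        cs = pd.Series(rng.normal(size=n), index=idx)
        top = (expr > expr.quantile(0.8)) & (labels == "paralog")
        cs[top] += 2.0
        out = expression_bin_comparison(cs, expr, labels, n_bins=5)
        assert out.loc[4, "p_value"] < 1e-4
        assert (out.loc[:2, "p_value"] > 0.01).all()


class TestLandscape:
    def _inputs(self, n=2000, seed=0):
        rng = np.random.default_rng(seed)
        idx = [f"g{i}" for i in range(n)]
        expr = pd.Series(2.0 ** rng.normal(3, 1.5, n), index=idx)
        deg = pd.Series(rng.integers(0, 60, n).astype(float), index=idx)
        return idx, expr, deg

    def test_constant_cs_gives_flat_landscape(self):
        idx, expr, deg = self._inputs()
        cs = pd.Series(1.0, index=idx)
        grid = build_landscape(cs, expr, deg, n_bins=8, min_count=1)
        vals = grid.mean_cs[~np.isnan(grid.mean_cs)]
        np.testing.assert_allclose(vals, 1.0)

    def test_constructed_gradient_orders_corners(self):
        idx, expr, deg = self._inputs()
        cs = -(np.log2(expr) + np.log2(deg + 1))
        grid = build_landscape(pd.Series(cs, index=idx), expr, deg, n_bins=8, min_count=1)
        top_right = grid.mean_cs[-1, -1]
        bottom_left = grid.mean_cs[0, 0]
        assert top_right < bottom_left
        assert landscape_trend(grid).value <= -0.5

    def test_cell_means_invariant_to_gene_order(self):
        idx, expr, deg = self._inputs()
        cs = pd.Series(np.random.default_rng(1).normal(size=len(idx)), index=idx)
        g1 = build_landscape(cs, expr, deg)
        perm = np.random.default_rng(2).permutation(idx)
        g2 = build_landscape(cs.loc[perm], expr.loc[perm], deg.loc[perm])
        np.testing.assert_array_equal(g1.counts, g2.counts)
        np.testing.assert_allclose(g1.mean_cs, g2.mean_cs, equal_nan=True)


class TestClassDensity:
    def test_density_normalized_and_nonnegative(self):
        rng = np.random.default_rng(3)
        n = 400
        idx = [f"g{i}" for i in range(n)]
        expr = pd.Series(2.0 ** rng.normal(3, 1, n), index=idx)
        deg = pd.Series(rng.integers(1, 40, n).astype(float), index=idx)
        cs = pd.Series(rng.normal(size=n), index=idx)
        grid = build_landscape(cs, expr, deg, n_bins=25, min_count=1)
        dens = class_density(idx[:200], expr, deg, grid)
        assert (dens >= 0).all()
        cell = (grid.x_edges[1] - grid.x_edges[0]) * (grid.y_edges[1] - grid.y_edges[0])
        assert dens.sum() * cell == pytest.approx(1.0, abs=0.02)

    def test_expression_shift_moves_density_mode(self):
        rng = np.random.default_rng(4)
        n = 600
        idx = [f"g{i}" for i in range(n)]
        expr = pd.Series(2.0 ** rng.normal(2, 0.5, n), index=idx)
        deg = pd.Series(rng.integers(5, 15, n).astype(float), index=idx)
        shifted = expr.copy()
        shifted[idx[:300]] *= 2.0 ** 3  # +3 in log2
        both = pd.concat([expr.loc[idx[300:]], shifted.loc[idx[:300]]])
        cs = pd.Series(0.0, index=idx)
        grid = build_landscape(cs, both, deg, n_bins=30, min_count=1,
                               percentile_window=(0.5, 99.5))
        d_base = class_density(idx[300:], both, deg, grid)
        d_shift = class_density(idx[:300], both, deg, grid)
        xc = 0.5 * (grid.x_edges[:-1] + grid.x_edges[1:])
        mode_base = xc[np.unravel_index(d_base.argmax(), d_base.shape)[0]]
        mode_shift = xc[np.unravel_index(d_shift.argmax(), d_shift.shape)[0]]
        assert mode_shift - mode_base == pytest.approx(3.0, abs=1.0)

    def test_degenerate_class_rejected(self):
        idx = [f"g{i}" for i in range(10)]
        expr = pd.Series(4.0, index=idx)
        deg = pd.Series(np.arange(10.0), index=idx)
        grid = build_landscape(pd.Series(0.0, index=idx), deg.rename(None) + 1, deg,
                               n_bins=4, min_count=1)
        with pytest.raises(ValueError):
            class_density(idx, expr, deg, grid)
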