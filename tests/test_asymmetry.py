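"""Expression-asymmetry machinery: the A statistic, P1/P2 orientation,
asymmetry-dCS coupling, coexpression and coregulation, interface size."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from paralogcs import generate_study, score_study
from paralogcs.asymmetry import (
    assign_p1_p2,
    asym_deltaCS_relationship,
    asymmetry,
    binned_p1_gt_p2_probability,
    coexpression,
    compare_correlation_distributions,
    interface_cs_correlation,
    p1_p2_cs_comparison,
    pair_line_table,
    per_pair_asym_cs_correlation,
    protein_coregulation,
    _partial_pearson,
)
from paralogcs.config import SimulationConfig


def pairs_df(rows):
    return pd.DataFrame(rows, columns=["gene_a", "gene_b"]).assign(
        pair_id=lambda d: [f"P{i}" for i in range(len(d))]).set_index("pair_id")


@pytest.fixture(scope="module")
def coupled_study():
    """Single-dataset study with many cell lines (asymmetry-analysis shape)."""
    cfg = SimulationConfig(n_genes=400, n_cell_lines=(10,), seed=2)
    study = generate_study(cfg)
    scores = score_study(study)
    table = pair_line_table(study.pairs, study.mrna, scores["merged"])
    return study, scores, table


class TestAsymmetryStatistic:
    @pytest.mark.parametrize("e1,e2,expected", [(10, 10, 0.0), (3, 1, 0.5), (1, 0, 1.0)])
    def test_known_values(self, e1, e2, expected):
        assert asymmetry(e1, e2) == pytest.approx(expected)

    def test_both_zero_is_nan(self):
        assert np.isnan(asymmetry(0.0, 0.0))

    @settings(max_examples=50, derandomize=True)
    @given(
        e1=st.floats(0, 1e6, allow_nan=False),
        e2=st.floats(0, 1e6, allow_nan=False),
        c=st.floats(1e-3, 1e3),
    )
    def test_symmetric_and_scale_invariant(self, e1, e2, c):
        if e1 + e2 == 0 or (c * e1 + c * e2) == 0:
            return
        assert asymmetry(e1, e2) == pytest.approx(asymmetry(e2, e1))
        assert asymmetry(c * e1, c * e2) == pytest.approx(asymmetry(e1, e2), rel=1e-9)

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            asymmetry(-1.0, 2.0)


class TestOrientation:
    def test_higher_expressed_is_p1(self):
        expr = pd.Series({"A": 5.0, "B": 2.0})
        out = assign_p1_p2(pairs_df([("A", "B")]), expr)
        assert out.loc["P0", "p1"] == "A"
        assert not out.loc["P0", "tie"]

    def test_tie_breaks_lexicographically_with_flag(self):
        expr = pd.Series({"B": 3.0, "A": 3.0})
        out = assign_p1_p2(pairs_df([("B", "A")]), expr)
        assert out.loc["P0", "p1"] == "A"
        assert bool(out.loc["P0", "tie"])

    def test_orientation_can_reverse_across_lines(self):
        pairs = pairs_df([("A", "B")])
        expr = pd.DataFrame({"CL1": {"A": 5.0, "B": 1.0}, "CL2": {"A": 1.0, "B": 5.0}})
        cs = pd.DataFrame({"CL1": {"A": 0.0, "B": 0.0}, "CL2": {"A": 0.0, "B": 0.0}})
        table = pair_line_table(pairs, expr, cs)
        assert set(table["p1"]) == {"A", "B"}

    def test_missing_expression_skips_pair(self, caplog):
        expr = pd.Series({"A": 5.0})
        with caplog.at_level("WARNING"):
            out = assign_p1_p2(pairs_df([("A", "B")]), expr)
        assert len(out) == 0


class TestP1P2Comparison:
    def test_planted_link_makes_p1_more_deleterious(self, coupled_study):
        study, scores, table = coupled_study
        het_ids = set(study.pairs.index[study.pairs["heteromer"]])
        het_table = table[table["pair_id"].isin(het_ids)]
        res = p1_p2_cs_comparison(het_table)
        assert res.extra["median_a"] < res.extra["median_b"]
        assert res.p_value < 0.01

    def test_null_orientation_calibrated(self):
        rng = np.random.default_rng(0)
        ps = []
        for _ in range(20):
            n = 200
            t = pd.DataFrame({
                "cs_p1": rng.normal(size=n), "cs_p2": rng.normal(size=n),
            })
            ps.append(p1_p2_cs_comparison(t).p_value)
        assert stats.kstest(ps, "uniform").pvalue > 0.01

    def test_degenerate_single_observation_flagged(self):
        t = pd.DataFrame({"cs_p1": [0.1], "cs_p2": [0.2]})
        res = p1_p2_cs_comparison(t)
        assert res.extra["flag"] == "degenerate"


class TestBinnedProbability:
    def _table(self, delta, n=100, seed=0):
        rng = np.random.default_rng(seed)
        cs_p2 = rng.normal(size=n)
        return pd.DataFrame({
            "asymmetry": rng.uniform(size=n),
            "cs_p1": cs_p2 + delta,
            "cs_p2": cs_p2,
        }).assign(delta_cs=lambda d: d["cs_p1"] - d["cs_p2"])

    def test_always_negative_delta_gives_zero_probability(self):
        out = binned_p1_gt_p2_probability(self._table(-1.0), n_bins=5)
        assert (out["p_cs_p1_gt_p2"] == 0.0).all()

    def test_random_orientation_near_half(self):
        rng = np.random.default_rng(1)
        n = 4000
        t = pd.DataFrame({
            "asymmetry": rng.uniform(size=n),
            "cs_p1": rng.normal(size=n),
            "cs_p2": rng.normal(size=n),
        }).assign(delta_cs=lambda d: d["cs_p1"] - d["cs_p2"])
        out = binned_p1_gt_p2_probability(t, n_bins=10)
        assert (out["p_cs_p1_gt_p2"] - 0.5).abs().max() < 0.08

    def test_bins_partition_observations(self):
        t = self._table(0.5, n=97)
        out = binned_p1_gt_p2_probability(t, n_bins=10)
        assert out["n"].sum() == 97


class TestAsymDeltaCS:
    def test_constant_asymmetry_pair_excluded(self):
        t = pd.DataFrame({
            "pair_id": ["P0"] * 5,
            "asymmetry": [0.3] * 5,
            "delta_cs": [0.1, -0.2, 0.3, 0.0, 0.1],
            "cs_p1": 0.0, "cs_p2": 0.0, "cell_line": list("abcde"),
        })
        assert len(per_pair_asym_cs_correlation(t)) == 0

    def test_per_pair_statistic_invariant_to_line_order(self, coupled_study):
        _, _, table = coupled_study
        r1 = per_pair_asym_cs_correlation(table)
        shuffled = table.sample(frac=1, random_state=3)
        r2 = per_pair_asym_cs_correlation(shuffled)
        pd.testing.assert_series_equal(r1.sort_index(), r2.sort_index())

    def test_planted_coupling_shifts_heteromer_correlations_down(self, coupled_study):
        study, _, table = coupled_study
        per_pair = per_pair_asym_cs_correlation(table)
        res = compare_correlation_distributions(per_pair, study.pairs["heteromer"])
        het = study.pairs["heteromer"].reindex(per_pair.index).fillna(False).astype(bool)
        assert per_pair[het].median() < per_pair[~het].median()
        assert res.p_value < 0.01

    def test_no_coupling_bins_flat_within_ci(self):
        # a clean null requires b_expr = 0 too: an expression -> fitness
        # effect induces an asymmetry-dCS relation on its own
        from paralogcs.config import EffectModel

        cfg = SimulationConfig(
            n_genes=400, n_cell_lines=(10,), seed=5, asymmetry_coupling=0.0,
            effect_model=EffectModel(b_expr=0.0),
        )
        study = generate_study(cfg)
        scores = score_study(study)
        table = pair_line_table(study.pairs, study.mrna, scores["merged"])
        bins = asym_deltaCS_relationship(table, n_bins=8)
        covers_zero = (bins["ci_low"] <= 0) & (0 <= bins["ci_high"])
        assert covers_zero.mean() >= 0.7


class TestCoexpression:
    def test_identical_members_fully_coexpressed(self):
        mrna = pd.DataFrame(
            np.vstack([np.arange(6.0), np.arange(6.0)]), index=["A", "B"]
        )
        r = coexpression(pairs_df([("A", "B")]), mrna)
        assert r["P0"] == pytest.approx(1.0)

    def test_independent_members_centered_at_zero(self):
        rng = np.random.default_rng(2)
        n_pairs = 150
        genes, rows = [], []
        for i in range(2 * n_pairs):
            genes.append(f"G{i}")
            rows.append(rng.normal(size=20))
        mrna = pd.DataFrame(rows, index=genes)
        pairs = pairs_df([(f"G{2 * i}", f"G{2 * i + 1}") for i in range(n_pairs)])
        r = coexpression(pairs, mrna)
        assert abs(r.mean()) < 0.1

    def test_zscore_affine_invariance(self):
        rng = np.random.default_rng(3)
        a = rng.normal(size=12)
        b = 0.5 * a + rng.normal(size=12)
        mrna = pd.DataFrame([a, b], index=["A", "B"])
        mrna_scaled = pd.DataFrame([3 * a + 7, b], index=["A", "B"])
        r1 = coexpression(pairs_df([("A", "B")]), mrna)
        r2 = coexpression(pairs_df([("A", "B")]), mrna_scaled)
        assert r1["P0"] == pytest.approx(r2["P0"], abs=1e-12)


class TestProteinCoregulation:
    def test_protein_driven_by_mrna_with_private_noise_gives_zero_partial(self):
        vals = []
        for seed in range(10):
            rng = np.random.default_rng(seed)
            ma = rng.normal(size=100)
            mb = rng.normal(size=100)
            protein = pd.DataFrame(
                [2 * ma + 1 + 0.3 * rng.normal(size=100),
                 -ma + 3 * mb + 0.3 * rng.normal(size=100)],
                index=["A", "B"],
            )
            mrna = pd.DataFrame([ma, mb], index=["A", "B"])
            r = protein_coregulation(pairs_df([("A", "B")]), protein, mrna)
            vals.append(r["P0"])
        assert abs(np.mean(vals)) < 0.1

    def test_exactly_deterministic_protein_is_flagged_undefined(self):
        ma = np.arange(30.0)
        mb = np.linspace(-3, 3, 30)
        protein = pd.DataFrame([2 * ma + 1, -ma + 3 * mb], index=["A", "B"])
        mrna = pd.DataFrame([ma, mb], index=["A", "B"])
        r = protein_coregulation(pairs_df([("A", "B")]), protein, mrna)
        assert len(r) == 0  # NaN partials are dropped

    def test_planted_shared_residual_detected(self):
        cfg = SimulationConfig(n_genes=400, n_cell_lines=(10,),
                               protein_line_fraction=1.0, seed=6)
        study = generate_study(cfg)
        log_prot = np.log2(study.protein)
        log_mrna = np.log2(study.mrna)
        r = protein_coregulation(study.pairs, log_prot, log_mrna)
        het = study.pairs["heteromer"].reindex(r.index).fillna(False).astype(bool)
        assert r[het].median() > r[~het].median()
        res = compare_correlation_distributions(r, study.pairs["heteromer"])
        assert res.p_value < 0.01

    def test_no_covariates_reduces_to_plain_pearson(self):
        rng = np.random.default_rng(7)
        x = rng.normal(size=25)
        y = 0.3 * x + rng.normal(size=25)
        assert _partial_pearson(x, y, np.empty((25, 0))) == pytest.approx(
            stats.pearsonr(x, y).statistic, abs=1e-12
        )


class TestInterface:
    def _study_cs(self, seed=1):
        cfg = SimulationConfig(n_genes=400, n_cell_lines=(3,), seed=seed)
        study = generate_study(cfg)
        return study, score_study(study)["aggregated"]

    def test_planted_negative_relation_recovered(self):
        rhos = []
        for seed in (1, 2, 3):
            study, agg = self._study_cs(seed)
            res = interface_cs_correlation(study.pairs, agg)
            rhos.append(res.value)
        assert all(r < 0 for r in rhos)

    def test_shuffled_interface_decorrelates(self):
        study, agg = self._study_cs(4)
        pairs = study.pairs.copy()
        rng = np.random.default_rng(0)
        vals = pairs["interface_size"].dropna()
        rhos = []
        for _ in range(10):
            pairs.loc[vals.index, "interface_size"] = rng.permutation(vals.to_numpy())
            rhos.append(interface_cs_correlation(pairs, agg).value)
        assert abs(np.mean(rhos)) < 0.15

    def test_monotone_transform_leaves_rho_unchanged(self):
        study, agg = self._study_cs(5)
        res1 = interface_cs_correlation(study.pairs, agg)
        pairs = study.pairs.copy()
        pairs["interface_size"] = np.exp(pairs["interface_size"] / 50.0)
        res2 = interface_cs_correlation(pairs, agg)
        assert res1.value == pytest.approx(res2.value, abs=1e-12)

    def test_too_few_pairs_refused(self):
        pairs = pairs_df([("A", "B")])
        pairs["interface_size"] = [10.0]
        cs = pd.Series({"A": 0.0, "B": 1.0})
        with pytest.raises(ValueError, match="heteromer pairs"):
            interface_cs_correlation(pairs, cs)
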