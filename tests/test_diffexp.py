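"""Normalization, normal-score transform, interaction ANOVA, rank
association, delta log p, direction tables and qPCR fold change."""

import warnings
from dataclasses import replace

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import iclipkit as ik

from oracles import anova_two_way_hand, fisher_two_sided_exact


def _design(reps=2, treatments=("A", "B")):
    rows = []
    for geno in ("wildtype", "null"):
        for trt in treatments:
            for r in range(1, reps + 1):
                rows.append((f"{geno}_{trt}_{r}", geno, trt, r))
    return pd.DataFrame(
        rows, columns=["sample", "genotype", "treatment", "replicate"]
    ).set_index("sample")


class TestQuartileNormalize:
    def test_scale_invariance(self):
        a = pd.Series([1.0, 0.0, 5.0, 9.0])
        mat = pd.DataFrame({"s1": a, "s2": 2 * a})
        out = ik.quartile_normalize(mat)
        pd.testing.assert_series_equal(out["s1"], out["s2"], check_names=False)

    def test_single_sample_identity(self):
        mat = pd.DataFrame({"s1": [1.0, 2.0, 3.0, 4.0]})
        pd.testing.assert_frame_equal(ik.quartile_normalize(mat), mat)

    def test_hand_computed_toy_matrix(self):
        # nonzero uppper quartiles by hand (linear interpolation):
        # s1: sorted nonzero [2,4,6] -> 5.0 ; s2: [1,3,5,7] -> 5.5
        mat = pd.DataFrame({"s1": [2.0, 0.0, 6.0, 4.0],
                            "s2": [1.0, 3.0, 5.0, 7.0]})
        out = ik.quartile_normalize(mat)
        expect_s1 = np.array([2.0, 0.0, 6.0, 4.0]) / 5.0 * 5.25
        expect_s2 = np.array([1.0, 3.0, 5.0, 7.0]) / 5.5 * 5.25
        assert np.allclose(out["s1"], expect_s1)
        assert np.allclose(out["s2"], expect_s2)

    def test_all_zero_sample_rejected(self):
        with pytest.raises(ValueError):
            ik.quartile_normalize(pd.DataFrame({"s1": [0.0, 0.0]}))


class TestQuantileTransform:
    def test_median_maps_to_zero_odd_n(self):
        out = ik.quantile_transform([5.0, 1.0, 9.0])
        assert out[0] == pytest.approx(0.0, abs=1e-12)

    def test_ties_share_scores(self):
        out = ik.quantile_transform([3.0, 3.0, 1.0, 7.0])
        assert out[0] == out[1]

    def test_four_values_match_quantile_table(self):
        # Phi^-1 of {0.125, 0.375, 0.625, 0.875} from a normal table
        out = ik.quantile_transform([10.0, 20.0, 30.0, 40.0])
        expect = [-1.150349, -0.318639, 0.318639, 1.150349]
        assert np.allclose(out, expect, atol=1e-5)

    def test_identical_values_map_to_zero(self):
        assert np.array_equal(ik.quantile_transform([4.0] * 6), np.zeros(6))

    def test_mean_zero_and_sd_approaches_one(self):
        rng = np.random.default_rng(0)
        out = ik.quantile_transform(rng.normal(size=400))
        assert out.mean() == pytest.approx(0.0, abs=1e-10)
        assert out.std() == pytest.approx(1.0, abs=0.05)


class TestInteractionAnova:
    def test_hand_worked_two_way_anova(self):
        """A printed 2x2x2 toy table reproduces a hand-computed ANOVA."""
        cells = {
            (0, 0): [4.0, 6.0], (0, 1): [5.0, 7.0],
            (1, 0): [10.0, 12.0], (1, 1): [1.0, 3.0],
        }
        # genotype level 0 = null per categorical order; treatment 0 = A
        design = _design(reps=2)
        row = {}
        for (i, j), vals in cells.items():
            geno = ["null", "wildtype"][i]
            trt = ["A", "B"][j]
            for r, v in enumerate(vals, start=1):
                row[f"{geno}_{trt}_{r}"] = v
        mat = pd.DataFrame([row], index=["g"])[design.index]
        res = ik.interaction_anova(mat, design, n_perm=10, seed=0, transform=False)
        f_geno, f_trt, f_int = anova_two_way_hand(cells)
        assert res.at["g", "F_genotype"] == pytest.approx(f_geno, rel=1e-10)
        assert res.at["g", "F_experiment"] == pytest.approx(f_trt, rel=1e-10)
        assert res.at["g", "F_interaction"] == pytest.approx(f_int, rel=1e-10)

    def test_matches_statsmodels_ols(self):
        """Cross-check the vectorized F statistics against a per-gene
        statsmodels two-way OLS ANOVA."""
        import statsmodels.api as sm
        from statsmodels.formula.api import ols

        rng = np.random.default_rng(3)
        design = _design(reps=3)
        mat = pd.DataFrame(rng.normal(size=(5, len(design))),
                           columns=design.index)
        res = ik.interaction_anova(mat, design, n_perm=10, seed=0, transform=False)
        for gene in mat.index:
            df = design.copy()
            df["y"] = mat.loc[gene, design.index].to_numpy()
            fit = ols("y ~ C(genotype) * C(treatment)", data=df).fit()
            tbl = sm.stats.anova_lm(fit, typ=2)
            assert res.at[gene, "F_interaction"] == pytest.approx(
                tbl.loc["C(genotype):C(treatment)", "F"], rel=1e-8
            )

    def test_perfect_crossover_has_largest_f(self):
        rng = np.random.default_rng(1)
        design = _design(reps=3)
        mat = pd.DataFrame(rng.normal(size=(30, len(design))), columns=design.index)
        cross = {s: (1000.0 if (d.genotype == "null") == (d.treatment == "B")
                     else -1000.0) + rng.normal(0, 0.01)
                 for s, d in design.iterrows()}
        mat.loc["crossover"] = pd.Series(cross)[design.index].to_numpy()
        res = ik.interaction_anova(mat, design, n_perm=10, seed=0)
        assert res["F_interaction"].idxmax() == "crossover"

    def test_unreplicated_cell_rejected(self):
        design = _design(reps=1)
        mat = pd.DataFrame(np.ones((2, len(design))), columns=design.index)
        with pytest.raises(ValueError):
            ik.interaction_anova(mat, design, n_perm=5)

    def test_planted_effect_recovered_from_cell_means(self, small_world):
        """The planted interaction effect is recovered within 25% from
        cell-mean contrasts at default noise."""
        cfg = replace(small_world["cfg"], n_replicates_counts=6)
        counts, design = ik.generate_counts_experiment(
            small_world["ann"], small_world["fpkm"], cfg
        )
        norm = ik.quartile_normalize(counts)
        planted = ik.planted_interaction_genes(small_world["ann"], cfg)
        d = design

        def cell(geno, trt):
            cols = d.index[(d["genotype"] == geno) & (d["treatment"] == trt)]
            return norm.loc[planted, cols].mean(axis=1)

        est = np.log2(
            (cell("null", "B") / cell("null", "A"))
            / (cell("wildtype", "B") / cell("wildtype", "A"))
        ).mean()
        assert abs(est - cfg.interaction_effect) < 0.25 * cfg.interaction_effect


class TestRankAssociation:
    def _ranking(self, genes):
        return pd.DataFrame({"gene_id": genes, "rank": np.arange(1, len(genes) + 1)})

    def _interaction(self, genes, f_vals):
        df = pd.DataFrame({"F_interaction": f_vals}, index=genes)
        df["rank_F"] = df["F_interaction"].rank(ascending=False).astype(int)
        return df

    def test_identical_rankings_give_rho_one(self):
        genes = [f"g{i}" for i in range(40)]
        inter = self._interaction(genes, np.linspace(10, 1, 40))
        out = ik.rank_association(inter, self._ranking(genes), top_k=10)
        assert out["spearman_rho"] == pytest.approx(1.0)
        assert out["p_regression"] < 1e-4

    def test_independent_ranks_not_significant(self):
        rng = np.random.default_rng(8)
        genes = [f"g{i}" for i in range(200)]
        inter = self._interaction(genes, rng.permutation(200).astype(float))
        out = ik.rank_association(inter, self._ranking(genes), top_k=50)
        assert out["p_regression"] > 0.01

    def test_median_split_sizes(self):
        genes = [f"g{i}" for i in range(50)]
        inter = self._interaction(genes, np.arange(50, dtype=float))
        out = ik.rank_association(inter, self._ranking(genes), top_k=20)
        assert len(out["high"]) == len(out["low"]) == 10
        out21 = ik.rank_association(inter, self._ranking(genes), top_k=21)
        assert len(out21["low"]) == len(out21["high"]) + 1  # extra gene to low

    def test_top_k_exceeding_universe_rejected(self):
        genes = ["g1", "g2"]
        inter = self._interaction(genes, [1.0, 2.0])
        with pytest.raises(ValueError):
            ik.rank_association(inter, self._ranking(genes), top_k=5)

    def test_high_set_enriched_for_planted_genes(self, default_pipeline):
        """End to end: the high-interaction half of the top targets is
        enriched for genes carrying the planted interaction."""
        cfg, ann = default_pipeline["cfg"], default_pipeline["ann"]
        counts, design = ik.generate_counts_experiment(
            ann, default_pipeline["fpkm"], cfg
        )
        norm = ik.quartile_normalize(counts)
        res = ik.interaction_anova(norm, design, n_perm=50, seed=5)
        out = ik.rank_association(res, default_pipeline["ranking"], top_k=50)
        assert out["p_regression"] < 0.01
        planted = set(ik.planted_interaction_genes(ann, cfg))
        k = len(out["high"] & planted)
        p = stats.hypergeom.sf(k - 1, len(res), len(planted), len(out["high"]))
        assert p < 0.01


class TestDeltaLogP:
    UNIVERSE = {f"g{i}" for i in range(40)}

    def test_symmetric_term_gives_zero(self):
        high = {f"g{i}" for i in range(10)}
        low = {f"g{i}" for i in range(10, 20)}
        term = [f"g{i}" for i in range(5)] + [f"g{i}" for i in range(10, 15)]
        assert ik.delta_log_p("t", high, low, self.UNIVERSE, {"t": term}) == (
            pytest.approx(0.0, abs=1e-12)
        )

    def test_term_inside_high_is_negative(self):
        high = {f"g{i}" for i in range(10)}
        low = {f"g{i}" for i in range(10, 20)}
        term = list(high)[:6]
        assert ik.delta_log_p("t", high, low, self.UNIVERSE, {"t": term}) < 0

    def test_matches_direct_enrichment_recomputation(self):
        rng = np.random.default_rng(2)
        genes = sorted(self.UNIVERSE)
        high = set(rng.choice(genes, 12, replace=False))
        low = set(rng.choice([g for g in genes if g not in high], 12, replace=False))
        term = list(rng.choice(genes, 15, replace=False))
        got = ik.delta_log_p("t", high, low, self.UNIVERSE, {"t": term})
        N, K = 40, 15
        p_high = stats.hypergeom.sf(len(high & set(term)) - 1, N, K, 12)
        p_low = stats.hypergeom.sf(len(low & set(term)) - 1, N, K, 12)
        assert got == pytest.approx(np.log10(p_high) - np.log10(p_low), rel=1e-10)

    def test_validation(self):
        with pytest.raises(KeyError):
            ik.delta_log_p("missing", {"g1"}, {"g2"}, self.UNIVERSE, {})
        with pytest.raises(ValueError):
            ik.delta_log_p("t", {"g1"}, {"g1"}, self.UNIVERSE, {"t": ["g1"]})


class TestDirectionTable:
    def test_printed_category_counts_match_enumeration_oracle(self):
        dt = ik.direction_table_from_counts([[19, 2], [7, 14]],
                                            "regulation of synaptic plasticity")
        expect = float(fisher_two_sided_exact([[19, 2], [7, 14]]))
        assert dt.fisher_p == pytest.approx(expect, abs=1e-12)

    def test_balanced_table_is_null(self):
        dt = ik.direction_table_from_counts([[5, 5], [5, 5]])
        assert dt.fisher_p == pytest.approx(1.0)
        assert dt.odds_ratio == pytest.approx(1.0)

    def test_zero_cross_cells_flag_infinite_odds(self):
        dt = ik.direction_table_from_counts([[8, 0], [0, 6]])
        assert np.isinf(dt.odds_ratio)

    def test_ratio_ties_excluded_from_matrix_classification(self):
        design = _design(reps=2)
        genes = ["up", "tie", "down"]
        mat = pd.DataFrame(1.0, index=genes, columns=design.index)
        for s, d in design.iterrows():
            if d.treatment == "B":
                mat.loc["up", s] = 3.0
                mat.loc["down", s] = 0.5
        dt = ik.direction_table(genes, mat, design, treatments=("A", "B"))
        assert dt.excluded == 2  # the tied gene, in both genotypes
        assert dt.counts.sum() == 4

    def test_missing_genes_rejected(self):
        design = _design(reps=2)
        mat = pd.DataFrame(1.0, index=["g1"], columns=design.index)
        with pytest.raises(KeyError):
            ik.direction_table(["g1", "gX"], mat, design)


class TestDdct:
    def test_identical_delta_ct_gives_fold_one(self):
        rec = ik.ddct_fold_change([20, 20, 20], [15, 15, 15],
                                  [22, 22, 22], [17, 17, 17])
        assert rec.ddct == pytest.approx(0.0)
        assert rec.fold_change == pytest.approx(1.0)

    @pytest.mark.parametrize("shift, fold", [(1.0, 2.0), (-1.0, 0.5)])
    def test_unit_ddct_doubles_or_halves(self, shift, fold):
        rec = ik.ddct_fold_change([20 + shift] * 3, [15] * 3, [20] * 3, [15] * 3)
        assert rec.ddct == pytest.approx(shift)
        assert rec.fold_change == pytest.approx(fold)

    def test_missing_replicate_warns_and_averages_rest(self):
        with pytest.warns(UserWarning, match="missing"):
            rec = ik.ddct_fold_change([20, np.nan, 22], [15, 15, 15],
                                      [21, 21, 21], [15, 15, 15])
        assert rec.dct_control == pytest.approx(6.0)

    def test_all_missing_rejected(self):
        with pytest.raises(ValueError):
            ik.ddct_fold_change([np.nan] * 3, [15] * 3, [20] * 3, [15] * 3)
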