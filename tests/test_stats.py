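"""VIF pruning, log-curve threshold rule, heritability, effect size, loci."""

import numpy as np
import pandas as pd
import pytest

import rootph as rp
from rootph.stats import TASRecord


def make_table(arrays: dict) -> pd.DataFrame:
    return pd.DataFrame({k: np.asarray(v, dtype=float) for k, v in arrays.items()})


class TestVIF:
    def test_orthogonal_columns_unit_vif(self):
        t = make_table({"a": [1, -1, 1, -1], "b": [1, 1, -1, -1]})
        assert np.allclose(rp.vif_values(t), 1.0)

    def test_known_r2_gives_known_vif(self):
        # construct y = x + e with residual variance tuned so R^2 = 0.875
        rng = np.random.default_rng(0)
        n = 4000
        x = rng.normal(size=n)
        x -= x.mean()
        e = rng.normal(size=n)
        e -= e.mean()
        # orthogonalize e against x, then scale: R^2 = 1 - SSR/SST = 7/8
        e = e - (e @ x) / (x @ x) * x
        e *= np.sqrt((x @ x) / (7 * (e @ e)))
        t = make_table({"x": x, "y": x + e})
        vif = rp.vif_values(t)
        assert vif["y"] == pytest.approx(8.0, rel=1e-6)

    def test_exact_collinearity_infinite(self):
        rng = np.random.default_rng(1)
        a, b = rng.normal(size=(2, 50))
        t = make_table({"a": a, "b": b, "c": a + b})
        assert np.all(np.isinf(rp.vif_values(t)))

    def test_constant_column_named_in_error(self):
        t = make_table({"a": np.arange(5), "flat": np.ones(5)})
        with pytest.raises(ValueError, match="flat"):
            rp.vif_values(t)

    def test_too_few_samples_advises_reduction(self):
        t = make_table({c: np.random.default_rng(2).normal(size=3)
                        for c in "abcd"})
        with pytest.raises(ValueError, match="reduce"):
            rp.vif_values(t)

    def test_matches_statsmodels(self):
        import statsmodels.api as sm
        from statsmodels.stats.outliers_influence import variance_inflation_factor

        rng = np.random.default_rng(3)
        X = rng.normal(size=(200, 4))
        X[:, 3] = X[:, 0] * 0.8 + rng.normal(size=200) * 0.3
        t = make_table({f"t{i}": X[:, i] for i in range(4)})
        mine = rp.vif_values(t).to_numpy()
        exog = sm.add_constant(X)
        theirs = [variance_inflation_factor(exog, i + 1) for i in range(4)]
        assert np.allclose(mine, theirs, rtol=1e-8)


class TestVIFPrune:
    def test_below_threshold_unchanged(self):
        rng = np.random.default_rng(4)
        t = make_table({f"t{i}": rng.normal(size=100) for i in range(5)})
        pruned, removed = rp.vif_prune(t, 8.0)
        assert removed == []
        assert list(pruned.columns) == list(t.columns)

    def test_duplicate_column_one_removed(self):
        rng = np.random.default_rng(5)
        a, b = rng.normal(size=(2, 60))
        t = make_table({"a": a, "b": b, "a2": a})
        pruned, removed = rp.vif_prune(t, 8.0)
        assert len(removed) == 1
        assert {"a", "a2"} & set(pruned.columns)  # one of the pair survives
        assert "b" in pruned.columns

    @pytest.mark.parametrize("seed", range(3))
    def test_independent_columns_never_pruned(self, seed):
        rng = np.random.default_rng(100 + seed)
        t = make_table({f"t{i}": rng.normal(size=500) for i in range(10)})
        _, removed = rp.vif_prune(t, 8.0)
        assert removed == []

    def test_post_condition_all_vif_below_threshold(self):
        rng = np.random.default_rng(6)
        base = rng.normal(size=(200, 3))
        cols = {f"b{i}": base[:, i] for i in range(3)}
        for j in range(4):  # derived, collinear columns
            w = rng.normal(size=3)
            cols[f"d{j}"] = base @ w + rng.normal(size=200) * 0.05
        pruned, removed = rp.vif_prune(make_table(cols), 8.0)
        assert removed
        assert rp.vif_values(pruned).max() <= 8.0


class TestThresholdSweep:
    @pytest.fixture
    def collinear_table(self):
        rng = np.random.default_rng(7)
        base = rng.normal(size=(300, 4))
        cols = {f"b{i}": base[:, i] for i in range(4)}
        for j in range(6):
            w = rng.normal(size=4)
            cols[f"d{j}"] = base @ w + rng.normal(size=300) * 0.2
        return make_table(cols)

    def test_counts_non_decreasing(self, collinear_table):
        x, y = rp.vif_threshold_sweep(collinear_table, np.arange(1.5, 40, 1.0))
        assert np.all(np.diff(y) >= 0)

    def test_low_thresholds_collapse_to_core(self, collinear_table):
        x, y = rp.vif_threshold_sweep(collinear_table, [1.2, 1.5, 2.0, 3.0])
        assert y[0] <= 5  # near the 4-column independent core

    def test_high_threshold_keeps_everything(self, collinear_table):
        vmax = rp.vif_values(collinear_table).max()
        x, y = rp.vif_threshold_sweep(
            collinear_table, [vmax + 1, vmax + 2, vmax + 3, vmax + 4])
        assert np.all(y == collinear_table.shape[1])

    def test_needs_four_thresholds(self, collinear_table):
        with pytest.raises(ValueError):
            rp.vif_threshold_sweep(collinear_table, [2.0, 3.0, 4.0])


class TestLogCurve:
    A, B, C = 15.71, 0.8853, 57.88

    def test_noiseless_recovery(self):
        x = np.arange(2.0, 50.5, 1.0)
        y = self.A * np.log(x - self.B) + self.C
        fit = rp.fit_log_curve(x, y)
        assert fit.a == pytest.approx(self.A, abs=1e-3)
        assert fit.b == pytest.approx(self.B, abs=1e-3)
        assert fit.c == pytest.approx(self.C, abs=1e-3)

    def test_noisy_recovery(self):
        rng = np.random.default_rng(9)
        x = np.arange(2.0, 50.5, 0.5)
        y = self.A * np.log(x - self.B) + self.C + rng.normal(0, 0.5, x.size)
        fit = rp.fit_log_curve(x, y)
        assert fit.a == pytest.approx(self.A, abs=0.5)
        assert fit.b == pytest.approx(self.B, abs=0.5)

    def test_constant_y_degenerate_warning(self):
        x = np.arange(2.0, 10.0)
        with pytest.warns(UserWarning, match="degenerate"):
            fit = rp.fit_log_curve(x, np.full(x.size, 5.0))
        assert abs(fit.a) < 1e-6

    def test_fitted_offset_below_data(self):
        x = np.arange(2.0, 30.0)
        y = 3.0 * np.log(x - 1.2) + 4.0
        fit = rp.fit_log_curve(x, y)
        assert fit.b < x.min()


class TestVIFThresholds:
    def test_published_fit_parameters_give_published_threshold(self):
        fit = rp.LogFitParams(15.71, 0.8853, 57.88)
        assert rp.high_vif_threshold(fit) == pytest.approx(16.5953, abs=1e-4)

    @pytest.mark.parametrize("a,b,expected", [(1.0, 0.0, 1.0), (2.0, 3.0, 5.0)])
    def test_closed_form(self, a, b, expected):
        assert rp.high_vif_threshold(rp.LogFitParams(a, b, 0.0)) == expected

    def test_slope_one_property_random_parameters(self):
        rng = np.random.default_rng(10)
        for _ in range(100):
            a, b = rng.uniform(0.1, 30), rng.uniform(-5, 5)
            x = rp.high_vif_threshold(rp.LogFitParams(a, b, 0.0))
            assert a / (x - b) == pytest.approx(1.0)

    def test_negative_slope_rejected(self):
        with pytest.raises(ValueError):
            rp.high_vif_threshold(rp.LogFitParams(-1.0, 0.0, 0.0))

    @pytest.mark.parametrize("high,expected", [(16.5953, 8.29765), (10, 5), (4, 2)])
    def test_median_is_exact_half(self, high, expected):
        assert rp.median_vif_threshold(high) == pytest.approx(expected)


class TestMultivariatePCs:
    def test_correlated_pair_one_component(self):
        x = np.linspace(0, 1, 12)
        t = make_table({"a": x, "b": 2 * x + 1})
        mpcs = rp.multivariate_pcs(t)
        assert list(mpcs.columns) == ["mPC1"]

    def test_component_count_from_variance_rule(self):
        # three independent scaled features; standardized PCA spreads variance
        rng = np.random.default_rng(11)
        t = make_table({c: rng.normal(size=200) for c in "abc"})
        mpcs = rp.multivariate_pcs(t, cumulative_threshold=0.9)
        assert mpcs.shape[1] in (2, 3)
        assert list(mpcs.columns) == [f"mPC{i + 1}" for i in range(mpcs.shape[1])]

    def test_row_order_permutation(self):
        rng = np.random.default_rng(12)
        t = make_table({c: rng.normal(size=30) for c in "abcd"})
        m1 = rp.multivariate_pcs(t)
        perm = rng.permutation(30)
        m2 = rp.multivariate_pcs(t.iloc[perm])
        assert np.allclose(m1.to_numpy()[perm], m2.to_numpy(), atol=1e-10)


class TestHeritability:
    def test_balanced_closed_form(self):
        # two genotypes, two replicates: genotype means +/- sqrt(6)/2 give
        # between MS = 6 = nrep*Vg + Vr; within deviations +/-1 give
        # within MS = Vr = 2; so Vg = 2 and H2 = 2 / (2 + 2/2) = 2/3
        genotypes = np.repeat(["g1", "g2"], 2)
        m = np.sqrt(6) / 2
        values = np.array([-m - 1, -m + 1, m - 1, m + 1])
        assert rp.heritability(values, genotypes) == pytest.approx(2 / 3)

    def test_no_genetic_variance_floors_at_zero(self):
        genotypes = np.repeat(["a", "b", "c"], 4)
        rng = np.random.default_rng(13)
        values = rng.normal(size=12) * 0.01
        values -= np.repeat([values[:4].mean(), values[4:8].mean(),
                             values[8:].mean()], 4)  # equal genotype means
        assert rp.heritability(values, genotypes) == 0.0

    def test_single_genotype_undefined(self):
        with pytest.raises(ValueError):
            rp.heritability(np.arange(4.0), np.repeat("g", 4))

    @pytest.mark.parametrize("seed", range(5))
    def test_simulation_recovers_closed_form(self, seed):
        rng = np.random.default_rng(200 + seed)
        k, nrep = 200, 3
        # condition on the realized components: the simulated truth has
        # exactly Vg = 1 and Vr = 1, so the check isolates estimator error
        g = rng.normal(0, 1.0, k)
        g = (g - g.mean()) / g.std(ddof=1)
        e = rng.normal(0, 1.0, k * nrep)
        e = (e - e.mean()) / e.std(ddof=1)
        values = np.repeat(g, nrep) + e
        genotypes = np.repeat(np.arange(k), nrep)
        assert rp.heritability(values, genotypes) == pytest.approx(0.75, abs=0.05)

    def test_consistency_at_large_k(self):
        rng = np.random.default_rng(42)
        k, nrep = 1000, 3
        # condition on the realized components: the simulated truth has
        # exactly Vg = 1 and Vr = 1, so the check isolates estimator error
        g = rng.normal(0, 1.0, k)
        g = (g - g.mean()) / g.std(ddof=1)
        e = rng.normal(0, 1.0, k * nrep)
        e = (e - e.mean()) / e.std(ddof=1)
        values = np.repeat(g, nrep) + e
        h2 = rp.heritability(values, np.repeat(np.arange(k), nrep))
        assert abs(h2 - 0.75) < 0.02


class TestEffectSize:
    @pytest.mark.parametrize("estimate,mean,expected", [
        (1.5, 3.0, 0.5), (-0.6, 3.0, -0.2), (0.0, 3.0, 0.0)])
    def test_ratio_with_sign(self, estimate, mean, expected):
        vals = np.full(10, mean)
        assert rp.allele_effect_size(estimate, vals) == pytest.approx(expected)

    def test_zero_mean_undefined(self):
        with pytest.raises(ValueError):
            rp.allele_effect_size(1.0, np.array([-1.0, 1.0]))


class TestColocalization:
    @staticmethod
    def rec(snp, chrom, pos, group="univariate", trait="t"):
        return TASRecord(snp, chrom, pos, trait, group)

    def test_within_window_shares_locus(self):
        loci, _ = rp.colocalize_tas([
            self.rec("a", "4", 170_000_000, "PH"),
            self.rec("b", "4", 170_500_000, "univariate")])
        assert len(loci) == 1
        assert loci[0].groups == {"PH", "univariate"}

    def test_different_chromosomes_distinct(self):
        loci, _ = rp.colocalize_tas([
            self.rec("a", "1", 1000), self.rec("b", "2", 1000)])
        assert len(loci) == 2

    def test_transitive_chaining(self):
        loci, _ = rp.colocalize_tas([
            self.rec("a", "1", 0),
            self.rec("b", "1", 900_000),
            self.rec("c", "1", 1_800_000)])
        assert len(loci) == 1

    def test_window_zero_one_locus_per_position(self):
        records = [self.rec(f"s{i}", "1", p) for i, p in
                   enumerate([0, 0, 5, 5, 9])]
        loci, _ = rp.colocalize_tas(records, window=0)
        assert len(loci) == 3

    def test_venn_counts_by_group_combination(self):
        loci, venn = rp.colocalize_tas([
            self.rec("a", "1", 0, "PH"),
            self.rec("b", "1", 500_000, "univariate"),
            self.rec("c", "2", 0, "multivariate"),
            self.rec("d", "3", 0, "PH")])
        assert venn[("PH", "univariate")] == 1
        assert venn[("multivariate",)] == 1
        assert venn[("PH",)] == 1

    def test_invalid_group_rejected(self):
        with pytest.raises(ValueError):
            TASRecord("a", "1", 0, "t", "bogus")
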