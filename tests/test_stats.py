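import numpy as np
import pandas as pd
import pytest

from mycomap.stats import (
    ColonizationAnova,
    ColonizationPCA,
    FrequencyIntensityRegression,
    HistogramSpec,
    correlation_matrix,
    fit_frequency_intensity,
    format_p,
    histogram,
    lsd_letters,
    pca,
    round_half_up,
    two_way_anova,
)


def crossed_table(rng, n_per_cell=30, effects=None):
    """Balanced A1/A2 x B2..B5 layout with iid normal noise."""
    rows = []
    effects = effects or {}
    for t in ("A1", "A2"):
        for p in ("B2", "B3", "B4", "B5"):
            y = rng.normal(size=n_per_cell) + effects.get((t, p), 0.0)
            for i, v in enumerate(y):
                rows.append(dict(treatment=t, phenophase=p, plant_id=1,
                                 fragment_id=1, field_index=i, intensity=v))
    return pd.DataFrame(rows)


class TestHistogram:
    def test_direct_binning(self):
        counts, edges = histogram([5, 15, 95], HistogramSpec("frequency", 10, 0, 100))
        assert counts.tolist() == [1, 1, 0, 0, 0, 0, 0, 0, 0, 1]
        assert edges[0] == 0 and edges[-1] == 100

    def test_final_bin_closed(self):
        counts, _ = histogram([100.0], HistogramSpec("frequency", 10, 0, 100))
        assert counts[-1] == 1

    def test_all_zero_and_conservation(self):
        counts, _ = histogram([0.0] * 7, HistogramSpec.for_parameter("vesicles"))
        assert counts[0] == 7
        rng = np.random.default_rng(1)
        vals = rng.uniform(0, 100, 500)
        counts, _ = histogram(vals, HistogramSpec.for_parameter("intensity"))
        assert counts.sum() == 500

    def test_derived_range_for_ratio(self):
        counts, edges = histogram([0.2, 1.4, 3.3],
                                  HistogramSpec.for_parameter("mnm_report"))
        assert edges[-1] == 3.5 and counts.sum() == 3

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError, match="outside"):
            histogram([-1.0], HistogramSpec("frequency", 10, 0, 100))
        with pytest.raises(ValueError, match="at least one"):
            histogram([], HistogramSpec("frequency", 10, 0, 100))


class TestCorrelations:
    def test_complement_pair_is_minus_one(self, design_table):
        corr = correlation_matrix(design_table)
        assert corr.loc["intensity", "non_mycorrhizal"] == pytest.approx(-1.0)
        assert (np.diag(corr) == 1.0).all()
        assert np.allclose(corr, corr.T)

    def test_independent_columns_near_zero(self):
        rng = np.random.default_rng(5)
        n = 10000
        t = pd.DataFrame({"frequency": rng.normal(size=n),
                          "intensity": rng.normal(size=n)})
        r = correlation_matrix(t, parameters=["frequency", "intensity"])
        assert abs(r.loc["frequency", "intensity"]) < 0.05

    def test_constant_column_flagged_not_fatal(self):
        t = pd.DataFrame({"frequency": [1.0, 2.0, 3.0], "vesicles": 0.0})
        with pytest.warns(UserWarning, match="vesicles"):
            r = correlation_matrix(t, parameters=["frequency", "vesicles"])
        assert np.isnan(r.loc["frequency", "vesicles"])


class TestRegression:
    def test_exact_recovery_of_printed_coefficients(self):
        x = np.linspace(0, 60, 40)
        y = 0.46 + 0.42 * x
        fit = FrequencyIntensityRegression(x, y).fit()
        assert fit.intercept == pytest.approx(0.46, abs=1e-12)
        assert fit.slope == pytest.approx(0.42, abs=1e-12)
        assert fit.equation == "y = 0.46 + 0.42 × x"

    def test_two_points_interpolated(self):
        fit = FrequencyIntensityRegression([10.0, 30.0], [4.0, 13.0]).fit()
        assert fit.predict([10, 30]) == pytest.approx([4.0, 13.0])

    def test_noisy_slope_near_unity(self):
        rng = np.random.default_rng(8)
        x = rng.uniform(0, 100, 10000)
        y = x + rng.normal(scale=5.0, size=x.size)
        fit = FrequencyIntensityRegression(x, y).fit()
        assert 0.97 <= fit.slope <= 1.03

    def test_residual_orthogonality(self):
        rng = np.random.default_rng(9)
        x = rng.uniform(0, 50, 300)
        y = 2 + 0.4 * x + rng.normal(size=300)
        fit = FrequencyIntensityRegression(x, y).fit()
        assert fit.resid.sum() == pytest.approx(0.0, abs=1e-8)
        assert (fit.resid * x).sum() == pytest.approx(0.0, abs=1e-6)

    def test_constant_frequency_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            FrequencyIntensityRegression([5.0, 5.0, 5.0], [1.0, 2.0, 3.0])

    def test_from_table_per_variant(self, design_table):
        fit = fit_frequency_intensity(design_table, ("A0", "B1"))
        assert fit.nobs == 450
        assert 0.0 < fit.slope < 1.0


class TestAnova:
    def test_sequential_partition_is_exact(self):
        rng = np.random.default_rng(12)
        res = two_way_anova(crossed_table(rng), "intensity")
        tab = res.table
        total = tab["sum_sq"].sum()
        y = crossed_table  # noqa: F841  (partition checked against data below)
        assert tab.loc["residual", "df"] == 8 * 30 - 8
        data = None
        # recompute SS_total directly from a fresh identical table
        rng2 = np.random.default_rng(12)
        data = crossed_table(rng2)["intensity"]
        ss_total = ((data - data.mean()) ** 2).sum()
        assert total == pytest.approx(ss_total, rel=1e-10)

    def test_control_point_excluded_from_factorial(self, design_table):
        res = two_way_anova(design_table, "intensity")
        n_used = 8 * 675
        assert res.residual_df == n_used - 8

    def test_degenerate_zero_variance(self):
        rng = np.random.default_rng(3)
        t = crossed_table(rng)
        t["intensity"] = 7.0
        res = two_way_anova(t, "intensity")
        assert res.degenerate
        assert set(res.lsd_letters().values()) == {"a"}

    def test_large_shift_detected(self):
        rng = np.random.default_rng(4)
        effects = {("A2", p): 10.0 for p in ("B2", "B3", "B4", "B5")}
        res = two_way_anova(crossed_table(rng, effects=effects), "intensity")
        assert res.table.loc["treatment", "p"] < 0.001

    def test_empty_cell_named(self):
        rng = np.random.default_rng(6)
        t = crossed_table(rng)
        t = t[~((t.treatment == "A2") & (t.phenophase == "B4"))]
        with pytest.raises(ValueError, match="cell"):
            two_way_anova(t, "intensity")

    def test_one_way_covers_all_nine_variants(self, design_table):
        res = ColonizationAnova(design_table, "frequency", kind="one_way").fit()
        assert len(res.group_means) == 9
        letters = res.lsd_letters()
        assert set(letters) == set(res.group_means.index)
        # highest mean carries 'a'
        top = res.group_means.idxmax()
        assert "a" in letters[top]


class TestLsdLetters:
    def oracle_check(self, means, ms, df, sizes, alpha=0.05):
        from scipy import stats as sps
        letters = lsd_letters(means, ms, df, sizes, alpha)
        tcrit = sps.t.ppf(1 - alpha / 2, df)
        for gi in means:
            for gj in means:
                if gi == gj:
                    continue
                lsd = tcrit * np.sqrt(ms * (1 / sizes[gi] + 1 / sizes[gj]))
                differ = abs(means[gi] - means[gj]) > lsd
                share = bool(set(letters[gi]) & set(letters[gj]))
                assert share != differ, (means, letters, gi, gj)
        return letters

    def test_two_groups_far_apart(self):
        letters = lsd_letters({"g1": 100.0, "g2": 0.0}, 1.0, 20, {"g1": 5, "g2": 5})
        assert letters == {"g1": "a", "g2": "b"}

    def test_all_equal_share_a(self):
        letters = lsd_letters({"g1": 5.0, "g2": 5.0, "g3": 5.0}, 1.0, 20,
                              {"g1": 5, "g2": 5, "g3": 5})
        assert set(letters.values()) == {"a"}

    def test_overlapping_middle_group(self):
        # extremes differ; the middle group is separable from neither
        means = {"hi": 2.0, "mid": 1.0, "lo": 0.0}
        sizes = {"hi": 8, "mid": 8, "lo": 8}
        # LSD ~ 1.04 at MS=1, df=21: |2-1| and |1-0| ns, |2-0| significant
        letters = self.oracle_check(means, 1.0, 21, sizes)
        assert letters == {"hi": "a", "mid": "ab", "lo": "b"}

    @pytest.mark.parametrize("k", [2, 3, 4, 5, 6])
    def test_oracle_agreement_random_instances(self, k):
        rng = np.random.default_rng(100 + k)
        for _ in range(60):
            means = {f"g{i}": float(rng.uniform(0, 6)) for i in range(k)}
            sizes = {g: 6 for g in means}
            self.oracle_check(means, float(rng.uniform(0.2, 4.0)), 30, sizes)

    def test_df_guard(self):
        with pytest.raises(ValueError):
            lsd_letters({"a": 1.0, "b": 2.0}, 1.0, 0.5, {"a": 3, "b": 3})


class TestPca:
    def test_two_correlated_variables_closed_form(self):
        rng = np.random.default_rng(21)
        x = rng.normal(size=4000)
        for rho in (0.3, 0.8, -0.6):
            y = rho * x + np.sqrt(1 - rho**2) * rng.normal(size=x.size)
            t = pd.DataFrame({"frequency": x, "intensity": y})
            res = pca(t, parameters=["frequency", "intensity"])
            r = np.corrcoef(x, y)[0, 1]
            expected = 100 * (1 + abs(r)) / 2
            assert res.explained.iloc[0] == pytest.approx(expected, abs=1e-6)

    def test_perfectly_correlated_rank_one(self):
        t = pd.DataFrame({"frequency": [1.0, 2.0, 3.0, 4.0]})
        t["intensity"] = 2 * t["frequency"]
        res = pca(t, parameters=["frequency", "intensity"])
        assert res.explained.iloc[0] == pytest.approx(100.0)
        assert res.explained.iloc[1] == pytest.approx(0.0)

    def test_variance_shares_sum_to_100(self, design_table):
        res = pca(design_table)
        assert res.explained.sum() == pytest.approx(100.0)
        # loading vectors orthonormal
        L = res.loadings.to_numpy()
        assert np.allclose(L.T @ L, np.eye(L.shape[1]), atol=1e-10)

    def test_affine_rescaling_invariance(self, design_table):
        res1 = pca(design_table, parameters=["frequency", "intensity", "arbuscules"])
        scaled = design_table.copy()
        scaled["frequency"] = scaled["frequency"] * 3.7 + 11.0
        res2 = pca(scaled, parameters=["frequency", "intensity", "arbuscules"])
        assert np.allclose(res1.explained, res2.explained, atol=1e-10)
        assert np.allclose(res1.loadings, res2.loadings, atol=1e-10)

    def test_matches_sklearn_on_standardized_data(self, design_table):
        sklearn = pytest.importorskip("sklearn.decomposition")
        data = design_table[["frequency", "intensity", "arbuscules", "vesicles"]].dropna()
        res = ColonizationPCA(design_table,
                              ["frequency", "intensity", "arbuscules", "vesicles"]).fit()
        Z = (data - data.mean()) / data.std(ddof=1)
        sk = sklearn.PCA(n_components=4).fit(Z.to_numpy())
        share = 100 * sk.explained_variance_ratio_
        assert np.allclose(res.explained, share, atol=1e-6)

    def test_degenerate_inputs(self):
        t = pd.DataFrame({"frequency": [1.0, 2.0, 3.0], "vesicles": 0.0})
        with pytest.warns(UserWarning):
            with pytest.raises(ValueError, match="non-constant"):
                pca(t, parameters=["frequency", "vesicles"])


class TestFormatting:
    def test_round_half_up(self):
        assert round_half_up(0.425, 2) == 0.43
        assert round_half_up(2.675, 2) == 2.68
        assert round_half_up(-0.425, 2) == -0.43

    def test_p_floor(self):
        assert format_p(0.0004) == "p < 0.001"
        assert format_p(0.0312) == "0.031"
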