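import numpy as np
import pandas as pd
import pytest

import rppa_triscore as rt
from rppa_triscore.anova import AnovaEngine, effect_residuals, fit_three_way_anova, fold_change


def values_from(sheet, fn):
    """Build a one-protein value vector from a per-row function of the sheet."""
    v = sheet.apply(fn, axis=1).astype(float)
    return pd.DataFrame({"p": v.to_numpy()}, index=sheet["sample_id"])


class TestThreeWayAnova:
    def test_pure_medium_shift_noiseless(self, sheet85):
        vals = values_from(sheet85, lambda r: 2.0 if r["medium"] == "3D" else 0.0)
        tab = fit_three_way_anova(vals, sheet85)
        assert tab.loc["p", "delta_medium"] == pytest.approx(2.0, abs=1e-10)
        assert tab.loc["p", "p_medium"] == 0.0
        assert tab.loc["p", "delta_treatment"] == pytest.approx(0.0, abs=1e-10)
        assert tab.loc["p", "fc_medium"] == pytest.approx(4.0)

    def test_balanced_16_obs_matches_design_matrix_oracle(self, rng):
        # independent brute force: one-hot design matrices + RSS comparisons
        sheet = rt.build_design(1, 1, 2)  # 2 lines x 2 x 2 x 2 = 16 obs
        y = rng.normal(size=16) + (sheet["medium"] == "3D") * 0.9
        tab = fit_three_way_anova(pd.DataFrame({"p": y.to_numpy()}, index=sheet["sample_id"]), sheet)

        def onehot(col):
            levels = sorted(sheet[col].unique())
            return np.column_stack([(sheet[col] == l).to_numpy(float) for l in levels[1:]])

        C, M, T = onehot("cell_line"), onehot("medium"), onehot("treatment")
        I = M * T
        one = np.ones((16, 1))

        def rss(*blocks):
            X = np.column_stack([one, *blocks]) if blocks else one
            beta, *_ = np.linalg.lstsq(X, y, rcond=None)
            r = y - X @ beta
            return float(r @ r)

        rss_full = rss(C, M, T, I)
        df_resid = 16 - 5
        comparisons = {
            "cellline": (rss(M, T, I), rss(C, M, T, I), 1),
            "medium": (rss(C, T), rss(C, T, M), 1),
            "treatment": (rss(C, M), rss(C, M, T), 1),
            "interaction": (rss(C, M, T), rss_full, 1),
        }
        for term, (r0, r1, df) in comparisons.items():
            F_oracle = ((r0 - r1) / df) / (rss_full / df_resid)
            assert tab.loc["p", f"F_{term}"] == pytest.approx(F_oracle, rel=1e-8), term

    def test_matches_statsmodels_type2_on_unbalanced_design(self, sheet85, rng):
        import statsmodels.formula.api as smf
        from statsmodels.stats.anova import anova_lm

        y = rng.normal(size=85)
        tab = fit_three_way_anova(pd.DataFrame({"p": y}, index=sheet85["sample_id"]), sheet85)
        df = sheet85.copy()
        df["value"] = y
        fit = smf.ols(
            "value ~ C(cell_line, Sum) + C(medium, Sum) + C(treatment, Sum)"
            " + C(medium, Sum):C(treatment, Sum)", df,
        ).fit()
        a2 = anova_lm(fit, typ=2)
        sm_p = a2["PR(>F)"].dropna().to_numpy()
        ours = tab.loc["p", ["p_cellline", "p_medium", "p_treatment", "p_interaction"]].to_numpy(float)
        assert np.allclose(np.sort(sm_p), np.sort(ours), rtol=1e-8)

    def test_type2_equals_type3_on_balanced_data(self, small_sheet, rng):
        import statsmodels.formula.api as smf
        from statsmodels.stats.anova import anova_lm

        y = rng.normal(size=len(small_sheet))
        tab = fit_three_way_anova(pd.DataFrame({"p": y}, index=small_sheet["sample_id"]), small_sheet)
        df = small_sheet.copy()
        df["value"] = y
        fit = smf.ols(
            "value ~ C(cell_line, Sum) + C(medium, Sum) + C(treatment, Sum)"
            " + C(medium, Sum):C(treatment, Sum)", df,
        ).fit()
        a3 = anova_lm(fit, typ=3).drop(index=["Intercept"])
        sm_p = a3["PR(>F)"].dropna().to_numpy()
        ours = tab.loc["p", ["p_cellline", "p_medium", "p_treatment", "p_interaction"]].to_numpy(float)
        assert np.allclose(np.sort(sm_p), np.sort(ours), rtol=1e-8)

    def test_null_pvalues_uniform(self, sheet85, rng):
        Y = pd.DataFrame(rng.normal(size=(85, 800)), index=sheet85["sample_id"])
        tab = AnovaEngine(sheet85).fit(Y)
        band = 3 * np.sqrt(0.05 * 0.95 / 800)
        for term in ("cellline", "medium", "treatment", "interaction"):
            frac = (tab[f"p_{term}"] < 0.05).mean()
            assert abs(frac - 0.05) < band, term

    def test_delta_is_level_mean_difference_on_balanced_data(self, small_sheet, rng):
        y = rng.normal(size=len(small_sheet))
        vals = pd.DataFrame({"p": y}, index=small_sheet["sample_id"])
        tab = fit_three_way_anova(vals, small_sheet)
        is3d = (small_sheet["medium"] == "3D").to_numpy()
        assert tab.loc["p", "delta_medium"] == pytest.approx(
            y[is3d].mean() - y[~is3d].mean(), abs=1e-10
        )

    def test_single_level_factor_raises(self):
        sheet = rt.build_design(2, 2, 2)
        sheet = sheet[sheet["medium"] == "2D"]
        vals = pd.DataFrame({"p": np.arange(float(len(sheet)))}, index=sheet["sample_id"])
        with pytest.raises(ValueError, match="medium"):
            fit_three_way_anova(vals, sheet)

    def test_missing_samples_handled(self, sheet85, rng):
        Y = pd.DataFrame(rng.normal(size=(85, 3)), index=sheet85["sample_id"])
        Y.iloc[0, 0] = np.nan
        tab = AnovaEngine(sheet85).fit(Y)
        assert np.isfinite(tab["p_medium"]).all()


class TestFoldChange:
    @pytest.mark.parametrize("delta,expected", [(1.0, 2.0), (-1.0, -2.0), (0.0, 1.0)])
    def test_definition(self, delta, expected):
        assert fold_change(delta) == pytest.approx(expected)

    def test_sign_and_magnitude_invariants(self, rng):
        d = rng.normal(size=50)
        fc = fold_change(d)
        assert np.all(np.sign(fc) == np.where(d >= 0, 1, -1))
        assert np.all(np.abs(fc) >= 1)

    def test_non_finite_raises(self):
        with pytest.raises(ValueError):
            fold_change(np.nan)


class TestEffectResiduals:
    def test_pure_medium_shift_all_columns_equal_delta(self, sheet85):
        vals = values_from(sheet85, lambda r: 1.7 if r["medium"] == "3D" else 0.0)
        col, cond = effect_residuals(vals, sheet85, "medium")
        arr = col.to_numpy(float)
        assert np.allclose(arr[np.isfinite(arr)], 1.7, atol=1e-10)
        # the dropped LNZ308 replicate-2 column has no 3D members
        assert col[("LNZ308", 2)].isna().all()

    def test_pure_cellline_effects_give_zero_residuals(self, sheet85):
        lines = {l: i * 0.5 for i, l in enumerate(sheet85["cell_line"].unique())}
        vals = values_from(sheet85, lambda r: lines[r["cell_line"]])
        col, _ = effect_residuals(vals, sheet85, "medium")
        arr = col.to_numpy(float)
        assert np.allclose(arr[np.isfinite(arr)], 0.0, atol=1e-10)

    def test_interaction_correction_removes_interaction(self, sheet85):
        # value = medium effect + interaction; the interaction is fitted and
        # subtracted, so every column residual equals the medium effect
        def fn(r):
            v = 1.0 if r["medium"] == "3D" else 0.0
            if r["medium"] == "3D" and r["treatment"] == "hypoxia":
                v += 0.6
            return v

        vals = values_from(sheet85, fn)
        col, cond = effect_residuals(vals, sheet85, "medium")
        arr = col.to_numpy(float)
        assert np.allclose(arr[np.isfinite(arr)], np.nanmean(arr), atol=1e-9)

    def test_simulated_medium_effect_mean_near_planted(self, sheet85, rng):
        from rppa_triscore import synth

        cfg = synth.EffectConfig(protein_effects={"p": synth.ProteinEffect(medium=1.0)})
        truth = rt.simulate_truth(sheet85, ["p"], cfg, seed=13)
        mat = rt.sample_matrix(truth, seed=14)
        col, _ = effect_residuals(mat, sheet85, "medium")
        assert np.nanmean(col.to_numpy(float)) == pytest.approx(1.0, abs=0.05)

    def test_treatment_residuals_symmetric_definition(self, sheet85):
        vals = values_from(sheet85, lambda r: 0.9 if r["treatment"] == "hypoxia" else 0.0)
        col, cond = effect_residuals(vals, sheet85, "treatment")
        arr = col.to_numpy(float)
        assert np.allclose(arr[np.isfinite(arr)], 0.9, atol=1e-10)
        assert cond.columns.names == ["cell_line", "replicate", "medium"]
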