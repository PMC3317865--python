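import itertools
import warnings

import numpy as np
import pandas as pd
import pytest

import rppa_triscore as rt
from rppa_triscore import synth
from rppa_triscore.quantify import assemble_matrix, correct_spatial_trend, fit_joint_logistic
from rppa_triscore.synth import CurveConfig, logistic_intensity


def make_spots(x_by_sample, curve, antibody="AB", steps=range(5), series=(1, 2, 3)):
    """Noise-free spot table for explicit concentrations (test helper)."""
    rows = []
    for i, (s, x) in enumerate(x_by_sample.items()):
        for ser, k in itertools.product(series, steps):
            rows.append({
                "antibody": antibody, "sample_id": s, "dilution_step": k,
                "series": ser, "row": i, "col": 5 * ser + k,
                "intensity": float(logistic_intensity(np.array([x]), np.array([k]), curve)[0]),
                "role": "sample",
            })
    return pd.DataFrame(rows)


def null_truth(sheet, proteins, seed=0, **kw):
    cfg = synth.EffectConfig(protein_effects={p: synth.ProteinEffect() for p in proteins}, **kw)
    return rt.simulate_truth(sheet, proteins, cfg, seed=seed)


class TestSpatialCorrection:
    def test_trend_free_table_unchanged(self, small_sheet):
        truth = null_truth(small_sheet, ["p"], technical_sd=0.0, loading_sd=0.0)
        spots = rt.render_slides(truth, CurveConfig(noise_sd=0.0), seed=1)
        adj, diag = correct_spatial_trend(spots)
        assert np.allclose(adj["intensity"], spots["intensity"], atol=1e-6)
        assert diag["p"] == pytest.approx((0.0, 0.0), abs=1e-9)

    @pytest.mark.parametrize("gradient", [(0.5, 0.0), (3.0, 1.5)])
    def test_planted_gradient_recovered(self, small_sheet, gradient):
        truth = null_truth(small_sheet, ["p"], technical_sd=0.0, loading_sd=0.0)
        spots = rt.render_slides(truth, CurveConfig(noise_sd=0.0, spatial_gradient=gradient), seed=1)
        _, diag = correct_spatial_trend(spots)
        assert diag["p"] == pytest.approx(gradient, abs=1e-6)

    def test_mean_adjustment_zero(self, small_sheet):
        truth = null_truth(small_sheet, ["p"], seed=3)
        spots = rt.render_slides(truth, CurveConfig(spatial_gradient=(2.0, 1.0)), seed=4)
        adj, _ = correct_spatial_trend(spots)
        assert (adj["intensity"] - spots["intensity"]).mean() == pytest.approx(0.0, abs=1e-6)

    def test_too_few_anchors_warns_and_passes_through(self):
        spots = pd.DataFrame({
            "antibody": ["A", "A"], "sample_id": ["c", "c"], "dilution_step": [0, 0],
            "series": [1, 1], "row": [0, 1], "col": [0, 0],
            "intensity": [10.0, 20.0], "role": ["negative_control"] * 2,
        })
        with pytest.warns(UserWarning, match="anchor"):
            adj, diag = correct_spatial_trend(spots)
        assert np.allclose(adj["intensity"], spots["intensity"])
        assert diag["A"] == (0.0, 0.0)


class TestJointLogisticFit:
    def test_noiseless_recovery_within_1e3(self):
        curve = CurveConfig(L=100.0, U=10100.0, eta=1.0, noise_sd=0.0)
        x_true = {"s0": 0.0, "s1": 1.0, "s2": 2.0, "s3": 3.0}
        fit = fit_joint_logistic(make_spots(x_true, curve))
        xh = np.array([fit.x_hat[s] for s in x_true])
        xt = np.array(list(x_true.values()))
        d = xh - xt
        assert np.abs(d - d.mean()).max() < 1e-3  # up to additive constant
        assert fit.converged and fit.eta == pytest.approx(1.0, rel=1e-3)
        assert fit.U - fit.L == pytest.approx(10000.0, rel=1e-2)

    def test_duplicate_sample_symmetry(self):
        curve = CurveConfig(L=100.0, U=10100.0, noise_sd=0.0)
        fit = fit_joint_logistic(make_spots({"a": 0.7, "b": 0.7, "c": 2.0}, curve))
        assert fit.x_hat["a"] == pytest.approx(fit.x_hat["b"], abs=1e-9)

    def test_saturated_low_sample_flagged_and_excluded(self, small_sheet):
        curve = CurveConfig(L=100.0, U=10100.0, noise_sd=0.0)
        x = {"lo": -9.0, "s1": 0.5, "s2": 1.5, "s3": 2.5}
        fit = fit_joint_logistic(make_spots(x, curve))
        assert "saturated-low" in fit.flags.get("lo", [])
        assert "lo" not in fit.quantified
        sheet = pd.DataFrame({
            "sample_id": list(x), "cell_line": ["l"] * 4, "lineage": ["glioma"] * 4,
            "medium": ["2D"] * 4, "treatment": ["normoxia"] * 4, "replicate": [1, 2, 3, 4],
        })
        mat = assemble_matrix({"AB": fit}, sheet)
        assert mat["AB"].isna().sum() == 1

    def test_all_flat_slide_raises(self):
        curve = CurveConfig(L=100.0, U=10100.0, noise_sd=0.0)
        with pytest.raises(ValueError, match="saturated"):
            fit_joint_logistic(make_spots({"a": -20.0, "b": -21.0}, curve))

    def test_shift_equivariance(self):
        # doubling all concentrations of one sample (+1 in log2) moves x_hat by +1
        curve = CurveConfig(L=100.0, U=10100.0, noise_sd=0.0)
        base = {"a": 0.3, "b": 1.1, "c": 2.2}
        f1 = fit_joint_logistic(make_spots(base, curve))
        shifted = dict(base, b=base["b"] + 1.0)
        f2 = fit_joint_logistic(make_spots(shifted, curve))
        d1 = f1.x_hat["b"] - f1.x_hat["a"]
        d2 = f2.x_hat["b"] - f2.x_hat["a"]
        assert d2 - d1 == pytest.approx(1.0, abs=1e-3)

    def test_rss_matches_dense_grid_oracle(self):
        # noisy tiny instance: joint fit must be at least as good as a dense
        # grid over (eta, gap, x_s) at the grid's resolution
        rng = np.random.default_rng(5)
        curve = CurveConfig(L=200.0, U=8200.0, eta=1.2, noise_sd=80.0)
        x_true = {"a": 0.5, "b": 1.5, "c": 2.5}
        spots = make_spots(x_true, curve, series=(1,))
        spots["intensity"] += rng.normal(0, 80.0, len(spots))
        fit = fit_joint_logistic(spots)

        y = spots["intensity"].to_numpy()
        k = spots["dilution_step"].to_numpy(float)
        sid = spots["sample_id"].map({"a": 0, "b": 1, "c": 2}).to_numpy()
        best = np.inf
        for eta in np.linspace(0.8, 1.6, 9):
            for gap in np.linspace(6000, 10000, 9):
                for xa in np.linspace(0, 1, 6):
                    for xb in np.linspace(1, 2, 6):
                        for xc in np.linspace(2, 3, 6):
                            x = np.array([xa, xb, xc])
                            mu = 1 / (1 + np.exp(-eta * (x[sid] - k)))
                            # profile out L analytically
                            resid = y - gap * mu
                            rss = float(((resid - resid.mean()) ** 2).sum())
                            best = min(best, rss)
        assert fit.rss <= best + 1e-6

    def test_sample_with_too_few_steps_not_quantified(self):
        curve = CurveConfig(L=100.0, U=10100.0, noise_sd=0.0)
        spots = make_spots({"a": 0.5, "b": 1.5}, curve)
        extra = make_spots({"thin": 1.0}, curve, steps=[0, 1], series=(1,))
        fit = fit_joint_logistic(pd.concat([spots, extra], ignore_index=True))
        assert "too-few-steps" in fit.flags["thin"]
        assert "thin" not in fit.x_hat


class TestAssembleMatrix:
    def test_shape_and_missing(self, sheet85):
        fits = {}
        curve = CurveConfig(L=100.0, U=10100.0, noise_sd=0.0)
        x = {s: 0.5 + 0.01 * i for i, s in enumerate(sheet85["sample_id"].head(4))}
        fit = fit_joint_logistic(make_spots(x, curve))
        mat = assemble_matrix({"AB1": fit}, sheet85)
        assert mat.shape == (85, 1)
        assert mat["AB1"].notna().sum() == 4

    def test_unknown_sample_raises(self, sheet85):
        curve = CurveConfig(L=100.0, U=10100.0, noise_sd=0.0)
        fit = fit_joint_logistic(make_spots({"ghost1": 0.5, "ghost2": 1.5}, curve))
        with pytest.raises(KeyError, match="ghost"):
            assemble_matrix({"AB": fit}, sheet85)

    def test_empty_fits_raises(self, sheet85):
        with pytest.raises(ValueError):
            assemble_matrix({}, sheet85)


class TestEndToEndQuantification:
    def test_render_then_quantify_recovers_truth(self, small_sheet):
        """Default-noise slides: recovery within replicate-noise scale."""
        proteins = ["q1", "q2"]
        truth = null_truth(small_sheet, proteins, seed=8, loading_sd=0.0)
        spots = rt.render_slides(truth, CurveConfig(spatial_gradient=(2.0, 1.0)), seed=9)
        adj, _ = correct_spatial_trend(spots)
        for p in proteins:
            fit = fit_joint_logistic(adj[adj["antibody"] == p])
            xh = np.array([fit.x_hat[s] for s in truth.values.index])
            d = xh - truth.values[p].to_numpy()
            d -= d.mean()
            rms = float(np.sqrt((d**2).mean()))
            assert rms < 2 * truth.config.technical_sd
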