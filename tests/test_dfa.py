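"""Dynamic factor model: likelihood oracle, EM, rotation, intervals,
covariate coefficients."""

import numpy as np
import pandas as pd
import pytest
from dataclasses import replace

from riversync import simulate
from riversync.dfa import (
    DFAModelSpec,
    DynamicFactorAnalysis,
    _kalman_filter,
    _Params,
    aicc,
    fit_dfa,
    fit_dfa_covariate,
    loglik_exact,
    varimax,
)
from riversync.panel import LengthPanel


def _complete_panel(seed, S, T, m, obs_sd=8.0):
    truth = simulate.default_truth(seed=seed, S=S, T=T, m=m, obs_sd=obs_sd, missing=False)
    panel, truth = simulate.simulate_panel(truth)
    return panel.center(), truth


class TestLikelihoodOracle:
    @pytest.mark.parametrize("structure", ["diagonal_equal", "equalvarcov", "diagonal_unequal"])
    @pytest.mark.parametrize("m", [1, 2])
    def test_kalman_equals_bruteforce_on_complete_panels(self, structure, m):
        panel, _ = _complete_panel(seed=3 + m, S=4, T=6, m=m)
        fit = DynamicFactorAnalysis(panel, m=m, r_structure=structure).fit(max_iter=40)
        assert fit.loglik == pytest.approx(loglik_exact(panel, fit), abs=1e-6)

    def test_kalman_equals_bruteforce_with_missing_cells(self):
        truth = simulate.default_truth(seed=5, S=4, T=8, m=1, obs_sd=8.0, min_obs=5)
        panel, _ = simulate.simulate_panel(truth)
        panel = panel.center()
        fit = DynamicFactorAnalysis(panel, m=1, r_structure="equalvarcov").fit(max_iter=40)
        assert fit.loglik == pytest.approx(loglik_exact(panel, fit), abs=1e-6)

    def test_zero_loading_reduces_to_independent_normals(self):
        panel, _ = _complete_panel(seed=9, S=3, T=5, m=1)
        model = DynamicFactorAnalysis(panel, m=1)
        sigma2 = np.array([4.0, 9.0, 16.0])
        params = _Params(
            Z=np.zeros((3, 1)),
            a=np.zeros(3),
            D=np.zeros((3, 0)),
            pi=np.zeros(1),
            sigma2=sigma2,
            cov=0.0,
        )
        ll = _kalman_filter(panel.values, model.obs_idx, params, None, want_states=False)
        y = panel.values
        direct = sum(
            -0.5 * (np.log(2 * np.pi * sigma2[i]) + y[i, t] ** 2 / sigma2[i])
            for i in range(3)
            for t in range(5)
        )
        assert ll == pytest.approx(direct, abs=1e-9)

    def test_sign_flip_of_trend_and_loading_column_preserves_likelihood(self):
        panel, _ = _complete_panel(seed=2, S=4, T=10, m=2)
        fit = DynamicFactorAnalysis(panel, m=2).fit(max_iter=60)
        model = fit.model
        flipped = replace(
            fit.params,
            Z=fit.params.Z * np.array([1.0, -1.0]),
            pi=fit.params.pi * np.array([1.0, -1.0]),
        )
        ll0 = _kalman_filter(panel.values, model.obs_idx, fit.params, None, False)
        ll1 = _kalman_filter(panel.values, model.obs_idx, flipped, None, False)
        assert ll1 == pytest.approx(ll0, abs=1e-8)

    def test_equalvarcov_at_zero_covariance_matches_diagonal_equal(self):
        panel, _ = _complete_panel(seed=4, S=5, T=12, m=1)
        model = DynamicFactorAnalysis(panel, m=1)
        base = model.fit(max_iter=60).params
        p_eq = replace(base, sigma2=np.full(5, 30.0), cov=0.0)
        ll_diag = _kalman_filter(panel.values, model.obs_idx, p_eq, None, False)
        model_cov = DynamicFactorAnalysis(panel, m=1, r_structure="equalvarcov")
        ll_cov = _kalman_filter(panel.values, model_cov.obs_idx, p_eq, None, False)
        assert ll_cov == pytest.approx(ll_diag, abs=1e-6)


class TestEMFit:
    def test_loglik_never_decreases(self):
        for seed in range(5):
            truth = simulate.default_truth(seed=seed, S=6, T=25, m=2, obs_sd=10.0)
            panel, _ = simulate.simulate_panel(truth)
            fit = DynamicFactorAnalysis(
                panel.center(), m=2, r_structure=["diagonal_equal", "equalvarcov",
                                                  "diagonal_unequal"][seed % 3]
            ).fit(max_iter=120, track_loglik=True)
            assert np.diff(fit.loglik_path).min() >= -1e-8

    def test_noise_free_panel_is_interpolated(self):
        truth = simulate.default_truth(seed=8, S=5, T=20, m=1, obs_sd=0.01, missing=False)
        panel, _ = simulate.simulate_panel(truth)
        p = panel.center()
        fit = DynamicFactorAnalysis(p, m=1).fit(max_iter=500, tol=1e-8)
        err = np.abs(fit.fittedvalues() - p.values)
        assert err.max() < 0.1

    def test_low_noise_trend_recovery(self):
        # trends are identified up to rotation; at low noise the matched
        # correlation with the truth (after optimal orthogonal alignment)
        # should be high for seeds whose realized walks carry signal
        from scipy.linalg import orthogonal_procrustes
        from scipy.optimize import linear_sum_assignment

        truth = simulate.default_truth(seed=0, S=19, T=51, m=3, obs_sd=3.0)
        panel, truth = simulate.simulate_panel(truth)
        fit = DynamicFactorAnalysis(panel.center(), m=3).fit(max_iter=3000, tol=1e-6)
        rot = fit.rotate()
        H, _ = orthogonal_procrustes(rot.x.T, truth.trends.T)
        aligned = (rot.x.T @ H).T
        C = np.abs(np.corrcoef(truth.trends, aligned)[:3, 3:])
        r, c = linear_sum_assignment(-C)
        assert C[r, c].mean() >= 0.9

    def test_max_iter_reached_flags_not_raises(self):
        panel, _ = _complete_panel(seed=1, S=4, T=10, m=1)
        fit = DynamicFactorAnalysis(panel, m=1).fit(max_iter=2)
        assert not fit.converged
        assert fit.n_iter == 2

    def test_model_validation_errors(self):
        panel, _ = _complete_panel(seed=1, S=3, T=8, m=1)
        with pytest.raises(ValueError, match="m="):
            DynamicFactorAnalysis(panel, m=3)
        raw = panel.uncenter()
        with pytest.raises(ValueError, match="centered"):
            DynamicFactorAnalysis(raw, m=1)
        values = panel.values.copy()
        values[0, :] = np.nan
        dead = LengthPanel(values, panel.rivers, panel.years, centered=True)
        with pytest.raises(ValueError, match="no observations"):
            DynamicFactorAnalysis(dead, m=1)


class TestAICc:
    def test_formula(self):
        assert aicc(-100.0, 5, 50) == pytest.approx(200 + 2 * 5 * 50 / 44)

    def test_decreases_with_n_for_fixed_k_and_loglik(self):
        values = [aicc(-100.0, 5, n) for n in (20, 50, 200, 1000)]
        assert all(a > b for a, b in zip(values, values[1:]))

    def test_small_sample_returns_inf(self):
        assert aicc(-10.0, 10, 11) == np.inf

    def test_counted_parameters_match_structure(self):
        panel, _ = _complete_panel(seed=1, S=5, T=10, m=2)
        k = {}
        for structure, extra in [
            ("diagonal_equal", 1),
            ("equalvarcov", 2),
            ("diagonal_unequal", 5),
        ]:
            model = DynamicFactorAnalysis(panel, m=2, r_structure=structure)
            # free loadings: S*m - m(m-1)/2 = 9; initial state m = 2
            assert model.n_params == 9 + 2 + extra


class TestVarimax:
    def test_single_factor_is_identity(self):
        L = np.random.default_rng(0).normal(size=(6, 1))
        rotated, H = varimax(L)
        np.testing.assert_allclose(H, np.eye(1))
        np.testing.assert_allclose(rotated, L)

    def test_rotation_is_orthogonal(self, two_trend_fit):
        _, _, fit = two_trend_fit
        rot = fit.rotate()
        np.testing.assert_allclose(rot.rotation.T @ rot.rotation, np.eye(2), atol=1e-10)

    def test_fitted_values_invariant(self, two_trend_fit):
        _, _, fit = two_trend_fit
        rot = fit.rotate()
        assert np.abs(rot.fittedvalues() - fit.fittedvalues()).max() < 1e-10

    def test_matches_statsmodels_rotation(self, rng):
        from statsmodels.multivariate.factor_rotation import rotate_factors

        L = rng.normal(size=(10, 3))
        ours, _ = varimax(L)
        ref, _ = rotate_factors(L, "varimax")
        # varimax is unique up to column order and sign: compare the
        # sorted squared-column criterion and matched columns
        C = np.abs(ours.T @ ref)
        order = C.argmax(axis=1)
        assert sorted(order) == [0, 1, 2]
        for j, k in enumerate(order):
            sign = np.sign(ours[:, j] @ ref[:, k])
            np.testing.assert_allclose(ours[:, j], sign * ref[:, k], atol=1e-5)


class TestFittedIntervals:
    def test_zero_loading_row_has_zero_width(self, small_fit):
        fit = replace(small_fit, params=replace(small_fit.params, Z=np.zeros_like(small_fit.Z)))
        ci = fit.fitted_with_ci(0.95)
        np.testing.assert_allclose((ci.upper - ci.lower).to_numpy(), 0.0, atol=1e-12)

    def test_intervals_widen_with_level(self, small_fit):
        ci95 = small_fit.fitted_with_ci(0.95)
        ci99 = small_fit.fitted_with_ci(0.99)
        w95 = (ci95.upper - ci95.lower).to_numpy()
        w99 = (ci99.upper - ci99.lower).to_numpy()
        assert (w99 > w95).all()

    def test_band_covers_latent_signal_at_low_noise(self):
        # the interval carries smoothed-state uncertainty only (no
        # parameter uncertainty), so its empirical coverage of the latent
        # signal sits below the nominal level; it must stay in a sane band
        hits = tot = 0
        for seed in range(10):
            truth = simulate.default_truth(
                seed=seed, S=4, T=15, m=1, obs_sd=0.5, missing=False
            )
            panel, truth = simulate.simulate_panel(truth)
            p = panel.center()
            signal = truth.loadings @ truth.trends + truth.offsets[:, None]
            signal = signal - signal.mean(axis=1, keepdims=True)
            fit = DynamicFactorAnalysis(p, m=1).fit(max_iter=300, tol=1e-7)
            ci = fit.fitted_with_ci(0.95)
            inside = (signal >= ci.lower.to_numpy()) & (signal <= ci.upper.to_numpy())
            hits += inside.sum()
            tot += inside.size
        assert 0.75 <= hits / tot <= 1.0


class TestCovariateModels:
    def _panel_with_effect(self, seed, beta=10.0, S=6, T=35):
        rng = np.random.default_rng(seed)
        truth = simulate.default_truth(seed=seed, S=S, T=T, m=1, obs_sd=8.0, missing=False)
        panel, truth = simulate.simulate_panel(truth)
        d = rng.standard_normal(T)
        d = (d - d.mean()) / d.std(ddof=1)
        values = panel.values.copy()
        values[0] += beta * d  # river 1 only responds to the covariate
        panel = LengthPanel(values, panel.rivers, panel.years)
        cov = pd.Series(d, index=panel.years, name="x")
        return panel.center(), cov

    def test_each_covariate_adds_one_parameter_per_series(self):
        panel, cov = self._panel_with_effect(seed=0)
        spec = DFAModelSpec(m=1, max_iter=5)
        base = fit_dfa(panel, spec)
        one = fit_dfa_covariate(panel, spec, cov)
        other = pd.Series(
            np.sin(np.arange(len(cov))), index=cov.index, name="y"
        )
        two = fit_dfa_covariate(panel, spec, pd.concat([cov, other], axis=1))
        S = panel.n_rivers
        assert one.n_params == base.n_params + S
        assert two.n_params == base.n_params + 2 * S

    def test_known_effect_recovered_with_calibrated_intervals(self):
        ok_effect = ok_null = n = 0
        for seed in range(5):
            panel, cov = self._panel_with_effect(seed=seed, beta=10.0)
            spec = DFAModelSpec(m=1, max_iter=400, tol=1e-6)
            fit = fit_dfa_covariate(panel, spec, cov)
            table = fit.covariate_table()
            river1 = table.iloc[0]
            ok_effect += river1["ci_lower"] <= 10.0 <= river1["ci_upper"]
            others = table.iloc[1:]
            ok_null += ((others["ci_lower"] <= 0) & (others["ci_upper"] >= 0)).mean() >= 0.8
            n += 1
        assert ok_effect >= 3  # majority of seeds
        assert ok_null >= 3

    def test_incomplete_covariate_rejected(self):
        panel, cov = self._panel_with_effect(seed=1)
        cov.iloc[3] = np.nan
        with pytest.raises(ValueError, match="complete"):
            fit_dfa_covariate(panel, DFAModelSpec(m=1, max_iter=5), cov)

    def test_serialization_roundtrip_fields(self, small_fit):
        d = small_fit.to_dict()
        assert set(d) >= {"Z", "x", "loglik", "AICc", "converged", "m", "r_structure"}
        np.testing.assert_allclose(np.array(d["Z"]), small_fit.Z)

    def test_spec_loads_from_yaml_config(self, tmp_path):
        cfg = tmp_path / "dfa.yaml"
        cfg.write_text("m: 3\nR: equalvarcov\ntol: 1.0e-6\nmax_iter: 50000\n")
        spec = DFAModelSpec.from_file(cfg)
        assert (spec.m, spec.r_structure, spec.tol, spec.max_iter) == (
            3,
            "equalvarcov",
            1e-6,
            50000,
        )

    def test_summary_mentions_key_quantities(self, small_fit):
        text = small_fit.summary()
        assert "AICc" in text and "Loadings" in text and "equalvarcov" not in text
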