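import numpy as np
import pytest

from betashift.synthetic import survey_times
from betashift.trajectories import (
    fit_linear,
    fit_logistic,
    fit_quadratic,
    logistic_curve,
    orthogonal_poly,
    select_model,
    stepwise_regression,
)


class TestOrthogonalPoly:
    def test_classical_equally_spaced_contrasts(self):
        design = orthogonal_poly(np.arange(1, 6), degree=2)
        lin = design[:, 0] / np.abs(design[:, 0]).max() * 2
        quad = design[:, 1] / np.abs(design[:, 1]).max() * 2
        np.testing.assert_allclose(lin, [-2, -1, 0, 1, 2], atol=1e-10)
        np.testing.assert_allclose(quad, [2, -1, -2, -1, 2], atol=1e-10)

    def test_gram_matrix_identity_and_centering(self):
        rng = np.random.default_rng(0)
        t = rng.uniform(2004, 2012, 40)
        design = orthogonal_poly(t, degree=2)
        np.testing.assert_allclose(design.T @ design, np.eye(2), atol=1e-10)
        np.testing.assert_allclose(design.sum(axis=0), 0, atol=1e-10)

    def test_too_few_distinct_times(self):
        with pytest.raises(ValueError, match="distinct"):
            orthogonal_poly([1.0, 1.0, 2.0], degree=2)


class TestUnivariateFits:
    def test_linear_noiseless(self):
        t = np.arange(10.0)
        fit = fit_linear(t, 2 * t + 1)
        assert fit.params["slope"] == pytest.approx(2.0, abs=1e-10)
        assert fit.r2 == pytest.approx(1.0)

    def test_quadratic_vertex_noiseless(self):
        t = np.linspace(2004, 2012, 15)
        fit = fit_quadratic(t, -((t - 2009) ** 2) + 40)
        assert fit.vertex_time == pytest.approx(2009.0, abs=1e-8)
        assert fit.r2 == pytest.approx(1.0)

    def test_convex_quadratic_has_no_vertex_time(self):
        t = np.linspace(0, 10, 12)
        fit = fit_quadratic(t, (t - 5) ** 2)
        assert fit.vertex_time is None

    def test_logistic_noiseless_recovery(self):
        t = np.repeat(survey_times(), 3)
        y = logistic_curve(t, 50, 5, 2008, 0.5)
        fit = fit_logistic(t, y)
        assert fit.converged
        for key, truth in zip(("y_b", "y_a", "T", "sigma"), (50, 5, 2008, 0.5)):
            assert fit.params[key] == pytest.approx(truth, rel=1e-4)
        assert fit.decline_pct == pytest.approx(90.0, abs=1e-6)

    def test_logistic_midpoint_and_limits(self):
        fit = fit_logistic(np.repeat(survey_times(), 3),
                           logistic_curve(np.repeat(survey_times(), 3), 40, 4, 2007.5, 0.4))
        p = fit.params
        assert fit.predict([p["T"]])[0] == pytest.approx((p["y_b"] + p["y_a"]) / 2, rel=1e-6)
        assert fit.predict([1900.0])[0] == pytest.approx(p["y_b"], rel=1e-4)
        assert fit.predict([2100.0])[0] == pytest.approx(p["y_a"], rel=1e-4)

    def test_logistic_inflection_recovery_under_noise(self):
        """Noisy collapse (sd 3, 3 replicates × 14 steps): median |T̂−T| small."""
        rng = np.random.default_rng(1)
        t = np.repeat(survey_times(), 3)
        errors = []
        for _ in range(50):
            y = logistic_curve(t, 50, 5, 2008, 0.5) + rng.normal(0, 3, t.size)
            fit = fit_logistic(t, y)
            if fit.converged:
                errors.append(abs(fit.params["T"] - 2008))
        assert np.median(errors) <= 0.3

    def test_quadratic_vertex_recovery_under_noise(self):
        rng = np.random.default_rng(2)
        t = np.repeat(survey_times(), 3)
        vertices = []
        for _ in range(50):
            y = -1.2 * (t - 2008.75) ** 2 + 40 + rng.normal(0, 2, t.size)
            vertices.append(fit_quadratic(t, y).vertex_time)
        assert abs(np.median(vertices) - 2008.75) <= 0.5


class TestSelectModel:
    def test_logistic_data_selects_logistic(self):
        rng = np.random.default_rng(3)
        t = np.repeat(survey_times(), 3)
        wins = 0
        for _ in range(40):
            y = logistic_curve(t, 50, 5, 2008, 0.4) + rng.normal(0, 2, t.size)
            fits = [fit_linear(t, y), fit_quadratic(t, y), fit_logistic(t, y)]
            wins += select_model(fits).kind == "logistic"
        assert wins >= 38  # ≥95 %

    def test_linear_data_quadratic_f_test_calibrated(self):
        rng = np.random.default_rng(4)
        t = np.repeat(survey_times(), 3)
        nonsig = 0
        for _ in range(60):
            y = 3 * (t - 2004) + rng.normal(0, 2, t.size)
            best = select_model([fit_linear(t, y), fit_quadratic(t, y)])
            nonsig += best.params["quadratic_vs_linear"]["p"] > 0.05
        assert nonsig >= 0.9 * 60 * 0.9  # ≥~90 % non-significant

    def test_single_candidate_returned(self):
        t = np.arange(6.0)
        fit = fit_linear(t, t)
        assert select_model([fit]) is fit

    def test_all_failed_raises(self):
        from betashift.trajectories import TrajectoryFit
        failed = TrajectoryFit(kind="logistic", params={}, converged=False)
        with pytest.raises(ValueError, match="converge"):
            select_model([failed])


class TestStepwise:
    @staticmethod
    def _design(rng, n_sites=4, n_rep=2):
        times = np.asarray(survey_times())
        t = np.tile(np.repeat(times, n_rep), n_sites)
        site = np.repeat([f"S{i}" for i in range(n_sites)], len(times) * n_rep)
        season = np.where(t % 1 == 0, "wet", "dry")
        return t, site, season

    def test_pure_noise_retains_little(self):
        """AIC-stepwise admits a spurious 1-df term whenever its F exceeds
        ~2, so on pure noise the expected model is empty or tiny — never the
        full space-time design."""
        rng = np.random.default_rng(5)
        t, site, season = self._design(rng)
        n_retained = []
        for _ in range(30):
            res = stepwise_regression(rng.normal(size=len(t)), t, site, season)
            n_retained.append(len(res.retained))
        n_retained = np.asarray(n_retained)
        assert (n_retained == 0).mean() >= 0.3
        assert n_retained.mean() <= 2.5
        assert (n_retained == 6).mean() <= 0.1  # full design almost never kept

    def test_time_site_signal_excludes_interaction(self):
        rng = np.random.default_rng(6)
        t, site, season = self._design(rng)
        site_effect = {f"S{i}": 3.0 * i for i in range(4)}
        y = 2.0 * (t - t.mean()) + np.array([site_effect[s] for s in site])
        y = y + rng.normal(0, 0.5, len(t))
        res = stepwise_regression(y, t, site, season)
        assert "time" in res.retained and "site" in res.retained
        assert "time:site" not in res.retained and "time2:site" not in res.retained

    def test_full_signal_retained_and_r2_partition(self):
        rng = np.random.default_rng(7)
        t, site, season = self._design(rng)
        slopes = {"S0": 1.0, "S1": 3.0, "S2": -2.0, "S3": 0.5}
        y = (np.array([slopes[s] for s in site]) * (t - t.mean())
             + np.where(season == "dry", 2.0, 0.0)
             + rng.normal(0, 0.4, len(t)))
        res = stepwise_regression(y, t, site, season)
        for term in ("time", "site", "time:site", "season"):
            assert term in res.retained
        # sequential r2 contributions sum to the full-model R²
        assert res.anova["r2"].sum() == pytest.approx(res.r2, abs=1e-10)
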