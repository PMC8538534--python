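"""Tests for weighted outcome models, diagnostics and index effects."""

import numpy as np
import pytest

from mitralmorph import (
    cohort_frame,
    compute_sipw,
    default_config,
    delta_index_effect,
    fit_ps_model,
    fit_weighted_linear,
    fit_weighted_ordinal,
    generate_cohort,
    linear_diagnostics,
    surrogate_residuals,
)
from mitralmorph.cohort import EXPOSURES
from mitralmorph.ordinal import fit_proportional_odds
from mitralmorph.outcomes import MissingCoefficientError


def wls_oracle(y, X, w):
    """Explicit (X'WX)^-1 X'Wy and HC0 sandwich."""
    D = np.column_stack([np.ones(len(y)), X])
    W = np.diag(w)
    bread = np.linalg.inv(D.T @ W @ D)
    beta = bread @ D.T @ W @ y
    e = y - D @ beta
    meat = D.T @ np.diag(w ** 2 * e ** 2) @ D
    cov = bread @ meat @ bread
    return beta, cov


class TestWeightedLinear:
    def test_constant_weights_equal_ols(self):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(80, 3))
        y = X @ [1.0, -0.5, 0.2] + rng.normal(size=80)
        f1 = fit_weighted_linear(y, X, np.full(80, 3.7))
        f2 = fit_weighted_linear(y, X, np.ones(80))
        assert np.allclose(f1.coef, f2.coef, atol=1e-10)

    def test_matches_matrix_oracle(self):
        rng = np.random.default_rng(1)
        for _ in range(10):
            n = rng.integers(40, 200)
            p = rng.integers(1, 15)
            X = rng.normal(size=(n, p))
            y = rng.normal(size=n)
            w = rng.uniform(0.2, 3.0, size=n)
            fit = fit_weighted_linear(y, X, w)
            beta, cov = wls_oracle(y, X, w)
            assert np.allclose(fit.coef, beta[1:], atol=1e-8)
            assert np.allclose(fit.robust_se,
                               np.sqrt(np.diag(cov))[1:], atol=1e-8)

    def test_recovers_generator_effects_with_weights(self):
        cfg = default_config(n=1000, seed=21)
        records, truth = generate_cohort(cfg)
        fr = cohort_frame(records)
        X = fr[EXPOSURES].to_numpy()
        m = fit_ps_model(fr)
        w = compute_sipw(fr, m).sipw
        for outcome in ("amvl_i", "mvad_i"):
            f = fit_weighted_linear(fr[outcome].to_numpy(), X, w,
                                    outcome=outcome)
            b = truth.outcome_effects[outcome]
            assert np.all(np.abs(f.coef - b) < 3.2 * f.robust_se)

    def test_collinear_column_raises_with_names(self):
        rng = np.random.default_rng(2)
        X = rng.normal(size=(50, 3))
        X[:, 2] = X[:, 0]
        from mitralmorph.outcomes import EstimationErrorLinear
        with pytest.raises(EstimationErrorLinear):
            fit_weighted_linear(rng.normal(size=50), X, np.ones(50))


class TestWeightedOrdinal:
    def test_two_category_collapse_equals_weighted_logistic(self):
        import statsmodels.api as sm
        rng = np.random.default_rng(3)
        X = rng.normal(size=(300, 2))
        y = (X @ [1.0, -0.7] + rng.logistic(size=300) > 0).astype(int)
        w = rng.uniform(0.5, 2.0, size=300)
        f = fit_weighted_ordinal(y, X, w)
        glm = sm.GLM(y, sm.add_constant(X), family=sm.families.Binomial(),
                     var_weights=w).fit()
        assert np.allclose(f.coef, glm.params[1:], atol=1e-6)

    def test_sparse_top_category_merges_down(self):
        """Unobserved category labels are compressed with a warning."""
        rng = np.random.default_rng(4)
        X = rng.normal(size=(200, 2))
        y = np.searchsorted([-0.5, 0.8], X @ [0.8, 0.3]
                            + rng.logistic(size=200))
        y[y == 2] = 3          # label gap: categories {0, 1, 3}
        f = fit_weighted_ordinal(y, X, np.ones(200))
        assert len(f.cutpoints) == 2
        assert f.converged


class TestSurrogateResiduals:
    def test_deterministic_given_seed(self, medium_frame):
        X = medium_frame[EXPOSURES].to_numpy()
        y = medium_frame["jet"].to_numpy().astype(int)
        f = fit_weighted_ordinal(y, X, np.ones(len(y)))
        r1, s1 = surrogate_residuals(f, X, y, seed=11)
        r2, s2 = surrogate_residuals(f, X, y, seed=11)
        assert np.array_equal(r1, r2)
        assert s1 == s2

    def test_misspecification_inflates_residual_trend(self):
        """Non-proportional effects bend the residual-exposure relation.

        A proportionality violation (category-specific slopes) shows up as
        a nonlinear trend of the surrogate residuals in the offending
        exposure — the plot-based diagnostic summarized here as the
        correlation between the residual and the squared exposure.
        """
        from mitralmorph.outcomes import OutcomeFit

        rng = np.random.default_rng(5)
        n = 4000
        X = rng.normal(size=(n, 2))

        def curvature(y):
            fit = fit_proportional_odds(y, X)
            of = OutcomeFit(outcome="t", family="ordinal",
                            exposure_names=["x1", "x2"], coef=fit.beta,
                            robust_se=fit.se_robust[:2],
                            p_values=np.ones(2),
                            cov_robust=fit.cov_robust[:2, :2],
                            cutpoints=fit.cutpoints)
            resid, _ = surrogate_residuals(of, X, y, seed=6, replicates=20)
            return abs(np.corrcoef(resid, X[:, 0] ** 2)[0, 1])

        lat = X @ [0.8, -0.4] + rng.logistic(size=n)
        y_ok = np.searchsorted([-1.0, 0.0, 1.0], lat)
        # slope for x1 differs between the two thresholds
        u = rng.logistic(size=n)
        y_bad = ((X @ [2.5, -0.4] + u > -1.0).astype(int)
                 + (X @ [0.0, -0.4] + u > 1.0).astype(int))
        assert curvature(y_bad) > 2.0 * curvature(y_ok)


class TestLinearDiagnostics:
    def test_orthonormal_design_has_unit_vifs(self):
        rng = np.random.default_rng(7)
        raw = rng.normal(size=(100, 4))
        q, _ = np.linalg.qr(raw - raw.mean(axis=0))   # centered, orthonormal
        X = q[:, :4]
        y = rng.normal(size=100)
        f = fit_weighted_linear(y, X, np.ones(100),
                                exposure_names=list("abcd"))
        rep = linear_diagnostics(f, X, y, np.ones(100))
        for v in rep.vif.values():
            assert v == pytest.approx(1.0, abs=1e-6)

    def test_duplicated_column_flagged_unbounded(self):
        rng = np.random.default_rng(8)
        base = rng.normal(size=(60, 2))
        X = np.column_stack([base, base[:, 0] * 1.0 + 1e-14])
        y = rng.normal(size=60)
        # fit on the first two columns only, diagnose the 3-column matrix
        f = fit_weighted_linear(y, base, np.ones(60),
                                exposure_names=["a", "b"])
        f.exposure_names = ["a", "b", "dup"]
        f.coef = np.append(f.coef, 0.0)
        rep = linear_diagnostics(
            type(f)(outcome="t", family="linear",
                    exposure_names=["a", "b", "dup"],
                    coef=np.array([0.0, 0.0, 0.0]),
                    robust_se=np.ones(3), p_values=np.ones(3),
                    cov_robust=np.eye(3), intercept=0.0),
            X, y, np.ones(60))
        assert rep.vif["dup"] == np.inf
        assert "dup" in rep.collinear_flags

    def test_gaussian_residuals_pass_normality_most_seeds(self):
        ok = 0
        for s in range(30):
            rng = np.random.default_rng(100 + s)
            X = rng.normal(size=(500, 3))
            y = X @ [0.5, -0.2, 0.1] + rng.normal(size=500)
            w = rng.uniform(0.5, 2, size=500)
            f = fit_weighted_linear(y, X, w, exposure_names=list("abc"))
            rep = linear_diagnostics(f, X, y, w)
            ok += rep.normality_p > 0.05
        assert ok >= 24


class TestDeltaIndexEffects:
    def make_fit(self, names, coef, cov):
        from mitralmorph.outcomes import OutcomeFit
        coef = np.asarray(coef, dtype=float)
        return OutcomeFit(outcome="y", family="linear",
                          exposure_names=list(names), coef=coef,
                          robust_se=np.sqrt(np.diag(cov)),
                          p_values=np.ones(len(coef)),
                          cov_robust=np.asarray(cov, dtype=float))

    def test_thoracic_index_hand_value(self):
        """beta_TW = 0.5, TH = 14.95, zero covariance: effect 0.074750."""
        fit = self.make_fit(["tw", "th"], [0.5, -0.1], np.zeros((2, 2)))
        point = {"tw": 11.95, "th": 14.95}
        [eff] = delta_index_effect(fit, "thoracic_index", point,
                                   "vary_numerator")
        assert eff.effect == pytest.approx(0.5 * 14.95 / 100, abs=1e-12)
        assert eff.delta_se == 0.0

    def test_linear_index_is_exact_combination(self):
        cov = np.array([[0.04, 0.01], [0.01, 0.09]])
        fit = self.make_fit(["hl", "nl"], [0.3, -0.1], cov)
        point = {"hl": 7.7, "nl": 3.2}
        [eff] = delta_index_effect(fit, "hnl", point)
        s = np.array([7.7 / 10.9, 3.2 / 10.9])
        assert eff.effect == pytest.approx(s @ [0.3, -0.1], rel=1e-12)
        assert eff.delta_se == pytest.approx(np.sqrt(s @ cov @ s), rel=1e-12)

    def test_both_variants_and_missing_coefficient(self):
        fit = self.make_fit(["tw", "th"], [0.5, -0.1], np.eye(2) * 0.01)
        point = {"tw": 11.95, "th": 14.95, "weight": 9.15, "wh": 29.2}
        effs = delta_index_effect(fit, "thoracic_index", point, "both")
        assert {e.variant for e in effs} == {"vary_numerator",
                                             "vary_denominator"}
        # vary-denominator derivative: -beta_TH * TH^2 / (100 * TW)
        vd = next(e for e in effs if e.variant == "vary_denominator")
        assert vd.effect == pytest.approx(
            0.1 * 14.95 ** 2 / (100 * 11.95), rel=1e-12)
        # volume index needs a body-weight coefficient for the numerator
        with pytest.raises(MissingCoefficientError):
            delta_index_effect(fit, "volume_index", point, "vary_denominator")

    def test_recovers_simulated_thoracic_index_effect(self):
        """Outcome built from TI alone: delta effect ~ the true slope."""
        cfg = default_config(n=2000, seed=31)
        records, _ = generate_cohort(cfg)
        fr = cohort_frame(records)
        rng = np.random.default_rng(32)
        gamma = 0.05
        ti = 100.0 * fr["tw"] / fr["th"]
        y = (gamma * ti + rng.normal(0, 0.5, len(fr))).to_numpy()
        X = fr[EXPOSURES].to_numpy()
        f = fit_weighted_linear(y, X, np.ones(len(fr)),
                                exposure_names=EXPOSURES)
        point = {m: float(np.median(fr[m])) for m in EXPOSURES}
        [eff] = delta_index_effect(f, "thoracic_index", point,
                                   "vary_numerator")
        assert abs(eff.effect - gamma) < 3 * eff.delta_se + 0.1 * gamma
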