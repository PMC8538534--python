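"""Tests for the propensity model, stabilized weights, and diagnostics."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import norm

from mitralmorph import (
    balance_report,
    check_positivity,
    cohort_frame,
    compute_sipw,
    default_config,
    fit_ps_model,
    generate_cohort,
    screen_interactions,
    select_ps_model,
)
from mitralmorph.cohort import EXPOSURES
from mitralmorph.weights import (
    EstimationError,
    WeightSet,
    weighted_correlation,
)


def toy_frame(n=200, seed=0, slope=2.0):
    rng = np.random.default_rng(seed)
    age = rng.normal(5, 2, n)
    x = 10 + slope * age + rng.normal(0, 1, n)
    data = {"dog_id": [f"d{i}" for i in range(n)], "age": age,
            "weight": rng.normal(9, 1, n), "sex_F": rng.integers(0, 2, n),
            "blenheim": rng.integers(0, 2, n), "x": x}
    return pd.DataFrame(data)


class TestPropensityFit:
    def test_single_exposure_slope_matches_closed_form(self):
        fr = toy_frame()
        m = fit_ps_model(fr, exposures=["x"], covariates=["age"])
        a = fr["age"] - fr["age"].mean()
        slope = float((a * fr["x"]).sum() / (a * a).sum())
        assert m.coefficient_matrix[1, 0] == pytest.approx(slope, rel=1e-10)

    def test_constant_covariates_reduce_to_marginal_moments(self):
        fr = toy_frame()
        fr["age"] = 5.0
        fr["weight"] = 9.0
        fr["sex_F"] = 1.0
        fr["blenheim"] = 0.0
        m = fit_ps_model(fr, exposures=["x"])
        assert set(m.dropped_terms) == {"age", "weight", "sex_F", "blenheim"}
        assert m.design_terms == ["intercept"]
        # intercept-only residual covariance = sample covariance (ddof=1)
        assert m.residual_covariance[0, 0] == pytest.approx(
            np.var(fr["x"], ddof=1), rel=1e-12)

    def test_rank_deficient_design_names_collinear_terms(self):
        fr = toy_frame()
        fr["weight"] = 2.0 * fr["age"]
        with pytest.raises(EstimationError, match="weight"):
            fit_ps_model(fr, exposures=["x"], covariates=["age", "weight"])

    def test_matches_per_exposure_least_squares(self, medium_frame):
        """Multivariate fit equals column-by-column OLS on the same design."""
        import statsmodels.api as sm
        m = fit_ps_model(medium_frame)
        D = m.design_for(medium_frame)
        for j, e in enumerate(EXPOSURES):
            beta = sm.OLS(medium_frame[e].to_numpy(), D).fit().params
            assert np.allclose(m.coefficient_matrix[:, j], beta, atol=1e-8)

    def test_recovers_generator_coefficients(self, medium_cohort,
                                             medium_frame):
        """Known confounding matrix recovered within 3 SEs at n = 2000."""
        records, truth = medium_cohort
        fr = medium_frame
        m = fit_ps_model(fr)
        D = m.design_for(fr)
        XtXinv = np.linalg.inv(D.T @ D)
        # generator loads standardized age; design uses raw age.  Map the
        # truth to the raw-age slope for the designated HL column.
        cfg = default_config(n=2000, seed=1)
        _, age_sd = cfg.age_moments()
        j = EXPOSURES.index("hl")
        truth_slope = truth.confounding[j, 0] / age_sd
        col = m.design_terms.index("age")
        se = np.sqrt(m.residual_covariance[j, j] * XtXinv[col, col])
        assert abs(m.coefficient_matrix[col, j] - truth_slope) < 3 * se


class TestStabilizedWeights:
    def test_identity_ratio_gives_unit_weights(self, medium_frame):
        """Intercept-only conditional model = marginal => weights all 1."""
        m = fit_ps_model(medium_frame, covariates=[])
        ws = compute_sipw(medium_frame, m)
        assert np.allclose(ws.sipw, 1.0, atol=1e-10)

    def test_zero_confounding_true_densities_give_unit_weights(self):
        cfg = default_config(n=300, seed=8)
        cfg.confounding = np.zeros((13, 4))
        records, truth = generate_cohort(cfg)
        fr = cohort_frame(records)
        m = fit_ps_model(fr)
        ws = compute_sipw(fr, m, density_source="supplied",
                          ground_truth=truth)
        assert np.allclose(ws.sipw, 1.0, atol=1e-10)

    def test_scalar_normal_density_ratio_oracle(self):
        """1 exposure, 1 covariate: weight = ratio of two normal pdfs."""
        fr = toy_frame(n=150, seed=3)
        m = fit_ps_model(fr, exposures=["x"], covariates=["age"])
        ws = compute_sipw(fr, m)
        x = fr["x"].to_numpy()
        mu_m, sd_m = x.mean(), x.std(ddof=1)
        D = m.design_for(fr)
        cond_mean = (D @ m.coefficient_matrix)[:, 0]
        sd_c = np.sqrt(m.residual_covariance[0, 0])
        expected = norm.pdf(x, mu_m, sd_m) / norm.pdf(x, cond_mean, sd_c)
        assert np.allclose(ws.sipw, expected, rtol=1e-10)

    def test_truncation_clips_to_percentiles(self, medium_frame):
        m = fit_ps_model(medium_frame)
        raw = compute_sipw(medium_frame, m)
        trunc = compute_sipw(medium_frame, m, truncation=(5, 95))
        lo, hi = np.percentile(raw.sipw, [5, 95])
        assert trunc.sipw.min() >= lo - 1e-12
        assert trunc.sipw.max() <= hi + 1e-12
        assert trunc.truncation == (5, 95)

    def test_mean_weight_near_one(self, medium_frame):
        m = fit_ps_model(medium_frame)
        ws = compute_sipw(medium_frame, m)
        assert 0.8 <= ws.sipw.mean() <= 1.2


class TestBalance:
    def test_equal_weights_reproduce_unweighted_correlations(self,
                                                             medium_frame):
        m = fit_ps_model(medium_frame)
        ws = compute_sipw(medium_frame, m)
        ws_unit = WeightSet(sipw=np.ones(len(medium_frame)),
                            dog_ids=ws.dog_ids,
                            marginal_mean=ws.marginal_mean,
                            marginal_cov=ws.marginal_cov, model=m,
                            density_source="estimated")
        rep = balance_report(medium_frame, ws_unit)
        assert np.allclose(rep.table["r_weighted"],
                           rep.table["r_unweighted"], atol=1e-12)

    def test_four_point_hand_example(self):
        """Weights (1,1,2,2) equal frequency-expanding the last two rows."""
        x = np.array([1.0, 2.0, 3.0, 4.0])
        y = np.array([2.0, 1.0, 5.0, 3.0])
        w = np.array([1.0, 1.0, 2.0, 2.0])
        expanded_x = np.array([1, 2, 3, 3, 4, 4], dtype=float)
        expanded_y = np.array([2, 1, 5, 5, 3, 3], dtype=float)
        expected = np.corrcoef(expanded_x, expanded_y)[0, 1]
        assert weighted_correlation(x, y, w) == pytest.approx(expected,
                                                              rel=1e-12)

    def test_true_weights_improve_summary(self, medium_frame, medium_cohort):
        _, truth = medium_cohort
        m = fit_ps_model(medium_frame)
        ws = compute_sipw(medium_frame, m)
        ws_true = WeightSet(sipw=truth.true_weights(), dog_ids=ws.dog_ids,
                            marginal_mean=truth.marginal_mean,
                            marginal_cov=truth.marginal_cov, model=m,
                            density_source="supplied")
        rep = balance_report(medium_frame, ws_true)
        assert rep.summary_weighted < rep.summary_unweighted

    def test_zero_variance_pair_reported_undefined(self):
        fr = toy_frame(n=50, seed=1)
        fr["x"] = 3.14
        m = fit_ps_model(fr, exposures=["x"], covariates=["age"])
        ws = compute_sipw(fr, m, ridge=1e-6)
        rep = balance_report(fr, ws, covariates=["age"])
        assert ("age", "x") in rep.undefined_pairs


class TestModelSelection:
    def test_single_candidate_returned(self, medium_frame):
        m = fit_ps_model(medium_frame)
        best, reports = select_ps_model(medium_frame, [m])
        assert best is m
        assert len(reports) == 1

    def test_identical_candidates_tie_break_to_additive(self, medium_frame):
        add = fit_ps_model(medium_frame, "additive")
        clone = fit_ps_model(medium_frame, "additive")
        clone.variant = "interaction"
        best, _ = select_ps_model(medium_frame, [clone, add])
        assert best.variant == "additive"

    def test_balancing_model_beats_unit_weight_model(self, medium_frame):
        """A no-op (intercept-only) PS yields weights 1 and loses."""
        noop = fit_ps_model(medium_frame, covariates=[])
        noop.covariates = list(
            fit_ps_model(medium_frame).covariates)  # align complete cases
        noop.variant = "interaction"
        real = fit_ps_model(medium_frame, "additive")
        best, reports = select_ps_model(medium_frame, [noop, real])
        assert best is real


class TestInteractionScreening:
    def test_true_interaction_detected(self):
        cfg = default_config(n=1000, seed=6)
        records, _ = generate_cohort(cfg)
        fr = cohort_frame(records)
        # inject a strong age x weight interaction into one exposure
        az = (fr["age"] - fr["age"].mean()) / fr["age"].std()
        wz = (fr["weight"] - fr["weight"].mean()) / fr["weight"].std()
        fr["hl"] = fr["hl"] + 0.8 * fr["hl"].std() * az * wz
        found = screen_interactions(fr)
        assert ("age", "weight") in found

    def test_null_false_positive_rate_near_alpha(self):
        """Without interactions, hits occur at roughly the alpha rate."""
        hits = 0
        tests = 0
        for s in range(30):
            cfg = default_config(n=300, seed=900 + s)
            cfg.confounding = np.zeros((13, 4))
            records, _ = generate_cohort(cfg)
            fr = cohort_frame(records)
            for pair_hit in screen_interactions(fr, alpha=0.05):
                hits += 1
            tests += 6          # covariate pairs examined per seed
        rate = hits / tests
        # a pair is flagged if ANY of 13 (correlated) exposure models hits,
        # so the per-pair rate sits above alpha but well below 13 * alpha
        assert 0.01 < rate < 0.45

    def test_empty_covariate_set_returns_nothing(self, medium_frame):
        assert screen_interactions(medium_frame, covariates=[]) == []


class TestPositivity:
    def test_triangle_matches_analytic_half_plane_oracle(self):
        tri = np.array([[0.0, 0.0], [4.0, 0.0], [0.0, 4.0]])
        g = np.linspace(-1, 5, 25)
        pts = np.array([[x, y] for x in g for y in g])
        inside_true = np.array([
            x >= -1e-12 and y >= -1e-12 and x + y <= 4 + 1e-12
            for x, y in pts])
        rep = check_positivity(tri, pts, exposure_names=["a", "b"])
        assert np.array_equal(rep.inside, inside_true)

    def test_centroid_inside_and_far_point_outside(self, medium_frame):
        X = medium_frame[EXPOSURES].to_numpy()[:200]
        centroid = X.mean(axis=0, keepdims=True)
        beyond = X.max(axis=0, keepdims=True) + 10.0
        rep = check_positivity(X, np.vstack([centroid, beyond]))
        assert rep.inside.tolist() == [True, False]

    def test_observed_points_inside_own_hull(self, medium_frame):
        X = medium_frame[EXPOSURES].to_numpy()[:150]
        rep = check_positivity(X, max_hull_dim=5)
        assert rep.inside.all()
        assert rep.hull_dim == 5

    def test_zero_variance_exposure_dropped(self):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(50, 3))
        X[:, 1] = 7.0
        rep = check_positivity(X, exposure_names=["a", "b", "c"])
        assert rep.dropped_exposures == ["b"]
        assert rep.inside.all()
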