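"""Generalized multivariate propensity scores and stabilized IP weights.

With 13 continuous, mutually correlated exposures, the propensity model
is a multivariate multiple regression of the exposure vector on the
covariates (age, weight, sex, coat collapsed to Blenheim vs other),
optionally with bivariate covariate interactions.  The stabilized
inverse-probability weight of subject *i* is the density ratio

    w_i = f(x_i) / f(x_i | c_i),

with both densities taken multivariate normal: the marginal from the
sample mean and covariance of the exposures, the conditional from the
model-predicted mean and the residual covariance.  Weighting by w_i
breaks the covariate-exposure association while keeping the weighted
sample size near the original (mean weight ~ 1).

The module also provides the supporting diagnostics: covariate-exposure
balance before/after weighting, balance-based selection between the
additive and interaction propensity models, interaction screening, and a
positivity check based on membership in the convex hull of the observed
exposure vectors (decided by linear-programming feasibility, optionally
in a leading principal-component subspace).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.linalg import solve_triangular
from scipy.optimize import linprog
import statsmodels.api as sm

__all__ = [
    "EstimationError",
    "PropensityModel",
    "WeightSet",
    "BalanceReport",
    "PositivityReport",
    "DEFAULT_COVARIATES",
    "fit_ps_model",
    "screen_interactions",
    "compute_sipw",
    "check_positivity",
    "balance_report",
    "select_ps_model",
    "weighted_correlation",
]

DEFAULT_COVARIATES = ["age", "weight", "sex_F", "blenheim"]


class EstimationError(RuntimeError):
    """Estimation failed (rank deficiency, singular covariance, ...)."""


def _build_design(frame: pd.DataFrame, covariates: Sequence[str],
                  interactions: Sequence[tuple[str, str]]):
    """Design matrix with intercept, covariate mains, and product terms.

    Covariate columns with zero variance are dropped (they duplicate the
    intercept); the dropped names are returned for reporting.
    """
    names = ["intercept"]
    cols = [np.ones(len(frame))]
    dropped = []
    for c in covariates:
        v = frame[c].to_numpy(dtype=float)
        if np.ptp(v) == 0.0:
            dropped.append(c)
            continue
        names.append(c)
        cols.append(v)
    for a, b in interactions:
        v = frame[a].to_numpy(dtype=float) * frame[b].to_numpy(dtype=float)
        if np.ptp(v) == 0.0:
            dropped.append(f"{a}:{b}")
            continue
        names.append(f"{a}:{b}")
        cols.append(v)
    return np.column_stack(cols), names, dropped


def _check_rank(D: np.ndarray, names: list[str]) -> None:
    q, r = np.linalg.qr(D)
    diag = np.abs(np.diag(r))
    tol = diag.max() * max(D.shape) * np.finfo(float).eps * 1e3
    bad = [names[j] for j in range(len(names)) if diag[j] < tol]
    if bad:
        raise EstimationError(
            f"rank-deficient propensity design; collinear term(s): "
            f"{', '.join(bad)}"
        )


@dataclass
class PropensityModel:
    """Multivariate regression of the exposures on the covariate design."""

    variant: str                         # "additive" | "interaction"
    design_terms: list[str]
    covariates: list[str]
    interaction_terms: list[tuple[str, str]]
    coefficient_matrix: np.ndarray       # (terms, n_exposures)
    residual_covariance: np.ndarray      # (n_exposures, n_exposures)
    exposure_names: list[str]
    fitted_on: int
    log_exposures: bool = False
    dropped_terms: list[str] = field(default_factory=list)

    def design_for(self, frame: pd.DataFrame) -> np.ndarray:
        D, names, _ = _build_design(frame, self.covariates,
                                    self.interaction_terms)
        keep = [j for j, nm in enumerate(names) if nm in self.design_terms]
        return D[:, keep]

    def predict(self, frame: pd.DataFrame) -> np.ndarray:
        return self.design_for(frame) @ self.coefficient_matrix


def _complete_cases(frame: pd.DataFrame, columns: Sequence[str]) -> pd.DataFrame:
    sub = frame[list(columns)].astype(float)
    return frame.loc[np.isfinite(sub.to_numpy()).all(axis=1)]


def fit_ps_model(frame: pd.DataFrame,
                 variant: str = "additive",
                 interaction_terms: Optional[Sequence[tuple[str, str]]] = None,
                 exposures: Optional[Sequence[str]] = None,
                 covariates: Sequence[str] = DEFAULT_COVARIATES,
                 log_exposures: bool = False) -> PropensityModel:
    """Fit the generalized multivariate propensity model by least squares.

    The residual covariance is the residual cross-product divided by
    (n - number of design terms).  Complete cases only.
    """
    from .cohort import EXPOSURES
    exposures = list(exposures or EXPOSURES)
    inter = list(interaction_terms or []) if variant == "interaction" else []
    if variant not in ("additive", "interaction"):
        raise ValueError(f"unknown variant {variant!r}")
    cc = _complete_cases(frame, list(exposures) + list(covariates))
    D, names, dropped = _build_design(cc, covariates, inter)
    n, k = D.shape
    if n < k + 2:
        raise EstimationError(
            f"too few complete cases (n={n}) for {k} design terms"
        )
    _check_rank(D, names)
    X = cc[exposures].to_numpy(dtype=float)
    if log_exposures:
        X = np.log(X)
    beta, *_ = np.linalg.lstsq(D, X, rcond=None)
    resid = X - D @ beta
    Sigma = resid.T @ resid / (n - k)
    return PropensityModel(
        variant=variant,
        design_terms=names,
        covariates=list(covariates),
        interaction_terms=inter,
        coefficient_matrix=beta,
        residual_covariance=Sigma,
        exposure_names=exposures,
        fitted_on=n,
        log_exposures=log_exposures,
        dropped_terms=dropped,
    )


def screen_interactions(frame: pd.DataFrame,
                        alpha: float = 0.05,
                        exposures: Optional[Sequence[str]] = None,
                        covariates: Sequence[str] = DEFAULT_COVARIATES,
                        ) -> list[tuple[str, str]]:
    """Exploratory screen for bivariate covariate interactions.

    For every exposure and every covariate pair (u, v) a small normal
    model ``exposure ~ u + v + u:v`` is fitted; pairs whose interaction
    term is significant at ``alpha`` in any exposure model are returned,
    deduplicated, in covariate order.  Estimation failures are skipped.
    """
    from .cohort import EXPOSURES
    exposures = list(exposures or EXPOSURES)
    covariates = list(covariates)
    if len(covariates) < 2:
        return []
    cc = _complete_cases(frame, list(exposures) + covariates)
    found: list[tuple[str, str]] = []
    for u, v in itertools.combinations(covariates, 2):
        hit = False
        xu = cc[u].to_numpy(dtype=float)
        xv = cc[v].to_numpy(dtype=float)
        D = np.column_stack([np.ones(len(cc)), xu, xv, xu * xv])
        if np.linalg.matrix_rank(D) < 4:
            continue
        for e in exposures:
            y = cc[e].to_numpy(dtype=float)
            try:
                res = sm.OLS(y, D).fit()
            except Exception:
                continue
            if res.pvalues[3] < alpha:
                hit = True
                break
        if hit:
            found.append((u, v))
    return found


@dataclass
class WeightSet:
    """Per-subject stabilized inverse-probability weights."""

    sipw: np.ndarray
    dog_ids: list[str]
    marginal_mean: np.ndarray
    marginal_cov: np.ndarray
    model: Optional[PropensityModel]
    density_source: str
    truncation: Optional[tuple[float, float]] = None
    flagged: list[str] = field(default_factory=list)


def _mvn_logpdf_rows(x, means, cov, ridge=0.0):
    cov = np.asarray(cov, dtype=float)
    if ridge > 0:
        cov = cov + ridge * np.eye(cov.shape[0])
    try:
        L = np.linalg.cholesky(cov)
    except np.linalg.LinAlgError:
        raise EstimationError(
            "singular exposure covariance; pass ridge > 0 to regularize"
        ) from None
    z = solve_triangular(L, (x - means).T, lower=True)
    logdet = 2.0 * np.sum(np.log(np.diag(L)))
    d = x.shape[1]
    return -0.5 * (d * np.log(2 * np.pi) + logdet + np.sum(z ** 2, axis=0))


def compute_sipw(frame: pd.DataFrame,
                 model: PropensityModel,
                 density_source: str = "estimated",
                 ground_truth=None,
                 truncation: Optional[tuple[float, float]] = None,
                 ridge: float = 0.0) -> WeightSet:
    """Stabilized inverse-probability weights from the density ratio.

    ``density_source="estimated"`` uses the sample marginal moments and
    the fitted conditional model; ``"supplied"`` uses the generator's
    exact densities (for validation).  ``truncation`` optionally clips
    the weights at symmetric percentiles, e.g. ``(1, 99)``.
    """
    cc = _complete_cases(frame, list(model.exposure_names) + model.covariates)
    X = cc[model.exposure_names].to_numpy(dtype=float)
    if model.log_exposures:
        X = np.log(X)
    if density_source == "estimated":
        marg_mean = X.mean(axis=0)
        marg_cov = np.atleast_2d(np.cov(X.T, ddof=1))
        lw_m = _mvn_logpdf_rows(X, marg_mean, marg_cov, ridge)
        cond_mean = model.predict(cc)
        lw_c = _mvn_logpdf_rows(X, cond_mean, model.residual_covariance, ridge)
    elif density_source == "supplied":
        if ground_truth is None:
            raise ValueError("density_source='supplied' needs ground_truth")
        marg_mean = ground_truth.marginal_mean
        marg_cov = ground_truth.marginal_cov
        lw_m = ground_truth.log_marginal_density()
        lw_c = ground_truth.log_conditional_density()
    else:
        raise ValueError(f"unknown density_source {density_source!r}")
    w = np.exp(lw_m - lw_c)
    flagged = [str(d) for d in cc["dog_id"].to_numpy()[~np.isfinite(w)]] \
        if "dog_id" in cc else []
    if flagged:
        w = np.where(np.isfinite(w), w, np.nan)
    if truncation is not None:
        lo, hi = np.percentile(w[np.isfinite(w)], truncation)
        w = np.clip(w, lo, hi)
    return WeightSet(
        sipw=w,
        dog_ids=[str(d) for d in cc["dog_id"]] if "dog_id" in cc else
                [str(i) for i in cc.index],
        marginal_mean=np.asarray(marg_mean, dtype=float),
        marginal_cov=np.asarray(marg_cov, dtype=float),
        model=model,
        density_source=density_source,
        truncation=truncation,
        flagged=flagged,
    )


def weighted_correlation(x: np.ndarray, y: np.ndarray, w: np.ndarray) -> float:
    """Weighted Pearson correlation (weights as frequency weights)."""
    w = np.asarray(w, dtype=float)
    sw = w.sum()
    mx = np.sum(w * x) / sw
    my = np.sum(w * y) / sw
    cxy = np.sum(w * (x - mx) * (y - my)) / sw
    vx = np.sum(w * (x - mx) ** 2) / sw
    vy = np.sum(w * (y - my) ** 2) / sw
    if np.ptp(x) == 0 or np.ptp(y) == 0 or vx <= 0 or vy <= 0:
        return float("nan")
    return float(cxy / np.sqrt(vx * vy))


@dataclass
class BalanceReport:
    """Covariate-exposure association before and after weighting."""

    table: pd.DataFrame         # covariate, exposure, r_unweighted, r_weighted
    summary_unweighted: float   # mean |r|
    summary_weighted: float
    undefined_pairs: list[tuple[str, str]]


def balance_report(frame: pd.DataFrame, weights: WeightSet,
                   covariates: Sequence[str] = DEFAULT_COVARIATES,
                   ) -> BalanceReport:
    """Weighted vs unweighted Pearson correlation for every pair."""
    model = weights.model
    exposures = model.exposure_names if model is not None else None
    from .cohort import EXPOSURES
    exposures = exposures or EXPOSURES
    cc = _complete_cases(frame, list(exposures) + list(covariates))
    w = weights.sipw
    if len(w) != len(cc):
        raise ValueError("weights are not aligned with the complete cases")
    ones = np.ones(len(cc))
    rows = []
    undefined = []
    for c in covariates:
        xc = cc[c].to_numpy(dtype=float)
        for e in exposures:
            xe = cc[e].to_numpy(dtype=float)
            ru = weighted_correlation(xc, xe, ones)
            rw = weighted_correlation(xc, xe, w)
            if not np.isfinite(rw):
                undefined.append((c, e))
            rows.append({"covariate": c, "exposure": e,
                         "r_unweighted": ru, "r_weighted": rw})
    tab = pd.DataFrame(rows)
    return BalanceReport(
        table=tab,
        summary_unweighted=float(np.nanmean(np.abs(tab["r_unweighted"]))),
        summary_weighted=float(np.nanmean(np.abs(tab["r_weighted"]))),
        undefined_pairs=undefined,
    )


def select_ps_model(frame: pd.DataFrame,
                    candidates: Sequence[PropensityModel],
                    covariates: Sequence[str] = DEFAULT_COVARIATES,
                    ) -> tuple[PropensityModel, list[BalanceReport]]:
    """Pick the candidate whose SIPW best balance the covariates.

    The balance summary is the mean absolute weighted covariate-exposure
    correlation; ties go to the additive (simpler) model.
    """
    if not candidates:
        raise ValueError("need at least one candidate model")
    reports = []
    for m in candidates:
        ws = compute_sipw(frame, m)
        reports.append(balance_report(frame, ws, covariates))
    best = None
    best_s = np.inf
    for m, rep in zip(candidates, reports):
        s = rep.summary_weighted
        better = s < best_s - 1e-12
        tie = abs(s - best_s) <= 1e-12
        if better or (tie and m.variant == "additive"
                      and best is not None and best.variant != "additive"):
            best, best_s = m, min(s, best_s)
    return best, reports


@dataclass
class PositivityReport:
    """Convex-hull positivity check over the exposure support."""

    exposure_range: pd.DataFrame     # per-exposure observed min/max
    inside: np.ndarray               # verdict per evaluation point
    hull_dim: int
    dropped_exposures: list[str]
    n_points: int


def _in_hull(points: np.ndarray, p: np.ndarray) -> bool:
    """Is p a convex combination of the rows of points? (LP feasibility)"""
    n, d = points.shape
    A_eq = np.vstack([points.T, np.ones((1, n))])
    b_eq = np.concatenate([p, [1.0]])
    res = linprog(np.zeros(n), A_eq=A_eq, b_eq=b_eq,
                  bounds=[(0, None)] * n, method="highs")
    return bool(res.status == 0)


def check_positivity(exposures: np.ndarray,
                     eval_points: Optional[np.ndarray] = None,
                     max_hull_dim: int = 5,
                     exposure_names: Optional[Sequence[str]] = None,
                     ) -> PositivityReport:
    """Hull-membership positivity check.

    Zero-variance exposures are reported and dropped.  When the exposure
    dimension exceeds ``max_hull_dim`` the test is run in the leading
    principal-component subspace of that dimension, with the per-exposure
    min/max reported alongside.  ``eval_points`` defaults to the observed
    points themselves (each must lie inside its own hull).
    """
    X = np.asarray(exposures, dtype=float)
    from .cohort import EXPOSURES
    names = list(exposure_names or EXPOSURES[: X.shape[1]])
    sd = X.std(axis=0)
    keep = sd > 0
    dropped = [names[j] for j in range(X.shape[1]) if not keep[j]]
    Xk = X[:, keep]
    if eval_points is None:
        eval_points = X
    P = np.asarray(eval_points, dtype=float)[:, keep]
    d = Xk.shape[1]
    hull_dim = min(d, max_hull_dim)
    if d > max_hull_dim:
        mu = Xk.mean(axis=0)
        _, _, Vt = np.linalg.svd(Xk - mu, full_matrices=False)
        proj = Vt[:max_hull_dim].T
        Xh = (Xk - mu) @ proj
        Ph = (P - mu) @ proj
    else:
        Xh, Ph = Xk, P
    if Xh.shape[0] < hull_dim + 1:
        raise EstimationError(
            f"need at least {hull_dim + 1} points for a {hull_dim}-d hull"
        )
    inside = np.array([_in_hull(Xh, p) for p in Ph], dtype=bool)
    rng_tab = pd.DataFrame({
        "exposure": names,
        "min": X.min(axis=0),
        "max": X.max(axis=0),
    })
    return PositivityReport(
        exposure_range=rng_tab,
        inside=inside,
        hull_dim=hull_dim,
        dropped_exposures=dropped,
        n_points=X.shape[0],
    )
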