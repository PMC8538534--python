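"""SIPW-weighted outcome models, diagnostics, and index effects.

Six continuous echocardiographic outcomes (weight-indexed AMVL, AMVW,
AMVA, MVAd, MVAs, and the sphericity index) are modelled by weighted
least squares; three ordinal outcomes (MVP grade, regurgitant jet grade,
murmur grade) by weighted proportional-odds logistic regression.  All 13
morphometric exposures enter each model simultaneously.  Standard errors
are heteroscedasticity-consistent sandwiches with the weights treated as
fixed, and p-values use the normal approximation with no multiplicity
correction.

Effects of the composite morphometric indexes (ratios of measurements,
e.g. thoracic index = 100*TW/TH) are not directly identified by models
in the raw measurements; they are derived from the fitted coefficients
by reparameterizing the index along a stated direction (numerator moving
with the denominator held fixed, or vice versa) and propagating the
robust covariance by the first-order delta method.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from statsmodels.stats.diagnostic import het_breuschpagan, linear_reset

from .cohort import EXPOSURES
from .ordinal import ConvergenceError, OrdinalFit, fit_proportional_odds

__all__ = [
    "OutcomeFit",
    "DiagnosticsReport",
    "IndexEffect",
    "fit_weighted_linear",
    "fit_weighted_ordinal",
    "surrogate_residuals",
    "linear_diagnostics",
    "delta_index_effect",
    "INDEX_DEFINITIONS",
]

log = logging.getLogger(__name__)


@dataclass
class OutcomeFit:
    """One fitted outcome model with robust inference."""

    outcome: str
    family: str                      # "linear" | "ordinal"
    exposure_names: list[str]
    coef: np.ndarray                 # per-exposure estimates
    robust_se: np.ndarray
    p_values: np.ndarray
    cov_robust: np.ndarray           # exposure block of the sandwich
    intercept: Optional[float] = None
    cutpoints: Optional[np.ndarray] = None
    n_used: int = 0
    converged: bool = True
    separation_flag: bool = False
    loglik: Optional[float] = None
    weights_used: Optional[np.ndarray] = None

    def coef_table(self) -> pd.DataFrame:
        return pd.DataFrame({
            "exposure": self.exposure_names,
            "coef": self.coef,
            "robust_se": self.robust_se,
            "p": self.p_values,
        })


def fit_weighted_linear(y, X, w, outcome: str = "y",
                        exposure_names: Optional[Sequence[str]] = None,
                        ) -> OutcomeFit:
    """Weighted least squares with an HC0 sandwich (weights fixed).

    Solves ``argmin sum_i w_i (y_i - b0 - x_i'b)^2``; the robust
    covariance is ``(X'WX)^-1 (sum w_i^2 e_i^2 x_i x_i') (X'WX)^-1``.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    w = np.asarray(w, dtype=float)
    names = list(exposure_names or EXPOSURES[: X.shape[1]])
    D = sm.add_constant(X, has_constant="add")
    if np.linalg.matrix_rank(D) < D.shape[1]:
        q, r = np.linalg.qr(np.sqrt(w)[:, None] * D)
        diag = np.abs(np.diag(r))
        tol = diag.max() * max(D.shape) * np.finfo(float).eps * 1e3
        bad = [(["intercept"] + names)[j]
               for j in range(D.shape[1]) if diag[j] < tol]
        raise EstimationErrorLinear(
            f"singular weighted cross-product; collinear column(s): "
            f"{', '.join(bad) or 'unknown'}"
        )
    res = sm.WLS(y, D, weights=w).fit(cov_type="HC0")
    coef = res.params[1:]
    cov = res.cov_params()
    se = np.sqrt(np.diag(cov))[1:]
    z = coef / se
    p = 2.0 * stats.norm.sf(np.abs(z))
    fit = OutcomeFit(
        outcome=outcome, family="linear", exposure_names=names,
        coef=coef, robust_se=se, p_values=p,
        cov_robust=cov[1:, 1:], intercept=float(res.params[0]),
        n_used=len(y), weights_used=w,
    )
    fit._sm_result = res
    return fit


class EstimationErrorLinear(RuntimeError):
    """Weighted linear estimation failed (collinearity)."""


def fit_weighted_ordinal(y, X, w, outcome: str = "y",
                         exposure_names: Optional[Sequence[str]] = None,
                         ) -> OutcomeFit:
    """Weighted proportional-odds fit with sandwich errors.

    Categories observed with zero count are merged with the adjacent
    lower category (by label compression), with a logged warning.
    """
    y = np.asarray(y)
    X = np.asarray(X, dtype=float)
    names = list(exposure_names or EXPOSURES[: X.shape[1]])
    cats = np.unique(y)
    full = np.arange(cats.min(), cats.max() + 1)
    if len(cats) != len(full):
        log.warning("%s: unobserved ordinal categories merged downward "
                    "(observed %s)", outcome, cats.tolist())
    res = fit_proportional_odds(y, X, weights=np.asarray(w, dtype=float))
    p_exp = X.shape[1]
    se = res.se_robust[:p_exp]
    z = res.beta / se
    fit = OutcomeFit(
        outcome=outcome, family="ordinal", exposure_names=names,
        coef=res.beta, robust_se=se,
        p_values=2.0 * stats.norm.sf(np.abs(z)),
        cov_robust=res.cov_robust[:p_exp, :p_exp],
        cutpoints=res.cutpoints, n_used=res.n_obs,
        converged=res.converged, separation_flag=res.separation_flag,
        loglik=res.loglik, weights_used=np.asarray(w, dtype=float),
    )
    fit._ordinal_result = res
    return fit


def surrogate_residuals(fit: OutcomeFit, X, y, seed: int,
                        replicates: int = 1) -> tuple[np.ndarray, dict]:
    """Latent-scale surrogate residuals for an ordinal fit.

    For each subject a latent value is sampled from the fitted logistic
    latent distribution truncated to the interval implied by the observed
    category; the residual is (latent - linear predictor).  Under a
    correctly specified proportional-odds model the residuals have mean
    zero and are uncorrelated with the predictor and the exposures.
    ``replicates > 1`` averages several draws per subject.
    """
    if fit.family != "ordinal" or fit.cutpoints is None:
        raise ValueError("surrogate residuals require an ordinal fit")
    rng = np.random.default_rng(seed)
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    cats = np.unique(y)
    yc = np.searchsorted(cats, y)
    K = len(cats)
    alpha = np.asarray(fit.cutpoints, dtype=float)
    eta = X @ fit.coef
    lo = np.where(yc > 0, alpha[np.maximum(yc - 1, 0)] - eta, -np.inf)
    hi = np.where(yc < K - 1, alpha[np.minimum(yc, K - 2)] - eta, np.inf)
    from scipy.special import expit
    u_lo = expit(lo)
    u_hi = expit(hi)
    draws = np.zeros((replicates, len(y)))
    for r in range(replicates):
        u = u_lo + (u_hi - u_lo) * rng.random(len(y))
        u = np.clip(u, 1e-12, 1 - 1e-12)
        draws[r] = np.log(u / (1.0 - u))      # logistic quantile = residual
    resid = draws.mean(axis=0)
    summaries = {
        "mean": float(resid.mean()),
        "corr_fitted": float(np.corrcoef(resid, eta)[0, 1])
        if np.std(eta) > 0 else float("nan"),
        "corr_exposures": {
            nm: float(np.corrcoef(resid, X[:, j])[0, 1])
            for j, nm in enumerate(fit.exposure_names)
        },
    }
    return resid, summaries


@dataclass
class DiagnosticsReport:
    """Assumption checks for one linear outcome fit."""

    outcome: str
    normality_stat: float
    normality_p: float
    bp_stat: float                  # Breusch-Pagan LM on weighted residuals
    bp_p: float
    reset_p: float                  # RESET linearity check
    vif: dict = field(default_factory=dict)
    collinear_flags: list = field(default_factory=list)


def linear_diagnostics(fit: OutcomeFit, X, y, w) -> DiagnosticsReport:
    """Normality, heteroscedasticity, linearity and collinearity checks."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    w = np.asarray(w, dtype=float)
    rw = np.sqrt(w)
    D = sm.add_constant(X, has_constant="add")
    resid_w = rw * (y - D @ np.concatenate([[fit.intercept], fit.coef]))
    k2, norm_p = stats.normaltest(resid_w)
    try:
        bp_stat, bp_p, _, _ = het_breuschpagan(resid_w, D)
    except Exception:
        bp_stat, bp_p = float("nan"), float("nan")
    try:
        ols = sm.OLS(rw * y, rw[:, None] * D).fit()
        reset = linear_reset(ols, power=2, use_f=True)
        reset_p = float(reset.pvalue)
    except Exception:
        reset_p = float("nan")
    vif = {}
    flags = []
    for j, nm in enumerate(fit.exposure_names):
        others = np.delete(X, j, axis=1)
        Dj = sm.add_constant(others, has_constant="add")
        beta, *_ = np.linalg.lstsq(Dj, X[:, j], rcond=None)
        e = X[:, j] - Dj @ beta
        tss = np.sum((X[:, j] - X[:, j].mean()) ** 2)
        rss = np.sum(e ** 2)
        if tss <= 0 or rss / tss < 1e-12:
            vif[nm] = float("inf")
            flags.append(nm)
        else:
            vif[nm] = float(tss / rss)
    return DiagnosticsReport(
        outcome=fit.outcome,
        normality_stat=float(k2), normality_p=float(norm_p),
        bp_stat=float(bp_stat), bp_p=float(bp_p),
        reset_p=reset_p, vif=vif, collinear_flags=flags,
    )


# ---------------------------------------------------------------------------
# Delta-method effects of the composite indexes

#: index name -> (numerator measurements, denominator measurements, scale);
#: the index value is scale * sum(numerator) / sum(denominator).  "hnl" is
#: the linear head + nose length (no denominator).
INDEX_DEFINITIONS = {
    "cephalic_index": (("hw",), ("hl", "nl"), 100.0),
    "craniofacial_ratio": (("nl",), ("hl",), 1.0),
    "thoracic_index": (("tw",), ("th",), 100.0),
    "height_thorax_index": (("th",), ("wh",), 100.0),
    "volume_index": (("weight",), ("wh",), 100.0),
    "body_size": (("wh",), ("bl",), 100.0),
    "hnl": (("hl", "nl"), (), 1.0),
}


class MissingCoefficientError(KeyError):
    """The outcome fit lacks a coefficient required by the index."""


@dataclass
class IndexEffect:
    """Delta-method effect of a composite index on an outcome."""

    index_name: str
    outcome: str
    variant: str                  # "vary_numerator" | "vary_denominator" | "linear"
    effect: float
    delta_se: float
    p_value: float
    eval_point: dict


def _coef_lookup(fit: OutcomeFit, name: str) -> int:
    try:
        return fit.exposure_names.index(name)
    except ValueError:
        raise MissingCoefficientError(
            f"outcome model for {fit.outcome!r} has no coefficient "
            f"for measurement {name!r}"
        ) from None


def _one_variant(fit: OutcomeFit, num, den, scale, point, variant):
    g = np.zeros(len(fit.exposure_names))
    N = sum(point[m] for m in num)
    D = sum(point[m] for m in den) if den else None
    if variant == "linear":
        # move the components proportionally: dx_m = (x_m / L) dL
        for m in num:
            g[_coef_lookup(fit, m)] = point[m] / N
    elif variant == "vary_numerator":
        # I = s N / D with D fixed  =>  dx_m = (D / s)(x_m / N) dI
        for m in num:
            g[_coef_lookup(fit, m)] = (D / scale) * (point[m] / N)
    elif variant == "vary_denominator":
        # D = s N / I with N fixed  =>  dx_m = -(D x_m / (s N)) dI
        for m in den:
            g[_coef_lookup(fit, m)] = -(D * point[m]) / (scale * N)
    else:
        raise ValueError(f"unknown variant {variant!r}")
    effect = float(g @ fit.coef)
    var = float(g @ fit.cov_robust @ g)
    se = float(np.sqrt(max(var, 0.0)))
    p = 2.0 * stats.norm.sf(abs(effect) / se) if se > 0 else \
        (0.0 if effect != 0 else 1.0)
    return effect, se, p


def delta_index_effect(fit: OutcomeFit, index_name: str, point: dict,
                       variant: str = "both") -> list[IndexEffect]:
    """Model-implied effect(s) of a composite index at an evaluation point.

    ``point`` maps measurement names (and ``weight`` where needed) to the
    values — cohort medians by default in the pipeline — at which the
    reparameterization derivative is taken.  ``variant`` is
    ``"vary_numerator"`` (denominator held fixed), ``"vary_denominator"``
    (numerator held fixed), or ``"both"``, which returns every variant
    whose coefficients exist in the fit.  A variant that needs a
    coefficient outside the model (e.g. body weight in the volume index)
    raises when requested explicitly and is silently omitted by "both".
    """
    try:
        num, den, scale = INDEX_DEFINITIONS[index_name]
    except KeyError:
        raise KeyError(f"unknown index {index_name!r}") from None
    for m in (*num, *den):
        if m not in point:
            raise ValueError(f"evaluation point is missing {m!r}")
    if not den:
        variants = ["linear"]
    elif variant == "both":
        variants = ["vary_numerator", "vary_denominator"]
    else:
        variants = [variant]
    out = []
    for v in variants:
        try:
            eff, se, p = _one_variant(fit, num, den, scale, point, v)
        except MissingCoefficientError:
            if variant == "both":
                continue
            raise
        out.append(IndexEffect(
            index_name=index_name, outcome=fit.outcome, variant=v,
            effect=eff, delta_se=se, p_value=p,
            eval_point={m: point[m] for m in (*num, *den)},
        ))
    return out
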