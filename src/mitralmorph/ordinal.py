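"""Weighted proportional-odds (cumulative logit) regression.

Maximizes the weighted cumulative-logit likelihood

    sum_i w_i * log[ sigma(alpha_{y_i} - x_i'beta) - sigma(alpha_{y_i - 1} - x_i'beta) ]

over the exposure coefficients beta and strictly increasing cutpoints
alpha_1 < ... < alpha_{K-1} (parameterized internally as the first
cutpoint plus log-increments).  Standard errors come from the weighted
sandwich: bread = inverse Hessian of the weighted log-likelihood, meat =
outer product of the weighted per-subject scores, so the weights are
treated as fixed known quantities (appropriate for IPW with an
externally estimated propensity model).

For two categories the model reduces exactly to weighted binary
logistic regression (slope beta, intercept -alpha_1).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy.optimize import minimize
from scipy.special import expit

__all__ = ["OrdinalFit", "ConvergenceError", "fit_proportional_odds"]


class ConvergenceError(RuntimeError):
    """The likelihood optimizer did not converge."""


@dataclass
class OrdinalFit:
    """Converged weighted proportional-odds fit."""

    beta: np.ndarray              # (p,) exposure coefficients
    cutpoints: np.ndarray         # (K-1,) increasing thresholds
    cov_robust: np.ndarray        # ((p + K - 1)^2) sandwich, order [beta, alpha]
    cov_model: np.ndarray         # inverse-Hessian covariance, same order
    loglik: float
    n_iter: int
    converged: bool
    separation_flag: bool
    categories: np.ndarray        # original category labels, ascending
    n_obs: int

    @property
    def se_robust(self) -> np.ndarray:
        return np.sqrt(np.diag(self.cov_robust))


def _unpack(theta: np.ndarray, p: int, K: int):
    beta = theta[:p]
    if K == 2:
        alpha = theta[p:p + 1]
    else:
        raw = theta[p:]
        alpha = np.concatenate([[raw[0]], raw[0] + np.cumsum(np.exp(raw[1:]))])
    return beta, alpha


def _alpha_jacobian(theta: np.ndarray, p: int, K: int) -> np.ndarray:
    """d alpha_k / d raw_j, lower-triangular in the log-increment part."""
    m = K - 1
    J = np.zeros((m, m))
    J[:, 0] = 1.0
    raw = theta[p:]
    for j in range(1, m):
        J[j:, j] = np.exp(raw[j])
    return J


def _loglik_terms(theta, y, X, K):
    p = X.shape[1]
    beta, alpha = _unpack(theta, p, K)
    eta = X @ beta
    a_hi = np.where(y < K - 1, alpha[np.minimum(y, K - 2)] - eta, np.inf)
    a_lo = np.where(y > 0, alpha[np.maximum(y - 1, 0)] - eta, -np.inf)
    F_hi = expit(a_hi)
    F_lo = expit(a_lo)
    prob = np.clip(F_hi - F_lo, 1e-300, None)
    f_hi = np.where(np.isfinite(a_hi), F_hi * (1.0 - F_hi), 0.0)
    f_lo = np.where(np.isfinite(a_lo), F_lo * (1.0 - F_lo), 0.0)
    return beta, alpha, eta, prob, f_hi, f_lo


def _score_obs(theta, y, X, K):
    """Per-observation score in the raw parameterization, (n, p + K - 1)."""
    p = X.shape[1]
    beta, alpha, eta, prob, f_hi, f_lo = _loglik_terms(theta, y, X, K)
    dl_deta = (f_lo - f_hi) / prob
    S_beta = dl_deta[:, None] * X
    m = K - 1
    S_alpha = np.zeros((len(y), m))
    hi_idx = np.minimum(y, K - 2)
    rows = np.arange(len(y))
    mask_hi = y < K - 1
    S_alpha[rows[mask_hi], hi_idx[mask_hi]] += (f_hi / prob)[mask_hi]
    lo_idx = np.maximum(y - 1, 0)
    mask_lo = y > 0
    S_alpha[rows[mask_lo], lo_idx[mask_lo]] -= (f_lo / prob)[mask_lo]
    if K > 2:
        S_alpha = S_alpha @ _alpha_jacobian(theta, p, K)
    return np.column_stack([S_beta, S_alpha]), np.log(prob)


def fit_proportional_odds(y, X, weights: Optional[np.ndarray] = None,
                          maxiter: int = 500, gtol: float = 1e-7,
                          ) -> OrdinalFit:
    """Fit the weighted proportional-odds model.

    ``y`` is an ordinal outcome (any ascending integer labels; observed
    categories are compressed to 0..K-1, which merges unobserved
    intermediate levels with their lower neighbour).  ``X`` holds the
    exposures (no intercept column: the cutpoints absorb the level).
    """
    y = np.asarray(y)
    X = np.asarray(X, dtype=float)
    n, p = X.shape
    cats = np.unique(y)
    if len(cats) < 2:
        raise ValueError("need at least two observed outcome categories")
    yc = np.searchsorted(cats, y)
    K = len(cats)
    w = np.ones(n) if weights is None else np.asarray(weights, dtype=float)
    if np.any(w < 0) or not np.all(np.isfinite(w)):
        raise ValueError("weights must be finite and non-negative")

    # start: beta = 0, cutpoints from weighted cumulative frequencies
    cum = np.cumsum(np.bincount(yc, weights=w, minlength=K))[:-1] / w.sum()
    cum = np.clip(cum, 1e-4, 1 - 1e-4)
    alpha0 = np.log(cum / (1 - cum))
    alpha0 = np.maximum.accumulate(alpha0)
    alpha0 += 1e-6 * np.arange(K - 1)        # strictly increasing start
    if K == 2:
        raw0 = alpha0
    else:
        incr = np.maximum(np.diff(alpha0), 1e-4)
        raw0 = np.concatenate([[alpha0[0]], np.log(incr)])
    theta0 = np.concatenate([np.zeros(p), raw0])

    # standardize exposures internally for optimizer conditioning
    mu, sd = X.mean(axis=0), X.std(axis=0)
    sd = np.where(sd > 0, sd, 1.0)
    Z = (X - mu) / sd

    def negll(theta):
        _, ll = _score_obs(theta, yc, Z, K)
        return -np.sum(w * ll)

    def grad(theta):
        S, _ = _score_obs(theta, yc, Z, K)
        return -(S.T @ w)

    res = minimize(negll, theta0, jac=grad, method="BFGS",
                   options={"maxiter": maxiter, "gtol": gtol})
    if not res.success and np.linalg.norm(res.jac) > 1e-3 * (1 + abs(res.fun)):
        raise ConvergenceError(
            f"proportional-odds optimizer failed after {res.nit} iterations: "
            f"{res.message} (|grad| = {np.linalg.norm(res.jac):.3g})"
        )
    theta = res.x
    beta_z, alpha_z = _unpack(theta, p, K)
    separation = bool(np.max(np.abs(Z @ beta_z)) > 30.0)

    # sandwich in the raw parameterization, then map to (beta, alpha)
    S, _ = _score_obs(theta, yc, Z, K)
    meat = (S * w[:, None]).T @ (S * w[:, None])
    H = _numeric_hessian(lambda t: -(_score_obs(t, yc, Z, K)[0].T @ w), theta)
    H = 0.5 * (H + H.T)
    try:
        bread = np.linalg.inv(H)
    except np.linalg.LinAlgError:
        raise ConvergenceError("singular Hessian at the optimum") from None
    cov_raw = bread @ meat @ bread
    cov_model_raw = bread

    # raw -> (beta, alpha) jacobian, then undo the exposure standardization:
    # beta = beta_z / sd, alpha = alpha_z + mu' beta
    m = K - 1
    G1 = np.eye(p + m)
    if K > 2:
        G1[p:, p:] = _alpha_jacobian(theta, p, K)
    G2 = np.zeros((p + m, p + m))
    G2[:p, :p] = np.diag(1.0 / sd)
    G2[p:, :p] = np.tile((mu / sd), (m, 1))
    G2[p:, p:] = np.eye(m)
    G = G2 @ G1
    cov = G @ cov_raw @ G.T
    cov_model = G @ cov_model_raw @ G.T
    beta = beta_z / sd
    alpha = alpha_z + (mu / sd) @ beta_z

    return OrdinalFit(
        beta=beta,
        cutpoints=alpha,
        cov_robust=cov,
        cov_model=cov_model,
        loglik=float(-res.fun),
        n_iter=int(res.nit),
        converged=bool(res.success or np.linalg.norm(res.jac) <= 1e-3),
        separation_flag=separation,
        categories=cats,
        n_obs=n,
    )


def _numeric_hessian(grad_fn, theta: np.ndarray, h: float = 1e-5) -> np.ndarray:
    """Central-difference Jacobian of an analytic gradient."""
    k = len(theta)
    H = np.zeros((k, k))
    for j in range(k):
        hj = h * (1.0 + abs(theta[j]))
        tp = theta.copy(); tp[j] += hj
        tm = theta.copy(); tm[j] -= hj
        H[:, j] = (grad_fn(tp) - grad_fn(tm)) / (2 * hj)
    return H
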