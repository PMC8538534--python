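"""Synthetic CKCS cohort generator with known causal ground truth.

Emulates the data-generating structure the weighting analysis assumes:

* baseline covariates (age, sex, body weight, coat) drawn from
  distributions matched to reference cohort medians and
  interquartile ranges (age median 4.16 y, weight median 9.15 kg,
  ~75 % female, ~68 % Blenheim);
* the 13 morphometric exposures as a linear function of (centred)
  covariates plus correlated Gaussian anatomical noise, located and
  scaled so the sample medians fall inside the reference IQRs;
* six continuous echocardiographic outcomes (the weight-indexed valve
  and annulus measures and the sphericity index) driven by exposures
  and directly by covariates (confounding), plus Gaussian noise;
* three ordinal outcomes (MVP grade, regurgitant jet grade, murmur
  grade) from latent logistic variables cut at configured thresholds.

Because the exposures and the outcomes share covariate inputs, naive
exposure-outcome regressions are confounded; the generator returns the
exact parameters and per-subject exposure densities (``GroundTruth``) so
weight construction, balance improvement, and bias removal can all be
verified against a known truth.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy import stats
from scipy.optimize import brentq

from .cohort import (
    COATS,
    EXPOSURES,
    WESSELOWSKI_EXPONENTS,
    DogRecord,
    MorphometricProfile,
)

__all__ = [
    "GeneratorConfig",
    "GroundTruth",
    "default_config",
    "generate_cohort",
    "CONTINUOUS_OUTCOMES",
    "ORDINAL_OUTCOMES",
]

CONTINUOUS_OUTCOMES = ["amvl_i", "amvw_i", "amva_i", "mvad_i", "mvas_i", "si"]
ORDINAL_OUTCOMES = ["mvp", "jet", "murmur"]

#: Published cohort medians for the 13 exposures (cm; HA degrees).
EXPOSURE_MEDIANS = np.array([
    29.20, 33.75, 12.25, 14.95, 11.95, 20.15,
    47.00, 47.50, 45.50, 7.70, 3.20, 7.75, 115.00,
])

#: Spread per exposure derived from the reference IQR width / 1.349
#: (normal-equivalent standard deviation).
EXPOSURE_SDS = np.array([
    (31.58 - 27.78), (35.85 - 29.70), (13.53 - 11.45), (16.13 - 13.58),
    (13.00 - 11.28), (22.10 - 18.68), (49.63 - 45.00), (50.63 - 46.00),
    (49.50 - 43.58), (8.13 - 7.20), (3.50 - 2.80), (8.10 - 7.50),
    (120.00 - 110.00),
]) / 1.349

#: Baseline (median) level per outcome on its analysis scale.
OUTCOME_BASELINES = {
    "amvl_i": 0.70, "amvw_i": 0.14, "amva_i": 0.08,
    "mvad_i": 0.78, "mvas_i": 0.61, "si": 1.37,
}

#: Normal-equivalent SD of each continuous outcome from the reference IQRs.
OUTCOME_SDS = {
    "amvl_i": (0.79 - 0.63) / 1.349,
    "amvw_i": (0.16 - 0.12) / 1.349,
    "amva_i": (0.11 - 0.06) / 1.349,
    "mvad_i": (0.88 - 0.74) / 1.349,
    "mvas_i": (0.66 - 0.55) / 1.349,
    "si": (1.50 - 1.24) / 1.349,
}

_COVARIATES = ["age_z", "weight_z", "sex_F", "blenheim"]


class ConfigurationError(ValueError):
    """The generator configuration is internally inconsistent."""


def _cumlogit_cutpoints(cum_probs) -> np.ndarray:
    p = np.asarray(cum_probs, dtype=float)
    return np.log(p / (1.0 - p))


@dataclass
class GeneratorConfig:
    """Full parameterization of the synthetic cohort.

    Exposures are generated as ``x = mu + A c + eps`` where ``c`` is the
    centred covariate vector (age_z, weight_z, sex_F - p_F,
    blenheim - p_B) and ``eps ~ N(0, Sigma_x)``.  Continuous outcomes are
    ``y = b0 + B (x - mu) + Gamma c + e``; ordinal outcomes cut a latent
    ``B (x - mu) + Gamma c + logistic`` at the configured thresholds.
    """

    n: int
    seed: int
    # covariate distributions
    age_shape: float = 0.0          # gamma shape (filled by default_config)
    age_scale: float = 0.0          # gamma scale
    p_female: float = 0.75
    weight_mean: float = 9.15
    weight_sd: float = 1.80
    weight_min: float = 4.0
    p_blenheim: float = 0.68
    coat_probs: tuple = (0.68, 0.075, 0.04, 0.205)   # blenheim, b&t, ruby, tri
    p_neutered: float = 0.135
    bcs_values: tuple = (3, 4, 5, 6)
    bcs_probs: tuple = (6 / 52, 10 / 52, 26 / 52, 10 / 52)
    # exposures
    exposure_means: np.ndarray = field(default_factory=lambda: EXPOSURE_MEDIANS.copy())
    confounding: np.ndarray = None          # (13, 4) coefficients on centred covariates
    exposure_noise_cov: np.ndarray = None   # (13, 13) positive definite
    # outcomes
    outcome_effects: dict = None            # outcome -> (13,) raw-unit coefficients
    covariate_effects: dict = None          # outcome -> (4,) direct effects
    outcome_noise_sd: dict = None           # continuous outcomes
    ordinal_cutpoints: dict = None          # ordinal outcome -> increasing array

    def validate(self) -> None:
        if self.n < 2:
            raise ConfigurationError("n must be at least 2")
        S = np.asarray(self.exposure_noise_cov, dtype=float)
        if S.shape != (13, 13) or not np.allclose(S, S.T):
            raise ConfigurationError("exposure_noise_cov must be symmetric 13x13")
        try:
            np.linalg.cholesky(S)
        except np.linalg.LinAlgError:
            raise ConfigurationError(
                "exposure_noise_cov is not positive definite"
            ) from None
        if np.asarray(self.confounding).shape != (13, 4):
            raise ConfigurationError("confounding matrix must be 13x4")
        for name, cuts in self.ordinal_cutpoints.items():
            c = np.asarray(cuts, dtype=float)
            if np.any(np.diff(c) <= 0):
                raise ConfigurationError(f"cutpoints for {name} must increase")

    # --- exact covariate moments (used for centring and for the true
    #     marginal exposure density) -------------------------------------

    def age_moments(self) -> tuple[float, float]:
        m = self.age_shape * self.age_scale
        s = np.sqrt(self.age_shape) * self.age_scale
        return m, s

    def weight_moments(self) -> tuple[float, float]:
        a = (self.weight_min - self.weight_mean) / self.weight_sd
        m, v = stats.truncnorm.stats(a, np.inf, loc=self.weight_mean,
                                     scale=self.weight_sd, moments="mv")
        return float(m), float(np.sqrt(v))

    def covariate_cov(self) -> np.ndarray:
        pf, pb = self.p_female, self.p_blenheim
        return np.diag([1.0, 1.0, pf * (1 - pf), pb * (1 - pb)])


def default_config(n: int, seed: int) -> GeneratorConfig:
    """Study-condition defaults.

    The age gamma distribution is solved so its median and IQR shape match
    the reference 4.16 (2.91-6.00) years; exposure locations/scales come
    from the reference medians and IQRs; confounding loads body weight on
    every measurement and age specifically on head length, with direct
    covariate effects on the outcomes sized to produce material
    confounding bias at cohort scale.
    """
    # gamma shape k solving IQR-width / median = (6.00 - 2.91) / 4.16
    target = (6.00 - 2.91) / 4.16

    def f(k):
        q = stats.gamma.ppf([0.25, 0.5, 0.75], k)
        return (q[2] - q[0]) / q[1] - target

    k = brentq(f, 0.8, 60.0)
    scale = 4.16 / stats.gamma.ppf(0.5, k)

    # Confounding loadings (fraction of each exposure SD per covariate SD).
    # Sized so the induced bias on the designated head-length coefficient is
    # several robust SEs at cohort scale while the stabilized density-ratio
    # weights stay well behaved (effective sample size ~ half of n).
    sds = EXPOSURE_SDS
    A = np.zeros((13, 4))
    A[:, 1] = 0.15 * sds                       # heavier dogs are larger overall
    A[:, 2] = -0.10 * sds                      # females slightly smaller
    A[EXPOSURES.index("hl"), 0] = 0.30 * sds[EXPOSURES.index("hl")]   # age -> HL
    A[EXPOSURES.index("hw"), 3] = -0.15 * sds[EXPOSURES.index("hw")]  # Blenheim narrower head

    cfg = GeneratorConfig(n=n, seed=seed, age_shape=k, age_scale=scale)
    cov_c = cfg.covariate_cov()
    # residual variance so the total exposure SD matches the reference scale
    noise_var = np.maximum(sds ** 2 - np.einsum("ij,jk,ik->i", A, cov_c, A),
                           0.2 * sds ** 2)
    noise_sd = np.sqrt(noise_var)
    rho = 0.30                                 # exchangeable anatomical correlation
    corr = np.full((13, 13), rho)
    np.fill_diagonal(corr, 1.0)
    Sigma = corr * np.outer(noise_sd, noise_sd)

    def _B(**std_effects) -> np.ndarray:
        """Raw-unit effect vector from per-SD standardized effects."""
        b = np.zeros(13)
        for name, eff in std_effects.items():
            b[EXPOSURES.index(name)] = eff / sds[EXPOSURES.index(name)]
        return b

    ysd = OUTCOME_SDS
    effects = {
        # continuous outcomes: per-SD effects scaled by the outcome SD
        "amvl_i": _B(hl=0.40 * ysd["amvl_i"]),
        "amvw_i": _B(tw=0.35 * ysd["amvw_i"], tl=-0.30 * ysd["amvw_i"]),
        "amva_i": _B(),
        "mvad_i": _B(tw=0.35 * ysd["mvad_i"], th=-0.30 * ysd["mvad_i"],
                     nl=-0.35 * ysd["mvad_i"]),
        "mvas_i": _B(ha=0.35 * ysd["mvas_i"], th=-0.30 * ysd["mvas_i"]),
        "si": _B(hl=0.35 * ysd["si"], tc1=0.30 * ysd["si"]),
        # ordinal latent scale (logistic noise, SD ~ 1.81)
        "mvp": _B(),
        "jet": _B(hl=-1.00),
        "murmur": _B(bl=-0.50, nl=-0.60),
    }
    gamma = {}
    for o in CONTINUOUS_OUTCOMES:
        g = np.zeros(4)
        g[0] = 0.15 * ysd[o]                   # age
        g[1] = 0.30 * ysd[o]                   # weight
        gamma[o] = g
    gamma["amvl_i"][0] = 0.50 * OUTCOME_SDS["amvl_i"]   # strong age confounding
    for o in ORDINAL_OUTCOMES:
        gamma[o] = np.array([0.40, 0.40, 0.0, 0.0])
    gamma["jet"][0] = 0.80                      # age confounds the HL -> jet path

    cfg.exposure_means = EXPOSURE_MEDIANS.copy()
    cfg.confounding = A
    cfg.exposure_noise_cov = Sigma
    cfg.outcome_effects = effects
    cfg.covariate_effects = gamma
    cfg.outcome_noise_sd = {o: 0.8 * ysd[o] for o in CONTINUOUS_OUTCOMES}
    cfg.ordinal_cutpoints = {
        # cumulative category frequencies of the reference cohort
        "mvp": _cumlogit_cutpoints([1 / 52, 32 / 52, 51 / 52]),
        "jet": _cumlogit_cutpoints([6 / 52, 24 / 52, 31 / 52, 45 / 52]),
        "murmur": _cumlogit_cutpoints([26 / 52, 46 / 52]),
    }
    return cfg


@dataclass
class GroundTruth:
    """Exact generator parameters plus per-subject exposure densities.

    The conditional exposure density given covariates is multivariate
    normal with mean ``mu + A c_i`` and the noise covariance; the marginal
    density is taken as the Gaussian with the exact first two marginal
    moments (``mu + A E[c]``, ``A Cov(c) A' + Sigma_x``).  Their ratio is
    the oracle stabilized weight.
    """

    confounding: np.ndarray
    exposure_noise_cov: np.ndarray
    outcome_effects: dict
    covariate_effects: dict
    ordinal_cutpoints: dict
    covariates_centered: np.ndarray      # (n, 4)
    conditional_means: np.ndarray        # (n, 13)
    marginal_mean: np.ndarray            # (13,)
    marginal_cov: np.ndarray             # (13, 13)
    exposures: np.ndarray                # (n, 13)

    def log_conditional_density(self) -> np.ndarray:
        return _mvn_logpdf_rows(self.exposures, self.conditional_means,
                                self.exposure_noise_cov)

    def log_marginal_density(self) -> np.ndarray:
        return _mvn_logpdf_rows(self.exposures,
                                np.broadcast_to(self.marginal_mean,
                                                self.exposures.shape),
                                self.marginal_cov)

    def true_weights(self) -> np.ndarray:
        """Oracle stabilized weights: marginal / conditional density."""
        return np.exp(self.log_marginal_density()
                      - self.log_conditional_density())

    def to_json(self, path) -> None:
        payload = {
            "confounding": self.confounding.tolist(),
            "exposure_noise_cov": self.exposure_noise_cov.tolist(),
            "outcome_effects": {k: np.asarray(v).tolist()
                                for k, v in self.outcome_effects.items()},
            "covariate_effects": {k: np.asarray(v).tolist()
                                  for k, v in self.covariate_effects.items()},
            "ordinal_cutpoints": {k: np.asarray(v).tolist()
                                  for k, v in self.ordinal_cutpoints.items()},
            "marginal_mean": self.marginal_mean.tolist(),
            "marginal_cov": self.marginal_cov.tolist(),
            "exposure_names": EXPOSURES,
        }
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(payload, fh, indent=1)


def _mvn_logpdf_rows(x: np.ndarray, means: np.ndarray, cov: np.ndarray) -> np.ndarray:
    """Row-wise multivariate normal log-density with per-row means."""
    from scipy.linalg import solve_triangular

    L = np.linalg.cholesky(cov)
    d = x.shape[1]
    z = solve_triangular(L, (x - means).T, lower=True)
    logdet = 2.0 * np.sum(np.log(np.diag(L)))
    return -0.5 * (d * np.log(2 * np.pi) + logdet + np.sum(z ** 2, axis=0))


def generate_cohort(config: GeneratorConfig) -> tuple[list[DogRecord], GroundTruth]:
    """Draw a cohort and its ground truth.  Fixed seed => identical output."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    n = config.n

    age = rng.gamma(config.age_shape, config.age_scale, size=n)
    age = np.maximum(age, 0.1)
    a_lo = (config.weight_min - config.weight_mean) / config.weight_sd
    weight = stats.truncnorm.rvs(a_lo, np.inf, loc=config.weight_mean,
                                 scale=config.weight_sd, size=n,
                                 random_state=rng)
    sex_F = rng.random(n) < config.p_female
    coat_idx = rng.choice(4, size=n, p=np.asarray(config.coat_probs)
                          / np.sum(config.coat_probs))
    coat = np.array(COATS)[coat_idx]
    blen = coat == "blenheim"
    neutered = rng.random(n) < config.p_neutered
    bcs = rng.choice(config.bcs_values, size=n,
                     p=np.asarray(config.bcs_probs) / np.sum(config.bcs_probs))

    am, asd = config.age_moments()
    wm, wsd = config.weight_moments()
    C = np.column_stack([
        (age - am) / asd,
        (weight - wm) / wsd,
        sex_F.astype(float) - config.p_female,
        blen.astype(float) - config.p_blenheim,
    ])

    A = np.asarray(config.confounding, dtype=float)
    Sigma = np.asarray(config.exposure_noise_cov, dtype=float)
    L = np.linalg.cholesky(Sigma)
    eps = rng.standard_normal((n, 13)) @ L.T
    cond_mean = config.exposure_means + C @ A.T
    X = cond_mean + eps
    Xc = X - config.exposure_means

    # continuous outcomes on the indexed scale
    ycont = {}
    for o in CONTINUOUS_OUTCOMES:
        b = np.asarray(config.outcome_effects[o], dtype=float)
        g = np.asarray(config.covariate_effects[o], dtype=float)
        y = (OUTCOME_BASELINES[o] + Xc @ b + C @ g
             + rng.normal(0.0, config.outcome_noise_sd[o], size=n))
        ycont[o] = np.maximum(y, 0.005)        # physical measures stay positive

    # ordinal outcomes from a latent logistic variable
    yord = {}
    for o in ORDINAL_OUTCOMES:
        b = np.asarray(config.outcome_effects[o], dtype=float)
        g = np.asarray(config.covariate_effects[o], dtype=float)
        latent = Xc @ b + C @ g + rng.logistic(0.0, 1.0, size=n)
        yord[o] = np.searchsorted(np.asarray(config.ordinal_cutpoints[o]),
                                  latent)

    # regurgitant-jet raw fields consistent with the generated grade
    arj = np.zeros(n)
    all_sys = np.zeros(n, dtype=bool)
    jet = yord["jet"]
    u = rng.random(n)
    arj[jet == 1] = 1.0 + 8.5 * u[jet == 1]
    arj[jet == 2] = 1.0 + 8.5 * u[jet == 2]
    all_sys[jet == 2] = True
    arj[jet == 3] = 10.0 + 19.5 * u[jet == 3]
    all_sys[jet == 3] = True
    arj[jet == 4] = 30.0 + 39.0 * u[jet == 4]
    all_sys[jet == 4] = True

    la_ao = rng.uniform(1.15, 1.55, size=n)
    lviddn = rng.uniform(1.30, 1.68, size=n)

    records = []
    for i in range(n):
        prof = MorphometricProfile(*[float(X[i, j]) for j in range(13)])
        rec = DogRecord(
            dog_id=f"dog{i + 1:04d}",
            age=float(age[i]),
            sex="F" if sex_F[i] else "M",
            neutered=bool(neutered[i]),
            weight=float(weight[i]),
            coat=str(coat[i]),
            bcs=int(bcs[i]),
            murmur_grade=int(yord["murmur"][i]),
            la_ao=float(la_ao[i]),
            lviddn=float(lviddn[i]),
            mvp_grade=int(yord["mvp"][i]),
            arj_laa_pct=float(arj[i]),
            jet_all_systoles=bool(all_sys[i]),
            amvl=float(ycont["amvl_i"][i] * weight[i] ** WESSELOWSKI_EXPONENTS["amvl"]),
            amvw=float(ycont["amvw_i"][i] * weight[i] ** WESSELOWSKI_EXPONENTS["amvw"]),
            amva=float(ycont["amva_i"][i] * weight[i] ** WESSELOWSKI_EXPONENTS["amva"]),
            mvad=float(ycont["mvad_i"][i] * weight[i] ** WESSELOWSKI_EXPONENTS["mvad"]),
            mvas=float(ycont["mvas_i"][i] * weight[i] ** WESSELOWSKI_EXPONENTS["mvas"]),
            si=float(ycont["si"][i]),
            morpho=prof,
        )
        rec.validate()
        records.append(rec)

    cov_c = config.covariate_cov()
    truth = GroundTruth(
        confounding=A,
        exposure_noise_cov=Sigma,
        outcome_effects={k: np.asarray(v, dtype=float)
                         for k, v in config.outcome_effects.items()},
        covariate_effects={k: np.asarray(v, dtype=float)
                           for k, v in config.covariate_effects.items()},
        ordinal_cutpoints={k: np.asarray(v, dtype=float)
                           for k, v in config.ordinal_cutpoints.items()},
        covariates_centered=C,
        conditional_means=cond_mean,
        marginal_mean=np.asarray(config.exposure_means, dtype=float),
        marginal_cov=A @ cov_c @ A.T + Sigma,
        exposures=X,
    )
    return records, truth
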