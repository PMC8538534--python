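"""End-to-end analysis pipeline: weight -> fit -> report.

``run_full_analysis`` reproduces the whole weighting workflow on a
cohort: complete-case subsetting, additive and (screened) interaction
propensity models, balance-based model selection, stabilized weights,
positivity reporting, the nine weighted outcome models with diagnostics,
delta-method index effects, and a compact significance matrix (rows =
outcomes, columns = exposures, cells = stars plus the sign of the
association, 'p' positive / 'n' negative).
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from . import __version__
from .cohort import EXPOSURES, DogRecord, cohort_frame
from .outcomes import (
    INDEX_DEFINITIONS,
    DiagnosticsReport,
    IndexEffect,
    OutcomeFit,
    delta_index_effect,
    fit_weighted_linear,
    fit_weighted_ordinal,
    linear_diagnostics,
    surrogate_residuals,
)
from .weights import (
    DEFAULT_COVARIATES,
    BalanceReport,
    PositivityReport,
    WeightSet,
    balance_report,
    check_positivity,
    compute_sipw,
    fit_ps_model,
    screen_interactions,
    select_ps_model,
)

__all__ = ["RunConfig", "AnalysisResult", "run_full_analysis",
           "describe_cohort", "significance_cell"]

CONTINUOUS_OUTCOMES = ["amvl_i", "amvw_i", "amva_i", "mvad_i", "mvas_i", "si"]
ORDINAL_OUTCOMES = ["mvp", "jet", "murmur"]


@dataclass
class RunConfig:
    """Settings for a full analysis run (JSON/YAML serializable)."""

    seed: int = 0
    n: int = 50                              # generator size (simulate)
    input: Optional[str] = None              # cohort CSV (analyze/describe)
    exposures: list = field(default_factory=lambda: list(EXPOSURES))
    covariates: list = field(default_factory=lambda: list(DEFAULT_COVARIATES))
    ps_variant: str = "auto"                 # additive | interaction | auto
    alpha: float = 0.05
    screening_alpha: float = 0.05
    truncation: Optional[tuple] = None       # e.g. (1, 99)
    run_positivity: bool = True
    positivity_dim: int = 5
    surrogate_replicates: int = 1
    outdir: Optional[str] = None

    def __post_init__(self):
        if set(self.exposures) & set(self.covariates):
            raise ValueError("exposure and covariate lists must be disjoint")

    @classmethod
    def from_file(cls, path) -> "RunConfig":
        text = Path(path).read_text(encoding="utf-8")
        if str(path).endswith((".yaml", ".yml")):
            import yaml
            data = yaml.safe_load(text)
        else:
            data = json.loads(text)
        if data.get("truncation") is not None:
            data["truncation"] = tuple(data["truncation"])
        return cls(**data)

    def config_hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]


@dataclass
class AnalysisResult:
    """Everything the pipeline produced for one cohort."""

    config: RunConfig
    n_input: int
    n_used: int
    excluded_ids: list
    selected_variant: str
    screened_interactions: list
    weights: WeightSet
    balance: dict                        # variant -> BalanceReport
    positivity: Optional[PositivityReport]
    fits: dict                           # outcome -> OutcomeFit
    diagnostics: dict                    # outcome -> report
    surrogate: dict                      # ordinal outcome -> summaries
    index_effects: list                  # IndexEffect
    significance: pd.DataFrame
    failures: dict = field(default_factory=dict)

    def to_json_dict(self) -> dict:
        fits = {}
        for name, f in self.fits.items():
            fits[name] = {
                "family": f.family,
                "coef": dict(zip(f.exposure_names, f.coef.tolist())),
                "robust_se": dict(zip(f.exposure_names, f.robust_se.tolist())),
                "p": dict(zip(f.exposure_names, f.p_values.tolist())),
                "cutpoints": None if f.cutpoints is None
                             else f.cutpoints.tolist(),
                "intercept": f.intercept,
                "n_used": f.n_used,
                "converged": f.converged,
            }
        return {
            "package_version": __version__,
            "config_hash": self.config.config_hash(),
            "seed": self.config.seed,
            "n_input": self.n_input,
            "n_used": self.n_used,
            "excluded_ids": list(self.excluded_ids),
            "selected_variant": self.selected_variant,
            "screened_interactions": [list(t) for t in
                                      self.screened_interactions],
            "balance_summary": {
                k: {"unweighted": v.summary_unweighted,
                    "weighted": v.summary_weighted}
                for k, v in self.balance.items()
            },
            "fits": fits,
            "surrogate": self.surrogate,
            "index_effects": [
                {"index": e.index_name, "outcome": e.outcome,
                 "variant": e.variant, "effect": e.effect,
                 "delta_se": e.delta_se, "p": e.p_value}
                for e in self.index_effects
            ],
            "failures": {k: str(v) for k, v in self.failures.items()},
        }


def significance_cell(coef: float, p: float, alpha: float = 0.05) -> str:
    """Table-cell code: stars by p-value plus the association sign."""
    if not np.isfinite(p) or p >= alpha:
        return ""
    if p < 0.001:
        stars = "***"
    elif p < 0.01:
        stars = "**"
    else:
        stars = "*"
    return f"{stars} {'p' if coef > 0 else 'n'}"


def _significance_frame(fits: dict, exposures: Sequence[str],
                        alpha: float) -> pd.DataFrame:
    order = ORDINAL_OUTCOMES + CONTINUOUS_OUTCOMES
    rows = {}
    for name in order:
        f = fits.get(name)
        if f is None:
            rows[name] = {e: "" for e in exposures}
            continue
        rows[name] = {
            e: significance_cell(c, p, alpha)
            for e, c, p in zip(f.exposure_names, f.coef, f.p_values)
        }
    return pd.DataFrame.from_dict(rows, orient="index")[list(exposures)]


def run_full_analysis(records: Sequence[DogRecord],
                      config: Optional[RunConfig] = None) -> AnalysisResult:
    """Run the complete weighting analysis on a validated cohort."""
    config = config or RunConfig()
    frame = cohort_frame(records)
    needed = (list(config.exposures) + list(config.covariates)
              + CONTINUOUS_OUTCOMES + ORDINAL_OUTCOMES)
    mask = np.isfinite(frame[needed].to_numpy(dtype=float)).all(axis=1)
    cc = frame.loc[mask].reset_index(drop=True)
    excluded = frame.loc[~mask, "dog_id"].tolist()

    additive = fit_ps_model(cc, "additive", exposures=config.exposures,
                            covariates=config.covariates)
    screened = []
    candidates = [additive]
    if config.ps_variant in ("interaction", "auto"):
        screened = screen_interactions(cc, alpha=config.screening_alpha,
                                       exposures=config.exposures,
                                       covariates=config.covariates)
        if screened:
            candidates.append(
                fit_ps_model(cc, "interaction", interaction_terms=screened,
                             exposures=config.exposures,
                             covariates=config.covariates))

    if config.ps_variant == "additive" or len(candidates) == 1:
        model = candidates[0] if config.ps_variant != "interaction" \
            else candidates[-1]
        reports = []
    elif config.ps_variant == "interaction":
        model = candidates[-1]
        reports = []
    else:
        model, reports = select_ps_model(cc, candidates,
                                         covariates=config.covariates)

    ws = compute_sipw(cc, model, truncation=config.truncation)
    balance = {}
    for cand in candidates:
        wsc = ws if cand is model else compute_sipw(cc, cand,
                                                    truncation=config.truncation)
        balance[cand.variant] = balance_report(cc, wsc,
                                               covariates=config.covariates)

    positivity = None
    if config.run_positivity:
        positivity = check_positivity(
            cc[config.exposures].to_numpy(dtype=float),
            max_hull_dim=config.positivity_dim,
            exposure_names=config.exposures,
        )

    X = cc[config.exposures].to_numpy(dtype=float)
    w = ws.sipw
    fits, diagnostics, surrogate, failures = {}, {}, {}, {}
    for name in CONTINUOUS_OUTCOMES:
        y = cc[name].to_numpy(dtype=float)
        try:
            f = fit_weighted_linear(y, X, w, outcome=name,
                                    exposure_names=config.exposures)
            fits[name] = f
            diagnostics[name] = linear_diagnostics(f, X, y, w)
        except Exception as e:            # keep going, record the failure
            failures[name] = e
    for k, name in enumerate(ORDINAL_OUTCOMES):
        y = cc[name].to_numpy(dtype=float).astype(int)
        try:
            f = fit_weighted_ordinal(y, X, w, outcome=name,
                                     exposure_names=config.exposures)
            fits[name] = f
            _, summ = surrogate_residuals(
                f, X, y, seed=config.seed + 7919 * (k + 1),
                replicates=config.surrogate_replicates)
            surrogate[name] = summ
        except Exception as e:
            failures[name] = e

    medians = {m: float(np.median(cc[m])) for m in config.exposures}
    medians["weight"] = float(np.median(cc["weight"]))
    index_effects = []
    for idx in ("cephalic_index", "craniofacial_ratio", "thoracic_index",
                "height_thorax_index", "volume_index", "body_size"):
        for f in fits.values():
            index_effects.extend(delta_index_effect(f, idx, medians, "both"))

    sig = _significance_frame(fits, config.exposures, config.alpha)
    return AnalysisResult(
        config=config,
        n_input=len(frame),
        n_used=len(cc),
        excluded_ids=excluded,
        selected_variant=model.variant,
        screened_interactions=screened,
        weights=ws,
        balance=balance,
        positivity=positivity,
        fits=fits,
        diagnostics=diagnostics,
        surrogate=surrogate,
        index_effects=index_effects,
        significance=sig,
        failures=failures,
    )


def describe_cohort(records: Sequence[DogRecord]) -> dict:
    """Median (IQR) summaries and category counts, cohort-table style.

    Quantiles use linear interpolation, so for values (1,2,3,4,5) the
    median is 3 with IQR (2, 4).
    """
    frame = cohort_frame(records)
    numeric = (["age", "weight", "la_ao", "lviddn", "si", "arj_laa_pct",
                "amvl_i", "amvw_i", "amva_i", "mvad_i", "mvas_i", "severity"]
               + EXPOSURES
               + [c for c in frame.columns if c.startswith("idx_")])
    rows = []
    for c in numeric:
        v = frame[c].to_numpy(dtype=float)
        v = v[np.isfinite(v)]
        if len(v) == 0:
            rows.append({"variable": c, "median": np.nan,
                         "q25": np.nan, "q75": np.nan, "n": 0})
            continue
        q25, med, q75 = np.percentile(v, [25, 50, 75])
        rows.append({"variable": c, "median": med, "q25": q25,
                     "q75": q75, "n": len(v)})
    counts = {}
    for c in ("sex_F", "blenheim", "murmur", "mvp", "jet", "bcs"):
        s = frame[c].dropna()
        counts[c] = {str(k): int(v) for k, v in
                     s.value_counts().sort_index().items()}
    return {"numeric": pd.DataFrame(rows), "counts": counts}
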