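"""Pooled parametric models for the g-formula (Step 1).

One model per time-varying covariate, fitted in a declared order on the
pooled person-period data, plus pooled logistic hazard models for the
outcome and the competing event with a cubic polynomial in follow-up year.

History summary
---------------
Each covariate model's predictors are: intercept, baseline covariates (age at
entry, sex), the lag-1 value of every time-varying covariate, the
*current-year* value of covariates earlier in the declared order, and time
terms ``k, k^2, k^3``. A log-scale covariate (triglycerides) contributes its
lag both raw and log-transformed, so that models linear on either scale are
nested; current-value predictors enter raw. Binary covariates use pooled logistic regression; continuous
covariates use linear regression (triglycerides on the log scale). Diabetes,
antihypertensive use and lipid-lowering use are absorbing: their transition
models are fitted only on person-years where the state was previously absent.

The hazard models' time-varying predictors are the current-year covariates
under the default ``concurrent`` exposure ordering, or the lag-1 covariates
under the ``lagged`` sensitivity ordering (which delays intervention effects
by one interval and attenuates estimates toward the null when effects are
immediate).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .cohort import (ABSORBING_COVS, BASELINE_COVS, BINARY_COVS,
                     LOG_SCALE_COVS, TIME_VARYING)


class ModelFitError(RuntimeError):
    """Raised when a component model cannot be fitted; names the model."""


def _default_families() -> dict:
    fam = {}
    for cov in TIME_VARYING:
        if cov in BINARY_COVS:
            fam[cov] = "pooled_logistic"
        elif cov in LOG_SCALE_COVS:
            fam[cov] = "linear_log_scale"
        else:
            fam[cov] = "linear"
    return fam


@dataclass
class ModelSpec:
    """Declarative description of the Step-1 model set."""

    covariate_order: list = field(default_factory=lambda: list(TIME_VARYING))
    families: dict = field(default_factory=_default_families)
    absorbing: set = field(default_factory=lambda: set(ABSORBING_COVS))
    exposure_ordering: str = "concurrent"  # or "lagged"
    time_degree: int = 3
    baseline_covariates: list = field(default_factory=lambda: list(BASELINE_COVS))

    def __post_init__(self):
        if sorted(self.covariate_order) != sorted(set(self.covariate_order)):
            raise ValueError("covariate_order contains duplicates")
        if self.exposure_ordering not in ("concurrent", "lagged"):
            raise ValueError("exposure_ordering must be concurrent or lagged")

    def _lag_terms(self) -> list[tuple]:
        terms = []
        for c in self.covariate_order:
            terms.append(("lag", c))
            if c in LOG_SCALE_COVS:
                terms.append(("laglog", c))
        return terms

    def covariate_terms(self, cov: str) -> list[tuple]:
        """Predictor terms for one covariate model."""
        i = self.covariate_order.index(cov)
        terms = [("const",)]
        terms += [("base", b) for b in self.baseline_covariates]
        terms += self._lag_terms()
        terms += [("cur", c) for c in self.covariate_order[:i]]
        terms += [("time", p) for p in range(1, self.time_degree + 1)]
        return terms

    def hazard_terms(self) -> list[tuple]:
        """Predictor terms for the outcome / competing hazard models."""
        terms = [("const",)]
        terms += [("base", b) for b in self.baseline_covariates]
        if self.exposure_ordering == "concurrent":
            terms += [("cur", c) for c in self.covariate_order]
        else:
            terms += self._lag_terms()
        terms += [("time", p) for p in range(1, self.time_degree + 1)]
        return terms


def term_name(term: tuple) -> str:
    kind = term[0]
    if kind == "const":
        return "const"
    if kind == "time":
        return f"k^{term[1]}"
    return f"{kind}_{term[1]}"


def _prepare_frame(pp: pd.DataFrame, spec: ModelSpec) -> pd.DataFrame:
    """Add lag-1 columns (lag at k=0 defined as the current/baseline value)."""
    df = pp.sort_values(["pid", "k"], kind="stable").reset_index(drop=True)
    if not spec.covariate_order:
        return df
    lagged = df.groupby("pid", sort=False)[spec.covariate_order].shift(1)
    for cov in spec.covariate_order:
        col = lagged[cov].to_numpy()
        cur = df[cov].to_numpy(dtype=float)
        df[f"lag_{cov}"] = np.where(np.isnan(col), cur, col)
    return df


def _column(df: pd.DataFrame, term: tuple, spec: ModelSpec) -> np.ndarray:
    kind = term[0]
    if kind == "const":
        return np.ones(len(df))
    if kind == "time":
        return df["k"].to_numpy(dtype=float) ** term[1]
    if kind == "base":
        return df[term[1]].to_numpy(dtype=float)
    name = term[1]
    if kind == "lag":
        return df[f"lag_{name}"].to_numpy(dtype=float)
    if kind == "laglog":
        return np.log(df[f"lag_{name}"].to_numpy(dtype=float))
    return df[name].to_numpy(dtype=float)  # "cur"


def _design(df: pd.DataFrame, terms: list[tuple], spec: ModelSpec) -> np.ndarray:
    return np.column_stack([_column(df, t, spec) for t in terms])


@dataclass
class FittedModel:
    """One fitted component model with everything needed to simulate from it."""

    name: str
    family: str
    terms: list
    params: np.ndarray
    cov_params: np.ndarray
    scale: float | None  # residual SD for linear families
    value_range: tuple | None  # observed (min, max) on the raw scale
    n_obs: int
    converged: bool

    def linpred(self, X: np.ndarray) -> np.ndarray:
        return X @ self.params

    def se(self) -> np.ndarray:
        return np.sqrt(np.diag(self.cov_params))


def _fit_logistic(name, y, X, terms) -> FittedModel:
    if len(np.unique(y)) < 2:
        raise ModelFitError(f"model {name!r}: response has a single level")
    try:
        res = sm.GLM(y, X, family=sm.families.Binomial()).fit(maxiter=100)
    except Exception as exc:  # separation, singular design
        raise ModelFitError(f"model {name!r} failed to fit: {exc}") from exc
    if not np.all(np.isfinite(res.params)):
        raise ModelFitError(f"model {name!r}: non-finite coefficients")
    return FittedModel(name, "pooled_logistic", terms, np.asarray(res.params),
                       np.asarray(res.cov_params()), None, None, len(y),
                       bool(getattr(res, "converged", True)))


def _fit_linear(name, family, y, X, terms, raw) -> FittedModel:
    if np.unique(y).size < 2:
        raise ModelFitError(f"model {name!r}: response is constant")
    res = sm.OLS(y, X).fit()
    scale = float(np.sqrt(res.scale))
    if not np.isfinite(scale) or scale <= 0:
        raise ModelFitError(f"model {name!r}: degenerate residual scale")
    return FittedModel(name, family, terms, np.asarray(res.params),
                       np.asarray(res.cov_params()), scale,
                       (float(np.min(raw)), float(np.max(raw))), len(y), True)


def fit_covariate_models(pp: pd.DataFrame, spec: ModelSpec) -> dict:
    """Fit the per-covariate transition models on person-years at risk.

    Uses transitions from year k-1 to k (k >= 1) among rows that remain
    event-free and uncensored, which is every person-period row by
    construction. Returns ``{covariate: FittedModel}``.
    """
    df = _prepare_frame(pp, spec)
    df = df[df["k"] >= 1]
    fitted = {}
    for cov in spec.covariate_order:
        vals = df[cov].to_numpy(dtype=float)
        if np.unique(vals).size < 2:
            raise ModelFitError(f"covariate {cov!r} is constant in the data")
        terms = spec.covariate_terms(cov)
        sub = df
        if cov in spec.absorbing:
            sub = df[df[f"lag_{cov}"] < 0.5]
            if len(sub) == 0 or np.unique(sub[cov]).size < 2:
                raise ModelFitError(
                    f"covariate {cov!r}: no observable onsets to model")
        X = _design(sub, terms, spec)
        if spec.families[cov] == "pooled_logistic":
            fitted[cov] = _fit_logistic(cov, sub[cov].to_numpy(dtype=float),
                                        X, terms)
            fitted[cov].value_range = (0.0, 1.0)
        else:
            raw = sub[cov].to_numpy(dtype=float)
            y = np.log(raw) if spec.families[cov] == "linear_log_scale" else raw
            fitted[cov] = _fit_linear(cov, spec.families[cov], y, X, terms, raw)
    return fitted


def _fit_hazard(pp, spec, response, name, rows=None) -> FittedModel:
    df = _prepare_frame(pp, spec)
    if rows is not None:
        df = df[rows(df)]
    y = df[response].to_numpy(dtype=float)
    if y.sum() < 1:
        raise ModelFitError(f"model {name!r}: zero events")
    X = _design(df, spec.hazard_terms(), spec)
    return _fit_logistic(name, y, X, spec.hazard_terms())


def fit_outcome_model(pp: pd.DataFrame, spec: ModelSpec) -> FittedModel:
    """Pooled logistic discrete-time hazard model for the outcome."""
    return _fit_hazard(pp, spec, "y", "outcome")


def fit_competing_model(pp: pd.DataFrame, spec: ModelSpec) -> FittedModel:
    """Pooled logistic hazard model for the competing event, fitted among
    person-years free of the outcome within the interval."""
    return _fit_hazard(pp, spec, "c", "competing",
                       rows=lambda d: d["y"].to_numpy() == 0)


@dataclass
class FittedModels:
    """The complete fitted model set plus the empirical baseline pool.

    ``baseline_pool`` holds the eligible cohort's year-0 person-period rows
    (baseline covariates included) from which the Monte Carlo engine resamples
    pseudo-individuals with replacement.
    """

    spec: ModelSpec
    covariates: dict
    outcome: FittedModel
    competing: FittedModel | None
    baseline_pool: pd.DataFrame
    horizon: int
    diagnostics: dict = field(default_factory=dict)


def fit_all(pp: pd.DataFrame, spec: ModelSpec | None = None,
            all_cause: bool = False, horizon: int = 29) -> FittedModels:
    """Fit every Step-1 model and bundle them for the simulation engine.

    With ``all_cause=True`` no competing model is fitted (deaths are the
    outcome).
    """
    spec = spec or ModelSpec()
    covs = fit_covariate_models(pp, spec)
    outcome = fit_outcome_model(pp, spec)
    competing = None if all_cause else fit_competing_model(pp, spec)
    pool_cols = (["pid"] + spec.baseline_covariates + spec.covariate_order
                 + (["tc"] if "tc" in pp.columns else []))
    pool = pp[pp["k"] == 0][pool_cols].reset_index(drop=True)
    diags = {
        "person_years": int(len(pp)),
        "participants": int(pp["pid"].nunique()),
        "events": int(pp["y"].sum()),
        "competing_events": int(pp["c"].sum()),
        "converged": {m.name: m.converged
                      for m in [*covs.values(), outcome]
                      + ([competing] if competing else [])},
    }
    return FittedModels(spec, covs, outcome, competing, pool, horizon, diags)


def coefficients_frame(fitted: FittedModels) -> pd.DataFrame:
    """Tidy export of every fitted coefficient for audit."""
    rows = []
    models = list(fitted.covariates.values()) + [fitted.outcome]
    if fitted.competing is not None:
        models.append(fitted.competing)
    for m in models:
        for t, b, s in zip(m.terms, m.params, m.se()):
            rows.append({"model": m.name, "family": m.family,
                         "term": term_name(t), "estimate": b, "se": s})
        if m.scale is not None:
            rows.append({"model": m.name, "family": m.family,
                         "term": "resid_sd", "estimate": m.scale, "se": np.nan})
    return pd.DataFrame(rows)
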