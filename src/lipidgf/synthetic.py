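"""Synthetic longitudinal cohort with a fully known data-generating process.

The generator emulates the shape of a community cohort followed for 29 years
with sparse in-person examination waves (defaults: years 0, 10, 15 and 20),
annual discrete-time hazards for a primary cardiovascular event and a
competing non-cardiovascular death, and baseline moments mirroring the study
population (mean age 46.6 (SD 7.7), 61% women, LDL-C 2.7 (0.8) mmol/L, ...).

Covariate dynamics are Markov order 1 on a one-year grid: continuous
covariates follow Gaussian AR(1) processes around linearly trending means
(triglycerides on the log scale); smoking is a near-absorbing two-state
chain; diabetes, antihypertensive use and lipid-lowering use are absorbing
with logistic onset probabilities driven by current glucose, SBP and LDL-C
respectively. LDL-C is tied to non-HDL-C through a Friedewald-type structural
equation ``LDL-C(k) = non-HDL-C(k) - TG(k)/2.2 - gap(k)`` where the remnant
gap follows an AR(1) in the *observed* lagged lipids (so the relation stays
well-defined under intervention on LDL-C), and ``TC = non-HDL-C + HDL-C``
exactly, keeping the lipid fractions internally consistent.

Both event hazards are logistic in (current age, sex, smoking, SBP, LDL-C,
diabetes). Within each one-year interval the primary-event hazard acts first
and the competing hazard applies to the outcome-free — the same ordering the
g-formula engine uses, so the oracle (:func:`true_counterfactual_risk`) and
the estimator target the identical estimand.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import expit

from . import cohort as ch
from . import regimes as rg
from .stratify import TenYearScorer, stratify_frame

# clip ranges keep covariates physiologic; chosen wide so the AR noise
# essentially never binds
_CLIPS = {
    "bmi": (15.0, 45.0),
    "sbp": (80.0, 230.0),
    "dbp": (45.0, 140.0),
    "hdl": (0.5, 3.0),
    "nonhdl": (0.8, 10.0),
    "glucose": (1.5, 25.0),
    "tg": (0.2, 10.0),
}


def _default_baseline() -> dict:
    return {
        "age0": (46.6, 7.7),
        "female": 0.61,
        "smoking": 0.24,
        "bmi": (23.9, 3.1),
        "sbp": (122.2, 18.8),
        "dbp": (79.5, 11.7),
        "hdl": (1.4, 0.3),
        "ldl": (2.7, 0.8),
        "log_tg": (math.log(1.2), 0.5),
        "glucose": (3.6, 1.7),
        "diabetes": 0.02,
        "antihtn": 0.05,
        "lipidrx": 0.014,
    }


def _default_drift() -> dict:
    # covariate -> (rho, annual trend in the mean, innovation SD)
    return {
        "bmi": (0.97, 0.06, 0.35),
        "sbp": (0.90, 0.55, 4.5),
        "dbp": (0.90, 0.10, 3.0),
        "log_tg": (0.90, 0.006, 0.12),
        "hdl": (0.92, -0.003, 0.07),
        "nonhdl": (0.20, 0.035, 0.80),
        "glucose": (0.90, 0.07, 0.35),
        # remnant gap non-HDL-C - LDL-C - TG/2.2, AR(1) around zero
        "ldl_gap": (0.60, 0.0, 0.25),
    }


def _default_transitions() -> dict:
    return {
        "smoking_quit": 0.05,
        "smoking_relapse": 0.01,
        # absorbing onsets: logit-linear in (current driver covariate, year)
        "diabetes": {"intercept": -8.0, "glucose": 0.55, "k": 0.02},
        "antihtn": {"intercept": -10.0, "sbp": 0.05, "k": 0.0},
        "lipidrx": {"intercept": -5.8, "ldl": 0.6, "k": 0.06},
        # persistent effect of being on lipid-lowering treatment (lagged
        # flag) on the next year's non-HDL-C trajectory, mmol/L
        "lipidrx_effect_nonhdl": -0.5,
    }


# intercepts calibrated once by forward simulation of the default process so
# that the 29-year primary-event and all-cause-death cumulative incidences sit
# near 0.25 and 0.29 (inside the targeted [0.15, 0.30] band)
def _default_hazard_y() -> dict:
    return {"intercept": -12.00, "age": 0.070, "male": 0.40,
            "smoking": 0.50, "sbp": 0.012, "ldl": 0.30, "diabetes": 0.50}


def _default_hazard_d() -> dict:
    return {"intercept": -13.35, "age": 0.090, "male": 0.50,
            "smoking": 0.40, "sbp": 0.004, "ldl": 0.0, "diabetes": 0.30}


@dataclass
class DGPParams:
    """Complete parameterisation of the synthetic data-generating process."""

    n_participants: int = 5735
    horizon_years: int = 29
    wave_years: tuple = (0, 10, 15, 20)
    seed: int = 0
    baseline_moments: dict = field(default_factory=_default_baseline)
    drift: dict = field(default_factory=_default_drift)
    transitions: dict = field(default_factory=_default_transitions)
    hazard_coefs_Y: dict = field(default_factory=_default_hazard_y)
    hazard_coefs_D: dict = field(default_factory=_default_hazard_d)

    def __post_init__(self):
        if self.n_participants <= 0:
            raise ValueError("n_participants must be positive")
        if self.horizon_years < 1:
            raise ValueError("horizon_years must be >= 1")
        if not set(self.wave_years) <= set(range(self.horizon_years)):
            raise ValueError("wave_years must lie inside the horizon")
        for name, mom in self.baseline_moments.items():
            if isinstance(mom, tuple):
                if mom[1] <= 0:
                    raise ValueError(f"baseline scale for {name} must be > 0")
            elif not 0.0 <= mom <= 1.0:
                raise ValueError(f"baseline prevalence for {name} outside [0, 1]")
        for name, (rho, _, sd) in self.drift.items():
            if sd <= 0:
                raise ValueError(f"drift SD for {name} must be > 0")


def cancer_control_params(**overrides) -> DGPParams:
    """Negative-control process: the primary event is cancer death, on whose
    hazard the lipid fractions have exactly zero effect; all other deaths and
    CVD compete. Intercepts calibrated for a ~9% 29-year cancer-death risk."""
    p = DGPParams(**overrides)
    p.hazard_coefs_Y = {"intercept": -11.05, "age": 0.080, "male": 0.30,
                        "smoking": 0.60, "sbp": 0.0, "ldl": 0.0, "diabetes": 0.0}
    p.hazard_coefs_D = {"intercept": -11.85, "age": 0.082, "male": 0.45,
                        "smoking": 0.45, "sbp": 0.008, "ldl": 0.15,
                        "diabetes": 0.40}
    return p


@dataclass
class TrueRiskOracle:
    """Ground-truth counterfactual risk curve under one regime.

    ``risk[t-1]`` is the true cumulative incidence of the primary event by
    year ``t``, obtained by forward-simulating the known process with the
    regime's assignments substituted; sampling error is O(1/sqrt(n)).
    """

    regime_label: str
    risk: np.ndarray
    competing: np.ndarray
    n: int


def _truncnorm(rng, mean, sd, lo, hi, size):
    x = rng.normal(mean, sd, size=size)
    # redraw outliers rather than clipping so moments stay near-nominal
    for _ in range(12):
        bad = (x < lo) | (x > hi)
        if not bad.any():
            break
        x[bad] = rng.normal(mean, sd, size=int(bad.sum()))
    return np.clip(x, lo, hi)


def _draw_baseline(params: DGPParams, n: int, rng: np.random.Generator) -> dict:
    bm = params.baseline_moments
    s = {}
    s["age0"] = _truncnorm(rng, *bm["age0"], 35.0, 90.0, n)
    s["female"] = (rng.uniform(size=n) < bm["female"]).astype(float)
    s["smoking"] = (rng.uniform(size=n) < bm["smoking"]).astype(float)
    s["bmi"] = _truncnorm(rng, *bm["bmi"], *_CLIPS["bmi"], size=n)
    s["sbp"] = _truncnorm(rng, *bm["sbp"], *_CLIPS["sbp"], size=n)
    s["dbp"] = _truncnorm(rng, *bm["dbp"], *_CLIPS["dbp"], size=n)
    s["hdl"] = _truncnorm(rng, *bm["hdl"], *_CLIPS["hdl"], size=n)
    s["ldl"] = _truncnorm(rng, *bm["ldl"], 0.5, 8.0, n)
    # baseline TG truncated below the trial's eligibility cutoff so generated
    # cohorts are eligible by construction
    log_tg = _truncnorm(rng, *bm["log_tg"], math.log(0.2),
                        math.log(ch.TG_ELIGIBILITY_CUTOFF - 0.02), n)
    s["tg"] = np.exp(log_tg)
    s["glucose"] = _truncnorm(rng, *bm["glucose"], *_CLIPS["glucose"], size=n)
    s["diabetes"] = (rng.uniform(size=n) < bm["diabetes"]).astype(float)
    s["antihtn"] = (rng.uniform(size=n) < bm["antihtn"]).astype(float)
    s["lipidrx"] = (rng.uniform(size=n) < bm["lipidrx"]).astype(float)
    rho_g, _, sd_g = params.drift["ldl_gap"]
    marg_sd = sd_g / math.sqrt(1.0 - rho_g**2) if rho_g < 1.0 else sd_g
    gap0 = rng.normal(0.0, marg_sd, size=n)
    s["nonhdl"] = np.clip(s["ldl"] + s["tg"] / 2.2 + gap0, s["ldl"],
                          _CLIPS["nonhdl"][1])
    s["tc"] = s["nonhdl"] + s["hdl"]
    return s


def _mean_path(params: DGPParams, cov: str, k: int) -> float:
    bm = params.baseline_moments
    _, trend, _ = params.drift[cov]
    if cov == "nonhdl":
        mu, sigma = bm["log_tg"]
        mu0 = bm["ldl"][0] + math.exp(mu + 0.5 * sigma**2) / 2.2
    elif cov == "log_tg":
        mu0 = bm["log_tg"][0]
    else:
        mu0 = bm[cov][0]
    return mu0 + trend * k


def _step_covariates(params: DGPParams, s: dict, k: int,
                     rng: np.random.Generator) -> None:
    """Advance the state from year k-1 to year k, in the modelling order.

    RNG consumption is fixed (every variable draws every year) so paths are
    reproducible and comparable across regimes under common random numbers.
    """
    tr = params.transitions
    n = len(s["age0"])
    # remnant gap from the *observed* (post-intervention) lagged lipids, so
    # the LDL-C structural equation stays linear in observables
    gap_prev = s["nonhdl"] - s["tg"] / 2.2 - s["ldl"]

    u = rng.uniform(size=n)
    p_smoke = np.where(s["smoking"] > 0.5, 1.0 - tr["smoking_quit"],
                       tr["smoking_relapse"])
    s["smoking"] = (u < p_smoke).astype(float)

    for cov in ("bmi", "sbp", "dbp"):
        rho, _, sd = params.drift[cov]
        mu_k = _mean_path(params, cov, k)
        mu_prev = _mean_path(params, cov, k - 1)
        s[cov] = np.clip(mu_k + rho * (s[cov] - mu_prev) + sd * rng.normal(size=n),
                         *_CLIPS[cov])

    rho, _, sd = params.drift["log_tg"]
    mu_k = _mean_path(params, "log_tg", k)
    mu_prev = _mean_path(params, "log_tg", k - 1)
    log_tg = mu_k + rho * (np.log(s["tg"]) - mu_prev) + sd * rng.normal(size=n)
    s["tg"] = np.clip(np.exp(log_tg), *_CLIPS["tg"])

    rho, _, sd = params.drift["hdl"]
    mu_k = _mean_path(params, "hdl", k)
    mu_prev = _mean_path(params, "hdl", k - 1)
    s["hdl"] = np.clip(mu_k + rho * (s["hdl"] - mu_prev) + sd * rng.normal(size=n),
                       *_CLIPS["hdl"])

    rho, _, sd = params.drift["nonhdl"]
    mu_k = _mean_path(params, "nonhdl", k)
    mu_prev = _mean_path(params, "nonhdl", k - 1)
    s["nonhdl"] = np.clip(
        mu_k + rho * (s["nonhdl"] - mu_prev)
        + tr["lipidrx_effect_nonhdl"] * s["lipidrx"]
        + sd * rng.normal(size=n),
        *_CLIPS["nonhdl"])

    rho_g, _, sd_g = params.drift["ldl_gap"]
    gap = rho_g * gap_prev + sd_g * rng.normal(size=n)
    s["ldl"] = np.clip(s["nonhdl"] - s["tg"] / 2.2 - gap, 0.3, s["nonhdl"])

    rho, _, sd = params.drift["glucose"]
    mu_k = _mean_path(params, "glucose", k)
    mu_prev = _mean_path(params, "glucose", k - 1)
    s["glucose"] = np.clip(
        mu_k + rho * (s["glucose"] - mu_prev) + sd * rng.normal(size=n),
        *_CLIPS["glucose"])

    for cov, driver in (("diabetes", "glucose"), ("antihtn", "sbp"),
                        ("lipidrx", "ldl")):
        c = tr[cov]
        p_on = expit(c["intercept"] + c[driver] * s[driver] + c["k"] * k)
        u = rng.uniform(size=n)
        s[cov] = np.where(s[cov] > 0.5, 1.0, (u < p_on).astype(float))

    s["tc"] = s["nonhdl"] + s["hdl"]


def _hazard(coefs: dict, s: dict, k: int) -> np.ndarray:
    lp = (coefs["intercept"]
          + coefs["age"] * (s["age0"] + k)
          + coefs["male"] * (1.0 - s["female"])
          + coefs["smoking"] * s["smoking"]
          + coefs["sbp"] * s["sbp"]
          + coefs["ldl"] * s["ldl"]
          + coefs["diabetes"] * s["diabetes"]
          # optional effect modification, e.g. for subgroup experiments
          + coefs.get("ldl_x_smoking", 0.0) * s["ldl"] * s["smoking"])
    return expit(lp)


def _stratify_state(s: dict, k: int, scorer: TenYearScorer) -> np.ndarray:
    df = pd.DataFrame({
        "age": s["age0"] + k, "female": s["female"], "smoking": s["smoking"],
        "bmi": s["bmi"], "sbp": s["sbp"], "dbp": s["dbp"], "tc": s["tc"],
        "hdl": s["hdl"], "ldl": s["ldl"], "nonhdl": s["nonhdl"],
        "diabetes": s["diabetes"], "antihtn": s["antihtn"],
    })
    return stratify_frame(df, scorer)


def _simulate_paths(params: DGPParams, n: int, cov_rng: np.random.Generator,
                    regime: rg.RegimeSpec | None = None,
                    regime_rng: np.random.Generator | None = None,
                    scorer: TenYearScorer | None = None,
                    collect_waves: bool = False):
    """Forward-simulate covariate paths and per-year hazards.

    Covariate evolution does not depend on event occurrence, so hazards can
    be accumulated analytically afterwards. Returns (h_Y, h_D, wave
    snapshots, intervened flags), each with one row per individual.
    """
    scorer = scorer or TenYearScorer()
    horizon = params.horizon_years
    s = _draw_baseline(params, n, cov_rng)
    baseline_ldl = s["ldl"].copy()
    h_y = np.empty((n, horizon))
    h_d = np.empty((n, horizon))
    intervened = np.zeros((n, horizon), dtype=bool)
    snapshots = {}
    u_person = None
    active = regime is not None and regime.kind != "natural"
    for k in range(horizon):
        if k > 0:
            _step_covariates(params, s, k, cov_rng)
        if regime_rng is not None:
            u3 = regime_rng.uniform(size=(3, n))
        else:
            u3 = np.zeros((3, n))
        if active:
            if regime.per_person_adherence:
                if u_person is None:
                    u_person = u3[0]
                u_adh = u_person
            else:
                u_adh = u3[0]
            stratum = _stratify_state(s, k, scorer)
            act, new_ldl, new_nonhdl = rg.apply_regime(
                regime, stratum, s["diabetes"] > 0.5, baseline_ldl,
                s["ldl"], s["nonhdl"], u_adh, u3[1], u3[2])
            s["ldl"], s["nonhdl"] = new_ldl, new_nonhdl
            if regime.sets_drug_flag:
                s["lipidrx"] = np.where(act, 1.0, s["lipidrx"])
            s["tc"] = s["nonhdl"] + s["hdl"]
            intervened[:, k] = act
        h_y[:, k] = _hazard(params.hazard_coefs_Y, s, k)
        h_d[:, k] = _hazard(params.hazard_coefs_D, s, k)
        if collect_waves and k in params.wave_years:
            snapshots[k] = {c: s[c].copy() for c in ch.TIME_VARYING + ["tc"]}
    return h_y, h_d, snapshots, intervened, s["age0"], s["female"]


def generate_cohort(params: DGPParams) -> pd.DataFrame:
    """Generate a long-format cohort table under the natural course.

    One row per participant per observed wave year (waves after a
    participant's exit are unobserved), with the event record (type in
    {primary, competing, censored} and exit-interval index) repeated on every
    row. Deterministic given ``params.seed``.
    """
    n, horizon = params.n_participants, params.horizon_years
    root = np.random.SeedSequence(params.seed)
    cov_rng, ev_rng = (np.random.default_rng(c) for c in root.spawn(2))
    h_y, h_d, snaps, _, age0, female = _simulate_paths(
        params, n, cov_rng, collect_waves=True)

    u_y = ev_rng.uniform(size=(n, horizon))
    u_d = ev_rng.uniform(size=(n, horizon))
    event_year = np.full(n, horizon - 1, dtype=int)
    event_type = np.full(n, "censored", dtype=object)
    alive = np.ones(n, dtype=bool)
    for k in range(horizon):
        ev_y = alive & (u_y[:, k] < h_y[:, k])
        ev_d = alive & ~ev_y & (u_d[:, k] < h_d[:, k])
        event_year[ev_y] = k
        event_type[ev_y] = "primary"
        event_year[ev_d] = k
        event_type[ev_d] = "competing"
        alive &= ~(ev_y | ev_d)

    rows = []
    for wy in sorted(params.wave_years):
        observed = event_year >= wy
        idx = np.nonzero(observed)[0]
        row = {"pid": idx, "wave_year": wy, "age0": age0[idx],
               "female": female[idx], "prevalent_cvd": 0}
        for c in ch.TIME_VARYING + ["tc"]:
            row[c] = snaps[wy][c][idx]
        row["event_type"] = event_type[idx]
        row["event_year"] = event_year[idx]
        rows.append(pd.DataFrame(row))
    out = pd.concat(rows, ignore_index=True)
    return out.sort_values(["pid", "wave_year"], kind="stable").reset_index(drop=True)


def true_counterfactual_risk(params: DGPParams, regime: rg.RegimeSpec,
                             n_large: int = 50_000, seed: int = 0,
                             scorer: TenYearScorer | None = None) -> TrueRiskOracle:
    """Ground-truth cumulative incidence under a regime, by forward simulation.

    Applies the regime's assignments inside the known process itself and
    accumulates the discrete-time competing-risk cumulative incidence
    analytically from the per-year hazards (outcome hazard first, competing
    hazard among the outcome-free), averaging over ``n_large`` paths.
    """
    root = np.random.SeedSequence(seed)
    cov_rng, reg_rng = (np.random.default_rng(c) for c in root.spawn(2))
    h_y, h_d, _, _, _, _ = _simulate_paths(
        params, n_large, cov_rng, regime=regime, regime_rng=reg_rng,
        scorer=scorer)
    risk, comp = cif_from_hazards(h_y, h_d)
    return TrueRiskOracle(regime.label, risk, comp, n_large)


def cif_from_hazards(h_y: np.ndarray, h_d: np.ndarray):
    """Discrete-time cause-specific cumulative incidence from hazard paths.

    ``R_Y(t) = E[ sum_{k<=t} h_Y(k) prod_{j<k} (1-h_Y(j))(1-h_D(j)) ]`` and
    the companion competing curve uses ``(1-h_Y(k)) h_D(k)`` in the sum.
    Returns two arrays of length ``horizon`` with element ``t-1`` = risk by
    year ``t``.
    """
    surv = (1.0 - h_y) * (1.0 - h_d)
    prev_surv = np.ones_like(h_y)
    prev_surv[:, 1:] = np.cumprod(surv[:, :-1], axis=1)
    risk = np.cumsum(h_y * prev_surv, axis=1).mean(axis=0)
    comp = np.cumsum((1.0 - h_y) * h_d * prev_surv, axis=1).mean(axis=0)
    return risk, comp
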