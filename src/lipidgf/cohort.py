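"""Longitudinal cohort I/O, eligibility, person-period expansion and LOCF.

The cohort travels as a long-format table: one row per participant per
observed examination wave, with the participant's event record repeated on
each row. Time is discrete, in integer years since each participant's own
baseline (0-based); an event during the interval ``[k, k+1)`` is recorded at
index ``k``.

Column dictionary (:data:`COLUMN_DICT`):

* ``pid`` -- participant identifier
* ``wave_year`` -- years since baseline at which the row's covariates were
  measured
* ``age0`` (years), ``female`` (0/1), ``prevalent_cvd`` (0/1) -- time-fixed
* time-varying covariates: ``smoking`` (0/1), ``bmi`` (kg/m^2), ``sbp``/
  ``dbp`` (mmHg), ``tg``, ``hdl``, ``nonhdl``, ``ldl``, ``tc``, ``glucose``
  (mmol/L), ``diabetes``, ``antihtn``, ``lipidrx`` (0/1)
* ``event_type`` in {``primary``, ``competing``, ``censored``} and
  ``event_year`` (interval index of exit)
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

#: modelling order of the time-varying covariates: lifestyle, metabolic,
#: glycaemic status, then medications.
TIME_VARYING = [
    "smoking", "bmi", "sbp", "dbp", "tg", "hdl",
    "nonhdl", "ldl", "glucose", "diabetes", "antihtn", "lipidrx",
]
BINARY_COVS = {"smoking", "diabetes", "antihtn", "lipidrx"}
LOG_SCALE_COVS = {"tg"}
#: chronic conditions / treatments that never revert once present
ABSORBING_COVS = {"diabetes", "antihtn", "lipidrx"}
BASELINE_COVS = ["age0", "female"]

WAVE_COLUMNS = (
    ["pid", "wave_year", "age0", "female", "prevalent_cvd"]
    + TIME_VARYING + ["tc", "event_type", "event_year"]
)

COLUMN_DICT = {
    "pid": "participant identifier (int)",
    "wave_year": "years since own baseline at measurement (int)",
    "age0": "age at baseline, years",
    "female": "1 = female, 0 = male",
    "prevalent_cvd": "1 = cardiovascular disease before baseline",
    "smoking": "current smoker (0/1)",
    "bmi": "body-mass index, kg/m^2",
    "sbp": "systolic blood pressure, mmHg",
    "dbp": "diastolic blood pressure, mmHg",
    "tg": "triglycerides, mmol/L",
    "hdl": "HDL cholesterol, mmol/L",
    "nonhdl": "non-HDL cholesterol (TC - HDL-C), mmol/L",
    "ldl": "LDL cholesterol, mmol/L",
    "tc": "total cholesterol, mmol/L",
    "glucose": "fasting glucose, mmol/L",
    "diabetes": "diabetes (0/1)",
    "antihtn": "antihypertensive medication (0/1)",
    "lipidrx": "cholesterol-lowering medication (0/1)",
    "event_type": "primary | competing | censored",
    "event_year": "interval index of exit (event or censoring)",
}

TG_ELIGIBILITY_CUTOFF = 4.52  # mmol/L (400 mg/dL), exclusive
MIN_AGE = 35.0  # years, inclusive

_FLOAT_FORMAT = "%.10g"


class CohortValidationError(ValueError):
    pass


def write_cohort(df: pd.DataFrame, path) -> None:
    """Write a cohort table as CSV with a fixed decimal format."""
    df.to_csv(path, index=False, float_format=_FLOAT_FORMAT)


def read_cohort(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = [c for c in ("pid", "wave_year", "event_type", "event_year")
               if c not in df.columns]
    if missing:
        raise CohortValidationError(f"cohort table missing columns: {missing}")
    return df


def validate_cohort(df: pd.DataFrame) -> list[str]:
    """Structural checks; returns a list of human-readable issues."""
    issues = []
    for pid, grp in df.groupby("pid"):
        wy = grp["wave_year"].to_numpy()
        if not (np.diff(np.sort(wy)) > 0).all():
            issues.append(f"pid {pid}: duplicate wave years")
        if grp["event_year"].nunique() > 1 or grp["event_type"].nunique() > 1:
            issues.append(f"pid {pid}: inconsistent event record across waves")
    if (df["event_year"] < 0).any():
        issues.append("negative event years present")
    if {"tc", "hdl", "nonhdl"} <= set(df.columns):
        resid = (df["tc"] - df["hdl"] - df["nonhdl"]).abs()
        n_bad = int((resid > 0.01).sum())
        if n_bad:
            issues.append(f"{n_bad} rows violate nonhdl = tc - hdl by > 0.01 mmol/L")
    return issues


def apply_eligibility(df: pd.DataFrame) -> tuple[pd.DataFrame, dict]:
    """Apply the trial eligibility criteria on baseline rows.

    Retains participants aged >= 35 at baseline, without prevalent
    cardiovascular disease, and with baseline triglycerides strictly below
    4.52 mmol/L (400 mg/dL). Criteria are applied in that order and the tally
    reports the exclusions attributable to each.
    """
    required = {"age0", "prevalent_cvd", "tg", "wave_year"}
    missing = required - set(df.columns)
    if missing:
        raise CohortValidationError(f"eligibility requires columns {sorted(missing)}")
    base = df[df["wave_year"] == 0]
    tally = {}
    keep = base["age0"] >= MIN_AGE
    tally["age_lt_35"] = int((~keep).sum())
    cvd = (base["prevalent_cvd"] > 0) & keep
    tally["prevalent_cvd"] = int(cvd.sum())
    keep &= ~(base["prevalent_cvd"] > 0)
    tg = (base["tg"] >= TG_ELIGIBILITY_CUTOFF) & keep
    tally["tg_ge_4.52"] = int(tg.sum())
    keep &= base["tg"] < TG_ELIGIBILITY_CUTOFF
    eligible_pids = base.loc[keep, "pid"]
    tally["retained"] = int(keep.sum())
    out = df[df["pid"].isin(set(eligible_pids))].reset_index(drop=True)
    return out, tally


def expand_person_periods(df: pd.DataFrame, horizon: int = 29,
                          all_cause_outcome: bool = False) -> pd.DataFrame:
    """Expand the cohort to one row per participant-year until exit.

    A participant exiting at ``event_year = e`` contributes rows
    ``k = 0..min(e, horizon-1)``; the outcome indicator ``y`` (or competing
    indicator ``c``) is set on the exit row according to the event type. With
    ``all_cause_outcome=True`` any death-type event counts as the outcome and
    no competing process exists.
    """
    base = df[df["wave_year"] == 0][
        ["pid", "age0", "female", "event_type", "event_year"]
    ].drop_duplicates("pid")
    ev_year = pd.to_numeric(base["event_year"], errors="coerce")
    if ev_year.isna().any() or (ev_year < 0).any():
        raise CohortValidationError("event years must be non-negative numbers")
    exit_k = np.minimum(ev_year.to_numpy().astype(int), horizon - 1)
    n_rows = exit_k + 1
    pid = np.repeat(base["pid"].to_numpy(), n_rows)
    k = np.concatenate([np.arange(m) for m in n_rows])
    pp = pd.DataFrame({"pid": pid, "k": k})
    pp = pp.merge(base[["pid", "age0", "female", "event_type", "event_year"]],
                  on="pid", how="left")
    is_exit = (pp["k"] == np.minimum(pp["event_year"].astype(int), horizon - 1))
    etype = pp["event_type"].to_numpy()
    if all_cause_outcome:
        pp["y"] = (is_exit & np.isin(etype, ["primary", "competing"])).astype(np.int8)
        pp["c"] = np.zeros(len(pp), dtype=np.int8)
    else:
        pp["y"] = (is_exit & (etype == "primary")).astype(np.int8)
        pp["c"] = (is_exit & (etype == "competing")).astype(np.int8)
    return pp.drop(columns=["event_type", "event_year"])


def locf_fill(pp: pd.DataFrame, waves: pd.DataFrame,
              covariates: list[str] | None = None) -> pd.DataFrame:
    """Carry each covariate forward from the most recent wave at or before k.

    ``waves`` is the long-format cohort table; every participant must have a
    complete wave-0 measurement. A measurement taken exactly at year ``k`` is
    used at year ``k``. Values are never imputed past a participant's exit
    because person-period rows end at exit. Idempotent.
    """
    covariates = covariates if covariates is not None else TIME_VARYING + ["tc"]
    w = waves[["pid", "wave_year"] + covariates].copy()
    if {"tc", "hdl", "nonhdl"} <= set(w.columns):
        recomputed = w["tc"] - w["hdl"]
        bad = (recomputed - w["nonhdl"]).abs() > 0.01
        if bad.any():
            warnings.warn(
                f"recomputed nonhdl = tc - hdl for {int(bad.sum())} wave rows "
                "disagreeing by > 0.01 mmol/L",
                stacklevel=2,
            )
            w.loc[bad, "nonhdl"] = recomputed[bad]
    base = w[w["wave_year"] == 0]
    if base[covariates].isna().any().any() or not set(pp["pid"]) <= set(base["pid"]):
        raise CohortValidationError("baseline (wave 0) measurements incomplete")
    w = w.rename(columns={"wave_year": "k"})
    out = pp.drop(columns=[c for c in covariates if c in pp.columns])
    out = out.merge(w, on=["pid", "k"], how="left")
    out = out.sort_values(["pid", "k"], kind="stable").reset_index(drop=True)
    out[covariates] = out.groupby("pid", sort=False)[covariates].ffill()
    return out
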