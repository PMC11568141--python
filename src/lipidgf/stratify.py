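"""Three-step cardiovascular risk stratification.

Implements the guideline-style stratifier used to choose lipid targets:

1. direct high-risk criteria (diabetes at age >= 40, LDL-C >= 4.9 mmol/L, or
   total cholesterol >= 7.2 mmol/L);
2. a sex-specific 10-year ASCVD risk category (<5%, 5-9%, >=10%) from a
   pluggable, monotone point-score table;
3. a lifetime-risk upgrade for intermediate-risk individuals younger than 55
   carrying >= 2 of: SBP >= 160 or DBP >= 100 mmHg, non-HDL-C >= 5.2 mmol/L,
   HDL-C < 1.0 mmol/L, BMI >= 28 kg/m^2, current smoking.

The guideline's exact published point system is not reproduced; the default
:class:`TenYearScorer` is a documented monotone lookup that respects the three
categories and can be replaced from a YAML config.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd
import yaml

LOW, INTERMEDIATE, HIGH = 0, 1, 2
STRATUM_NAMES = {LOW: "low", INTERMEDIATE: "intermediate", HIGH: "high"}

CAT_LT5, CAT_5TO9, CAT_GE10 = 0, 1, 2
CATEGORY_NAMES = {CAT_LT5: "<5%", CAT_5TO9: "5-9%", CAT_GE10: ">=10%"}

#: default monotone point-score table for the 10-year category.
#: ``age_bands_*`` award the points of the highest threshold reached;
#: ``tc_bands`` likewise on total cholesterol; ``hdl_bands`` award points when
#: HDL-C falls *below* the threshold (lowest threshold crossed wins).
DEFAULT_SCORER_TABLE: dict = {
    "age_bands_male": [[45, 1], [55, 2], [65, 3]],
    "age_bands_female": [[55, 1], [65, 2], [75, 3]],
    "tc_bands": [[5.2, 1], [6.2, 2]],
    "hdl_bands": [[1.3, 1], [1.0, 2]],
    "smoking_points": 2,
    "hypertension_points": 2,
    "threshold_intermediate": 4,
    "threshold_high": 6,
}


def _band_points_ge(values: np.ndarray, bands) -> np.ndarray:
    pts = np.zeros(len(values), dtype=float)
    for thr, p in sorted(bands):
        pts = np.where(values >= thr, float(p), pts)
    return pts


def _band_points_lt(values: np.ndarray, bands) -> np.ndarray:
    pts = np.zeros(len(values), dtype=float)
    for thr, p in sorted(bands, reverse=True):
        pts = np.where(values < thr, float(p), pts)
    return pts


@dataclass
class TenYearScorer:
    """Replaceable mapping from risk-factor profile to 10-year risk category.

    The default is an additive point score on age band (sex-specific), total
    cholesterol band, HDL-C band, current smoking and hypertension (SBP >= 140
    or DBP >= 90 mmHg or antihypertensive treatment -- treated hypertension
    counts). Adding points for worse values of any factor makes the category
    monotone by construction.
    """

    table: dict = field(default_factory=lambda: dict(DEFAULT_SCORER_TABLE))

    def category_frame(self, df: pd.DataFrame) -> np.ndarray:
        """Vectorised category (0=<5%, 1=5-9%, 2=>=10%) for each row."""
        t = self.table
        age = np.asarray(df["age"], dtype=float)
        female = np.asarray(df["female"], dtype=float) > 0.5
        pts = np.where(
            female,
            _band_points_ge(age, t["age_bands_female"]),
            _band_points_ge(age, t["age_bands_male"]),
        )
        pts = pts + _band_points_ge(np.asarray(df["tc"], dtype=float), t["tc_bands"])
        pts = pts + _band_points_lt(np.asarray(df["hdl"], dtype=float), t["hdl_bands"])
        pts = pts + t["smoking_points"] * (np.asarray(df["smoking"], dtype=float) > 0.5)
        htn = (
            (np.asarray(df["sbp"], dtype=float) >= 140.0)
            | (np.asarray(df["dbp"], dtype=float) >= 90.0)
            | (np.asarray(df["antihtn"], dtype=float) > 0.5)
        )
        pts = pts + t["hypertension_points"] * htn
        cat = np.full(len(age), CAT_LT5, dtype=np.int64)
        cat[pts >= t["threshold_intermediate"]] = CAT_5TO9
        cat[pts >= t["threshold_high"]] = CAT_GE10
        return cat

    def __call__(self, profile: Mapping) -> str:
        df = pd.DataFrame({k: [profile[k]] for k in
                           ("age", "female", "tc", "hdl", "smoking", "sbp", "dbp", "antihtn")})
        return CATEGORY_NAMES[int(self.category_frame(df)[0])]

    @classmethod
    def from_yaml(cls, path) -> "TenYearScorer":
        with open(path) as fh:
            table = yaml.safe_load(fh)
        return cls(table=table)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.table, fh)


@dataclass(frozen=True)
class RiskStratum:
    """Assigned stratum plus the step of the procedure that triggered it."""

    value: str  # "low" | "intermediate" | "high"
    step: int  # 1, 2 or 3


def step1_direct_high(profile: Mapping) -> bool:
    """Direct high-risk criteria: diabetes at age >= 40, LDL-C >= 4.9, or TC >= 7.2."""
    return bool(
        (profile["diabetes"] and profile["age"] >= 40.0)
        or profile["ldl"] >= 4.9
        or profile["tc"] >= 7.2
    )


def step3_lifetime_upgrade(profile: Mapping) -> bool:
    """Lifetime-risk upgrade: >= 2 of the five high-lifetime-risk factors.

    Factors: SBP >= 160 or DBP >= 100 mmHg; non-HDL-C >= 5.2 mmol/L;
    HDL-C < 1.0 mmol/L; BMI >= 28 kg/m^2; current smoking.
    """
    n = (
        int(profile["sbp"] >= 160.0 or profile["dbp"] >= 100.0)
        + int(profile["nonhdl"] >= 5.2)
        + int(profile["hdl"] < 1.0)
        + int(profile["bmi"] >= 28.0)
        + int(bool(profile["smoking"]))
    )
    return n >= 2


_CAT_TO_STRATUM = {"<5%": "low", "5-9%": "intermediate", ">=10%": "high"}


def stratify(profile: Mapping, scorer: TenYearScorer | None = None) -> RiskStratum:
    """Run the full 3-step procedure on one complete profile.

    Step 1 short-circuits to high risk; otherwise the scorer's category maps
    to {low, intermediate, high}; intermediate-risk individuals younger than
    55 are upgraded to high when the lifetime-risk step fires.
    """
    scorer = scorer or TenYearScorer()
    if step1_direct_high(profile):
        return RiskStratum("high", 1)
    cat = scorer(profile)
    if cat not in _CAT_TO_STRATUM:
        raise ValueError(f"scorer returned unknown category {cat!r}")
    value = _CAT_TO_STRATUM[cat]
    if value == "intermediate" and profile["age"] < 55.0 and step3_lifetime_upgrade(profile):
        return RiskStratum("high", 3)
    return RiskStratum(value, 2)


def stratify_frame(df: pd.DataFrame, scorer: TenYearScorer | None = None,
                   return_step: bool = False):
    """Vectorised 3-step stratification.

    Parameters
    ----------
    df
        One row per profile with columns age, female, smoking, bmi, sbp, dbp,
        tc, hdl, ldl, nonhdl, diabetes, antihtn.
    return_step
        Also return the triggering step (1, 2 or 3) per row for audit.

    Returns
    -------
    stratum : int array (0=low, 1=intermediate, 2=high), optionally with the
    triggering-step array.
    """
    scorer = scorer or TenYearScorer()
    age = np.asarray(df["age"], dtype=float)
    s1 = (
        ((np.asarray(df["diabetes"], dtype=float) > 0.5) & (age >= 40.0))
        | (np.asarray(df["ldl"], dtype=float) >= 4.9)
        | (np.asarray(df["tc"], dtype=float) >= 7.2)
    )
    cat = scorer.category_frame(df)
    stratum = cat.copy()  # category index coincides with stratum index
    step = np.full(len(age), 2, dtype=np.int64)

    lifetime = (
        ((np.asarray(df["sbp"], dtype=float) >= 160.0)
         | (np.asarray(df["dbp"], dtype=float) >= 100.0)).astype(np.int64)
        + (np.asarray(df["nonhdl"], dtype=float) >= 5.2)
        + (np.asarray(df["hdl"], dtype=float) < 1.0)
        + (np.asarray(df["bmi"], dtype=float) >= 28.0)
        + (np.asarray(df["smoking"], dtype=float) > 0.5)
    ) >= 2
    upgrade = (stratum == INTERMEDIATE) & (age < 55.0) & lifetime
    stratum[upgrade] = HIGH
    step[upgrade] = 3

    stratum[s1] = HIGH
    step[s1] = 1
    if return_step:
        return stratum, step
    return stratum
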