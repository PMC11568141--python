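"""Causal contrasts and bootstrap inference.

Turns risk curves into the trial's estimands: 29-year risk, risk difference
(RD) and risk ratio (RR) versus the natural course, restricted mean
event-free time (RMET, the area above the cumulative incidence curve), the
RMET-based number needed to treat (NNT = natural-course RMET divided by the
RMET gain), and the average percentage of person-years intervened. Confidence
intervals are percentile bootstrap over participants (whole histories are the
exchangeable unit), re-running model fitting and simulation in each
replicate.

NNT is computed from unrounded RMETs and ceiling-rounded only at
presentation; a zero RMET difference is reported as undefined (never as a
number), and a negative difference is a number needed to harm, kept with its
sign internally.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import cohort as ch
from . import engine as en
from . import models as md
from . import regimes as rg
from .stratify import TenYearScorer

log = logging.getLogger(__name__)

NATURAL_LABEL = "natural_course"


def rmet(curve: en.RiskCurve | np.ndarray, horizon: int = 29) -> float:
    """Restricted mean event-free time in years up to ``horizon``.

    Computed as the area above the cumulative incidence curve with a
    right-endpoint rule on the one-year grid:
    ``horizon - sum_{t=1..horizon} R(t)``.
    """
    risk = curve.risk if isinstance(curve, en.RiskCurve) else np.asarray(curve)
    if len(risk) < horizon:
        raise ValueError("curve not defined through the horizon")
    return float(horizon - np.sum(risk[:horizon]))


def nnt_rmet(rmet_natural: float, rmet_intervention: float) -> float | None:
    """RMET-based number needed to treat (unrounded; None when undefined).

    Negative values are number-needed-to-harm (sign preserved); use
    :func:`format_nnt` for the ceiling-rounded presentation value.
    """
    diff = rmet_intervention - rmet_natural
    if diff == 0.0:
        return None
    return rmet_natural / diff


def format_nnt(nnt: float | None) -> str:
    """Presentation form: ceiling-rounded integer, 'undefined', or NNH."""
    if nnt is None:
        return "undefined"
    n = math.ceil(abs(nnt) - 1e-9)
    return str(n) if nnt >= 0 else f"NNH {n}"


def average_percent_intervened(trace: en.SimulationTrace) -> tuple[float, float]:
    """(% of event-free person-years intervened, % ever intervened).

    Person-years are weighted by each pseudo-individual's probability of
    still being event-free at the start of the year, so interventions that
    would occur after death do not count.
    """
    w = en.survival_weights(trace)
    denom = w.sum()
    py_pct = float(100.0 * (w * trace.intervened).sum() / denom) if denom else 0.0
    ever_pct = float(100.0 * trace.intervened.any(axis=1).mean())
    return py_pct, ever_pct


def _regime_stats(curve: en.RiskCurve, trace: en.SimulationTrace,
                  natural_curve: en.RiskCurve, horizon: int) -> dict:
    r = float(curve.risk[horizon - 1])
    r0 = float(natural_curve.risk[horizon - 1])
    rm = rmet(curve, horizon)
    rm0 = rmet(natural_curve, horizon)
    py_pct, ever_pct = average_percent_intervened(trace)
    return {
        "risk_pct": 100.0 * r,
        "rd_pct": 100.0 * (r - r0),
        "rr": r / r0 if r0 > 0 else np.nan,
        "rmet_years": rm,
        "nnt": nnt_rmet(rm0, rm),
        "pct_py_intervened": py_pct,
        "pct_ever_intervened": ever_pct,
    }


STAT_COLUMNS = ["risk_pct", "rd_pct", "rr", "rmet_years", "nnt",
                "pct_py_intervened", "pct_ever_intervened"]
CI_COLUMNS = ["risk_pct", "rd_pct", "rr", "rmet_years", "nnt"]


@dataclass
class EstimandTable:
    """Point estimates (one row per regime) with optional bootstrap CIs."""

    table: pd.DataFrame
    n_boot: int = 0
    n_failed: int = 0
    replicates: pd.DataFrame | None = None

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False, float_format="%.10g")

    def formatted(self) -> pd.DataFrame:
        out = self.table.copy()
        out["nnt"] = [format_nnt(v if pd.notna(v) else None)
                      for v in out["nnt"]]
        return out


def table_from_results(curves: dict, traces: dict, horizon: int,
                       natural_label: str = NATURAL_LABEL) -> pd.DataFrame:
    """Assemble the estimand rows from already-simulated curves/traces."""
    if natural_label not in curves:
        raise ValueError("results must include the natural course as reference")
    nat = curves[natural_label]
    rows = []
    for label, curve in curves.items():
        stats = _regime_stats(curve, traces[label], nat, horizon)
        rows.append({"regime": label, **stats})
    return pd.DataFrame(rows)


def simulate_regimes(fitted: md.FittedModels, regime_list, n_mc, seed,
                     scorer=None) -> tuple[dict, dict]:
    """Simulate each regime under common random numbers (shared seed)."""
    curves, traces = {}, {}
    for reg in regime_list:
        tr = en.simulate(fitted, reg, n_mc=n_mc, seed=seed, scorer=scorer)
        curves[reg.label] = en.cumulative_incidence(tr)
        traces[reg.label] = tr
    if NATURAL_LABEL not in curves:
        tr = en.simulate(fitted, rg.natural_course(), n_mc=n_mc, seed=seed,
                         scorer=scorer)
        curves[NATURAL_LABEL] = en.cumulative_incidence(tr)
        traces[NATURAL_LABEL] = tr
    return curves, traces


def _run_point(pp: pd.DataFrame, spec: md.ModelSpec, regime_list, n_mc, seed,
               horizon, all_cause, scorer) -> tuple[pd.DataFrame, dict, dict]:
    fitted = md.fit_all(pp, spec, all_cause=all_cause, horizon=horizon)
    curves, traces = simulate_regimes(fitted, regime_list, n_mc, seed, scorer)
    labels = [reg.label for reg in regime_list]
    table = table_from_results(
        {k: curves[k] for k in labels} if NATURAL_LABEL in labels else curves,
        traces, horizon)
    table = table[table["regime"].isin(labels)].reset_index(drop=True)
    return table, curves, traces


def estimand_table(pp: pd.DataFrame, regime_list, spec: md.ModelSpec | None = None,
                   n_mc: int = 10_000, seed: int = 0, horizon: int = 29,
                   all_cause: bool = False,
                   scorer: TenYearScorer | None = None) -> EstimandTable:
    """Fit, simulate every regime and assemble point estimates (no CIs)."""
    spec = spec or md.ModelSpec()
    table, _, _ = _run_point(pp, spec, regime_list, n_mc, seed, horizon,
                             all_cause, scorer)
    return EstimandTable(table)


class BootstrapError(RuntimeError):
    pass


def _resample_waves(waves: pd.DataFrame, rng: np.random.Generator) -> pd.DataFrame:
    pids = waves["pid"].unique()
    take = rng.choice(pids, size=len(pids), replace=True)
    parts = []
    grouped = dict(tuple(waves.groupby("pid")))
    for new_pid, old in enumerate(take):
        g = grouped[old].copy()
        g["pid"] = new_pid
        parts.append(g)
    return pd.concat(parts, ignore_index=True)


def bootstrap_cis(waves: pd.DataFrame, regime_list,
                  spec: md.ModelSpec | None = None, n_boot: int = 500,
                  seed: int = 0, n_mc: int = 10_000, horizon: int = 29,
                  all_cause: bool = False, scorer: TenYearScorer | None = None,
                  max_failure_fraction: float = 0.10) -> EstimandTable:
    """Percentile-bootstrap confidence intervals for every estimand.

    Participants (whole wave histories) are resampled with replacement;
    model fitting and Monte Carlo simulation are re-run per replicate with
    deterministic replicate seeds derived from ``seed``. Replicates whose
    models fail are dropped and counted; more than 10% failures aborts.
    """
    if n_boot < 2:
        raise ValueError("n_boot must be >= 2")
    if waves["pid"].nunique() < 2:
        raise BootstrapError("cannot resample a cohort of fewer than 2 participants")
    spec = spec or md.ModelSpec()
    pp = ch.locf_fill(ch.expand_person_periods(waves, horizon, all_cause), waves)
    point, _, _ = _run_point(pp, spec, regime_list, n_mc, seed, horizon,
                             all_cause, scorer)

    root = np.random.SeedSequence(seed)
    child_seeds = root.generate_state(2 * n_boot, dtype=np.uint32)
    reps, n_failed = [], 0
    for b in range(n_boot):
        rng = np.random.default_rng(int(child_seeds[2 * b]))
        sim_seed = int(child_seeds[2 * b + 1])
        try:
            w_b = _resample_waves(waves, rng)
            pp_b = ch.locf_fill(
                ch.expand_person_periods(w_b, horizon, all_cause), w_b)
            tab, _, _ = _run_point(pp_b, spec, regime_list, n_mc, sim_seed,
                                   horizon, all_cause, scorer)
            tab["replicate"] = b
            reps.append(tab)
        except (md.ModelFitError, np.linalg.LinAlgError) as exc:
            n_failed += 1
            log.warning("bootstrap replicate %d failed: %s", b, exc)
    if n_failed > max_failure_fraction * n_boot:
        raise BootstrapError(
            f"{n_failed}/{n_boot} bootstrap replicates failed to fit; "
            "the cohort is too small or degenerate for resampling")
    rep_df = pd.concat(reps, ignore_index=True)
    out = point.copy()
    for col in CI_COLUMNS:
        lo, hi = [], []
        for reg in out["regime"]:
            vals = rep_df.loc[rep_df["regime"] == reg, col].astype(float).dropna()
            if len(vals):
                lo.append(float(np.percentile(vals, 2.5)))
                hi.append(float(np.percentile(vals, 97.5)))
            else:
                lo.append(np.nan)
                hi.append(np.nan)
        out[f"{col}_lo"] = lo
        out[f"{col}_hi"] = hi
    return EstimandTable(out, n_boot=n_boot, n_failed=n_failed,
                         replicates=rep_df)


SUBGROUP_DEFS = {
    "sex": [("women", lambda b: b["female"] > 0.5),
            ("men", lambda b: b["female"] <= 0.5)],
    "bmi": [("bmi_lt_24", lambda b: b["bmi"] < 24.0),
            ("bmi_ge_24", lambda b: b["bmi"] >= 24.0)],
    "smoking": [("smokers", lambda b: b["smoking"] > 0.5),
                ("non_smokers", lambda b: b["smoking"] <= 0.5)],
    "antihtn": [("antihtn_yes", lambda b: b["antihtn"] > 0.5),
                ("antihtn_no", lambda b: b["antihtn"] <= 0.5)],
}


def subgroup_run(waves: pd.DataFrame, grouping: str, regime_list,
                 spec: md.ModelSpec | None = None, n_mc: int = 10_000,
                 seed: int = 0, horizon: int = 29, all_cause: bool = False,
                 scorer: TenYearScorer | None = None) -> dict[str, EstimandTable]:
    """Run the full pipeline independently within each baseline subgroup.

    Groupings: sex, baseline BMI (< 24 vs >= 24 kg/m^2, with 24.0 in the
    upper arm), baseline smoking, baseline antihypertensive use. Empty
    subgroups are reported and skipped.
    """
    if grouping not in SUBGROUP_DEFS:
        raise ValueError(f"unknown grouping {grouping!r}; "
                         f"choose from {sorted(SUBGROUP_DEFS)}")
    base = waves[waves["wave_year"] == 0]
    out = {}
    for name, pred in SUBGROUP_DEFS[grouping]:
        pids = set(base.loc[pred(base), "pid"])
        if not pids:
            log.warning("subgroup %s is empty; skipped", name)
            out[name] = None
            continue
        sub = waves[waves["pid"].isin(pids)]
        pp = ch.locf_fill(ch.expand_person_periods(sub, horizon, all_cause), sub)
        out[name] = estimand_table(pp, regime_list, spec, n_mc=n_mc, seed=seed,
                                   horizon=horizon, all_cause=all_cause,
                                   scorer=scorer)
    return out
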