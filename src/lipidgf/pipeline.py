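"""End-to-end run orchestration: one config in, one result bundle out.

Stages: generate or ingest the cohort, apply eligibility, expand to
person-periods with LOCF, stratify for audit, fit the pooled models, simulate
every regime, assemble estimands (optionally with bootstrap CIs), run the
natural-course diagnostic and any sensitivity analyses, and write everything
to a run directory together with a manifest that suffices to reproduce the
run exactly. One master seed fans out deterministically to the generator,
the Monte Carlo engine and the bootstrap, so regimes are compared under
common random numbers.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import cohort as ch
from . import engine as en
from . import estimands as es
from . import models as md
from . import regimes as rg
from . import synthetic as sy
from .stratify import TenYearScorer, stratify_frame

log = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    """Raised when a stage fails; the message names the stage."""


def _regime_from_dict(d: dict) -> rg.RegimeSpec:
    return rg.RegimeSpec(**d)


@dataclass
class RunConfig:
    """Complete, explicit description of one analysis run.

    Seeds are always explicit (no wall-clock seeding). ``synthetic`` holds
    overrides for :class:`lipidgf.synthetic.DGPParams`; alternatively
    ``input_csv`` points at an existing long-format cohort table.
    """

    seed: int = 0
    input_csv: str | None = None
    synthetic: dict = field(default_factory=dict)
    outcome: str = "primary"  # "primary" (with competing events) | "all_cause"
    regimes: list = field(default_factory=lambda: [
        {"kind": "natural", "label": "natural_course"},
        {"kind": "treat_to_target", "label": "treat_to_target"},
        {"kind": "feasible", "adherence": 0.8},
        {"kind": "static_reduction", "delta": 1.0},
    ])
    model: dict = field(default_factory=dict)
    horizon: int = 29
    n_mc: int = 10_000
    n_boot: int = 0  # 0 disables the bootstrap (point estimates only)
    subgroups: list = field(default_factory=list)
    adherence_sweep: list = field(default_factory=list)
    lagged_sensitivity: bool = False

    def __post_init__(self):
        if self.outcome not in ("primary", "all_cause"):
            raise PipelineError(f"config: unknown outcome {self.outcome!r}")
        for d in self.regimes:
            _regime_from_dict(d)  # validates eagerly

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            return cls(**(yaml.safe_load(fh) or {}))

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=False)


def _child_seed(master: int, salt: int) -> int:
    return int(np.random.SeedSequence([master, salt]).generate_state(1)[0]
               % (2**31))


def _stage(name):
    def deco(fn):
        def wrapped(*a, **kw):
            log.info("stage %s: start", name)
            try:
                out = fn(*a, **kw)
            except PipelineError:
                raise
            except Exception as exc:
                raise PipelineError(f"stage {name!r} failed: {exc}") from exc
            log.info("stage %s: done", name)
            return out
        return wrapped
    return deco


@_stage("input")
def _load_cohort(config: RunConfig) -> pd.DataFrame:
    if config.input_csv:
        return ch.read_cohort(config.input_csv)
    params = sy.DGPParams(seed=_child_seed(config.seed, 1), **config.synthetic)
    return sy.generate_cohort(params)


def run(config: RunConfig, outdir) -> dict:
    """Execute the full analysis; returns the result bundle and writes it.

    The bundle maps stage names to in-memory results; on disk the run
    directory receives the manifest, the (synthetic) cohort, exclusion
    tallies, fitted coefficients, risk curves, estimand tables and the
    natural-course diagnostic, all as delimited text or YAML.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    config.to_yaml(outdir / "manifest.yaml")
    all_cause = config.outcome == "all_cause"
    scorer = TenYearScorer()
    spec = md.ModelSpec(**config.model)
    regimes = [_regime_from_dict(d) for d in config.regimes]
    if not any(r.kind == "natural" for r in regimes):
        regimes.insert(0, rg.natural_course())

    waves = _load_cohort(config)
    if config.input_csv is None:
        ch.write_cohort(waves, outdir / "cohort.csv")

    eligible, tally = _stage("eligibility")(ch.apply_eligibility)(waves)
    pp = _stage("person_periods")(
        lambda: ch.locf_fill(
            ch.expand_person_periods(eligible, config.horizon, all_cause),
            eligible))()

    base = pp[pp["k"] == 0].copy()
    base["age"] = base["age0"]
    strata, steps = stratify_frame(base, scorer, return_step=True)
    audit = pd.DataFrame({"pid": base["pid"], "stratum": strata,
                          "triggering_step": steps})
    audit.to_csv(outdir / "baseline_strata.csv", index=False)

    sim_seed = _child_seed(config.seed, 2)
    fitted = _stage("fit")(md.fit_all)(pp, spec, all_cause=all_cause,
                                       horizon=config.horizon)
    md.coefficients_frame(fitted).to_csv(outdir / "coefficients.csv",
                                         index=False, float_format="%.10g")
    curve_map, trace_map = _stage("simulate")(es.simulate_regimes)(
        fitted, regimes, config.n_mc, sim_seed, scorer)
    if config.n_boot:
        table = _stage("bootstrap")(es.bootstrap_cis)(
            eligible, regimes, spec, n_boot=config.n_boot,
            seed=_child_seed(config.seed, 3), n_mc=config.n_mc,
            horizon=config.horizon, all_cause=all_cause, scorer=scorer)
    else:
        table = es.EstimandTable(es.table_from_results(
            curve_map, trace_map, config.horizon))

    curves_rows = []
    for reg in regimes:
        cv = curve_map[reg.label]
        for t in range(config.horizon):
            curves_rows.append({"regime": reg.label, "year": t + 1,
                                "risk": cv.risk[t], "competing": cv.competing[t]})
    curves = pd.DataFrame(curves_rows)

    diag = _stage("diagnostic")(en.natural_course_diagnostic)(
        pp, fitted, n_mc=config.n_mc, seed=sim_seed, scorer=scorer)

    sensitivity = {}
    if config.lagged_sensitivity:
        lag_spec = dataclasses.replace(spec, exposure_ordering="lagged")
        sensitivity["lagged"] = _stage("lagged_ordering")(es.estimand_table)(
            pp, regimes, lag_spec, n_mc=config.n_mc, seed=sim_seed,
            horizon=config.horizon, all_cause=all_cause, scorer=scorer)
    if config.adherence_sweep:
        sweep = rg.adherence_sweep(rg.feasible(), config.adherence_sweep)
        sensitivity["adherence_sweep"] = _stage("adherence_sweep")(
            es.estimand_table)(
            pp, [rg.natural_course()] + sweep, spec, n_mc=config.n_mc,
            seed=sim_seed, horizon=config.horizon, all_cause=all_cause,
            scorer=scorer)

    subgroups = {}
    for grouping in config.subgroups:
        subgroups[grouping] = _stage(f"subgroup_{grouping}")(es.subgroup_run)(
            eligible, grouping, regimes, spec, n_mc=config.n_mc,
            seed=sim_seed, horizon=config.horizon, all_cause=all_cause,
            scorer=scorer)

    table.to_csv(outdir / "estimands.csv")
    curves.to_csv(outdir / "curves.csv", index=False, float_format="%.10g")
    diag_out = {
        "max_abs_gap": float(diag.max_abs_gap),
        "observed_risk_29": float(diag.observed[-1]),
        "simulated_risk_29": float(diag.simulated[-1]),
        "exclusions": {k: int(v) for k, v in tally.items()},
        "bootstrap_failures": int(table.n_failed),
    }
    with open(outdir / "diagnostics.yaml", "w") as fh:
        yaml.safe_dump(diag_out, fh)
    for name, sens in sensitivity.items():
        sens.to_csv(outdir / f"sensitivity_{name}.csv")
    for grouping, tables in subgroups.items():
        for sub, tab in tables.items():
            if tab is not None:
                tab.to_csv(outdir / f"subgroup_{grouping}_{sub}.csv")

    return {"config": config, "waves": waves, "eligible": eligible,
            "tally": tally, "person_periods": pp, "fitted": fitted,
            "estimands": table, "curves": curves, "diagnostic": diag,
            "sensitivity": sensitivity, "subgroups": subgroups,
            "outdir": outdir}


def report(bundle: dict, path=None, plot: bool = True) -> str:
    """Render a human-readable summary (estimand table per regime, diagnostic
    gap, exclusion tally) and optionally the risk-curve figure."""
    if "estimands" not in bundle:
        raise PipelineError("incomplete bundle: estimands missing")
    table: es.EstimandTable = bundle["estimands"]
    lines = ["Estimated effects of cholesterol-lowering regimes "
             "(29-year horizon unless configured otherwise)", ""]
    fmt = table.formatted()
    lines.append(fmt.to_string(index=False,
                               float_format=lambda v: f"{v:.2f}"))
    if table.n_boot:
        lines.append(f"\nPercentile 95% CIs from {table.n_boot} bootstrap "
                     f"replicates ({table.n_failed} failed).")
    else:
        lines.append("\nPoint estimates only (bootstrap disabled); "
                     "CI columns omitted.")
    diag = bundle.get("diagnostic")
    if diag is not None:
        lines.append(f"Natural-course diagnostic: max |observed - simulated| "
                     f"= {100 * diag.max_abs_gap:.2f} percentage points.")
    tally = bundle.get("tally")
    if tally:
        lines.append(f"Eligibility exclusions: {tally}.")
    text = "\n".join(lines)
    outdir = Path(bundle.get("outdir", "."))
    target = Path(path) if path else outdir / "report.txt"
    target.write_text(text + "\n")
    if plot and "curves" in bundle:
        import matplotlib
        matplotlib.use("Agg")
        import matplotlib.pyplot as plt
        fig, ax = plt.subplots(figsize=(7, 4.5))
        for reg, grp in bundle["curves"].groupby("regime"):
            ax.plot(grp["year"], 100 * grp["risk"], label=reg)
        ax.set_xlabel("years of follow-up")
        ax.set_ylabel("cumulative incidence (%)")
        ax.legend(frameon=False, fontsize=8)
        fig.tight_layout()
        fig.savefig(target.with_name("risk_curves.png"), dpi=150)
        plt.close(fig)
    return text
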