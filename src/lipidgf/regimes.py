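"""Cholesterol-lowering intervention strategies (dynamic regimes).

Four kinds of regime are supported:

``natural``
    No intervention ever; the reference "natural course".
``treat_to_target``
    Risk-based treat-to-target rule: whenever LDL-C or non-HDL-C is at or
    above its stratum-specific target bound, assign each lipid a fixed level
    drawn from a uniform distribution below the bound. Eligibility is
    re-assessed every year; the intervention stops (is withheld) as soon as
    both targets are met, and resumes if drift pushes cholesterol back up.
``feasible``
    As treat-to-target, but each eligible person-year receives the
    intervention only with probability ``adherence`` (headline value 0.8),
    emulating imperfect real-world uptake.
``static_reduction``
    Unconditional LDL-C reduction by ``delta`` mmol/L every year (positive
    control; headline value 1 mmol/L), with non-HDL-C reduced by the same
    amount.

Target bounds (mmol/L), by stratum:

=====================  ==========================  ==========
stratum                LDL-C upper                 non-HDL-C
=====================  ==========================  ==========
high with diabetes     min(1.8, 50% of baseline)   2.6
intermediate or high   2.6                         3.4
low                    3.4                         4.2
=====================  ==========================  ==========
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Mapping, Sequence

import numpy as np

from .stratify import HIGH, INTERMEDIATE, LOW

REGIME_KINDS = ("natural", "treat_to_target", "feasible", "static_reduction")


@dataclass(frozen=True)
class RegimeSpec:
    """Full definition of one intervention strategy.

    Parameters
    ----------
    kind
        One of :data:`REGIME_KINDS`.
    adherence
        Probability that an eligible person-year actually receives the
        intervention (1.0 for full treat-to-target).
    delta
        Static LDL-C reduction in mmol/L (``static_reduction`` only).
    lb_fraction
        Lower bound of the uniform target draw, as a fraction of the upper
        bound (the protocol states only the upper bound).
    floor
        Lowest assignable LDL-C under static reduction, mmol/L.
    per_person_adherence
        Draw adherence once per simulated person instead of independently per
        eligible person-year.
    label
        Name used in outputs and as the seed-stream label.
    """

    kind: str
    adherence: float = 1.0
    delta: float = 0.0
    lb_fraction: float = 0.5
    floor: float = 0.5
    per_person_adherence: bool = False
    label: str = ""

    def __post_init__(self):
        if self.kind not in REGIME_KINDS:
            raise ValueError(f"unknown regime kind {self.kind!r}")
        if not 0.0 <= self.adherence <= 1.0:
            raise ValueError("adherence must be in [0, 1]")
        if self.delta < 0:
            raise ValueError("delta must be >= 0")
        if self.label == "":
            if self.kind == "feasible":
                label = f"feasible_{int(round(self.adherence * 100))}"
            elif self.kind == "static_reduction":
                label = f"static_{self.delta:g}mmol"
            elif self.kind == "natural":
                label = "natural_course"
            else:
                label = self.kind
            object.__setattr__(self, "label", label)

    @property
    def sets_drug_flag(self) -> bool:
        """Treat-to-target style interventions mark the lipid-lowering flag;
        the static shift is a pure lipid displacement and does not."""
        return self.kind in ("treat_to_target", "feasible")


def natural_course() -> RegimeSpec:
    return RegimeSpec("natural", label="natural_course")


def treat_to_target(**kw) -> RegimeSpec:
    return RegimeSpec("treat_to_target", adherence=1.0, label="treat_to_target", **kw)


def feasible(adherence: float = 0.8, **kw) -> RegimeSpec:
    return RegimeSpec("feasible", adherence=adherence,
                      label=f"feasible_{int(round(adherence * 100))}", **kw)


def static_reduction(delta: float = 1.0, **kw) -> RegimeSpec:
    return RegimeSpec("static_reduction", delta=delta,
                      label=f"static_{delta:g}mmol", **kw)


def adherence_sweep(base: RegimeSpec, p_values: Sequence[float]) -> list[RegimeSpec]:
    """One feasible regime per adherence probability, sharing other settings."""
    out = []
    for p in p_values:
        if not 0.0 <= p <= 1.0:
            raise ValueError(f"adherence {p} outside [0, 1]")
        out.append(replace(base, kind="feasible", adherence=p,
                           label=f"feasible_{int(round(p * 100))}"))
    return out


def target_bounds(stratum, diabetes, baseline_ldl):
    """Stratum-specific (LDL-C, non-HDL-C) upper target bounds, mmol/L.

    Accepts scalars or arrays. ``stratum`` is the integer code from
    :mod:`lipidgf.stratify` (or the equivalent name). High-risk participants
    with diabetes get LDL-C ``min(1.8, 0.5 * baseline LDL-C)`` ("whichever is
    the lowest"); intermediate-to-high without diabetes (2.6, 3.4); low
    (3.4, 4.2).
    """
    name_map = {"low": LOW, "intermediate": INTERMEDIATE, "high": HIGH}
    if isinstance(stratum, str):
        stratum = name_map[stratum]
    stratum = np.asarray(stratum)
    if not np.isin(stratum, [LOW, INTERMEDIATE, HIGH]).all():
        raise ValueError("unknown stratum code")
    diabetes = np.asarray(diabetes, dtype=bool)
    baseline_ldl = np.asarray(baseline_ldl, dtype=float)

    ldl_up = np.where(stratum == LOW, 3.4, 2.6)
    nonhdl_up = np.where(stratum == LOW, 4.2, 3.4)
    high_dm = (stratum == HIGH) & diabetes
    ldl_up = np.where(high_dm, np.minimum(1.8, 0.5 * baseline_ldl), ldl_up)
    nonhdl_up = np.where(high_dm, 2.6, nonhdl_up)
    if ldl_up.ndim == 0:
        return float(ldl_up), float(nonhdl_up)
    return ldl_up, nonhdl_up


@dataclass(frozen=True)
class RegimeDecision:
    """Outcome of applying a regime to one person-year."""

    intervened: bool
    ldl: float
    nonhdl: float
    reason: str  # not_eligible | target_met | non_adherent | intervened


def apply_regime(regime: RegimeSpec, stratum, diabetes, baseline_ldl,
                 ldl, nonhdl, u_adhere, u_ldl, u_nonhdl):
    """Vectorised regime application for one year.

    Parameters are aligned arrays over individuals; ``u_*`` are Uniform(0,1)
    draws consumed only where the regime is stochastic (pass any array for a
    deterministic regime). Returns ``(intervened, new_ldl, new_nonhdl)``.
    Assigned values never exceed current values and never violate
    non-HDL-C >= LDL-C.
    """
    ldl = np.asarray(ldl, dtype=float)
    nonhdl = np.asarray(nonhdl, dtype=float)
    if regime.kind == "natural":
        return np.zeros(ldl.shape, dtype=bool), ldl.copy(), nonhdl.copy()

    if regime.kind == "static_reduction":
        new_ldl = np.minimum(ldl, np.maximum(ldl - regime.delta, regime.floor))
        new_nonhdl = np.minimum(nonhdl, np.maximum(nonhdl - regime.delta, new_ldl))
        return np.ones(ldl.shape, dtype=bool), new_ldl, new_nonhdl

    ldl_up, nonhdl_up = target_bounds(stratum, diabetes, baseline_ldl)
    eligible = (ldl >= ldl_up) | (nonhdl >= nonhdl_up)
    if regime.kind == "feasible" or regime.adherence < 1.0:
        act = eligible & (np.asarray(u_adhere) < regime.adherence)
    else:
        act = eligible
    lb = regime.lb_fraction
    draw_ldl = ldl_up * (lb + (1.0 - lb) * np.asarray(u_ldl))
    draw_nonhdl = nonhdl_up * (lb + (1.0 - lb) * np.asarray(u_nonhdl))
    new_ldl = np.where(act, np.minimum(ldl, draw_ldl), ldl)
    new_nonhdl = np.where(
        act, np.maximum(np.minimum(nonhdl, draw_nonhdl), new_ldl), nonhdl
    )
    return act, new_ldl, new_nonhdl


def decide(state: Mapping, stratum, regime: RegimeSpec,
           rng: np.random.Generator | None = None) -> RegimeDecision:
    """Apply a regime to a single person-year state.

    ``state`` must carry ``ldl``, ``nonhdl``, ``diabetes`` and
    ``baseline_ldl``; ``rng`` is required for stochastic regimes.
    """
    stochastic = regime.kind in ("treat_to_target", "feasible")
    if stochastic and rng is None:
        raise ValueError(f"regime kind {regime.kind!r} requires an rng")
    u = rng.uniform(size=3) if rng is not None else np.zeros(3)
    intervened, new_ldl, new_nonhdl = apply_regime(
        regime,
        np.asarray([stratum if not isinstance(stratum, str) else
                    {"low": LOW, "intermediate": INTERMEDIATE, "high": HIGH}[stratum]]),
        np.asarray([state["diabetes"]]),
        np.asarray([state.get("baseline_ldl", state["ldl"])]),
        np.asarray([state["ldl"]]),
        np.asarray([state["nonhdl"]]),
        u[0:1], u[1:2], u[2:3],
    )
    if regime.kind == "natural":
        reason = "not_eligible"
    elif intervened[0]:
        reason = "intervened"
    else:
        ldl_up, nonhdl_up = target_bounds(
            stratum, state["diabetes"], state.get("baseline_ldl", state["ldl"]))
        below = state["ldl"] < ldl_up and state["nonhdl"] < nonhdl_up
        reason = "target_met" if below else "non_adherent"
    return RegimeDecision(bool(intervened[0]), float(new_ldl[0]),
                          float(new_nonhdl[0]), reason)
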