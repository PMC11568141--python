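"""Monte Carlo standardisation engine: CIF arithmetic, determinism, regimes."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from lipidgf import engine as en
from lipidgf import models as md
from lipidgf import regimes as rg
from lipidgf import synthetic as sy


def enumerate_cif(h_y, h_d):
    """Independent oracle: exhaustive enumeration of the event-tree leaves.

    Within each interval the outcome occurs with probability h_y, else the
    competing event with probability h_d, else survival to the next interval.
    Every leaf (event year x event type, plus full survival) is visited with
    its probability computed by an explicit scalar product, independently of
    the vectorised implementation under test.
    """
    T = len(h_y)
    cif_y = np.zeros(T)
    cif_d = np.zeros(T)
    total = 0.0
    for k in range(T):
        for typ in ("y", "d"):
            prob = 1.0
            for j in range(k):
                prob = prob * (1 - h_y[j]) * (1 - h_d[j])
            if typ == "y":
                prob = prob * h_y[k]
                cif_y[k:] += prob
            else:
                prob = prob * (1 - h_y[k]) * h_d[k]
                cif_d[k:] += prob
            total += prob
    surv = 1.0
    for j in range(T):
        surv = surv * (1 - h_y[j]) * (1 - h_d[j])
    assert total + surv == pytest.approx(1.0, abs=1e-12)  # tree is exhaustive
    return cif_y, cif_d


class TestCumulativeIncidence:
    def test_matches_exhaustive_enumeration(self):
        """Closed-form CIF equals event-tree enumeration to 1e-12 for
        arbitrary hazard sequences up to 5 intervals."""
        rng = np.random.default_rng(42)
        for T in (1, 2, 3, 4, 5):
            for _ in range(10):
                h_y = rng.uniform(0, 0.9, T)
                h_d = rng.uniform(0, 0.9, T)
                risk, comp = sy.cif_from_hazards(h_y[None, :], h_d[None, :])
                ref_y, ref_d = enumerate_cif(h_y, h_d)
                np.testing.assert_allclose(risk, ref_y, atol=1e-12)
                np.testing.assert_allclose(comp, ref_d, atol=1e-12)

    def test_zero_hazard(self):
        risk, comp = sy.cif_from_hazards(np.zeros((3, 4)), np.zeros((3, 4)))
        assert (risk == 0).all() and (comp == 0).all()

    def test_constant_hazard_no_competition(self):
        risk, _ = sy.cif_from_hazards(np.full((1, 2), 0.1), np.zeros((1, 2)))
        assert risk[1] == pytest.approx(1 - 0.9**2)  # 0.19

    def test_constant_hazard_with_competition(self):
        risk, _ = sy.cif_from_hazards(np.full((1, 2), 0.1), np.full((1, 2), 0.1))
        assert risk[1] == pytest.approx(0.1 + 0.1 * 0.9 * 0.9)  # 0.181

    @settings(max_examples=60, derandomize=True)
    @given(st.lists(st.tuples(st.floats(0, 1), st.floats(0, 1)),
                    min_size=1, max_size=5))
    def test_enumeration_property(self, pairs):
        h_y = np.array([a for a, _ in pairs])
        h_d = np.array([b for _, b in pairs])
        risk, comp = sy.cif_from_hazards(h_y[None, :], h_d[None, :])
        ref_y, ref_d = enumerate_cif(h_y, h_d)
        np.testing.assert_allclose(risk, ref_y, atol=1e-12)
        np.testing.assert_allclose(comp, ref_d, atol=1e-12)
        assert (np.diff(risk) >= -1e-15).all()
        assert risk[-1] + comp[-1] <= 1 + 1e-12


def test_seed_determinism(dense_fitted):
    a = en.cumulative_incidence(
        en.simulate(dense_fitted, rg.treat_to_target(), n_mc=500, seed=11))
    b = en.cumulative_incidence(
        en.simulate(dense_fitted, rg.treat_to_target(), n_mc=500, seed=11))
    np.testing.assert_array_equal(a.risk, b.risk)
    c = en.cumulative_incidence(
        en.simulate(dense_fitted, rg.treat_to_target(), n_mc=500, seed=12))
    assert not np.array_equal(a.risk, c.risk)


def test_null_regime_equals_natural_course(dense_fitted):
    """A treat-to-target regime whose bounds are unreachable never alters
    values and reproduces the natural course exactly under a shared seed."""
    never = rg.RegimeSpec("treat_to_target", lb_fraction=1.0,
                          label="never_eligible")
    # unreachable bounds: raise targets far above any simulated lipid value
    import lipidgf.regimes as rmod
    nat = en.simulate(dense_fitted, rg.natural_course(), n_mc=800, seed=4)
    orig = rmod.target_bounds

    def huge_bounds(stratum, diabetes, baseline_ldl):
        ldl_up, nonhdl_up = orig(stratum, diabetes, baseline_ldl)
        return ldl_up + 1e6, nonhdl_up + 1e6

    rmod_engine = en.rg
    rmod_engine.target_bounds = huge_bounds
    try:
        null = en.simulate(dense_fitted, never, n_mc=800, seed=4)
    finally:
        rmod_engine.target_bounds = orig
    np.testing.assert_array_equal(nat.h_y, null.h_y)
    np.testing.assert_array_equal(nat.h_d, null.h_d)
    assert not null.intervened.any()


def test_invalid_simulation_arguments(dense_fitted):
    with pytest.raises(ValueError):
        en.simulate(dense_fitted, rg.natural_course(), n_mc=0, seed=1)
    with pytest.raises(ValueError):
        en.simulate(dense_fitted, rg.natural_course(), n_mc=10, seed=None)


def test_default_mc_size_matches_protocol(dense_fitted):
    import inspect
    assert inspect.signature(en.simulate).parameters["n_mc"].default == 10_000


def test_continuous_draws_truncated_to_observed_range(dense_fitted):
    """A model forced to predict far outside the data has its draws clamped
    to the observed range."""
    import copy
    fitted = copy.copy(dense_fitted)
    fitted.covariates = dict(dense_fitted.covariates)
    hacked = copy.copy(fitted.covariates["ldl"])
    hacked.params = hacked.params.copy()
    hacked.params[0] += 50.0  # intercept shift: mean prediction ~ +50
    fitted.covariates["ldl"] = hacked
    tr = en.simulate(fitted, rg.natural_course(), n_mc=200, seed=2)
    assert tr.truncations > 0
    hi = dense_fitted.covariates["ldl"].value_range[1]
    assert hi <= 10.0  # draws were recorded at the observed maximum, not +50


def test_monotone_dose_response(dense_fitted):
    """With a harmful LDL-C effect, 29-year risk is ordered natural >=
    feasible(0.8) >= full treat-to-target within 3 Monte Carlo SEs."""
    curves = {}
    for reg in (rg.natural_course(), rg.feasible(0.8), rg.treat_to_target()):
        curves[reg.label] = en.cumulative_incidence(
            en.simulate(dense_fitted, reg, n_mc=3000, seed=6))
    nat, f80, t2t = (curves[k] for k in
                     ("natural_course", "feasible_80", "treat_to_target"))
    tol = 3 * np.sqrt(nat.se[-1]**2 + t2t.se[-1]**2)
    assert nat.risk[-1] >= f80.risk[-1] - tol
    assert f80.risk[-1] >= t2t.risk[-1] - tol
    assert nat.risk[-1] > t2t.risk[-1]  # the effect itself is material


class TestNaturalCourseDiagnostic:
    def test_self_consistency(self, dense_pp, dense_fitted):
        """Data simulated from the fitted world agree with the fitted
        world's own natural course to within a small gap."""
        diag = en.natural_course_diagnostic(dense_pp, dense_fitted,
                                            n_mc=4000, seed=9)
        assert diag.max_abs_gap <= 0.02
        assert diag.observed.shape == diag.simulated.shape == (29,)

    def test_misspecification_widens_gap(self, dense_pp, dense_fitted):
        """Dropping the entire lipid block and the time trend from the
        outcome model on a process with strong LDL-C and age effects
        worsens the natural-course fit."""
        class CrippledSpec(md.ModelSpec):
            def hazard_terms(self):
                return [t for t in super().hazard_terms()
                        if t[0] == "const"
                        or (t[0] == "base" and t[1] == "female")
                        or (t[0] == "cur" and t[1] in ("smoking", "bmi"))]

        bad = md.fit_all(dense_pp, CrippledSpec())
        good = en.natural_course_diagnostic(dense_pp, dense_fitted,
                                            n_mc=4000, seed=9)
        worse = en.natural_course_diagnostic(dense_pp, bad, n_mc=4000, seed=9)
        assert worse.max_abs_gap > good.max_abs_gap


def test_nonparametric_cif_matches_lifelines(dense_pp):
    """Cross-check the discrete product-limit CIF against lifelines'
    Aalen-Johansen estimator on the same person-period data."""
    lifelines = pytest.importorskip("lifelines")
    risk, comp = en.nonparametric_cif(dense_pp)
    exits = dense_pp.groupby("pid").tail(1)
    # event time on the interval grid: use k+1 so year-k events are counted
    # by time k+1, matching R(t) = P(event by year t)
    durations = exits["k"].to_numpy() + 1
    events = np.where(exits["y"] == 1, 1, np.where(exits["c"] == 1, 2, 0))
    np.random.seed(0)  # lifelines jitters tied event times internally
    aj = lifelines.AalenJohansenFitter(calculate_variance=False, seed=0)
    aj.fit(durations, events, event_of_interest=1)
    # tie handling differs (we order the outcome hazard first within each
    # interval; the jittered AJ breaks ties at random), so agreement is to
    # O(h_y * h_d) per interval rather than exact
    # compare strictly inside the horizon: at the boundary, jittered event
    # times mix with administrative censoring at exactly 29
    col = aj.cumulative_density_.iloc[:, 0]
    for t in (5, 15, 28):
        ours = risk[t - 1]
        theirs = float(col.loc[: t + 0.5].iloc[-1])
        assert ours == pytest.approx(theirs, abs=5e-3)
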