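import pandas as pd
import pytest

from lipidgf import cohort as ch
from lipidgf import models as md
from lipidgf import synthetic as sy

DENSE_WAVES = tuple(range(29))


@pytest.fixture(scope="session")
def dense_params():
    """Moderate cohort with annual examinations (no LOCF gaps)."""
    return sy.DGPParams(n_participants=1500, seed=123, wave_years=DENSE_WAVES)


@pytest.fixture(scope="session")
def dense_cohort(dense_params):
    return sy.generate_cohort(dense_params)


@pytest.fixture(scope="session")
def dense_pp(dense_cohort):
    return ch.locf_fill(ch.expand_person_periods(dense_cohort), dense_cohort)


@pytest.fixture(scope="session")
def dense_fitted(dense_pp):
    return md.fit_all(dense_pp)


@pytest.fixture(scope="session")
def sparse_cohort():
    """Small cohort with the default sparse waves (exercises LOCF)."""
    return sy.generate_cohort(sy.DGPParams(n_participants=400, seed=7))


def make_profile(**kw):
    """A complete, unremarkable low-risk covariate profile."""
    base = dict(age=46.0, female=1.0, smoking=0.0, bmi=23.0, sbp=118.0,
                dbp=76.0, tc=4.5, hdl=1.4, ldl=2.5, nonhdl=3.1, tg=1.2,
                glucose=4.0, diabetes=0.0, antihtn=0.0, lipidrx=0.0)
    base.update(kw)
    return base


@pytest.fixture
def profile():
    return make_profile


def person_period_state(**kw):
    """Minimal person-period state mapping for regime decisions."""
    s = dict(ldl=3.0, nonhdl=3.7, diabetes=0.0, baseline_ldl=3.0)
    s.update(kw)
    return s
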