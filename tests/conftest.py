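import numpy as np
import pytest

from rascore import cohort as ch
from rascore import datasets as ds
from rascore import synthetic as syn


@pytest.fixture(scope="session")
def reference_table():
    return ds.reference_score_table()


@pytest.fixture(scope="session")
def default_cohort():
    """One default synthetic cohort (n=641), generated once per session."""
    return syn.generate_frame(syn.GeneratorConfig(seed=20240101))


@pytest.fixture(scope="session")
def solved_intercept():
    """Intercept of the default generator, solved once and reused by tests
    that generate many replicate cohorts."""
    cfg = syn.GeneratorConfig(seed=0)
    return syn.generate_frame(cfg).attrs["intercept"]


def make_record(**overrides) -> ch.PatientRecord:
    base = dict(
        id="p1", age=62.0, male=True, bmi=25.0, hypertension=True, n_ahm=2,
        diabetes=False, smoking=False, total_chol=180.0, hdl_chol=45.0,
        triglyceride=120.0, creatinine=0.9, upcr=50.0, cimt=0.85,
        cap_extent="none", cad_significant=False, ras_significant=False,
    )
    base.update(overrides)
    return ch.PatientRecord(**base)


@pytest.fixture
def record_factory():
    return make_record
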