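import numpy as np
import pytest

import busulfanpk as b


@pytest.fixture(scope="session")
def final_pop():
    return b.final_model()


@pytest.fixture(scope="session")
def small_cohort():
    """40-subject synthetic cohort under the packaged final model."""
    ds, truth = b.generate_cohort(b.CohortSpec(n_subjects=40), seed=123)
    return ds, truth


@pytest.fixture(scope="session")
def cohort124():
    """Full study-size cohort (124 subjects) under the packaged final model."""
    ds, truth = b.generate_cohort(seed=123)
    return ds, truth


@pytest.fixture(scope="session")
def cohort124_fixed_design():
    """Study-size cohort without TDM dose feedback.

    With adaptive dosing the realized concentrations are partially
    homogenized against each subject's clearance, so they are not
    exchangeable with standard model resimulations; simulation-based
    calibration checks (npde, vpc) therefore use this fixed-design cohort.
    """
    ds, truth = b.generate_cohort(b.CohortSpec(tdm=False), seed=123)
    return ds, truth


@pytest.fixture(scope="session")
def small_fit(small_cohort):
    """A quick final-model SAEM fit of the 40-subject cohort."""
    ds, _ = small_cohort
    settings = b.SaemSettings(exploration=300, smoothing=80, seed=5)
    return b.fit_saem(ds, b.final_model_spec(), settings)


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)
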