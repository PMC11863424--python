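import dataclasses

import numpy as np
import pytest

import span_mortality as sm
from span_mortality import cohort_prep, survival


@pytest.fixture(scope="session")
def scales():
    return sm.default_scales()


def _prepare(cohort):
    """Winsorize exposures and attach joint tertile cells."""
    cohort = cohort.copy()
    for e in survival.EXPOSURES:
        cohort[e] = cohort_prep.winsorize(cohort[e].to_numpy()).values
    cuts = {e: cohort_prep.tertile_cuts(cohort[e], name=e) for e in survival.EXPOSURES}
    return cohort_prep.assign_joint_categories(
        cohort, cuts["sleep"], cuts["mvpa"], cuts["dqs"]
    )


@pytest.fixture(scope="session")
def prepared_cohort():
    """A mid-size protective-truth cohort, prepared for modelling."""
    cfg = sm.SyntheticCohortConfig(n_participants=15_000, seed=11)
    cohort = sm.generate_cohort(cfg)
    cohort, _ = cohort_prep.apply_exclusions(
        cohort, {"death_in_first_year": True},
        covariate_cols=["age", "sex", "confounder"],
    )
    return _prepare(cohort)


@pytest.fixture(scope="session")
def joint_fit(prepared_cohort):
    return survival.fit_joint_tertile_model(
        prepared_cohort, covariate_cols=("age", "sex", "confounder")
    )


@pytest.fixture(scope="session")
def cont_fit(prepared_cohort):
    return survival.fit_continuous_model(
        prepared_cohort, covariate_cols=("age", "sex", "confounder")
    )


@pytest.fixture(scope="session")
def small_config():
    return dataclasses.replace(
        sm.SyntheticCohortConfig(), n_participants=4_000, seed=5
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
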