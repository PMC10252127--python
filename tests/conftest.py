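import warnings

import numpy as np
import pytest

from curemix import datagen, pipeline


@pytest.fixture(scope="session")
def study_cohort():
    """One synthetic study-like cohort (n=446) shared across tests."""
    return datagen.simulate_cohort(datagen.study_cohort_spec(n=446, seed=42))


@pytest.fixture(scope="session")
def encoded_study(study_cohort):
    return pipeline.encode_analysis_variables(study_cohort.table)


@pytest.fixture(scope="session")
def simple_cure_spec():
    """Small generating truth with one continuous and one binary covariate."""
    return datagen.CohortSpec(
        n=2000,
        covariates=[
            datagen.Continuous("x1", "normal", {"loc": 0.0, "scale": 1.0}),
            datagen.Categorical("arm", ["a", "b"], [0.5, 0.5]),
        ],
        b={"intercept": -0.5, "x1": 0.5, "arm=b": -0.4},
        beta={"x1": 0.6, "arm=b": -0.5},
        baseline=datagen.WeibullBaseline.from_median(1.6, 1.2),
        censor_window=(1.0, 8.5),
        seed=7,
    )


def build_simple_design(cohort):
    """CureDesign for cohorts drawn from ``simple_cure_spec``."""
    from curemix import CureDesign

    df = cohort.table.copy()
    df["arm_b"] = (df["arm"] == "b").astype(float)
    return CureDesign.build(df, ["x1", "arm_b"], ["x1", "arm_b"])


@pytest.fixture
def quiet_warnings():
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        yield


def rng_stream(seed):
    return np.random.default_rng(np.random.SeedSequence(seed))
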