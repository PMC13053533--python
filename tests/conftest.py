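import numpy as np
import pytest

from extval import (
    LogisticPredictionModel,
    PredictorSpec,
    development_spec,
    generate_cohort,
    validation_spec,
)


@pytest.fixture(scope="session")
def dev_spec():
    return development_spec(seed=101)


@pytest.fixture(scope="session")
def val_spec(dev_spec):
    return validation_spec(seed=202, dev=dev_spec)


@pytest.fixture(scope="session")
def dev_cohort(dev_spec):
    return generate_cohort(dev_spec)


@pytest.fixture(scope="session")
def val_cohort(val_spec):
    return generate_cohort(val_spec)


@pytest.fixture
def toy_model():
    return LogisticPredictionModel(
        intercept=-1.0,
        coefficients={"x1": 0.8, "x2": -0.5},
        predictors=(
            PredictorSpec("x1", "continuous", "unit"),
            PredictorSpec("x2", "continuous", "unit"),
        ),
        label="toy",
    )


def random_model(rng: np.random.Generator, k: int = 7) -> LogisticPredictionModel:
    names = [f"p{i}" for i in range(k)]
    return LogisticPredictionModel(
        intercept=float(rng.normal()),
        coefficients={n: float(rng.normal()) for n in names},
        predictors=tuple(PredictorSpec(n, "continuous", "u") for n in names),
        label="random",
    )
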