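import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from molarage.synthetic import GeneratorConfig, generate_cohort

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def default_cohort() -> pd.DataFrame:
    """The reference synthetic cohort used across modules (n=200, seed 1)."""
    return generate_cohort(GeneratorConfig(n_participants=200, seed=1))


@pytest.fixture(scope="session")
def large_cohort() -> pd.DataFrame:
    return generate_cohort(GeneratorConfig(n_participants=500, seed=1))


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(42)


def make_series(n=200, seed=0, slope=-0.07, intercept_f=-1.18, gap=0.11,
                sigma2=8e-4, variance="age", sex_ratio=0.5) -> pd.DataFrame:
    """Directly simulated ln-ratio series from the generating regression law.

    variance: 'age' => Var = sigma2*age (matches the 1/age weighting),
    'constant' => Var = sigma2.
    """
    g = np.random.default_rng(seed)
    age = g.uniform(14, 24, n)
    sex = np.where(g.random(n) < sex_ratio, "F", "M")
    mu = np.where(sex == "F", intercept_f, intercept_f + gap) + slope * age
    v = age if variance == "age" else np.ones(n)
    y = mu + g.normal(0, np.sqrt(sigma2 * v))
    return pd.DataFrame(
        {"participant_id": [f"S{i}" for i in range(n)], "sex": sex,
         "age_years": age, "y": y}
    )
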