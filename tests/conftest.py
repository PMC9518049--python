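import numpy as np
import pandas as pd
import pytest

from rplogit.data import CrashDataset
from rplogit.design import build_design
from rplogit.simulate import (
    GeneratorConfig,
    default_spec,
    default_truth,
    generate_dataset,
)
from rplogit.spec import ParameterSet, SeveritySpec, Term


@pytest.fixture(scope="session")
def mixed_spec() -> SeveritySpec:
    return default_spec()


@pytest.fixture(scope="session")
def mixed_truth() -> ParameterSet:
    return default_truth()


@pytest.fixture(scope="session")
def small_dataset(mixed_spec) -> CrashDataset:
    """300 synthetic crashes from the default truth; enough to exercise
    every code path without slowing the suite."""
    return generate_dataset(GeneratorConfig(n_obs=300, seed=42))


@pytest.fixture(scope="session")
def small_design(small_dataset, mixed_spec):
    return build_design(small_dataset, mixed_spec)


@pytest.fixture
def tiny_mnl_spec() -> SeveritySpec:
    return SeveritySpec(
        constants=["MI", "SI", "FI"],
        terms=[Term("a", "MI"), Term("b", "FI")],
    )


@pytest.fixture
def tiny_dataset() -> CrashDataset:
    rng = np.random.default_rng(7)
    n = 60
    df = pd.DataFrame(
        {
            "a": rng.integers(0, 2, n),
            "b": rng.integers(0, 2, n),
            "outcome": rng.choice(["NI", "MI", "SI", "FI"], n),
            "period": "2017",
            "group": "helmet",
        }
    )
    return CrashDataset(df=df, variables=["a", "b"])
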