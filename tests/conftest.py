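import numpy as np
import pandas as pd
import pytest

from methdriver import BetaMatrix, GeneratorConfig, OmicsMatrix, generate_cohort


@pytest.fixture(scope="session")
def small_config() -> GeneratorConfig:
    """Compact cohort for unit tests: 60 tumors, 15 normals, 20 genes."""
    return GeneratorConfig(
        n_tumor=60,
        n_normal=15,
        n_driver_hyper=4,
        n_driver_hypo=4,
        n_buffered=4,
        n_null=8,
    )


@pytest.fixture(scope="session")
def small_cohort(small_config):
    return generate_cohort(small_config, seed=11)


@pytest.fixture()
def beta_matrix() -> BetaMatrix:
    rng = np.random.default_rng(3)
    values = pd.DataFrame(
        rng.random((5, 4)),
        index=[f"S{i}" for i in range(5)],
        columns=[f"cg{i}" for i in range(4)],
    )
    return BetaMatrix(values=values)


@pytest.fixture()
def omics_matrix() -> OmicsMatrix:
    rng = np.random.default_rng(4)
    values = pd.DataFrame(
        rng.normal(8, 2, (6, 5)),
        index=[f"S{i}" for i in range(6)],
        columns=[f"G{i}" for i in range(5)],
    )
    return OmicsMatrix(values=values, kind="expression")
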