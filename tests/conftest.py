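import numpy as np
import pytest

from ductld import (
    HarmonicBasis,
    build_coupling_table,
    run_steady,
    run_transient,
    standard_config,
)


@pytest.fixture(scope="session")
def basis10():
    return HarmonicBasis(10)


@pytest.fixture(scope="session")
def table10(basis10):
    return build_coupling_table(basis10)


@pytest.fixture(scope="session")
def basis8():
    return HarmonicBasis(8)


@pytest.fixture(scope="session")
def table8(basis8):
    return build_coupling_table(basis8)


@pytest.fixture(scope="session")
def basis4():
    return HarmonicBasis(4)


@pytest.fixture(scope="session")
def table4(basis4):
    return build_coupling_table(basis4)


@pytest.fixture(scope="session")
def coarse_steady():
    """Standard-parameter steady run at the coarse test preset."""
    cfg = standard_config(Y=40, Z=32, N=8)
    result, summary, groups = run_steady(cfg)
    return cfg, result, summary, groups


@pytest.fixture(scope="session")
def small_oscillatory():
    """Small standard-parameter oscillatory run shared across tests."""
    cfg = standard_config(Y=24, Z=16, N=6)
    cfg = cfg.model_copy(
        update={
            "oscillation": cfg.oscillation.model_copy(
                update={"steps_per_period": 300, "n_periods": 4}
            )
        }
    )
    record, final, summary, groups = run_transient(cfg)
    return cfg, record, final, summary, groups


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
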