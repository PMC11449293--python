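import numpy as np
import pytest

from plateletpop import (
    AnnulusScheme,
    DelayDistribution,
    DiffusionParams,
    SyntheticConfig,
    ThresholdDistribution,
)


@pytest.fixture(scope="session")
def field() -> DiffusionParams:
    """Reference agonist field: ADP0 = 1.5e-5 M, D = 257 um^2/s, 80 um spot."""
    return DiffusionParams()


@pytest.fixture(scope="session")
def ref_thresholds() -> ThresholdDistribution:
    """Threshold law with median ~5e-7 M and moderate spread."""
    return ThresholdDistribution(mu=-14.5, sigma=1.7)


@pytest.fixture(scope="session")
def delays() -> DelayDistribution:
    return DelayDistribution(mu_d=0.7, sigma_d=0.3)


@pytest.fixture(scope="session")
def scheme() -> AnnulusScheme:
    return AnnulusScheme()


@pytest.fixture()
def tiny_config() -> SyntheticConfig:
    """Small, fast synthetic experiment for I/O and CLI tests."""
    return SyntheticConfig(
        n_cells=300,
        duration_s=90.0,
        flash_time_s=30.0,
        seed=7,
    )
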