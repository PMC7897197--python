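import numpy as np
import pytest

from t1norm import AcquisitionProtocol, CohortConfig, PipelineConfig


@pytest.fixture(scope="session")
def protocol() -> AcquisitionProtocol:
    return AcquisitionProtocol()


@pytest.fixture(scope="session")
def times(protocol):
    from t1norm import frame_times

    return frame_times(protocol)


@pytest.fixture(scope="session")
def small_cohort_cfg() -> CohortConfig:
    return CohortConfig(n_subjects=4, master_seed=42)


@pytest.fixture(scope="session")
def small_pipeline(small_cohort_cfg, protocol) -> PipelineConfig:
    return PipelineConfig(protocol=protocol, cohort=small_cohort_cfg)


@pytest.fixture(scope="session")
def fitted_small_cohort(small_pipeline):
    """Measurements and ages of a 4-subject end-to-end imaging run."""
    from t1norm import fit_cohort

    return fit_cohort(small_pipeline)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(2024)
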