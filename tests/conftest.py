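import pytest
from hypothesis import settings

settings.register_profile("ci", deadline=None, derandomize=True, max_examples=60)
settings.load_profile("ci")

from csmsim import CsmDecisionModel  # noqa: E402


@pytest.fixture(scope="session")
def fitted():
    """Calibrated model results shared across the suite (calibration is
    deterministic, so sharing does not couple tests)."""
    return CsmDecisionModel().fit()


@pytest.fixture(scope="session")
def calibrated_config(fitted):
    return fitted.config


@pytest.fixture(scope="session")
def calibrated_config_file(calibrated_config, tmp_path_factory):
    """A calibrated config on disk, for CLI tests that must not re-fit."""
    path = tmp_path_factory.mktemp("cfg") / "calibrated.yaml"
    calibrated_config.save(path)
    return path
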