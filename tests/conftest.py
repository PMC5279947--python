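import pandas as pd
import pytest

from synredist import ModelParams, average_by_intensity, exclude_saturated, make_sweeps, preset_config


@pytest.fixture(scope="session")
def default_params() -> ModelParams:
    return ModelParams()


@pytest.fixture(scope="session")
def mini_params() -> ModelParams:
    """A miniature parameter set for brute-force cross-checks."""
    return ModelParams(total_cells=200, horizon=10, prolif_scale=400.0)


@pytest.fixture(scope="session")
def control_responses() -> pd.DataFrame:
    """Averaged, de-saturated responses from the control-mature preset."""
    sweeps = make_sweeps(preset_config("control", seed=1))
    return exclude_saturated(average_by_intensity(sweeps))
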