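import numpy as np
import pytest

from redsnow import (
    CalibrationCurve,
    CountSimParams,
    SceneParams,
    generate_count_table,
    generate_scene,
)


@pytest.fixture(scope="session")
def calib():
    return CalibrationCurve()


@pytest.fixture(scope="session")
def small_scene():
    """Noise-free 64x64 mixed scene with exact truth bookkeeping."""
    return generate_scene(SceneParams(n_rows=64, n_cols=64, seed=11))


@pytest.fixture(scope="session")
def noisy_scene():
    return generate_scene(
        SceneParams(n_rows=64, n_cols=64, seed=12, reflectance_noise_sd=0.01)
    )


@pytest.fixture(scope="session")
def null_count_table():
    """Two exchangeable groups: no differential features."""
    return generate_count_table(
        CountSimParams(n_differential=0, log_fold_effect=0.0, seed=5)
    )


@pytest.fixture(scope="session")
def effect_count_table():
    """Strong between-group shift (the power-fixture conditions)."""
    return generate_count_table(CountSimParams(seed=5))
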