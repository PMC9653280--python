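"""Shared fixtures: built models and expensive session-scoped computations."""

import numpy as np
import pytest

from oocmech import materials, pipeline


@pytest.fixture(scope="session")
def mats():
    return materials.MaterialTable()


@pytest.fixture(scope="session")
def sec85(mats):
    return materials.build_section(8.5, mats)


@pytest.fixture(scope="session")
def small_system(mats):
    """Short dry model (0.2 mm span) for structural unit tests."""
    cfg = pipeline.ModelConfig(span_mm=0.2, with_fluid=False)
    system, _ = pipeline.build_model(cfg, mats)
    return system


@pytest.fixture(scope="session")
def coupled_model(mats):
    """Default working model (0.6 mm span) with its chamber coupling."""
    cfg = pipeline.ModelConfig()
    return pipeline.build_model(cfg, mats)


@pytest.fixture(scope="session")
def calibrated_cfg():
    """Configuration with the BM modulus matched to the measured volume
    compliance of 16.1 mm^4/N at x = 8.5 mm."""
    cfg, achieved = pipeline.calibrate_bm_modulus(pipeline.ModelConfig())
    return cfg, achieved


@pytest.fixture(scope="session")
def rtm_sweep():
    return pipeline.sweep_ratio(pipeline.ModelConfig(), "rtm",
                                frequency=1000.0)


@pytest.fixture(scope="session")
def rdc_sweep():
    return pipeline.sweep_ratio(pipeline.ModelConfig(), "rdc",
                                frequency=1000.0)


@pytest.fixture(scope="session")
def fullspan_response():
    """Hydrophone-normalized BM response of the 4 mm excised-turn model."""
    freqs = np.geomspace(300.0, 5000.0, 25)
    return pipeline.frequency_response(pipeline.full_span_config(), freqs)
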