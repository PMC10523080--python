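import numpy as np
import pytest

from tibstrain.synthgeom import TemplateConfig, build_template, generate_cohort

COARSE = dict(axial_sections=8, circumferential_sections=8)


@pytest.fixture(scope="session")
def coarse_config():
    return TemplateConfig(**COARSE)


@pytest.fixture(scope="session")
def coarse_template(coarse_config):
    return build_template(coarse_config)


@pytest.fixture(scope="session")
def small_cohort(coarse_config):
    """Six-subject cohort on the coarse template (session-cached)."""
    return generate_cohort(6, seed=7, config=coarse_config)


@pytest.fixture
def rng():
    return np.random.default_rng(42)
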