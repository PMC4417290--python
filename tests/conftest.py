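import pytest
from hypothesis import settings

settings.register_profile("default", derandomize=True, max_examples=50)
settings.load_profile("default")

from her2sig import GeneratorConfig, make_cohort, make_references


@pytest.fixture(scope="session")
def default_cfg():
    """Study-condition generator config (45 tumors, 28 genes, 8 informative)."""
    return GeneratorConfig(seed=1234)


@pytest.fixture(scope="session")
def refs(default_cfg):
    return make_references(default_cfg)


@pytest.fixture(scope="session")
def cohort(default_cfg):
    return make_cohort(default_cfg)


@pytest.fixture(scope="session")
def small_cfg():
    """10-gene panel with 4 informative genes; small cohort for oracles."""
    return GeneratorConfig(
        seed=77,
        n_tumors=20,
        pcr_fraction=0.5,
        panel_size=10,
        n_informative=4,
        archetype_separation=2.0,
        noise_sd=1.0,
    )
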