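import pytest
from hypothesis import HealthCheck, settings

from ricewash.registry import PesticideRegistry, PesticideSpec
from ricewash.simulate import SimConfig, simulate_study

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[
        HealthCheck.too_slow,
        # immutable (frozen-dataclass) fixtures are safe to share across examples
        HealthCheck.function_scoped_fixture,
    ],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def registry():
    from ricewash.registry import default_registry

    return default_registry()


@pytest.fixture
def spec():
    """A synthetic analyte with calibration references set."""
    return PesticideSpec(
        name="Testazole",
        loq=5.0,
        linear_range=(5.0, 100.0),
        rt_mean_calibration=5.30,
        ir_mean_calibration=50.0,
    )


@pytest.fixture
def mini_registry(spec):
    return PesticideRegistry([spec])


@pytest.fixture(scope="session")
def noiseless_study(registry):
    """Three-analyte study with every noise source switched off."""
    config = SimConfig(
        seed=7,
        analytes=("Pirimiphos-methyl", "Diazinon", "Fludioxonil"),
        cv_repeatability=0.0,
        cv_reproducibility=0.0,
        rt_jitter_sd=0.0,
    )
    return simulate_study(config, registry)
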