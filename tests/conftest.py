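import pytest

from spongeflux.synth import GeneratorConfig, generate_experiment


@pytest.fixture(scope="session")
def exact_bundle():
    """geodia_dom bundle with measurement noise off: exact forward model."""
    return generate_experiment(GeneratorConfig(preset="geodia_dom", seed=7, noise=0.0))


@pytest.fixture(scope="session")
def noisy_bundle():
    """vazella_bacteria bundle at default noise."""
    return generate_experiment(GeneratorConfig(preset="vazella_bacteria", seed=11))
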