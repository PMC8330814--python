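import pytest
from hypothesis import HealthCheck, settings

import weedcomp as wc

settings.register_profile(
    "det",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("det")


@pytest.fixture(scope="session")
def noise_free_trial():
    """Exact combined-model data: no noise, no sterility, no dropout."""
    design = wc.TrialDesign(dropout_rate=0.0)
    config = wc.GeneratorConfig(noise_sd=0.0, sterility_enabled=False, seed=3)
    obs, levels = wc.generate_trial(design, config)
    return obs, levels, config


@pytest.fixture(scope="session")
def noisy_trial():
    """Combined-model data with the default 0.5 t/ha yield noise."""
    design = wc.TrialDesign()
    config = wc.GeneratorConfig(noise_sd=0.5, sterility_enabled=False, seed=7)
    obs, levels = wc.generate_trial(design, config)
    return obs, levels, config


@pytest.fixture(scope="session")
def heatwave_trial():
    """Study-like data: sterility collapse in the hot year, both species."""
    design = wc.TrialDesign(species=("late_watergrass", "water_chestnut"))
    config = wc.GeneratorConfig(noise_sd=0.5, sterility_enabled=True, seed=11)
    obs, levels = wc.generate_trial(design, config)
    return obs, levels, config
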