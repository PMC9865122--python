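import numpy as np
import pytest

from abtox import ScreenDesign, compute_growth_ratios, simulate_screen


@pytest.fixture(scope="session")
def noisy_screen():
    """Small noisy screen with all planted classes, shared across tests."""
    design = ScreenDesign(
        n_strains=400, enhancer_fraction=0.05, protective_fraction=0.05,
        gal_deficient_fraction=0.02, glu_deficient_fraction=0.05,
        noise_cv=0.10, rng_seed=2)
    measurements, truth = simulate_screen(design)
    return design, measurements, truth


@pytest.fixture(scope="session")
def noisy_scores(noisy_screen):
    _, measurements, _ = noisy_screen
    return compute_growth_ratios(measurements)


@pytest.fixture(scope="session")
def zero_noise_screen():
    """Noise-free screen: every ratio equals its configured multiplier."""
    design = ScreenDesign(
        n_strains=200, enhancer_fraction=0.10, protective_fraction=0.10,
        gal_deficient_fraction=0.05, glu_deficient_fraction=0.05,
        noise_cv=0.0, rng_seed=11)
    measurements, truth = simulate_screen(design)
    return design, measurements, truth


@pytest.fixture
def rng():
    return np.random.default_rng(0)
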