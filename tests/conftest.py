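import numpy as np
import pytest

from pentaspin import (PentamerSpinSystem, InversionSettings,
                       generate_deer_trace)

PENTAGON_D1 = 25.0
RING_RADIUS = PENTAGON_D1 / (2.0 * np.sin(np.radians(36.0)))


@pytest.fixture(scope="session")
def clean_pentamer_system():
    """Fully labeled, noise-free pentamer with D1 = 25 A."""
    return PentamerSpinSystem(ring_radius=RING_RADIUS, site_spread=0.0,
                              labeling_f=1.0, lambda_inv=0.46,
                              bg_rate=0.0, noise_sigma=0.0, seed=1)


@pytest.fixture(scope="session")
def noisy_pentamer_trace():
    """Realistic noisy trace with background: the inversion workhorse."""
    system = PentamerSpinSystem(ring_radius=RING_RADIUS, site_spread=1.0,
                                labeling_f=0.8, lambda_inv=0.46,
                                bg_rate=0.12, noise_sigma=0.01, seed=7)
    trace, truth = generate_deer_trace(system, 8.0, 0.02, n_configs=1024)
    return trace, truth


@pytest.fixture(scope="session")
def fast_inversion_settings():
    """Reduced r-grid and alpha-grid for quick inversions in tests."""
    return InversionSettings(r_min=15.0, r_max=60.0, n_r=91,
                             alpha_grid=tuple(np.logspace(-3, 2, 12)))
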