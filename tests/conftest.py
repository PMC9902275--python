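import numpy as np
import pytest

from isletpulse import (StackConfig, compute_ratio_stack, make_oxygen_gradient,
                        simulate_fura_stack)


@pytest.fixture(scope="session")
def default_cfg():
    return StackConfig()


@pytest.fixture(scope="session")
def half_gradient(default_cfg):
    return make_oxygen_gradient(default_cfg.width, 20.0, "half")


@pytest.fixture(scope="session")
def default_stack(default_cfg, half_gradient):
    return simulate_fura_stack(default_cfg, half_gradient)


@pytest.fixture(scope="session")
def default_ratio_stack(default_stack):
    return compute_ratio_stack(default_stack.ch340, default_stack.ch380,
                               default_stack.times)


@pytest.fixture(scope="session")
def clean_cfg():
    """Noise-free, banding-free configuration for closed-form oracles."""
    return StackConfig(noise_sd=0.0, plateau_noise_sd=0.0,
                       banding_amplitude=0.0, width=64, height=8)


@pytest.fixture(scope="session")
def clean_stack(clean_cfg):
    grad = make_oxygen_gradient(clean_cfg.width, 20.0, "half")
    return simulate_fura_stack(clean_cfg, grad), grad


def naive_dft_cog(values, dt):
    """O(N^2) DFT-by-definition center-of-gravity oracle (per hour)."""
    v = np.asarray(values, dtype=float)
    n = v.size
    num = 0.0
    den = 0.0
    for k in range(1, n // 2 + 1):
        xk = sum(v[m] * np.exp(-2j * np.pi * k * m / n) for m in range(n))
        mag = abs(xk)
        num += (k / (n * dt)) * mag
        den += mag
    return 0.0 if den == 0 else 60.0 * num / den
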