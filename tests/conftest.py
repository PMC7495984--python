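import numpy as np
import pytest

from eeggc import (Montage, default_session_plan, simulate_session,
                   standard_montage_31)


@pytest.fixture(scope="session")
def montage31():
    return standard_montage_31()


@pytest.fixture(scope="session")
def short_session():
    """One default 20-min session with ground truth (shared across tests)."""
    plan = default_session_plan(seed=7, duration="short")
    return simulate_session(plan)


@pytest.fixture(scope="session")
def square_montage():
    return Montage(("A", "B", "C", "D"),
                   np.array([[0.0, 0.0], [1.0, 0.0], [0.0, 1.0], [1.0, 1.0]]))


def stable_random_varspec(rng, n_channels=2, order=3, diag=0.3, scale=0.18,
                          max_radius=0.95, noise_corr=None):
    """Rejection-sample a stable random VAR spec (test helper)."""
    from eeggc import VARSpec

    while True:
        coeffs = rng.normal(0.0, scale, (order, n_channels, n_channels))
        coeffs[0] += diag * np.eye(n_channels)
        try:
            c = rng.uniform(-0.4, 0.4) if noise_corr is None else noise_corr
            cov = np.eye(n_channels)
            if n_channels == 2:
                cov = np.array([[1.0, c], [c, 1.0]])
            spec = VARSpec(coeffs, cov, 125.0)
        except ValueError:
            continue
        if spec.spectral_radius < max_radius:
            return spec
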