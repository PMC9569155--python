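import numpy as np
import pytest

import kinrates as kr


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture(scope="session")
def gomp():
    """A mid-range Gompertz truth used across tests."""
    return kr.GompertzParams(mu_star=0.8, lag=2.0)


@pytest.fixture(scope="session")
def noiseless_gompertz_well(gomp):
    """Noise-free simulated well for a Gompertz growth truth."""
    cfg = kr.SimConfig()
    noise = kr.NoiseSpec(sigma=0.0)
    well = kr.simulate_well(
        lambda t: kr.gompertz_growth_rate(gomp, t),
        lambda t: np.zeros_like(np.asarray(t, float)),
        noise=noise,
        config=cfg,
        b0=float(kr.gompertz_biomass(gomp, 0.0)),
        seed=0,
    )
    return well, noise


@pytest.fixture(scope="session")
def noiseless_expression_well():
    """Noise-free well with a random-walk expression truth (fixed seed)."""
    from kinrates.simulate import gompertz_instance

    noise = kr.NoiseSpec(sigma=0.0)
    well, params, phi = gompertz_instance(
        np.random.default_rng(7), noise=noise, with_expression=True
    )
    return well, params, phi, noise


def euler_oracle(mu_fn, phi_fn, b0, y0, gamma, t_end, dt=1e-4):
    """Independent fine-step explicit Euler integration of the forward model.

    Vectorized recurrences: B_{i+1} = B_i (1 + dt mu_i) via cumulative
    product; y_{i+1} = a y_i + dt B_i phi_i with a = 1 - gamma dt via the
    scaled cumulative sum.
    """
    n = int(round(t_end / dt))
    t = dt * np.arange(n + 1)
    mu = np.asarray(mu_fn(t), float) + np.zeros_like(t)
    phi = np.asarray(phi_fn(t), float) + np.zeros_like(t)
    B = np.empty(n + 1)
    B[0] = b0
    B[1:] = b0 * np.cumprod(1.0 + dt * mu[:-1])
    a = 1.0 - gamma * dt
    drive = dt * B[:-1] * phi[:-1]
    y = np.empty(n + 1)
    y[0] = y0
    if gamma == 0.0:
        y[1:] = y0 + np.cumsum(drive)
    else:
        powers = a ** np.arange(1, n + 1)
        y[1:] = powers * (y0 + np.cumsum(drive / (a ** np.arange(1, n + 1))))
    return t, B, y
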