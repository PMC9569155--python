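"""Synthetic plate-reader kinetics with known ground truth.

Generates the benchmark substrate: Gompertz biomass with random parameters,
smoothed lognormal random-walk expression profiles, forward-Euler
integration of the measurement model, multiplicative white measurement
noise, additive background, plus the blank-media and no-reporter control
wells used by the background-correction path.

The Gompertz growth law is

    log(B / B0) = A * exp(-exp(mu_star * e * (lag - t) / A + 1)),
    A = log(B_max / B0),

whose implied specific growth rate

    mu(t) = mu_star * exp[ mu_star*e*(lag - t)/A
                           - exp(mu_star*e*(lag - t)/A + 1) + 2 ]

peaks at exactly ``mu_star`` at ``t = lag + A / (mu_star * e)``.

Measurements are formed as ``B_t = (B(t) + B')(1 + eps_t)`` and
``y_t = (y(t) + y')(1 + zeta_t)`` with ``eps, zeta`` independent white noise
of standard deviation ``sigma`` and backgrounds ``B' = y' = 0.1``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Callable, Optional

import numpy as np
from scipy.signal import savgol_filter

from .basis import GriddedProfile
from .timeseries import TimeSeries

__all__ = [
    "GompertzParams",
    "NoiseSpec",
    "SimConfig",
    "random_expression_profile",
    "gompertz_biomass",
    "gompertz_growth_rate",
    "sample_gompertz",
    "simulate_well",
    "simulate_controls",
    "SimulatedWell",
]

MU_STAR_RANGE = (0.5, 1.0)  # 1/h, uniform
LAG_RANGE = (0.0, 4.0)  # h, uniform


@dataclass(frozen=True)
class GompertzParams:
    """Gompertz growth-law parameters (simulation ground truth)."""

    mu_star: float  # maximal growth rate, 1/h
    lag: float  # lag phase length, h
    b0: float = 0.01  # minimum biomass, OD
    b_max: float = 1.0  # maximal biomass, OD

    def __post_init__(self):
        if self.mu_star <= 0 or self.lag < 0:
            raise ValueError("mu_star must be positive and lag nonnegative")
        if not 0 < self.b0 < self.b_max:
            raise ValueError("require 0 < b0 < b_max")

    @property
    def a(self) -> float:
        """``A = log(B_max / B0)``, dimensionless."""
        return float(np.log(self.b_max / self.b0))

    @property
    def peak_time(self) -> float:
        """Time of maximal growth rate, ``lag + A / (mu_star * e)``."""
        return self.lag + self.a / (self.mu_star * np.e)


@dataclass(frozen=True)
class NoiseSpec:
    """Measurement-noise settings: multiplicative scale and backgrounds."""

    sigma: float = 0.05  # std of the multiplicative noise
    bg_biomass: float = 0.1  # B', OD units
    bg_fluor: float = 0.1  # y', a.u.

    def __post_init__(self):
        if self.sigma < 0:
            raise ValueError("sigma must be nonnegative")


@dataclass(frozen=True)
class SimConfig:
    """Integration and random-profile settings."""

    dt: float = 2.4e-2  # forward-Euler step, h
    horizon: float = 24.0  # h
    sample_every: int = 10  # Euler steps per measurement (0.24 h cadence)
    rw_sigma2: float = 0.25  # variance of log xi in the random walk
    rw_window: int = 21  # Savitzky-Golay smoothing window
    rw_order: int = 2

    def __post_init__(self):
        if self.dt <= 0 or self.horizon <= 0:
            raise ValueError("dt and horizon must be positive")
        steps = self.horizon / self.dt
        if abs(steps - round(steps)) > 1e-9:
            raise ValueError("horizon must be an integral number of steps")

    @property
    def n_steps(self) -> int:
        return int(round(self.horizon / self.dt))

    def euler_grid(self) -> np.ndarray:
        return self.dt * np.arange(self.n_steps + 1)

    def measurement_grid(self) -> np.ndarray:
        return self.euler_grid()[:: self.sample_every]


def _rng(seed) -> np.random.Generator:
    return seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)


def random_expression_profile(
    n_points: int, config: SimConfig = SimConfig(), seed=None
) -> np.ndarray:
    """Smoothed lognormal random-walk profile, min-max normalized to [0, 1].

    ``phi_t = prod_i xi_i`` with ``log(xi_i) ~ N(0, rw_sigma2)``, smoothed by
    a Savitzky-Golay filter (order ``rw_order``, window ``rw_window``) and
    then affinely rescaled so min = 0 and max = 1.
    """
    if n_points <= config.rw_window:
        raise ValueError(f"n_points must exceed the smoothing window "
                         f"({config.rw_window})")
    rng = _rng(seed)
    steps = np.exp(rng.normal(0.0, np.sqrt(config.rw_sigma2), size=n_points))
    walk = np.cumprod(steps)
    smooth = savgol_filter(walk, config.rw_window, config.rw_order)
    span = smooth.max() - smooth.min()
    if span <= 0:
        warnings.warn("degenerate constant random walk; returning zeros",
                      RuntimeWarning)
        return np.zeros(n_points)
    return (smooth - smooth.min()) / span


def gompertz_biomass(params: GompertzParams, t) -> np.ndarray:
    """Gompertz biomass ``B(t)``, OD units."""
    t = np.asarray(t, dtype=float)
    u = params.mu_star * np.e * (params.lag - t) / params.a + 1.0
    return params.b0 * np.exp(params.a * np.exp(-np.exp(u)))


def gompertz_growth_rate(params: GompertzParams, t) -> np.ndarray:
    """Implied specific growth rate ``mu(t) = d log B / dt``, 1/h."""
    t = np.asarray(t, dtype=float)
    u = params.mu_star * np.e * (params.lag - t) / params.a
    return params.mu_star * np.exp(u - np.exp(u + 1.0) + 2.0)


def sample_gompertz(seed=None) -> GompertzParams:
    """Draw random Gompertz parameters: mu* ~ U[0.5, 1]/h, lag ~ U[0, 4] h."""
    rng = _rng(seed)
    return GompertzParams(
        mu_star=float(rng.uniform(*MU_STAR_RANGE)),
        lag=float(rng.uniform(*LAG_RANGE)),
    )


@dataclass(frozen=True)
class SimulatedWell:
    """One simulated well: noisy measurements plus the noiseless truth."""

    biomass: TimeSeries  # measured, background + noise included
    fluorescence: TimeSeries
    times: np.ndarray  # measurement grid
    true_biomass: np.ndarray
    true_fluorescence: np.ndarray
    true_mu: np.ndarray
    true_phi: np.ndarray

    def corrected(self, noise: NoiseSpec) -> tuple[TimeSeries, TimeSeries]:
        """Background-corrected measurement series (exact-constant
        subtraction, the large-n limit of control-well averaging)."""
        return (
            TimeSeries(self.times, self.biomass.values - noise.bg_biomass),
            TimeSeries(self.times, self.fluorescence.values - noise.bg_fluor),
        )


def simulate_well(
    mu_profile: Callable,
    phi_profile: Callable,
    gamma: float = 0.0,
    noise: NoiseSpec = NoiseSpec(),
    config: SimConfig = SimConfig(),
    b0: float = 0.01,
    y0: float = 0.0,
    seed=None,
) -> SimulatedWell:
    """Forward-Euler integration of the measurement model plus noise.

    ``mu_profile`` and ``phi_profile`` are callables defined on
    ``[0, horizon]``.  Returns noisy measurements subsampled to the
    measurement grid alongside the noiseless truth.
    """
    rng = _rng(seed)
    grid = config.euler_grid()
    mu = np.asarray(mu_profile(grid), dtype=float)
    phi = np.asarray(phi_profile(grid), dtype=float)
    B = np.empty_like(grid)
    y = np.empty_like(grid)
    B[0], y[0] = b0, y0
    dt = config.dt
    for i in range(len(grid) - 1):
        B[i + 1] = B[i] + dt * mu[i] * B[i]
        y[i + 1] = y[i] + dt * (B[i] * phi[i] - gamma * y[i])
    sl = slice(None, None, config.sample_every)
    t_meas = grid[sl]
    b_true, y_true = B[sl], y[sl]
    eps = rng.normal(0.0, noise.sigma, size=len(t_meas)) if noise.sigma else 0.0
    zeta = rng.normal(0.0, noise.sigma, size=len(t_meas)) if noise.sigma else 0.0
    b_meas = (b_true + noise.bg_biomass) * (1.0 + eps)
    y_meas = (y_true + noise.bg_fluor) * (1.0 + zeta)
    return SimulatedWell(
        biomass=TimeSeries(t_meas, np.asarray(b_meas, float)),
        fluorescence=TimeSeries(t_meas, np.asarray(y_meas, float)),
        times=t_meas,
        true_biomass=b_true,
        true_fluorescence=y_true,
        true_mu=mu[sl],
        true_phi=phi[sl],
    )


def gompertz_instance(
    seed,
    noise: NoiseSpec = NoiseSpec(),
    config: SimConfig = SimConfig(),
    gamma: float = 0.0,
    with_expression: bool = False,
):
    """One benchmark instance: random Gompertz (optionally plus a random
    expression profile), simulated and measured.

    Returns ``(well, params, phi_truth_profile)`` where the phi truth is a
    :class:`~kinrates.basis.GriddedProfile` on the measurement grid (None
    when ``with_expression`` is False).
    """
    rng = _rng(seed)
    params = sample_gompertz(rng)
    mu_fn = lambda t: gompertz_growth_rate(params, t)
    t_meas = config.measurement_grid()
    if with_expression:
        phi_vals = random_expression_profile(len(t_meas), config, rng)
        phi_truth = GriddedProfile(t_meas, phi_vals)
        phi_fn = phi_truth
    else:
        phi_truth = None
        phi_fn = lambda t: np.zeros_like(np.asarray(t, float))
    well = simulate_well(
        mu_fn, phi_fn, gamma=gamma, noise=noise, config=config,
        b0=float(gompertz_biomass(params, 0.0)), y0=0.0, seed=rng,
    )
    return well, params, phi_truth


def simulate_controls(
    noise: NoiseSpec = NoiseSpec(),
    config: SimConfig = SimConfig(),
    n_wells: int = 4,
    kind: str = "media_blank",
    growth: Optional[GompertzParams] = None,
    channels: tuple[str, ...] = ("OD", "RFP", "YFP", "CFP"),
    seed=None,
    well_prefix: str = "ctrl",
):
    """Control wells as long-format records for the plate pipeline.

    ``media_blank`` wells contain no cells: every channel reads pure
    background with multiplicative noise.  ``no_reporter`` wells contain
    grown cells without a reporter: the OD channel reads grown biomass plus
    background, the fluorescence channels pure background.

    Returns a list of dicts with keys well/sample/channel/time_h/value.
    """
    if n_wells < 1:
        raise ValueError("n_wells must be >= 1")
    if kind not in ("media_blank", "no_reporter"):
        raise ValueError(f"unknown control kind {kind!r}")
    rng = _rng(seed)
    t = config.measurement_grid()
    if kind == "no_reporter":
        growth = growth or sample_gompertz(rng)
        b_true = gompertz_biomass(growth, t)
    records = []
    sample = "MEDIA_BLANK" if kind == "media_blank" else "NO_REPORTER"
    for w in range(n_wells):
        well = f"{well_prefix}_{kind}_{w}"
        for channel in channels:
            if channel == "OD":
                base = noise.bg_biomass + (b_true if kind == "no_reporter" else 0.0)
            else:
                base = noise.bg_fluor
            e = rng.normal(0.0, noise.sigma, size=len(t)) if noise.sigma else 0.0
            vals = np.asarray(base * (1.0 + e) if np.ndim(base) else
                              np.full(len(t), base) * (1.0 + e), dtype=float)
            if np.ndim(vals) == 0:
                vals = np.full(len(t), float(vals))
            records.extend(
                {"well": well, "sample": sample, "channel": channel,
                 "time_h": float(tt), "value": float(vv)}
                for tt, vv in zip(t, vals)
            )
    return records
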