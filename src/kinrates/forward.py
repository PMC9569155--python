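"""Forward measurement models for biomass and reporter fluorescence.

The measurement model for a constitutively expressed reporter in a growing
bulk culture is

    dB/dt = mu(t) * B,            B(0) = B0,
    dy/dt = B(t) * phi(t) - gamma * y,   y(0) = y0,

where ``B`` is biomass (OD), ``mu`` the specific growth rate (1/h), ``y``
reporter intensity (a.u.), ``phi`` the expression (synthesis) rate per unit
biomass and ``gamma`` the reporter degradation rate (1/h, typically 0 for
stable fluorescent proteins).

With ``mu`` on the Gaussian basis the biomass solution is exact:
``B(t) = B0 * exp(int_0^t mu)`` with the integral in closed form.  The
fluorescence model is driven by the *measured* (noisy, interpolated) biomass
series, not a smoothed fit — the estimator is defined against the data —
and integrates by trapezoid on a refined grid.
"""

from __future__ import annotations

import numpy as np
from scipy.integrate import cumulative_trapezoid

from .basis import BasisProfile, gaussian_design
from .timeseries import TimeSeries

__all__ = [
    "forward_biomass",
    "forward_fluorescence",
    "refine_grid",
    "fluorescence_design",
]

#: Default quadrature refinement of the measurement grid for the
#: fluorescence integral (keeps discretisation error well below
#: measurement noise).
REFINE = 10


def forward_biomass(b0: float, mu: BasisProfile, t_grid) -> np.ndarray:
    """Closed-form biomass ``B(t) = b0 * exp(int_0^t mu)`` on ``t_grid``."""
    if b0 <= 0:
        raise ValueError("initial biomass b0 must be positive")
    return b0 * np.exp(mu.cumulative_integral(np.asarray(t_grid, dtype=float)))


def refine_grid(times: np.ndarray, refine: int = REFINE) -> np.ndarray:
    """Refined grid containing every measurement time plus ``refine - 1``
    equally spaced interior points per interval."""
    times = np.asarray(times, dtype=float)
    pieces = [
        np.linspace(times[i], times[i + 1], refine, endpoint=False)
        for i in range(len(times) - 1)
    ]
    return np.concatenate(pieces + [times[-1:]])


def _check_support(t_grid: np.ndarray, biomass: TimeSeries) -> None:
    tol = 1e-9
    if t_grid.min() < biomass.times[0] - tol or t_grid.max() > biomass.times[-1] + tol:
        raise ValueError("t_grid extends outside the biomass measurement support")


def forward_fluorescence(
    y0: float,
    phi: BasisProfile,
    biomass: TimeSeries,
    gamma: float = 0.0,
    t_grid=None,
    refine: int = REFINE,
) -> np.ndarray:
    """Reporter intensity driven by the measured biomass series.

    For ``gamma = 0``: ``y(t) = y0 + int_0^t Bbar(s) phi(s) ds``; for
    ``gamma > 0`` the integrating-factor form
    ``y(t) = exp(-gamma*t) * [y0 + int_0^t exp(gamma*s) Bbar(s) phi(s) ds]``.
    ``Bbar`` is linearly interpolated from the supplied (possibly noisy)
    biomass series.
    """
    if gamma < 0:
        raise ValueError("gamma must be nonnegative")
    if t_grid is None:
        t_grid = biomass.times
    t_grid = np.asarray(t_grid, dtype=float)
    _check_support(t_grid, biomass)
    fine = refine_grid(biomass.times, refine)
    b_fine = np.interp(fine, biomass.times, biomass.values)
    integrand = np.exp(gamma * fine) * b_fine * phi(fine)
    integral = cumulative_trapezoid(integrand, fine, initial=0.0)
    y_fine = np.exp(-gamma * fine) * (y0 + integral)
    return np.interp(t_grid, fine, y_fine)


def fluorescence_design(
    biomass: TimeSeries,
    delta: float,
    t_end: float,
    gamma: float = 0.0,
    t_grid=None,
    refine: int = REFINE,
) -> tuple[np.ndarray, np.ndarray]:
    """Linear operator of the fluorescence model in the basis weights.

    Returns ``(d, A)`` such that ``y(t_j) = d[j] * y0 + (A @ w)[j]`` with
    ``d[j] = exp(-gamma * t_j)`` and
    ``A[j, k] = exp(-gamma*t_j) * int_0^{t_j} exp(gamma*s) Bbar(s) G_k(s) ds``.

    The fluorescence forward model is linear in ``(y0, w)``; precomputing
    this operator makes the expression-rate inversion cheap.
    """
    if t_grid is None:
        t_grid = biomass.times
    t_grid = np.asarray(t_grid, dtype=float)
    _check_support(t_grid, biomass)
    fine = refine_grid(biomass.times, refine)
    b_fine = np.interp(fine, biomass.times, biomass.values)
    G = gaussian_design(fine, delta, t_end)
    integrand = (np.exp(gamma * fine) * b_fine)[:, None] * G
    integral = cumulative_trapezoid(integrand, fine, axis=0, initial=0.0)
    # evaluate the cumulative integrals at the measurement times
    idx = np.searchsorted(fine, t_grid)
    idx = np.clip(idx, 0, len(fine) - 1)
    # t_grid points are members of the refined grid up to rounding
    A = np.exp(-gamma * t_grid)[:, None] * integral[idx, :]
    d = np.exp(-gamma * t_grid)
    return d, A
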