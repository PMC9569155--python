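"""Time series container for single-well, single-channel kinetic measurements."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd


@dataclass(frozen=True)
class TimeSeries:
    """One measured channel of one well: paired time grid and values.

    Times are in hours and must be strictly increasing with at least three
    points.  Values are in the raw measurement units (OD for biomass,
    arbitrary fluorescence units for reporters) and may be negative after
    background correction.  Ingestion conventionally shifts the time origin
    so that the first retained measurement sits at t = 0; use
    :meth:`shifted_origin` for that.
    """

    times: np.ndarray
    values: np.ndarray

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        v = np.asarray(self.values, dtype=float)
        if t.ndim != 1 or v.ndim != 1:
            raise ValueError("times and values must be one-dimensional")
        if len(t) != len(v):
            raise ValueError(
                f"times and values differ in length ({len(t)} vs {len(v)})"
            )
        if len(t) < 3:
            raise ValueError("a time series needs at least 3 points")
        if not np.all(np.isfinite(t)):
            raise ValueError("times must be finite")
        if np.any(np.diff(t) <= 0):
            raise ValueError("times must be strictly increasing")
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "values", v)

    def __len__(self) -> int:
        return len(self.times)

    @property
    def t_end(self) -> float:
        return float(self.times[-1])

    @property
    def dt_median(self) -> float:
        """Median sampling interval in hours."""
        return float(np.median(np.diff(self.times)))

    def shifted_origin(self) -> "TimeSeries":
        """Return a copy with the first measurement defining t = 0."""
        return TimeSeries(self.times - self.times[0], self.values.copy())

    def same_grid(self, other: "TimeSeries", tol: float = 1e-9) -> bool:
        return len(self) == len(other) and bool(
            np.allclose(self.times, other.times, atol=tol, rtol=0.0)
        )

    @classmethod
    def from_dataframe(
        cls, df: pd.DataFrame, time: str = "time_h", value: str = "value"
    ) -> "TimeSeries":
        d = df.sort_values(time)
        return cls(d[time].to_numpy(float), d[value].to_numpy(float))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"time_h": self.times, "value": self.values})
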