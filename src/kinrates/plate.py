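"""Plate-data pipeline: I/O, background correction, per-well reconstruction,
replicate aggregation, growth-peak synchronization and ratiometric
comparison against an in-vivo reference transcription unit.

The on-disk dialect is a long-format CSV with columns
``well,sample,channel,time_h,value`` plus a metadata side table keyed by
sample (strain, media, vector, control flags).  A plate must carry at least
one media-blank and one no-reporter control sample: background correction
subtracts the time-wise mean of the media blanks from the OD channel and the
time-wise mean of the no-reporter wells from each fluorescence channel.
Negative corrected values are retained, not clipped — the estimators must
face them.

Profiles from different wells and experiments are made comparable by
synchronizing to the growth-rate peak time ``t0`` (``tau = t - t0``) and
z-normalizing (subtract mean, divide by population standard deviation).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .baselines import (
    DirectConfig,
    IndirectConfig,
    direct_expression,
    direct_growth,
    indirect_expression,
    indirect_growth,
)
from .inverse import ExpressionRateModel, GrowthRateModel
from .timeseries import TimeSeries
from .tuning import DEFAULT_LAMBDA_GRID, lambda_lcurve

__all__ = [
    "PlateDataset",
    "NormalizedProfile",
    "read_plate_csv",
    "subtract_background",
    "peak_time",
    "normalize_profile",
    "characterize_sample",
    "compare_to_reference",
    "SampleCharacterization",
    "ComparisonRecord",
    "build_synthetic_plate",
]

DATA_COLUMNS = ("well", "sample", "channel", "time_h", "value")
CHANNEL_ALIASES = {
    "od": "OD", "od600": "OD", "biomass": "OD",
    "rfp": "RFP", "yfp": "YFP", "cfp": "CFP",
}


@dataclass
class PlateDataset:
    """A plate of kinetic measurements with per-sample metadata.

    ``data`` is long format (well, sample, channel, time_h, value);
    ``metadata`` is keyed by sample and carries at least the boolean columns
    ``is_media_blank`` and ``is_no_reporter_control``.
    """

    data: pd.DataFrame
    metadata: pd.DataFrame
    corrected: bool = False

    def __post_init__(self):
        missing = [c for c in DATA_COLUMNS if c not in self.data.columns]
        if missing:
            raise ValueError(f"plate data missing columns: {missing}")
        for flag in ("is_media_blank", "is_no_reporter_control"):
            if flag not in self.metadata.columns:
                raise ValueError(f"metadata missing column: {flag}")
        if "sample" not in self.metadata.columns:
            raise ValueError("metadata missing column: sample")
        df = self.data.copy()
        df["channel"] = [
            CHANNEL_ALIASES.get(str(c).lower(), str(c)) for c in df["channel"]
        ]
        dup = df.duplicated(subset=["well", "channel", "time_h"])
        if dup.any():
            rows = df[dup].head(5)
            raise ValueError(f"duplicate (well, channel, time) rows, e.g.:\n{rows}")
        df = df.sort_values(["well", "channel", "time_h"]).reset_index(drop=True)
        for (well, channel), g in df.groupby(["well", "channel"], sort=False):
            if np.any(np.diff(g["time_h"].to_numpy(float)) <= 0):
                raise ValueError(f"non-monotone times in well {well!r}, "
                                 f"channel {channel!r}")
        # first retained measurement defines t = 0
        df["time_h"] = df["time_h"] - df["time_h"].min()
        self.data = df
        self.metadata = self.metadata.reset_index(drop=True)

    # -- access ------------------------------------------------------------
    @property
    def samples(self) -> list:
        return sorted(self.data["sample"].unique())

    @property
    def channels(self) -> list:
        return sorted(self.data["channel"].unique())

    def wells_of(self, sample: str) -> list:
        return sorted(self.data.loc[self.data["sample"] == sample, "well"].unique())

    def series(self, well: str, channel: str) -> TimeSeries:
        g = self.data[(self.data.well == well) & (self.data.channel == channel)]
        if g.empty:
            raise KeyError(f"no data for well {well!r}, channel {channel!r}")
        return TimeSeries(g["time_h"].to_numpy(float), g["value"].to_numpy(float))

    def control_samples(self, which: str) -> list:
        col = {"media_blank": "is_media_blank",
               "no_reporter": "is_no_reporter_control"}[which]
        return list(self.metadata.loc[self.metadata[col].astype(bool), "sample"])

    # -- I/O ----------------------------------------------------------------
    def to_csv(self, path) -> None:
        path = Path(path)
        self.data.to_csv(path, index=False)
        self.metadata.to_csv(_meta_path(path), index=False)

    def equals(self, other: "PlateDataset") -> bool:
        a = self.data.sort_values(list(DATA_COLUMNS)).reset_index(drop=True)
        b = other.data.sort_values(list(DATA_COLUMNS)).reset_index(drop=True)
        return bool(
            np.allclose(a["time_h"], b["time_h"])
            and np.allclose(a["value"], b["value"])
            and (a[["well", "sample", "channel"]] == b[["well", "sample", "channel"]])
            .all()
            .all()
        )


def _meta_path(path: Path) -> Path:
    return path.with_name(path.stem + "_meta" + path.suffix)


def read_plate_csv(path, metadata_path=None) -> PlateDataset:
    """Load a plate from the long-format CSV plus its metadata side table."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    meta_path = Path(metadata_path) if metadata_path else _meta_path(path)
    if not meta_path.exists():
        raise FileNotFoundError(
            f"metadata side table not found at {meta_path} "
            "(pass metadata_path explicitly)"
        )
    data = pd.read_csv(path)
    meta = pd.read_csv(meta_path)
    return PlateDataset(data, meta)


def subtract_background(ds: PlateDataset) -> PlateDataset:
    """Subtract time-wise control-well means from every series.

    OD channels: minus the mean of media-blank wells at each time point.
    Fluorescence channels: minus the mean of no-reporter control wells.
    Negative corrected values are retained.  Refuses to run twice.
    """
    if ds.corrected:
        raise ValueError("plate is already background-corrected")
    blanks = ds.control_samples("media_blank")
    norep = ds.control_samples("no_reporter")
    if not blanks or not norep:
        raise ValueError(
            "background correction needs at least one media blank and one "
            f"no-reporter control; found blanks={blanks}, no_reporter={norep}"
        )
    df = ds.data.copy()
    corrected_parts = []
    for channel, g in df.groupby("channel", sort=False):
        ref_samples = blanks if channel == "OD" else norep
        ref = g[g["sample"].isin(ref_samples)]
        if ref.empty:
            raise ValueError(f"no control data for channel {channel!r}")
        bg = ref.groupby("time_h")["value"].mean()
        corr = g.copy()
        corr["value"] = g["value"].to_numpy() - bg.reindex(g["time_h"]).to_numpy()
        if corr["value"].isna().any():
            raise ValueError(
                f"control wells do not cover the sample time grid in {channel!r}"
            )
        corrected_parts.append(corr)
    out = pd.concat(corrected_parts).sort_index()
    return PlateDataset(out, ds.metadata.copy(), corrected=True)


def peak_time(fit, t_end: Optional[float] = None, step: float = 0.01) -> float:
    """Time of the reconstructed growth-rate maximum on a dense grid.

    ``fit`` is a RateFit/results object (anything with ``rate``) or a bare
    callable.  Ties break to the earliest time; a flat profile
    (max - min < 1e-9) has no identifiable peak and raises.
    """
    rate = fit.rate if hasattr(fit, "rate") else fit
    if t_end is None:
        prof = getattr(fit, "profile", None)
        t_end = getattr(prof, "t_end", None)
        if t_end is None and prof is not None and hasattr(prof, "times"):
            t_end = float(prof.times[-1])
        if t_end is None:
            raise ValueError("t_end could not be inferred; pass it explicitly")
    grid = np.arange(0.0, t_end + step / 2, step)
    vals = np.asarray(rate(grid), dtype=float)
    if np.nanmax(vals) - np.nanmin(vals) < 1e-9:
        raise ValueError("no identifiable peak: the rate profile is flat")
    return float(grid[int(np.argmax(vals))])


@dataclass(frozen=True)
class NormalizedProfile:
    """A rate profile in the synchronized, z-normalized frame.

    ``tau`` is hours relative to the growth-rate peak (tau = 0 at the peak);
    ``z`` has mean 0 and population standard deviation 1 over the retained
    window.
    """

    tau: np.ndarray
    z: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        tau = np.asarray(self.tau, dtype=float)
        z = np.asarray(self.z, dtype=float)
        if len(tau) != len(z) or len(tau) < 3:
            raise ValueError("tau and z must be matching vectors of length >= 3")
        object.__setattr__(self, "tau", tau)
        object.__setattr__(self, "z", z)
        if self.meta.get("strict", True):
            if abs(float(np.mean(z))) > 1e-8 or abs(float(np.std(z)) - 1.0) > 1e-8:
                raise ValueError("z must have mean 0 and population std 1")


def normalize_profile(values, times, t0: float, meta: Optional[dict] = None
                      ) -> NormalizedProfile:
    """Shift to the tau frame and z-normalize over the full window.

    Uses the population (divide-by-n) standard deviation.  Zero variance is
    an error — a constant rate profile carries no shape to compare.
    """
    values = np.asarray(values, dtype=float)
    times = np.asarray(times, dtype=float)
    if len(values) < 3:
        raise ValueError("need at least 3 points")
    sd = float(np.std(values))
    if sd == 0 or not np.isfinite(sd):
        raise ValueError("zero or non-finite variance; cannot z-normalize")
    z = (values - float(np.mean(values))) / sd
    return NormalizedProfile(times - t0, z, dict(meta or {}))


@dataclass
class SampleCharacterization:
    """Per-replicate and aggregate normalized expression profiles."""

    sample: str
    channel: str
    method: str
    replicates: list  # NormalizedProfile per surviving well
    growth_fits: dict  # well -> growth RateFit / results
    tau: np.ndarray  # common tau grid
    z_mean: np.ndarray
    z_sd: np.ndarray
    n_replicates: int
    reliable: bool
    excluded: list  # (well, reason)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            dict(sample=self.sample, channel=self.channel, method=self.method,
                 tau_h=self.tau, z_mean=self.z_mean, z_sd=self.z_sd,
                 n_replicates=self.n_replicates)
        )

    @property
    def mean_profile(self) -> NormalizedProfile:
        return NormalizedProfile(self.tau, self.z_mean, {"strict": False,
                                                         "sample": self.sample})


def _fit_growth_by_method(od: TimeSeries, method, delta, lambda_reg, lambda_grid,
                          direct_config, indirect_config):
    if method == "inverse":
        lam = lambda_reg
        if lam == "lcurve":
            lam = lambda_lcurve(od, lambda_grid, delta=delta, which="growth")
        return GrowthRateModel(od, delta=delta).fit(lambda_reg=float(lam))
    if method == "direct":
        return direct_growth(od, direct_config)
    if method == "indirect_sg":
        return indirect_growth(od, indirect_config)
    if method == "indirect_zerophase":
        cfg = IndirectConfig(
            sg_window=indirect_config.sg_window, sg_order=indirect_config.sg_order,
            filter_kind="zerophase_butterworth",
            butter_order=indirect_config.butter_order,
            butter_cutoff=indirect_config.butter_cutoff,
        )
        return indirect_growth(od, cfg)
    raise ValueError(f"unknown method {method!r}")


def _fit_expression_by_method(fl: TimeSeries, od: TimeSeries, gamma, method, delta,
                              lambda_reg, lambda_grid, direct_config,
                              indirect_config):
    if method == "inverse":
        lam = lambda_reg
        if lam == "lcurve":
            lam = lambda_lcurve(fl, lambda_grid, delta=delta, which="expression",
                                biomass=od, gamma=gamma)
        return ExpressionRateModel(fl, od, gamma=gamma, delta=delta).fit(
            lambda_reg=float(lam))
    if method == "direct":
        return direct_expression(fl, od, gamma, direct_config)
    if method == "indirect_sg":
        return indirect_expression(fl, od, gamma, indirect_config)
    if method == "indirect_zerophase":
        cfg = IndirectConfig(
            sg_window=indirect_config.sg_window, sg_order=indirect_config.sg_order,
            filter_kind="zerophase_butterworth",
            butter_order=indirect_config.butter_order,
            butter_cutoff=indirect_config.butter_cutoff,
        )
        return indirect_expression(fl, od, gamma, cfg)
    raise ValueError(f"unknown method {method!r}")


def characterize_sample(
    ds: PlateDataset,
    sample: str,
    channel: str,
    method: str = "inverse",
    delta: float = 1.0,
    gamma: float = 0.0,
    lambda_reg="lcurve",
    lambda_grid: Sequence[float] = DEFAULT_LAMBDA_GRID,
    direct_config: DirectConfig = DirectConfig(),
    indirect_config: IndirectConfig = IndirectConfig(),
    tau_step: float = 0.1,
    min_replicates: int = 3,
) -> SampleCharacterization:
    """Characterize one sample's expression dynamics in one channel.

    Per replicate well: background-corrected OD -> growth fit -> peak time
    t0 -> expression fit -> z-normalized profile on tau = t - t0.  The
    aggregate is the mean and standard deviation of z across replicates on
    the common tau grid (intersection of replicate tau ranges, linear
    interpolation).  Replicate-level failures are logged and excluded; fewer
    than ``min_replicates`` survivors marks the sample unreliable.
    """
    if not ds.corrected:
        ds = subtract_background(ds)
    wells = ds.wells_of(sample)
    if not wells:
        raise KeyError(f"sample {sample!r} not on this plate")
    replicates, growth_fits, excluded = [], {}, []
    for well in wells:
        try:
            od = ds.series(well, "OD")
            fl = ds.series(well, channel)
            gfit = _fit_growth_by_method(od, method, delta, lambda_reg,
                                         lambda_grid, direct_config,
                                         indirect_config)
            t0 = peak_time(gfit, t_end=od.t_end)
            efit = _fit_expression_by_method(fl, od, gamma, method, delta,
                                             lambda_reg, lambda_grid,
                                             direct_config, indirect_config)
            rate = efit.rate(od.times - od.times[0])
            # rates below 1e-6/h are solver dust from all-zero channels,
            # far below any measurable synthesis rate
            if np.max(np.abs(rate)) < 1e-6:
                raise ValueError("expression rate is numerically zero; "
                                 "nothing to normalize")
            prof = normalize_profile(rate, od.times - od.times[0], t0,
                                     meta={"well": well, "sample": sample,
                                           "channel": channel, "method": method})
            replicates.append(prof)
            growth_fits[well] = gfit
        except (ValueError, KeyError, FloatingPointError) as err:
            warnings.warn(f"well {well!r} excluded: {err}", RuntimeWarning)
            excluded.append((well, str(err)))
    if not replicates:
        raise ValueError(f"no usable replicates for sample {sample!r}")
    lo = max(p.tau.min() for p in replicates)
    hi = min(p.tau.max() for p in replicates)
    tau = np.arange(lo, hi + tau_step / 2, tau_step)
    Z = np.vstack([np.interp(tau, p.tau, p.z) for p in replicates])
    reliable = len(replicates) >= min_replicates
    if not reliable:
        warnings.warn(
            f"sample {sample!r}: only {len(replicates)} surviving replicates; "
            "marked unreliable", RuntimeWarning,
        )
    return SampleCharacterization(
        sample=sample, channel=channel, method=method, replicates=replicates,
        growth_fits=growth_fits, tau=tau, z_mean=Z.mean(axis=0),
        z_sd=Z.std(axis=0), n_replicates=len(replicates), reliable=reliable,
        excluded=excluded,
    )


@dataclass(frozen=True)
class ComparisonRecord:
    """Similarity of a normalized profile to a reference profile."""

    rmsd: float
    pearson_r: float
    n_points: int
    tau_range: tuple


def compare_to_reference(
    profile: NormalizedProfile,
    reference: NormalizedProfile,
    step: float = 0.1,
    min_overlap: float = 4.0,
) -> ComparisonRecord:
    """RMSD and Pearson correlation of two z-profiles on their shared tau
    window (>= ``min_overlap`` hours required).

    The correlation sign captures qualitative inversions of the
    growth-rate/expression relationship between contexts.
    """
    lo = max(profile.tau.min(), reference.tau.min())
    hi = min(profile.tau.max(), reference.tau.max())
    if hi - lo < min_overlap:
        raise ValueError(
            f"insufficient tau overlap ({hi - lo:.2f} h < {min_overlap} h)"
        )
    tau = np.arange(lo, hi + step / 2, step)
    a = np.interp(tau, profile.tau, profile.z)
    b = np.interp(tau, reference.tau, reference.z)
    rmsd = float(np.sqrt(np.mean((a - b) ** 2)))
    r = float(np.corrcoef(a, b)[0, 1])
    return ComparisonRecord(rmsd=rmsd, pearson_r=r, n_points=len(tau),
                            tau_range=(float(lo), float(hi)))


def build_synthetic_plate(
    mu_profile,
    phi_profile,
    n_replicates: int = 10,
    gamma: float = 0.0,
    noise=None,
    config=None,
    channel: str = "RFP",
    sample: str = "sampleA",
    n_blanks: int = 4,
    n_no_reporter: int = 4,
    seed=None,
    time_offset: float = 0.0,
) -> PlateDataset:
    """Assemble a complete synthetic plate (samples + both control types).

    Thin composition over the simulator, used for end-to-end pipeline tests
    and by the CLI ``simulate`` command.  ``time_offset`` shifts every
    timestamp (ingestion must absorb it).
    """
    from .simulate import NoiseSpec, SimConfig, simulate_controls, simulate_well

    noise = noise or NoiseSpec()
    config = config or SimConfig()
    rng = np.random.default_rng(seed)
    records = []
    for w in range(n_replicates):
        well = f"{sample}_r{w}"
        sim = simulate_well(mu_profile, phi_profile, gamma=gamma, noise=noise,
                            config=config, seed=rng)
        for ch, vals in (("OD", sim.biomass.values),
                         (channel, sim.fluorescence.values)):
            records.extend(
                {"well": well, "sample": sample, "channel": ch,
                 "time_h": float(t), "value": float(v)}
                for t, v in zip(sim.times, vals)
            )
    records += simulate_controls(noise, config, n_blanks, "media_blank",
                                 channels=("OD", channel), seed=rng)
    records += simulate_controls(
        noise, config, n_no_reporter, "no_reporter",
        channels=("OD", channel), seed=rng,
        growth=None,
    )
    data = pd.DataFrame.from_records(records)
    data["time_h"] += time_offset
    meta = pd.DataFrame(
        [
            {"sample": sample, "strain": "synthetic", "media": "synthetic",
             "vector": "synthetic", "is_media_blank": False,
             "is_no_reporter_control": False},
            {"sample": "MEDIA_BLANK", "strain": "", "media": "synthetic",
             "vector": "", "is_media_blank": True,
             "is_no_reporter_control": False},
            {"sample": "NO_REPORTER", "strain": "synthetic", "media": "synthetic",
             "vector": "", "is_media_blank": False,
             "is_no_reporter_control": True},
        ]
    )
    return PlateDataset(data, meta)
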