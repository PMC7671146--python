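"""Synthetic under-rock intertidal microclimates.

The field design this module emulates: temperature loggers fixed under 12
mid-intertidal (MIZ, elevations −0.32–0.23 m above MLLW) and 12
high-intertidal (HIZ, 0.31–1.10 m) boulders, sampling every 30 minutes.
Rocks spend most of their time immersed, when every rock tracks the same
water temperature; at low tide higher rocks are exposed to air and their
under-rock airspaces heat by day and cool by night, the more so the longer
they are emersed.

Generative model
----------------
*Immersed* records equal a shared water process: an annual sinusoid plus a
small diurnal sinusoid plus AR(1) noise, identical across rocks at the
same timestamp.

*Emersed* records relax (Newtonian, time constant ``tau_hours``) toward an
air-driven target::

    target(t) = water_seasonal(t)
                + r_rock * [A_day * f_day(t) * day(t)
                            - A_night * f_night(t) * night(t)]
                + weather_sd * w(zone, day) * day(t)  + noise

where ``day(t)``/``night(t)`` are complementary half-cosine bumps peaking
mid-afternoon and pre-dawn, ``f_day``/``f_night`` modulate amplitudes
seasonally (daytime heating strongest in summer, night cooling strongest
in winter), ``r_rock`` is a fixed per-rock multiplicative random effect
(the among-rock heterogeneity), and ``w`` is a shared day-to-day weather
anomaly.  On re-immersion the rock snaps back to the water process, which
reproduces the sharp transitions seen in logger traces.

The default calibration constants (see ``data/default_config.yaml``) were
fitted once so that a default-seeded synthetic year reproduces the
zone-level statistics of the field record: HIZ/MIZ mean daily maxima near
16.4/13.9 °C, mean daily ranges near 5.2/2.2 °C, HIZ mean daily minimum
near 11.2 °C and an overall HIZ−MIZ mean gap near 0.3 °C, with no MIZ
daily maximum above the 30.5 °C mean heat tolerance but HIZ rock-days
above it in spring/summer.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from datetime import date
from typing import Sequence

import numpy as np
import pandas as pd

from hotrocks.tides import TideModel, tide_height

__all__ = [
    "RockSite",
    "MicroclimateCalibration",
    "LoggerReadReport",
    "LoggerFormatError",
    "generate_rock_field",
    "simulate_temperature_series",
    "summarize_daily",
    "seasonal_summary",
    "read_logger_csv",
    "write_logger_csv",
    "SPRING_SUMMER",
    "FALL_WINTER",
]

SPRING_SUMMER = "spring_summer"
FALL_WINTER = "fall_winter"

#: columns of a temperature-record frame
RECORD_COLUMNS = ["rock_id", "timestamp", "temperature", "emersed"]

_DAYS_PER_YEAR = 365.25


@dataclass(frozen=True)
class RockSite:
    """One boulder: the spatial unit of under-rock temperature."""

    rock_id: str
    zone: str  # "MIZ" or "HIZ"
    elevation: float  # m above MLLW
    surface_area: float  # cm^2
    volume: float  # cm^3
    grid_pos: tuple[int, int] | None = None

    def __post_init__(self):
        if self.zone not in ("MIZ", "HIZ"):
            raise ValueError(f"zone must be MIZ or HIZ, got {self.zone!r}")


@dataclass(frozen=True)
class _AirParams:
    day_amplitude: float
    night_amplitude: float
    seasonal_mod_day: float
    seasonal_mod_night: float
    rock_sd: float
    weather_sd: float
    noise_sd: float
    tau_hours: float
    # air excursions scale with elevation (higher rocks emerge longer and
    # heat/cool further): factor 1 + elevation_coef * (elev - elevation_ref)
    elevation_coef: float = 0.0
    elevation_ref: float = 0.0
    # exponent sharpening the daytime half-cosine bump: >1 concentrates
    # heating around midday without changing its peak
    day_sharpness: float = 1.0

    @classmethod
    def from_config(cls, block: dict) -> "_AirParams":
        return cls(
            day_amplitude=float(block["day_amplitude_c"]),
            night_amplitude=float(block["night_amplitude_c"]),
            seasonal_mod_day=float(block["seasonal_mod_day"]),
            seasonal_mod_night=float(block["seasonal_mod_night"]),
            rock_sd=float(block["rock_sd"]),
            weather_sd=float(block["weather_sd_c"]),
            noise_sd=float(block["noise_sd_c"]),
            tau_hours=float(block["tau_hours"]),
            elevation_coef=float(block.get("elevation_coef_per_m", 0.0)),
            elevation_ref=float(block.get("elevation_ref_m", 0.0)),
            day_sharpness=float(block.get("day_sharpness", 1.0)),
        )


@dataclass(frozen=True)
class MicroclimateCalibration:
    """All constants of the generative model (water process + per-zone air
    excursions).  Scales must be non-negative; under the defaults the HIZ
    among-rock heterogeneity exceeds the MIZ's.
    """

    water_mean: float
    water_seasonal_amplitude: float
    water_seasonal_peak_doy: float
    water_diurnal_amplitude: float
    ar_phi: float
    ar_sd: float
    air: dict  # zone -> _AirParams
    sampling_interval_min: int = 30
    quantize_half_degree: bool = False
    exclusion_windows: tuple[tuple[str, str], ...] = ()

    def __post_init__(self):
        scales = [
            self.water_seasonal_amplitude,
            self.water_diurnal_amplitude,
            self.ar_sd,
        ]
        for ap in self.air.values():
            scales += [
                ap.day_amplitude,
                ap.night_amplitude,
                ap.rock_sd,
                ap.weather_sd,
                ap.noise_sd,
                ap.tau_hours,
            ]
        if any(s < 0 for s in scales):
            raise ValueError("all calibration scales must be >= 0")
        if not 0.0 <= self.ar_phi < 1.0:
            raise ValueError("ar_phi must be in [0, 1)")

    @classmethod
    def from_config(cls, block: dict) -> "MicroclimateCalibration":
        water = block["water"]
        return cls(
            water_mean=float(water["mean_c"]),
            water_seasonal_amplitude=float(water["seasonal_amplitude_c"]),
            water_seasonal_peak_doy=float(water["seasonal_peak_doy"]),
            water_diurnal_amplitude=float(water["diurnal_amplitude_c"]),
            ar_phi=float(water["ar_phi"]),
            ar_sd=float(water["ar_sd"]),
            air={z: _AirParams.from_config(b) for z, b in block["air"].items()},
            sampling_interval_min=int(block.get("sampling_interval_min", 30)),
            quantize_half_degree=bool(block.get("quantize_half_degree", False)),
            exclusion_windows=tuple(
                tuple(w) for w in (block.get("exclusion_windows") or [])
            ),
        )


# ---------------------------------------------------------------------------
# rock field


def _bounded_power_sample(rng, lo, hi, target_mean, n):
    """Stratified draw from lo + (hi-lo)*Beta(a, 1): a power law on
    [lo, hi] whose mean matches ``target_mean``.  One jittered quantile is
    taken per stratum, mimicking a survey design that deliberately spans
    the zone's elevation gradient; the sample mean is therefore stable
    across seeds."""
    frac = (target_mean - lo) / (hi - lo)
    frac = min(max(frac, 0.05), 0.95)
    a = frac / (1.0 - frac)  # mean of Beta(a,1) is a/(a+1)
    u = (np.arange(n) + rng.uniform(0.1, 0.9, size=n)) / n
    rng.shuffle(u)
    return lo + (hi - lo) * u ** (1.0 / a)


def generate_rock_field(
    n_miz: int,
    n_hiz: int,
    seed: int,
    *,
    config: dict | None = None,
) -> list[RockSite]:
    """Draw a synthetic rock field with per-zone elevation, area and volume
    distributions matching the surveyed boulder field (MIZ elevations in
    [−0.32, 0.23] m with mean ≈ 0.0; HIZ in [0.31, 1.10] m with mean ≈ 0.8;
    areas 568–2671 cm²; volumes 5162–50472 cm³).

    Deterministic given ``seed``.  At least one of ``n_miz``/``n_hiz`` may
    be zero, but not a negative count.
    """
    if n_miz < 0 or n_hiz < 0 or n_miz + n_hiz < 1:
        raise ValueError("need non-negative counts with at least one rock")
    from hotrocks.config import default_config

    block = (config or default_config())["rock_field"]
    rng = np.random.default_rng(seed)
    rocks: list[RockSite] = []
    zone_specs = [
        ("MIZ", n_miz, block["miz_elevation_range"], block["miz_elevation_mean"]),
        ("HIZ", n_hiz, block["hiz_elevation_range"], block["hiz_elevation_mean"]),
    ]
    area_lo, area_hi = block["surface_area_range_cm2"]
    vol_lo, vol_hi = block["volume_range_cm3"]
    for zone, n, (lo, hi), mean in zone_specs:
        if n == 0:
            continue
        elev = _bounded_power_sample(rng, lo, hi, mean, n)
        areas = rng.uniform(area_lo, area_hi, size=n)
        vols = rng.uniform(vol_lo, vol_hi, size=n)
        for i in range(n):
            rocks.append(
                RockSite(
                    rock_id=f"{zone}-{i + 1:02d}",
                    zone=zone,
                    elevation=float(elev[i]),
                    surface_area=float(areas[i]),
                    volume=float(vols[i]),
                )
            )
    return rocks


# ---------------------------------------------------------------------------
# temperature synthesis


def _season_cos(doy: np.ndarray, peak_doy: float) -> np.ndarray:
    return np.cos(2.0 * np.pi * (doy - peak_doy) / _DAYS_PER_YEAR)


def _half_cos(hours: np.ndarray, peak_hour: float) -> np.ndarray:
    return np.maximum(0.0, np.cos(2.0 * np.pi * (hours - peak_hour) / 24.0))


def simulate_temperature_series(
    rocks: Sequence[RockSite],
    start: date | str,
    end: date | str,
    calib: MicroclimateCalibration,
    tide: TideModel,
    seed: int,
) -> pd.DataFrame:
    """Simulate 30-minute under-rock temperature records for every rock
    from ``start`` (inclusive) to ``end`` (exclusive).

    Returns a frame with columns ``rock_id, timestamp, temperature,
    emersed``, sorted by rock then time.  Bit-identical for identical
    seeds and calibrations.
    """
    if len(rocks) == 0:
        raise ValueError("rock list must not be empty")
    start_ts, end_ts = pd.Timestamp(start), pd.Timestamp(end)
    if start_ts >= end_ts:
        raise ValueError("start must precede end")

    step = pd.Timedelta(minutes=calib.sampling_interval_min)
    times = pd.date_range(start_ts, end_ts, freq=step, inclusive="left")
    n_t = len(times)
    n_r = len(rocks)
    dt_h = calib.sampling_interval_min / 60.0

    doy = times.dayofyear.to_numpy(dtype=float)
    hour = times.hour.to_numpy(dtype=float) + times.minute.to_numpy(dtype=float) / 60.0
    season = _season_cos(doy, calib.water_seasonal_peak_doy)
    day_index = np.asarray(
        (times.normalize() - times[0].normalize()).days, dtype=int
    )
    n_days = int(day_index.max()) + 1

    rng = np.random.default_rng(seed)

    # shared water process
    water_base = calib.water_mean + calib.water_seasonal_amplitude * season
    water_diurnal = calib.water_diurnal_amplitude * np.cos(
        2.0 * np.pi * (hour - 15.0) / 24.0
    )
    innov_sd = calib.ar_sd * np.sqrt(1.0 - calib.ar_phi**2)
    anomalies = rng.normal(0.0, innov_sd, size=n_t)
    anomalies[0] = rng.normal(0.0, calib.ar_sd)
    from scipy.signal import lfilter

    ar = lfilter([1.0], [1.0, -calib.ar_phi], anomalies)
    water = water_base + water_diurnal + ar

    # tide / emersion, per rock
    heights = tide_height(tide, times)
    elevations = np.array([r.elevation for r in rocks])
    emersed = heights[None, :] < elevations[:, None]  # (n_r, n_t)

    # air-target ingredients, grouped per zone
    zones = np.array([r.zone for r in rocks])
    day_bump = _half_cos(hour, 14.0)
    night_bump = _half_cos(hour, 2.0)
    rock_amp = np.empty(n_r)
    weather = {}  # zone -> per-day anomaly
    for zone in ("MIZ", "HIZ"):
        ap = calib.air[zone]
        idx = np.flatnonzero(zones == zone)
        elev_factor = 1.0 + ap.elevation_coef * (elevations[idx] - ap.elevation_ref)
        rock_amp[idx] = np.maximum(
            0.1, elev_factor * (1.0 + ap.rock_sd * rng.normal(size=idx.size))
        )
        weather[zone] = rng.normal(0.0, 1.0, size=n_days)

    targets = np.empty((n_r, n_t))
    for j, rock in enumerate(rocks):
        ap = calib.air[rock.zone]
        f_day = 1.0 + ap.seasonal_mod_day * season
        f_night = 1.0 - ap.seasonal_mod_night * season
        sharp_day = day_bump**ap.day_sharpness
        excursion = rock_amp[j] * (
            ap.day_amplitude * f_day * sharp_day
            - ap.night_amplitude * f_night * night_bump
        )
        wx = ap.weather_sd * weather[rock.zone][day_index] * sharp_day
        noise = ap.noise_sd * rng.normal(size=n_t)
        targets[j] = water_base + excursion + wx + noise

    # Newtonian relaxation while emersed; snap to water when immersed
    alpha = np.array(
        [1.0 - np.exp(-dt_h / calib.air[r.zone].tau_hours) for r in rocks]
    )
    temps = np.empty((n_r, n_t))
    prev = np.where(emersed[:, 0], targets[:, 0], water[0])
    temps[:, 0] = prev
    for k in range(1, n_t):
        em = emersed[:, k]
        relaxed = prev + alpha * (targets[:, k] - prev)
        prev = np.where(em, relaxed, water[k])
        temps[:, k] = prev

    if calib.quantize_half_degree:
        temps = np.round(temps * 2.0) / 2.0
    np.clip(temps, -5.0, 45.0, out=temps)

    frames = []
    for j, rock in enumerate(rocks):
        frames.append(
            pd.DataFrame(
                {
                    "rock_id": rock.rock_id,
                    "timestamp": times,
                    "temperature": temps[j],
                    "emersed": emersed[j],
                }
            )
        )
    records = pd.concat(frames, ignore_index=True)

    for w_start, w_end in calib.exclusion_windows:
        mask = (records["timestamp"] >= pd.Timestamp(w_start)) & (
            records["timestamp"] <= pd.Timestamp(w_end)
        )
        records = records.loc[~mask]
    return records.reset_index(drop=True)


# ---------------------------------------------------------------------------
# summaries


def summarize_daily(
    records: pd.DataFrame,
    rocks: Sequence[RockSite] | None = None,
) -> pd.DataFrame:
    """Per-rock per-calendar-day reductions of a record frame.

    Returns columns ``rock_id, date, t_max, t_min, t_mean, t_range,
    n_records`` (plus ``zone`` when ``rocks`` is given).  Empty input gives
    an empty frame.
    """
    cols = ["rock_id", "date", "t_max", "t_min", "t_mean", "t_range", "n_records"]
    if len(records) == 0:
        out = pd.DataFrame(columns=cols)
        return out
    day = records["timestamp"].dt.normalize()
    grouped = records.groupby(["rock_id", day], observed=True)["temperature"]
    summary = grouped.agg(t_max="max", t_min="min", t_mean="mean", n_records="count")
    summary["t_range"] = summary["t_max"] - summary["t_min"]
    summary = summary.reset_index().rename(columns={"timestamp": "date"})
    summary = summary[cols]
    if rocks is not None:
        zone_of = {r.rock_id: r.zone for r in rocks}
        summary["zone"] = summary["rock_id"].map(zone_of)
    return summary


def season_of(d: date | pd.Timestamp) -> str:
    """Astronomical split: spring/summer = Mar 20 – Sep 21, inclusive."""
    ts = pd.Timestamp(d)
    key = (ts.month, ts.day)
    return SPRING_SUMMER if (3, 20) <= key <= (9, 21) else FALL_WINTER


def seasonal_summary(summaries: pd.DataFrame) -> pd.DataFrame:
    """Zone × season mean/SD of daily maxima.

    ``summaries`` must carry a ``zone`` column (see
    :func:`summarize_daily`).  Seasons with no rock-days are absent from
    the table.
    """
    if "zone" not in summaries.columns:
        raise ValueError("summaries must carry a 'zone' column")
    if len(summaries) == 0:
        return pd.DataFrame(columns=["zone", "season", "mean_t_max", "sd_t_max", "n"])
    df = summaries.copy()
    df["season"] = df["date"].map(season_of)
    out = (
        df.groupby(["zone", "season"], observed=True)["t_max"]
        .agg(mean_t_max="mean", sd_t_max="std", n="count")
        .reset_index()
    )
    return out


# ---------------------------------------------------------------------------
# logger CSV I/O


class LoggerFormatError(ValueError):
    """The logger CSV lacks the required header columns."""


@dataclass
class LoggerReadReport:
    """Row-level problems found while reading a logger CSV."""

    n_read: int = 0
    skipped: list[tuple[int, str]] = field(default_factory=list)

    @property
    def n_skipped(self) -> int:
        return len(self.skipped)


_LOGGER_COLUMNS = ["rock_id", "timestamp", "temperature_C"]


def read_logger_csv(path) -> tuple[pd.DataFrame, LoggerReadReport]:
    """Read logger records from CSV (``rock_id,timestamp,temperature_C``,
    ISO-8601 timestamps).

    Malformed rows (unparseable timestamp or non-numeric/NA temperature)
    are skipped and reported with their 1-based line numbers.
    """
    raw = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = [c for c in _LOGGER_COLUMNS if c not in raw.columns]
    if missing:
        raise LoggerFormatError(f"missing required column(s): {', '.join(missing)}")
    report = LoggerReadReport()
    ts = pd.to_datetime(raw["timestamp"], errors="coerce", format="ISO8601")
    temp = pd.to_numeric(raw["temperature_C"], errors="coerce")
    bad_ts = ts.isna()
    bad_temp = temp.isna()
    for i in np.flatnonzero(bad_ts | bad_temp):
        lineno = int(i) + 2  # header is line 1
        reason = "bad timestamp" if bad_ts.iloc[i] else "bad temperature"
        report.skipped.append((lineno, reason))
    keep = ~(bad_ts | bad_temp)
    records = pd.DataFrame(
        {
            "rock_id": raw.loc[keep, "rock_id"].to_numpy(),
            "timestamp": ts[keep].to_numpy(),
            "temperature": temp[keep].to_numpy(),
        }
    ).reset_index(drop=True)
    report.n_read = len(records)
    return records, report


def write_logger_csv(records: pd.DataFrame, path) -> None:
    """Write a record frame as logger CSV (round-trips through
    :func:`read_logger_csv` on ``rock_id``/``timestamp``/``temperature``)."""
    out = pd.DataFrame(
        {
            "rock_id": records["rock_id"],
            "timestamp": records["timestamp"].dt.strftime("%Y-%m-%dT%H:%M:%S"),
            "temperature_C": records["temperature"],
        }
    )
    out.to_csv(path, index=False)
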