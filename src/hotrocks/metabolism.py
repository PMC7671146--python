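"""Tide-coupled baseline aerobic metabolism.

Resting oxygen-consumption rate is modelled as log-linear in temperature,
``log10(rate, µL O₂/h) = a + b·T``, with separate lines for small (0.9 g)
and large (4.3 g) crabs in air and in water.  Whether a record was taken
in air or water follows from the harmonic tide model (emersed → air).
Records hotter than the mean heat tolerance (30.5 °C, strict) are
censored — at such temperatures the animal would flee or die — and
contribute nothing to cumulative expenditure.

Cumulative daily expenditure integrates the instantaneous rate over the
interval between successive records (the last record of a day carries the
nominal sampling interval).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from hotrocks.microclimate import RockSite
from hotrocks.tides import TideModel, emersion_state

__all__ = [
    "MetabolicParams",
    "ExpenditureSeries",
    "instantaneous_rate",
    "medium_at",
    "daily_expenditure",
    "expenditure_summary",
    "SIZE_CLASSES",
    "MEDIA",
]

SIZE_CLASSES = ("small", "large")
MEDIA = ("air", "water")


@dataclass(frozen=True)
class MetabolicParams:
    """Per (size class × medium) log-linear coefficients on the
    whole-animal scale, plus the censoring threshold."""

    coefficients: dict  # (size_class, medium) -> (a, b)
    censor_threshold: float = 30.5
    masses_g: dict = field(default_factory=lambda: {"small": 0.9, "large": 4.3})

    def __post_init__(self):
        for size in SIZE_CLASSES:
            rates = {}
            for medium in MEDIA:
                key = (size, medium)
                if key not in self.coefficients:
                    raise ValueError(f"missing coefficients for {key}")
                a, b = self.coefficients[key]
                if b <= 0:
                    raise ValueError(
                        f"slope must be positive (rates rise with T): {key}"
                    )
                rates[medium] = 10.0 ** (a + b * 15.0)
            if not rates["air"] < rates["water"]:
                raise ValueError(
                    f"air rate must be below water rate for size {size!r}"
                )

    @classmethod
    def from_config(cls, block: dict) -> "MetabolicParams":
        """Build from the ``metabolism`` config block.

        Coefficient intercepts may be given mass-specific
        (``mass_specific: true``); they are then shifted by
        ``log10(mass_g)`` so all downstream rates are whole-animal.
        """
        masses = {k: float(v) for k, v in block["masses_g"].items()}
        mass_specific = bool(block.get("mass_specific", False))
        coeffs = {}
        for size, media in block["coefficients"].items():
            for medium, ab in media.items():
                a, b = float(ab["a"]), float(ab["b"])
                if mass_specific:
                    a += np.log10(masses[size])
                coeffs[(size, medium)] = (a, b)
        return cls(
            coefficients=coeffs,
            censor_threshold=float(block["censor_threshold_c"]),
            masses_g=masses,
        )


@dataclass(frozen=True)
class ExpenditureSeries:
    """Instantaneous rates per record and cumulative expenditure per
    rock-day.

    ``rates`` has one row per input record (``rate_uL_O2_per_h`` is NaN
    where censored); ``daily`` has one row per rock-day with the
    time-integrated ``cumulative_uL_O2`` (censored records contribute 0)
    and the censored-record count.
    """

    rates: pd.DataFrame
    daily: pd.DataFrame
    size_class: str


def instantaneous_rate(T, medium: str, size_class: str, params: MetabolicParams):
    """Whole-animal rate (µL O₂/h) at temperature ``T`` (°C), or NaN when
    the record is censored (``T`` strictly above the threshold).

    Accepts scalars or arrays.
    """
    if size_class not in SIZE_CLASSES:
        raise ValueError(f"unknown size class {size_class!r}")
    if medium not in MEDIA:
        raise ValueError(f"unknown medium {medium!r}")
    a, b = params.coefficients[(size_class, medium)]
    T = np.asarray(T, dtype=float)
    rate = 10.0 ** (a + b * T)
    rate = np.where(T > params.censor_threshold, np.nan, rate)
    return float(rate) if rate.ndim == 0 else rate


def medium_at(rock: RockSite, t, tide: TideModel):
    """"air" when the rock is emersed at time ``t``, else "water"
    (a tide exactly at the rock's elevation counts as immersed)."""
    em = emersion_state(rock, tide, t)
    if np.ndim(em) == 0:
        return "air" if em else "water"
    return np.where(em, "air", "water")


def _interval_hours(times: pd.Series, nominal_h: float) -> np.ndarray:
    dt = times.diff().shift(-1).dt.total_seconds().to_numpy() / 3600.0
    dt[-1] = nominal_h
    return dt


def daily_expenditure(
    records: pd.DataFrame,
    rock: RockSite,
    tide: TideModel,
    size_class: str,
    params: MetabolicParams,
    *,
    nominal_interval_min: float = 30.0,
) -> ExpenditureSeries:
    """Instantaneous rates and per-day cumulative expenditure for one
    rock's record frame (columns ``timestamp, temperature``; must be
    time-sorted).

    Each record's rate applies for the interval until the next record of
    the same day; the day's last record carries the nominal sampling
    interval.  Mixed 30-/15-minute spacing is therefore handled
    per-interval.  Censored records contribute zero and are counted.
    """
    if len(records) == 0:
        empty_daily = pd.DataFrame(
            columns=["rock_id", "date", "cumulative_uL_O2", "n_censored", "n_records"]
        )
        return ExpenditureSeries(records.copy(), empty_daily, size_class)
    ts = records["timestamp"].reset_index(drop=True)
    if not ts.is_monotonic_increasing:
        raise ValueError("records must be sorted by timestamp")

    medium = medium_at(rock, ts.to_numpy(), tide)
    T = records["temperature"].to_numpy(dtype=float)
    a_air = params.coefficients[(size_class, "air")]
    a_wat = params.coefficients[(size_class, "water")]
    log_rate = np.where(
        medium == "air", a_air[0] + a_air[1] * T, a_wat[0] + a_wat[1] * T
    )
    rate = 10.0**log_rate
    censored = T > params.censor_threshold
    rate[censored] = np.nan

    day = ts.dt.normalize()
    nominal_h = nominal_interval_min / 60.0
    dt_h = np.empty(len(ts))
    for _, idx in ts.groupby(day).groups.items():
        dt_h[idx] = _interval_hours(ts.loc[idx], nominal_h)

    rates = pd.DataFrame(
        {
            "rock_id": rock.rock_id,
            "timestamp": ts,
            "temperature": T,
            "medium": medium,
            "rate_uL_O2_per_h": rate,
            "censored": censored,
            "interval_h": dt_h,
        }
    )
    contrib = np.where(censored, 0.0, rate * dt_h)
    daily = (
        rates.assign(contrib=contrib, date=day)
        .groupby("date", observed=True)
        .agg(
            cumulative_uL_O2=("contrib", "sum"),
            n_censored=("censored", "sum"),
            n_records=("censored", "size"),
        )
        .reset_index()
    )
    daily.insert(0, "rock_id", rock.rock_id)
    return ExpenditureSeries(rates, daily, size_class)


def expenditure_summary(
    series: dict[str, list[ExpenditureSeries]] | list[tuple[str, ExpenditureSeries]],
) -> pd.DataFrame:
    """Per-zone × size-class summary of metabolic output.

    Accepts ``{zone: [ExpenditureSeries, ...]}`` (or an equivalent list of
    ``(zone, series)`` pairs) and reports, per zone and size class, the
    mean/SD of instantaneous rates, of per-rock maximum instantaneous
    rates (SD across rocks), and of per-rock-day cumulative expenditure.
    """
    if isinstance(series, dict):
        pairs = [(z, s) for z, lst in series.items() for s in lst]
    else:
        pairs = list(series)
    rows = []
    frame = pd.concat(
        [s.rates.assign(zone=z, size_class=s.size_class) for z, s in pairs],
        ignore_index=True,
    )
    daily = pd.concat(
        [s.daily.assign(zone=z, size_class=s.size_class) for z, s in pairs],
        ignore_index=True,
    )
    for (zone, size), grp in frame.groupby(["zone", "size_class"], observed=True):
        rock_max = grp.groupby("rock_id", observed=True)["rate_uL_O2_per_h"].max()
        dsub = daily[(daily["zone"] == zone) & (daily["size_class"] == size)]
        rows.append(
            {
                "zone": zone,
                "size_class": size,
                "mean_rate": grp["rate_uL_O2_per_h"].mean(),
                "sd_rate": grp["rate_uL_O2_per_h"].std(),
                "mean_max_rate": rock_max.mean(),
                "sd_max_rate": rock_max.std(),
                "mean_cumulative": dsub["cumulative_uL_O2"].mean(),
                "sd_cumulative": dsub["cumulative_uL_O2"].std(),
                "n_rocks": grp["rock_id"].nunique(),
            }
        )
    return pd.DataFrame(rows)
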