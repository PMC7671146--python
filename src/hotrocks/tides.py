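"""Harmonic tide model and immersion/emersion state.

Predicted water height drives two things downstream: whether an under-rock
record was taken in air or in water (metabolism), and when a rock's
temperature follows the shared water process versus an air-driven target
(microclimate synthesis).  The model is a generic sum of cosine
constituents around a mean level, with an optional time/height offset
correction for transferring a prediction between nearby sites.
"""

from __future__ import annotations

from dataclasses import dataclass
from datetime import datetime

import numpy as np
import pandas as pd

__all__ = ["TideModel", "tide_height", "emersion_state"]

#: reference epoch for constituent phases (arbitrary but fixed)
_EPOCH = pd.Timestamp("2000-01-01 00:00:00")


@dataclass(frozen=True)
class TideModel:
    """Sum-of-cosines tide: ``mean + Σ aᵢ·cos(2π t/Tᵢ + φᵢ)``.

    Parameters
    ----------
    constituents
        Sequence of ``(amplitude_m, period_h, phase_rad)`` triples.
    mean_level
        Mean water level (m above the elevation datum, MLLW).
    time_shift_h, height_shift_m
        Offset correction applied when transferring predictions between
        sites: the time argument is shifted by ``time_shift_h`` hours and
        the height by ``height_shift_m`` metres.
    """

    constituents: tuple[tuple[float, float, float], ...] = ()
    mean_level: float = 0.0
    time_shift_h: float = 0.0
    height_shift_m: float = 0.0

    @classmethod
    def from_config(cls, block: dict) -> "TideModel":
        off = block.get("offset_correction", {}) or {}
        return cls(
            constituents=tuple(tuple(c) for c in block.get("constituents", [])),
            mean_level=float(block.get("mean_level_m", 0.0)),
            time_shift_h=float(off.get("time_shift_h", 0.0)),
            height_shift_m=float(off.get("height_shift_m", 0.0)),
        )

    @property
    def amplitude_sum(self) -> float:
        return float(sum(a for a, _, _ in self.constituents))


def _hours_since_epoch(t) -> np.ndarray | float:
    ts = pd.DatetimeIndex(np.atleast_1d(np.asarray(t, dtype="datetime64[ns]")))
    hours = (ts - _EPOCH) / pd.Timedelta(hours=1)
    return np.asarray(hours, dtype=float)


def tide_height(model: TideModel, t: datetime | np.ndarray | pd.DatetimeIndex):
    """Predicted water height (m) at time(s) ``t``.

    Continuous in ``t``; returns a float for a scalar input, else an array.
    """
    scalar = np.ndim(t) == 0 and not isinstance(t, (pd.DatetimeIndex, np.ndarray))
    th = _hours_since_epoch(t) + model.time_shift_h
    height = np.full_like(th, model.mean_level, dtype=float)
    for amp, period, phase in model.constituents:
        height += amp * np.cos(2.0 * np.pi * th / period + phase)
    height += model.height_shift_m
    return float(height[0]) if scalar else height


def emersion_state(rock, model: TideModel, t) -> bool | np.ndarray:
    """True iff the rock is emersed (in air): tide height strictly below
    the rock's intertidal elevation.  A tide exactly at the elevation
    counts as immersed.
    """
    h = tide_height(model, t)
    return h < rock.elevation
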