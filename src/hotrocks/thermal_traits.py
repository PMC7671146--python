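"""Size-dependent thermal traits and the cardiac break-point estimator.

Three behavioural/physiological thresholds are modelled as functions of
carapace width (cw, mm):

* ``CT_max(cw) = 33.0 − 0.14·cw`` — cardiac heat tolerance, the break
  point of heart performance under a 0.1 °C/min ramp;
* ``T_esc(cw) = 35.12 − 0.88·cw`` — the temperature at which a crab
  voluntarily flees a heated refuge;
* ``T_pref = 15.0`` — preferred temperature, size-independent.

Large crabs are both physiologically and behaviourally less heat-tolerant
than small ones, and ``T_pref < T_esc(cw) < CT_max(cw)`` across the
natural 4–21 mm size range.

The break-point estimator reproduces the standard cardiac-ramp protocol:
fit one OLS line to the first 200 points of the heart-rate-vs-temperature
trace and another to the final 60 points before flatline, and report the
temperature where they intersect.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = [
    "RampTrace",
    "CrabTraits",
    "TraitRegression",
    "TraitCoefficients",
    "DegenerateFitError",
    "breakpoint_temperature",
    "ctmax_of_size",
    "tesc_of_size",
    "tpref",
    "fit_linear_trait",
    "sample_individual_traits",
]


class DegenerateFitError(ValueError):
    """Raised when a regression or intersection is ill-posed (constant
    predictor, parallel break-point segments)."""


@dataclass(frozen=True)
class RampTrace:
    """A heart-rate trace recorded during a thermal ramp."""

    temperature: np.ndarray  # °C, non-decreasing
    response: np.ndarray  # beats/min
    start_temp: float | None = None
    ramp_rate: float | None = None  # °C/min

    def __post_init__(self):
        t = np.asarray(self.temperature, dtype=float)
        r = np.asarray(self.response, dtype=float)
        if t.shape != r.shape or t.ndim != 1:
            raise ValueError("temperature and response must be equal-length 1-D")
        if np.any(np.diff(t) < 0):
            raise ValueError("ramp temperatures must be non-decreasing")
        object.__setattr__(self, "temperature", t)
        object.__setattr__(self, "response", r)

    def __len__(self) -> int:
        return len(self.temperature)


@dataclass(frozen=True)
class CrabTraits:
    """Thermal thresholds of one individual."""

    carapace_width: float  # mm
    ct_max: float  # °C
    t_esc: float  # °C
    t_pref: float  # °C


@dataclass(frozen=True)
class TraitRegression:
    """OLS summary for a trait-on-size (or temperature-on-elevation) model."""

    intercept: float
    slope: float
    r_squared: float
    p_value: float
    n: int
    residual_sd: float
    slope_se: float


@dataclass(frozen=True)
class TraitCoefficients:
    """Mean trait functions plus residual SDs used for individual sampling."""

    ctmax_intercept: float = 33.0
    ctmax_slope: float = -0.14
    ctmax_residual_sd: float = 1.5
    tesc_intercept: float = 35.12
    tesc_slope: float = -0.88
    tesc_residual_sd: float = 2.0
    tpref: float = 15.0
    mean_ctmax: float = 30.5
    mean_tesc: float = 20.5

    @classmethod
    def from_config(cls, block: dict) -> "TraitCoefficients":
        return cls(
            ctmax_intercept=float(block["ctmax"]["intercept_c"]),
            ctmax_slope=float(block["ctmax"]["slope_c_per_mm"]),
            ctmax_residual_sd=float(block["ctmax"]["residual_sd_c"]),
            tesc_intercept=float(block["tesc"]["intercept_c"]),
            tesc_slope=float(block["tesc"]["slope_c_per_mm"]),
            tesc_residual_sd=float(block["tesc"]["residual_sd_c"]),
            tpref=float(block["tpref_c"]),
            mean_ctmax=float(block["mean_ctmax_c"]),
            mean_tesc=float(block["mean_tesc_c"]),
        )


_DEFAULT = TraitCoefficients()


def _check_cw(cw) -> np.ndarray:
    cw = np.asarray(cw, dtype=float)
    if np.any(cw <= 0):
        raise ValueError("carapace width must be positive")
    return cw


def ctmax_of_size(cw, coeffs: TraitCoefficients = _DEFAULT):
    """Mean cardiac heat tolerance (°C) at carapace width ``cw`` (mm)."""
    cw = _check_cw(cw)
    out = coeffs.ctmax_intercept + coeffs.ctmax_slope * cw
    return float(out) if out.ndim == 0 else out


def tesc_of_size(cw, coeffs: TraitCoefficients = _DEFAULT):
    """Mean escape temperature (°C) at carapace width ``cw`` (mm)."""
    cw = _check_cw(cw)
    out = coeffs.tesc_intercept + coeffs.tesc_slope * cw
    return float(out) if out.ndim == 0 else out


def tpref(coeffs: TraitCoefficients = _DEFAULT) -> float:
    """Preferred temperature (°C); unrelated to body size."""
    return coeffs.tpref


def _truncate_flatline(trace: RampTrace, flatline_frac: float) -> RampTrace:
    """Drop the trailing run where the response has collapsed below
    ``flatline_frac`` of the trace's peak response."""
    r = trace.response
    peak = float(np.max(r)) if len(r) else 0.0
    if peak <= 0:
        return trace
    threshold = flatline_frac * peak
    end = len(r)
    while end > 0 and r[end - 1] < threshold:
        end -= 1
    return RampTrace(trace.temperature[:end], r[:end], trace.start_temp, trace.ramp_rate)


def _ols_line(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    slope, intercept = np.polyfit(x, y, 1)
    return float(slope), float(intercept)


def breakpoint_temperature(
    trace: RampTrace,
    head_n: int = 200,
    tail_n: int = 60,
    *,
    flatline_frac: float = 0.05,
    parallel_tol: float = 1e-9,
) -> float:
    """Cardiac break-point temperature: the intersection of OLS lines
    through the first ``head_n`` and the final ``tail_n`` pre-flatline
    points of the ramp trace.

    Raises
    ------
    ValueError
        If fewer than ``head_n + tail_n`` points remain after flatline
        truncation, or the intersection falls outside the observed
        temperature range.
    DegenerateFitError
        If the two segments are (near-)parallel.
    """
    trimmed = _truncate_flatline(trace, flatline_frac)
    if len(trimmed) < head_n + tail_n:
        raise ValueError(
            f"trace has {len(trimmed)} usable points; "
            f"need >= {head_n + tail_n} for the {head_n}+{tail_n} protocol"
        )
    t, r = trimmed.temperature, trimmed.response
    b1, c1 = _ols_line(t[:head_n], r[:head_n])
    b2, c2 = _ols_line(t[-tail_n:], r[-tail_n:])
    if abs(b1 - b2) < parallel_tol:
        raise DegenerateFitError("head and tail segments are parallel")
    t_break = (c2 - c1) / (b1 - b2)
    t_lo, t_hi = float(np.min(trace.temperature)), float(np.max(trace.temperature))
    if not t_lo <= t_break <= t_hi:
        raise ValueError(
            f"break point {t_break:.2f} °C outside observed range "
            f"[{t_lo:.2f}, {t_hi:.2f}]"
        )
    return float(t_break)


def fit_linear_trait(x, y) -> TraitRegression:
    """Simple OLS of ``y`` on ``x`` with the classical t-test for the slope.

    Used both for trait-on-size regressions and for habitat models
    (temperature vs. elevation or rock size).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length 1-D sequences")
    n = len(x)
    if n < 3:
        raise ValueError("need at least 3 observations")
    if np.ptp(x) == 0:
        raise DegenerateFitError("x is constant; slope is unidentified")
    res = stats.linregress(x, y)
    resid = y - (res.intercept + res.slope * x)
    residual_sd = float(np.sqrt(np.sum(resid**2) / (n - 2)))
    return TraitRegression(
        intercept=float(res.intercept),
        slope=float(res.slope),
        r_squared=float(res.rvalue**2),
        p_value=float(res.pvalue),
        n=n,
        residual_sd=residual_sd,
        slope_se=float(res.stderr),
    )


def sample_individual_traits(
    cw: float,
    rng: np.random.Generator,
    coeffs: TraitCoefficients = _DEFAULT,
    *,
    ctmax_sd: float | None = None,
    tesc_sd: float | None = None,
) -> CrabTraits:
    """Draw one individual's traits: the mean size functions plus
    independent Gaussian residuals (SDs default to the configured residual
    SDs; zero SDs recover the deterministic functions)."""
    ctmax_sd = coeffs.ctmax_residual_sd if ctmax_sd is None else ctmax_sd
    tesc_sd = coeffs.tesc_residual_sd if tesc_sd is None else tesc_sd
    if ctmax_sd < 0 or tesc_sd < 0:
        raise ValueError("residual SDs must be >= 0")
    ct = ctmax_of_size(cw, coeffs) + (rng.normal(0.0, ctmax_sd) if ctmax_sd else 0.0)
    te = tesc_of_size(cw, coeffs) + (rng.normal(0.0, tesc_sd) if tesc_sd else 0.0)
    return CrabTraits(
        carapace_width=float(cw), ct_max=float(ct), t_esc=float(te),
        t_pref=coeffs.tpref,
    )
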