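"""Postprandial concentration curves and their named summary features.

A sequential mixed-meal challenge (breakfast at 0 min, lunch at 240 min)
produces, per participant, a timed concentration series for each analyte.
Glycemic responses are summarized by fasting level, 1-h and 2-h incremental
AUC, 30-min and 1-h rises, and the maxima of the first (0-120 min) and
second (240-360 min) glucose peaks; lipemic responses by fasting level,
6-h incremental AUC, 6-h rise, the 0-360 min maximum, and the 4-h and 6-h
concentrations.  The incremental AUC follows the positive-increment
trapezoid convention: excursions below the fasting baseline contribute
zero area (a signed net-area variant is available via ``positive_only``).
Features are defined on sampled points only; no interpolation is done.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .exceptions import (
    InsufficientDataError,
    InvalidParameterError,
    MissingTimepointError,
)

__all__ = [
    "PostprandialCurve",
    "GlycemicFeatures",
    "LipemicFeatures",
    "curve_model",
    "iauc",
    "rise_from_fasting",
    "windowed_max",
    "extract_glycemic_features",
    "extract_lipemic_features",
    "GLYCEMIC_FEATURE_NAMES",
    "LIPEMIC_FEATURE_NAMES",
]

#: Windows (minutes) for the two glucose peaks and the TG maximum.
FIRST_GLUCOSE_PEAK_WINDOW = (0.0, 120.0)
SECOND_GLUCOSE_PEAK_WINDOW = (240.0, 360.0)
TG_MAX_WINDOW = (0.0, 360.0)

GLYCEMIC_FEATURE_NAMES = [
    "glu_fasting",
    "glu_1h_iauc",
    "glu_2h_iauc",
    "glu_30min_rise",
    "glu_1h_rise",
    "glu_max1",
    "glu_max2",
]
LIPEMIC_FEATURE_NAMES = [
    "tg_fasting",
    "tg_6h_iauc",
    "tg_6h_rise",
    "tg_max",
    "tg_at_4h",
    "tg_at_6h",
]


@dataclass(frozen=True)
class PostprandialCurve:
    """One participant's timed concentration series for one analyte.

    times are minutes since the breakfast meal, strictly increasing with
    ``times[0] == 0`` (the fasting draw); values are concentrations in
    mmol/L and must be non-negative.
    """

    participant_id: str
    analyte: str
    times: np.ndarray
    values: np.ndarray

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        v = np.asarray(self.values, dtype=float)
        if t.shape != v.shape or t.ndim != 1:
            raise InvalidParameterError("times and values must be equal-length 1-D arrays")
        if t.size < 1 or t[0] != 0:
            raise InvalidParameterError("first sampling time must be 0 (fasting)")
        if np.any(np.diff(t) <= 0):
            raise InvalidParameterError("times must be strictly increasing")
        if np.any(v < 0):
            raise InvalidParameterError("concentrations must be non-negative")
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "values", v)

    @property
    def fasting(self) -> float:
        return float(self.values[0])

    def value_at(self, at: float) -> float:
        """Concentration at a sampled time; raises if `at` was not sampled."""
        idx = np.flatnonzero(np.isclose(self.times, at))
        if idx.size == 0:
            raise MissingTimepointError(
                f"time {at} min not sampled for {self.participant_id}/{self.analyte}"
            )
        return float(self.values[idx[0]])


@dataclass(frozen=True)
class GlycemicFeatures:
    """The seven named glycemic curve summaries plus the two peak times."""

    participant_id: str
    glu_fasting: float
    glu_1h_iauc: float
    glu_2h_iauc: float
    glu_30min_rise: float
    glu_1h_rise: float
    glu_max1: float
    glu_tmax1: float
    glu_max2: float
    glu_tmax2: float

    def as_dict(self) -> dict[str, float]:
        d = {k: getattr(self, k) for k in GLYCEMIC_FEATURE_NAMES}
        d["glu_tmax1"] = self.glu_tmax1
        d["glu_tmax2"] = self.glu_tmax2
        return d


@dataclass(frozen=True)
class LipemicFeatures:
    """The six named lipemic curve summaries plus the peak time."""

    participant_id: str
    tg_fasting: float
    tg_6h_iauc: float
    tg_6h_rise: float
    tg_max: float
    tg_tmax: float
    tg_at_4h: float
    tg_at_6h: float

    def as_dict(self) -> dict[str, float]:
        d = {k: getattr(self, k) for k in LIPEMIC_FEATURE_NAMES}
        d["tg_tmax"] = self.tg_tmax
        return d


def curve_model(
    t: np.ndarray | float,
    peaks: list[tuple[float, float, float]],
    baseline: float,
) -> np.ndarray | float:
    """Parametric meal-response curve: baseline plus Gaussian peaks.

    Each peak is an (amplitude mmol/L, peak-time min, width min) triple;
    the curve is ``baseline + sum_k amp_k * exp(-(t - time_k)^2 / (2 width_k^2))``.

    Raises
    ------
    InvalidParameterError
        If any width is not strictly positive.
    """
    t_arr = np.asarray(t, dtype=float)
    out = np.full_like(t_arr, float(baseline), dtype=float)
    for amp, peak_time, width in peaks:
        if width <= 0:
            raise InvalidParameterError(f"peak width must be > 0, got {width}")
        out = out + amp * np.exp(-((t_arr - peak_time) ** 2) / (2.0 * width**2))
    if np.isscalar(t):
        return float(out)
    return out


def iauc(
    curve: PostprandialCurve,
    window_end: float,
    positive_only: bool = True,
) -> float:
    """Incremental area under the curve above the fasting baseline.

    Trapezoidal area of ``max(value - fasting, 0)`` over ``[0, window_end]``
    in mmol/L*min, restricted to sampled points.  With
    ``positive_only=False`` the signed net area is returned instead.
    """
    mask = curve.times <= window_end + 1e-9
    if mask.sum() < 2:
        raise InsufficientDataError(
            f"need >= 2 samples in [0, {window_end}] min, have {int(mask.sum())}"
        )
    t = curve.times[mask]
    inc = curve.values[mask] - curve.fasting
    if positive_only:
        inc = np.maximum(inc, 0.0)
    return float(np.trapezoid(inc, t))


def rise_from_fasting(curve: PostprandialCurve, at: float) -> float:
    """Concentration change from fasting at a sampled time (may be negative)."""
    return curve.value_at(at) - curve.fasting


def windowed_max(
    curve: PostprandialCurve, window: tuple[float, float]
) -> tuple[float, float]:
    """Maximum sampled concentration in a closed time window and its time.

    Ties resolve to the earliest time.
    """
    lo, hi = window
    mask = (curve.times >= lo - 1e-9) & (curve.times <= hi + 1e-9)
    if not mask.any():
        raise InsufficientDataError(f"no samples in window [{lo}, {hi}] min")
    t = curve.times[mask]
    v = curve.values[mask]
    i = int(np.argmax(v))  # argmax returns the first maximum -> earliest time
    return float(v[i]), float(t[i])


def _require_times(curve: PostprandialCurve, required: list[float]) -> None:
    missing = [at for at in required if not np.any(np.isclose(curve.times, at))]
    if missing:
        raise MissingTimepointError(
            f"{curve.analyte} curve for {curve.participant_id} is missing "
            f"required times (min): {missing}"
        )


def extract_glycemic_features(curve: PostprandialCurve) -> GlycemicFeatures:
    """Compute all glycemic features from a glucose curve.

    Requires samples at 30, 60 and 120 min (and at least one sample in each
    peak window).
    """
    if curve.analyte != "glucose":
        raise InvalidParameterError(f"expected a glucose curve, got {curve.analyte!r}")
    _require_times(curve, [30.0, 60.0, 120.0])
    max1, tmax1 = windowed_max(curve, FIRST_GLUCOSE_PEAK_WINDOW)
    max2, tmax2 = windowed_max(curve, SECOND_GLUCOSE_PEAK_WINDOW)
    return GlycemicFeatures(
        participant_id=curve.participant_id,
        glu_fasting=curve.fasting,
        glu_1h_iauc=iauc(curve, 60.0),
        glu_2h_iauc=iauc(curve, 120.0),
        glu_30min_rise=rise_from_fasting(curve, 30.0),
        glu_1h_rise=rise_from_fasting(curve, 60.0),
        glu_max1=max1,
        glu_tmax1=tmax1,
        glu_max2=max2,
        glu_tmax2=tmax2,
    )


def extract_lipemic_features(curve: PostprandialCurve) -> LipemicFeatures:
    """Compute all lipemic features from a TG curve.

    Requires samples at 240 and 360 min.
    """
    if curve.analyte != "tg":
        raise InvalidParameterError(f"expected a tg curve, got {curve.analyte!r}")
    _require_times(curve, [240.0, 360.0])
    tg_max, tmax = windowed_max(curve, TG_MAX_WINDOW)
    return LipemicFeatures(
        participant_id=curve.participant_id,
        tg_fasting=curve.fasting,
        tg_6h_iauc=iauc(curve, 360.0),
        tg_6h_rise=rise_from_fasting(curve, 360.0),
        tg_max=tg_max,
        tg_tmax=tmax,
        tg_at_4h=curve.value_at(240.0),
        tg_at_6h=curve.value_at(360.0),
    )
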