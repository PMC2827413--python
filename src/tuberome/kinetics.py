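"""Tuber growth-velocity estimation from repeated volume measurements.

A tuber scanned on several days yields a (time, volume) series; growth
velocity in cm^3/day is the OLS slope of volume on time (an endpoint
difference mode is available). Tubers are classified as growing when the
velocity exceeds either an absolute threshold (cm^3/day) or a relative
threshold times their mean volume (fraction/day) — "virtually stopped"
tubers fail both.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
from scipy import stats

__all__ = ["GrowthSeries", "GrowthEstimate", "estimate_velocity", "classify_growth"]

DEFAULT_ABS_THRESHOLD = 0.1  # cm^3/day
DEFAULT_REL_THRESHOLD = 0.01  # fraction of mean volume per day


@dataclass(frozen=True)
class GrowthSeries:
    """Per-tuber (time in days, volume in cm^3) observations, times increasing."""

    tuber_id: int
    times: tuple[float, ...]
    volumes: tuple[float, ...]

    def __post_init__(self) -> None:
        if len(self.times) != len(self.volumes):
            raise ValueError("times and volumes must have equal length")
        if len(self.times) < 2:
            raise ValueError("a growth series needs >= 2 observations")
        diffs = np.diff(self.times)
        if np.any(diffs <= 0):
            raise ValueError("times must be strictly increasing (no duplicates)")

    @property
    def mean_volume(self) -> float:
        return float(np.mean(self.volumes))


@dataclass(frozen=True)
class GrowthEstimate:
    tuber_id: int
    velocity: float  # cm^3/day
    intercept: float  # cm^3
    r_squared: float
    growing: bool

    def __post_init__(self) -> None:
        if not (0.0 <= self.r_squared <= 1.0 + 1e-12):
            raise ValueError(f"r_squared out of [0, 1]: {self.r_squared}")


def estimate_velocity(
    series: GrowthSeries,
    method: Literal["ols", "endpoint"] = "ols",
    abs_threshold: float = DEFAULT_ABS_THRESHOLD,
    rel_threshold: float = DEFAULT_REL_THRESHOLD,
) -> GrowthEstimate:
    """Estimate growth velocity (cm^3/day) for one tuber series.

    ``ols`` fits volume on time by least squares; ``endpoint`` uses
    (V_last - V_first) / (t_last - t_first). With exactly two observations
    both coincide and r^2 = 1. A flat series has velocity 0.
    """
    t = np.asarray(series.times, dtype=float)
    v = np.asarray(series.volumes, dtype=float)
    if method == "endpoint":
        slope = float((v[-1] - v[0]) / (t[-1] - t[0]))
        intercept = float(v[0] - slope * t[0])
        resid = v - (intercept + slope * t)
        sst = float(np.sum((v - v.mean()) ** 2))
        r2 = 1.0 if sst == 0 else max(0.0, 1.0 - float(np.sum(resid**2)) / sst)
    elif method == "ols":
        fit = stats.linregress(t, v)
        slope, intercept = float(fit.slope), float(fit.intercept)
        # flat series: linregress returns r = 0 (undefined); the fit is exact
        r2 = 1.0 if np.ptp(v) == 0 or len(t) == 2 else float(fit.rvalue) ** 2
    else:
        raise ValueError(f"unknown method {method!r}")
    growing = classify_growth(
        slope, abs_threshold=abs_threshold, rel_threshold=rel_threshold,
        mean_volume=series.mean_volume,
    )
    return GrowthEstimate(
        tuber_id=series.tuber_id,
        velocity=slope,
        intercept=intercept,
        r_squared=min(r2, 1.0),
        growing=growing,
    )


def classify_growth(
    velocity: float,
    abs_threshold: float = DEFAULT_ABS_THRESHOLD,
    rel_threshold: float = DEFAULT_REL_THRESHOLD,
    mean_volume: float = 0.0,
) -> bool:
    """Growing iff velocity > abs_threshold OR velocity > rel_threshold * mean_volume."""
    if abs_threshold < 0 or rel_threshold < 0:
        raise ValueError("thresholds must be >= 0")
    if mean_volume < 0:
        raise ValueError("mean_volume must be >= 0")
    return bool(velocity > abs_threshold or velocity > rel_threshold * mean_volume)
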