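"""Spirometric index computation from raw expiratory flow curves.

Measured indices follow the standard definitions: FVC is the total exhaled
volume, FEV1 the volume exhaled in the first second after time zero, PEF the
maximum instantaneous flow, FEF25-75 the mean flow between 25% and 75% of
FVC exhaled, and FEF75 the instantaneous flow at 75% of FVC exhaled.  Time
zero defaults to the first sample whose flow reaches 5% of PEF; the standard
back-extrapolation convention is available behind a flag.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.integrate import cumulative_trapezoid

from .simulate import SpiroCurve

__all__ = [
    "PFTIndex",
    "PFTResult",
    "CurveValidityError",
    "compute_volume",
    "compute_indices",
    "INDEX_NAMES",
]

INDEX_NAMES = ("FVC", "FEV1", "FEV1_FVC", "PEF", "FEF25_75", "FEF75")

#: fraction of PEF defining the default time-zero sample
_TIME_ZERO_PEF_FRAC = 0.05
#: tolerated back-flow (fraction of exhaled volume) before a curve is invalid
_MAX_BACKFLOW_FRAC = 0.05


class CurveValidityError(ValueError):
    """Raised when a maneuver fails basic validity checks."""


@dataclass
class PFTIndex:
    """Measured / predicted / LLN / z-score quadruple for one index."""

    name: str
    measured: float | None = None
    predicted: float | None = None
    lln: float | None = None
    z_score: float | None = None

    @property
    def pct_predicted(self) -> float | None:
        if self.measured is None or self.predicted is None:
            return None
        return 100.0 * self.measured / self.predicted

    def to_dict(self) -> dict:
        return {
            "name": self.name,
            "measured": self.measured,
            "predicted": self.predicted,
            "lln": self.lln,
            "z_score": self.z_score,
            "pct_predicted": self.pct_predicted,
        }


@dataclass
class PFTResult:
    """Full pulmonary-function result for one maneuver."""

    indices: dict = field(default_factory=dict)  # name -> PFTIndex
    t25: float | None = None  # s, time at 25% of FVC exhaled
    t75: float | None = None  # s, time at 75% of FVC exhaled
    time_zero: float = 0.0  # s, maneuver clock origin
    warnings: list = field(default_factory=list)

    def __getitem__(self, name: str) -> PFTIndex:
        return self.indices[name]

    def __contains__(self, name: str) -> bool:
        return name in self.indices

    def measured(self, name: str) -> float | None:
        idx = self.indices.get(name)
        return None if idx is None else idx.measured

    def to_dict(self) -> dict:
        return {
            "indices": {k: v.to_dict() for k, v in self.indices.items()},
            "t25": self.t25,
            "t75": self.t75,
            "time_zero": self.time_zero,
            "warnings": list(self.warnings),
        }


def compute_volume(curve: SpiroCurve) -> np.ndarray:
    """Cumulative exhaled volume (L) by trapezoidal integration; v[0] = 0."""
    flow = np.asarray(curve.flow, dtype=float)
    if flow.size < 2:
        raise CurveValidityError("curve must have at least 2 samples")
    return cumulative_trapezoid(flow, dx=curve.dt, initial=0.0)


def _time_zero(curve: SpiroCurve, back_extrapolate: bool) -> float:
    flow = curve.flow
    pef = float(np.max(flow))
    if pef <= 0:
        raise CurveValidityError("non-positive peak flow")
    i_pef = int(np.argmax(flow))
    if back_extrapolate:
        # standard convention: extrapolate the steepest rising-limb slope
        # back to zero volume and take the intercept time
        rising = np.diff(flow[: i_pef + 1]) / curve.dt
        if rising.size == 0 or np.max(rising) <= 0:
            return 0.0
        j = int(np.argmax(rising))
        slope = rising[j]
        t_mid = (j + 0.5) * curve.dt
        f_mid = 0.5 * (flow[j] + flow[j + 1])
        return max(t_mid - f_mid / slope, 0.0)
    idx = np.nonzero(flow[: i_pef + 1] >= _TIME_ZERO_PEF_FRAC * pef)[0]
    return float(idx[0]) * curve.dt if idx.size else 0.0


def compute_indices(
    curve: SpiroCurve, back_extrapolate: bool = False
) -> PFTResult:
    """Compute measured spirometric indices for one maneuver.

    Raises :class:`CurveValidityError` for degenerate input (non-positive
    exhaled volume, or substantial back-flow making the volume trace
    non-monotone).  A maneuver shorter than 1 s after time zero yields a
    result whose FEV1 (and ratio) are flagged missing rather than an error.
    """
    flow = np.asarray(curve.flow, dtype=float)
    volume = compute_volume(curve)
    fvc = float(volume[-1])
    if fvc <= 0:
        raise CurveValidityError("non-positive exhaled volume")
    neg = float(np.sum(np.clip(flow, None, 0.0)) * curve.dt)
    if -neg > _MAX_BACKFLOW_FRAC * fvc:
        raise CurveValidityError(
            "volume trace is non-monotone: back-flow exceeds "
            f"{_MAX_BACKFLOW_FRAC:.0%} of exhaled volume"
        )

    time = curve.time
    t0 = _time_zero(curve, back_extrapolate)
    pef = float(np.max(flow))
    result = PFTResult(time_zero=t0)
    result.indices["FVC"] = PFTIndex("FVC", measured=fvc)
    result.indices["PEF"] = PFTIndex("PEF", measured=pef)

    # volume is non-decreasing up to noise; interpolation on (volume, time)
    # needs a strictly increasing axis, so use the running maximum
    vmono = np.maximum.accumulate(volume)
    t_at = lambda v: float(np.interp(v, vmono, time))  # noqa: E731
    result.t25 = t_at(0.25 * fvc)
    result.t75 = t_at(0.75 * fvc)

    if time[-1] - t0 >= 1.0:
        fev1 = float(np.interp(t0 + 1.0, time, volume))
        result.indices["FEV1"] = PFTIndex("FEV1", measured=fev1)
        result.indices["FEV1_FVC"] = PFTIndex("FEV1_FVC", measured=fev1 / fvc)
    else:
        result.indices["FEV1"] = PFTIndex("FEV1", measured=None)
        result.indices["FEV1_FVC"] = PFTIndex("FEV1_FVC", measured=None)
        result.warnings.append("maneuver shorter than 1 s; FEV1 missing")

    denom = result.t75 - result.t25
    fef2575 = 0.5 * fvc / denom if denom > 0 else None
    result.indices["FEF25_75"] = PFTIndex("FEF25_75", measured=fef2575)
    # instantaneous flow at 75% of FVC exhaled
    fef75 = float(np.interp(0.75 * fvc, vmono, flow))
    result.indices["FEF75"] = PFTIndex("FEF75", measured=fef75)
    if result.warnings:
        for w in result.warnings:
            warnings.warn(w, stacklevel=2)
    return result
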