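"""LMS reference equations: predicted values, z-scores, and the LLN.

The reference distribution of each spirometric index is modelled by the LMS
method — skewness L, median M, coefficient of variation S — in the style of
the GLI-2012 multi-ethnic equations:

    M = exp(a0 + a1*ln(height) + a2*ln(age) + Mspline(age))
    S = exp(b0 + b1*ln(age) + Sspline(age))
    z = ((y/M)**L - 1) / (L*S)

with age-indexed spline offsets linearly interpolated from a lookup table.
The lower limit of normal (LLN) is the 5th centile, z = -1.645.

Official GLI-2012 coefficient tables are not redistributed; the loader
accepts their CSV schema (`sex,index,a0,a1,a2,b0,b1,L` plus a spline table
`sex,index,age,m_spline,s_spline`) and a synthetic table of plausible
magnitude ships for tests and simulation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .metrics import INDEX_NAMES, PFTIndex, PFTResult
from .simulate import Demographics

__all__ = [
    "LMSCoefficients",
    "AgeRangeError",
    "lms_predicted",
    "z_score",
    "value_at_z",
    "lln",
    "full_pft",
    "synthetic_reference_table",
    "LLN_Z",
]

LLN_Z = -1.645  # 5th centile of the reference distribution


class AgeRangeError(ValueError):
    """Age outside the spline table's range."""


@dataclass(frozen=True)
class _LMSEntry:
    a0: float
    a1: float  # coefficient on ln(height)
    a2: float  # coefficient on ln(age)
    b0: float
    b1: float  # coefficient on ln(age) in S
    L: float
    spline_age: tuple  # increasing ages, years
    m_spline: tuple
    s_spline: tuple


@dataclass
class LMSCoefficients:
    """Per (sex, index) LMS coefficients with age splines."""

    entries: dict = field(default_factory=dict)  # (sex, index) -> _LMSEntry

    def add(self, sex, index, a0, a1, a2, b0, b1, L,
            spline_age=(0.0, 200.0), m_spline=(0.0, 0.0), s_spline=(0.0, 0.0)):
        self.entries[(sex, index)] = _LMSEntry(
            a0, a1, a2, b0, b1, L,
            tuple(spline_age), tuple(m_spline), tuple(s_spline),
        )

    def has(self, sex: str, index: str) -> bool:
        return (sex, index) in self.entries

    def available_indices(self, sex: str) -> list:
        return [i for (s, i) in self.entries if s == sex]

    @classmethod
    def from_csv(cls, coeff_path, spline_path=None) -> "LMSCoefficients":
        """Load from the CSV schema `sex,index,a0,a1,a2,b0,b1,L` and the
        optional spline CSV `sex,index,age,m_spline,s_spline`."""
        coeffs = pd.read_csv(coeff_path)
        splines = pd.read_csv(spline_path) if spline_path is not None else None
        out = cls()
        for _, row in coeffs.iterrows():
            key_sex, key_index = row["sex"], row["index"]
            if splines is not None:
                sub = splines[
                    (splines["sex"] == key_sex) & (splines["index"] == key_index)
                ].sort_values("age")
            else:
                sub = None
            if sub is not None and len(sub):
                sa = tuple(sub["age"])
                ms = tuple(sub["m_spline"])
                ss = tuple(sub["s_spline"])
            else:
                sa, ms, ss = (0.0, 200.0), (0.0, 0.0), (0.0, 0.0)
            out.add(
                key_sex, key_index,
                row["a0"], row["a1"], row["a2"], row["b0"], row["b1"], row["L"],
                sa, ms, ss,
            )
        return out

    def to_csv(self, coeff_path, spline_path) -> None:
        rows, srows = [], []
        for (sex, index), e in self.entries.items():
            rows.append(
                dict(sex=sex, index=index, a0=e.a0, a1=e.a1, a2=e.a2,
                     b0=e.b0, b1=e.b1, L=e.L)
            )
            for a, m, s in zip(e.spline_age, e.m_spline, e.s_spline):
                srows.append(
                    dict(sex=sex, index=index, age=a, m_spline=m, s_spline=s)
                )
        pd.DataFrame(rows).to_csv(coeff_path, index=False)
        pd.DataFrame(srows).to_csv(spline_path, index=False)


def _interp_spline(age: float, entry: _LMSEntry, what: str) -> float:
    ages = np.asarray(entry.spline_age)
    vals = np.asarray(entry.m_spline if what == "m" else entry.s_spline)
    if age < ages[0] or age > ages[-1]:
        raise AgeRangeError(
            f"age {age} outside spline table range [{ages[0]}, {ages[-1]}]"
        )
    return float(np.interp(age, ages, vals))


def lms_predicted(
    coeffs: LMSCoefficients, demo: Demographics, index_name: str
) -> tuple:
    """Return (M, S, L) for one subject and index."""
    key = (demo.sex, index_name)
    if key not in coeffs.entries:
        raise KeyError(f"no LMS coefficients for {key}")
    e = coeffs.entries[key]
    m = math.exp(
        e.a0
        + e.a1 * math.log(demo.height)
        + e.a2 * math.log(demo.age)
        + _interp_spline(demo.age, e, "m")
    )
    s = math.exp(e.b0 + e.b1 * math.log(demo.age) + _interp_spline(demo.age, e, "s"))
    return m, s, e.L


def z_score(measured: float, m: float, s: float, L: float) -> float:
    """z = ((y/M)^L - 1)/(L*S), with the log-limit when |L| is tiny."""
    if measured <= 0 or m <= 0 or s <= 0:
        raise ValueError("measured, M, and S must all be positive")
    if abs(L) < 1e-6:
        return math.log(measured / m) / s
    return ((measured / m) ** L - 1.0) / (L * s)


def value_at_z(z: float, m: float, s: float, L: float) -> float:
    """Inverse of :func:`z_score`: the measurement whose z-score is ``z``."""
    if m <= 0 or s <= 0:
        raise ValueError("M and S must be positive")
    if abs(L) < 1e-6:
        return m * math.exp(z * s)
    arg = 1.0 + L * s * z
    if arg <= 0:
        raise ValueError("z outside the support of the LMS distribution")
    return m * arg ** (1.0 / L)


def lln(m: float, s: float, L: float) -> float:
    """Lower limit of normal: the value at z = -1.645 (5th centile)."""
    return value_at_z(LLN_Z, m, s, L)


def full_pft(
    curve_or_result,
    demo: Demographics,
    coeffs: LMSCoefficients,
) -> PFTResult:
    """Measured indices plus predicted / LLN / z for every index with
    coefficients.  Accepts a curve or an already-measured :class:`PFTResult`.

    Indices without a coefficient row are emitted measured-only with a
    warning recorded on the result.
    """
    if isinstance(curve_or_result, PFTResult):
        result = curve_or_result
    else:
        from .metrics import compute_indices

        result = compute_indices(curve_or_result)
    for name in INDEX_NAMES:
        idx = result.indices.get(name)
        if idx is None:
            idx = PFTIndex(name)
            result.indices[name] = idx
        if not coeffs.has(demo.sex, name):
            result.warnings.append(f"no reference coefficients for {name}")
            continue
        m, s, L = lms_predicted(coeffs, demo, name)
        idx.predicted = m
        idx.lln = lln(m, s, L)
        if idx.measured is not None and idx.measured > 0:
            idx.z_score = z_score(idx.measured, m, s, L)
    return result


def synthetic_reference_table() -> LMSCoefficients:
    """A synthetic LMS table of GLI-like magnitude for tests and simulation.

    Coefficients were chosen once so that predicted values for typical
    adults land in physiological ranges (FVC ~3-6 L, FEV1/FVC ~0.75-0.8,
    PEF ~7-10 L/s) with coefficients of variation near the 10-15% seen in
    adult reference data.  It is NOT a reproduction of any published table.
    """
    ages = (25.0, 40.0, 55.0, 70.0, 85.0)
    zero = (0.0,) * len(ages)
    c = LMSCoefficients()
    # a1 multiplies ln(height in cm); a2 multiplies ln(age in years)
    for sex, h0 in (("male", 176.0), ("female", 163.0)):
        lnh = math.log(h0)
        base = {
            # index: (M at (h0, age 50), a1, a2, S at age 50, b1, L)
            "FVC": (5.13 if sex == "male" else 4.04, 2.5, -0.30, 0.120, 0.05, 1.0),
            "FEV1": (4.38 if sex == "male" else 3.42, 2.3, -0.38, 0.133, 0.06, 1.0),
            "FEV1_FVC": (0.848, -0.35, -0.065, 0.065, 0.03, 1.2),
            "PEF": (10.2 if sex == "male" else 7.9, 1.9, -0.22, 0.163, 0.04, 1.0),
            "FEF25_75": (4.89 if sex == "male" else 4.03, 1.6, -0.55, 0.215, 0.07, 0.9),
            "FEF75": (2.59 if sex == "male" else 2.18, 1.4, -0.75, 0.284, 0.08, 0.8),
        }
        for index, (m50, a1, a2, s50, b1, L) in base.items():
            a0 = math.log(m50) - a1 * lnh - a2 * math.log(50.0)
            b0 = math.log(s50) - b1 * math.log(50.0)
            c.add(sex, index, a0, a1, a2, b0, b1, L, ages, zero, zero)
    return c
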