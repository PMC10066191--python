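"""Shared tolerance arithmetic: ppm windows and trapezoidal distances/scores.

Mass tolerances in IM-MS metabolomics are conventionally expressed in parts
per million with an absolute floor at low m/z, where ppm windows become
narrower than instrument accuracy.  Retention-time, mobility and CCS
agreement is scored with a trapezoidal (piecewise-linear) penalty: free below
a minimum tolerance, ramping linearly, and saturating above a maximum
tolerance.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "ToleranceRule",
    "TrapezoidParams",
    "ppm_window",
    "mz_half_width",
    "within_mz",
    "trapezoid_distance",
    "score_trapezoid",
]


@dataclass(frozen=True)
class ToleranceRule:
    """m/z tolerance: ``ppm`` above ``floor_below_mz``, absolute floor below.

    Defaults are 20 ppm with a 0.004 Da floor below m/z 200, so the window
    half-width is continuous at the threshold (20 ppm of 200 Da = 0.004 Da).
    """

    ppm: float = 20.0
    abs_floor_da: float = 0.004
    floor_below_mz: float = 200.0

    def __post_init__(self) -> None:
        if self.ppm <= 0 or self.abs_floor_da <= 0 or self.floor_below_mz <= 0:
            raise ValueError("all ToleranceRule fields must be positive")


@dataclass(frozen=True)
class TrapezoidParams:
    """Knots of the trapezoidal penalty: penalty-free below ``tol_min``,
    saturated above ``tol_max``.  Units follow the compared quantity."""

    tol_min: float
    tol_max: float

    def __post_init__(self) -> None:
        if not (0 < self.tol_min < self.tol_max):
            raise ValueError("require 0 < tol_min < tol_max")


def mz_half_width(mz, rule: ToleranceRule = ToleranceRule()):
    """Half-width of the m/z acceptance window at ``mz`` (scalar or array)."""
    mz = np.asarray(mz, dtype=float)
    if np.any(mz <= 0):
        raise ValueError("mz must be positive")
    hw = np.where(mz < rule.floor_below_mz, rule.abs_floor_da, rule.ppm * mz * 1e-6)
    return float(hw) if hw.ndim == 0 else hw


def ppm_window(mz: float, rule: ToleranceRule = ToleranceRule()) -> tuple[float, float]:
    """Symmetric acceptance window ``(low, high)`` about ``mz``."""
    hw = mz_half_width(mz, rule)
    return mz - hw, mz + hw


def within_mz(mz_a, mz_b, rule: ToleranceRule = ToleranceRule()):
    """Whether |mz_a - mz_b| falls within the window centred on ``mz_b``."""
    return np.abs(np.asarray(mz_a, dtype=float) - mz_b) <= mz_half_width(mz_b, rule)


def trapezoid_distance(delta, p: TrapezoidParams):
    """Trapezoidal distance in [0, 1].

    0 for ``delta <= tol_min``; linear ramp on (tol_min, tol_max]; 1 above.
    Accepts scalars or arrays; ``delta`` must be non-negative.
    """
    d = np.asarray(delta, dtype=float)
    if np.any(d < 0):
        raise ValueError("delta must be non-negative")
    out = np.clip((d - p.tol_min) / (p.tol_max - p.tol_min), 0.0, 1.0)
    return float(out) if out.ndim == 0 else out


def score_trapezoid(delta, p: TrapezoidParams):
    """Trapezoidal match score, the exact complement of
    :func:`trapezoid_distance`: 1 below ``tol_min``, 0 above ``tol_max``."""
    out = 1.0 - np.asarray(trapezoid_distance(delta, p))
    return float(out) if out.ndim == 0 else out
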