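"""Ratiometric intracellular-pH calculation from BCECF fluorescence.

BCECF AM is loaded into cells and excited at 490 nm (pH-sensitive) and
440 nm (pH-insensitive); emission is read at 535 nm for both the cell
suspension (S) and its filtrate (F).  The background-corrected ratio

    R = (S490 - S440) / (F490 - F440)

is mapped to intracellular pH through a per-strain calibration curve
acquired with ionophore-equilibrated cells (pHi = pHex) in buffers at
pH 4–8.  The transmembrane gradient is ΔpH = pHi − pHex.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.optimize import curve_fit

__all__ = [
    "FluorescenceReading",
    "CalibrationCurve",
    "emission_ratio",
    "fit_calibration_curve",
    "intracellular_ph",
    "ph_gradient",
]

logger = logging.getLogger("propiokin")


@dataclass(frozen=True)
class FluorescenceReading:
    """Raw dual-excitation intensities for one sample (arbitrary units)."""

    S490: float
    S440: float
    F490: float
    F440: float
    pH_ex: float | None = None
    strain: str = ""

    def __post_init__(self) -> None:
        for name in ("S490", "S440", "F490", "F440"):
            v = getattr(self, name)
            if not math.isfinite(v) or v < 0:
                raise ValueError(f"{name} must be finite and >= 0, got {v}")


def emission_ratio(r: FluorescenceReading) -> float:
    """R = (S490 − S440)/(F490 − F440); the filtrate difference is the
    sole background correction applied."""
    denom = r.F490 - r.F440
    if denom == 0:
        raise ZeroDivisionError(
            "F490 equals F440: filtrate difference is zero, ratio undefined")
    return (r.S490 - r.S440) / denom


def _logistic(pH, A, B, k, m):
    return A + (B - A) / (1.0 + np.exp(-k * (pH - m)))


@dataclass(frozen=True)
class CalibrationCurve:
    """Strictly monotone mapping between emission ratio and pH.

    ``points`` are the (pH, mean R) calibration nodes sorted by pH.
    ``kind`` selects the interpolant: ``"linear"`` is a monotone
    piecewise-linear map through the nodes (default), ``"logistic"`` a
    4-parameter logistic fit.  Extrapolation outside the calibrated
    ratio range is refused.
    """

    points: tuple[tuple[float, float], ...]
    kind: str = "linear"
    logistic_params: tuple[float, float, float, float] | None = None
    strain: str = ""

    @property
    def ph_range(self) -> tuple[float, float]:
        return self.points[0][0], self.points[-1][0]

    @property
    def ratio_range(self) -> tuple[float, float]:
        ratios = [r for _, r in self.points]
        return min(ratios), max(ratios)

    def predict_ratio(self, pH: float) -> float:
        lo, hi = self.ph_range
        if not lo <= pH <= hi:
            raise ValueError(f"pH {pH} outside calibrated range [{lo}, {hi}]")
        phs = np.array([p for p, _ in self.points])
        ratios = np.array([r for _, r in self.points])
        if self.kind == "logistic":
            return float(_logistic(pH, *self.logistic_params))
        return float(np.interp(pH, phs, ratios))

    def ph_from_ratio(self, R: float) -> float:
        lo, hi = self.ratio_range
        if not lo <= R <= hi:
            raise ValueError(
                f"ratio {R} outside calibration range [{lo:.4g}, {hi:.4g}]")
        phs = np.array([p for p, _ in self.points])
        ratios = np.array([r for _, r in self.points])
        if self.kind == "logistic":
            A, B, k, m = self.logistic_params
            # invert R = A + (B-A)/(1+exp(-k(pH-m))) on the node range
            frac = (R - A) / (B - A)
            frac = min(max(frac, 1e-12), 1 - 1e-12)
            return float(m + np.log(frac / (1.0 - frac)) / k)
        if ratios[0] > ratios[-1]:  # invert a decreasing map
            return float(np.interp(R, ratios[::-1], phs[::-1]))
        return float(np.interp(R, ratios, phs))


def fit_calibration_curve(points: Sequence[tuple[float, float]],
                          kind: str = "linear",
                          strain: str = "") -> CalibrationCurve:
    """Build a calibration curve from (pH, ratio) observations.

    Replicate readings at the same pH are averaged first.  At least four
    distinct pH levels are required and the averaged ratios must be
    strictly monotone in pH, otherwise the calibration is invalid.
    """
    if kind not in ("linear", "logistic"):
        raise ValueError(f"unknown calibration kind {kind!r}")
    by_ph: dict[float, list[float]] = {}
    for pH, r in points:
        by_ph.setdefault(float(pH), []).append(float(r))
    if len(by_ph) < 4:
        raise ValueError(
            f"need >= 4 distinct pH levels, got {len(by_ph)}")
    phs = np.array(sorted(by_ph))
    ratios = np.array([np.mean(by_ph[p]) for p in phs])
    diffs = np.diff(ratios)
    if not (np.all(diffs > 0) or np.all(diffs < 0)):
        raise ValueError(
            "averaged calibration ratios are not strictly monotone in pH; "
            "calibration invalid")
    nodes = tuple(zip(phs.tolist(), ratios.tolist()))
    if kind == "logistic":
        sign = 1.0 if diffs[0] > 0 else -1.0
        p0 = (ratios[0], ratios[-1], sign * 1.0, float(np.median(phs)))
        popt, _ = curve_fit(_logistic, phs, ratios, p0=p0, maxfev=10000)
        return CalibrationCurve(points=nodes, kind="logistic",
                                logistic_params=tuple(popt), strain=strain)
    return CalibrationCurve(points=nodes, kind="linear", strain=strain)


def intracellular_ph(R: float, curve: CalibrationCurve) -> float:
    """Invert the calibration curve at ratio R (within calibrated range)."""
    return curve.ph_from_ratio(R)


def ph_gradient(pHi: float, pHex: float) -> float:
    """Transmembrane pH gradient ΔpH = pHi − pHex."""
    if not (math.isfinite(pHi) and math.isfinite(pHex)):
        raise ValueError("pHi and pHex must be finite")
    return pHi - pHex
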