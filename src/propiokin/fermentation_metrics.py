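"""Fermentation performance parameters from time-course data.

Covers the standard bioprocess report card: specific growth rate µ on
the mid-exponential window, product yield Yps (total PA over consumed
substrate, volume-aware in fed-batch), PA:AA and PA:SA by-product
ratios, volumetric productivity Pv over a fixed interval (default
15–30 h), and specific uptake/production rates qs and qp obtained by
multiplying µ with the linear correlation of sugar or PA against
biomass on the same window.

Biomass is canonicalised to g DCW/L; absorbance readings are converted
through a strain-specific linear factor (``od_to_dcw``).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

from .kinetic_model import FeedProfile, TimeSeries

__all__ = [
    "DCW_FACTORS",
    "FermentationSummary",
    "od_to_dcw",
    "midexponential_window",
    "specific_growth_rate_midexp",
    "product_yield",
    "acid_ratio",
    "volumetric_productivity",
    "specific_rate_by_correlation",
    "substrate_consumed",
    "product_produced",
    "summarize",
]

logger = logging.getLogger("propiokin")

#: default A600 → g DCW/L conversion factors per strain
DCW_FACTORS = {"ATCC55737": 0.29, "WGS7": 0.25}

DEFAULT_PV_INTERVAL = (15.0, 30.0)
DEFAULT_WINDOW_POINTS = 4


@dataclass
class FermentationSummary:
    """One row of performance parameters for a fermentation run."""

    mu: float                      # h^-1, mid-exponential
    Yps: float                     # g PA / g sucrose consumed
    ratio_pa_aa: float             # g/g, whole run
    ratio_pa_sa: float             # g/g, whole run
    Pv: float                      # g/L/h over pv_interval
    pv_interval: tuple[float, float]
    qs: float                      # g sucrose / g DCW / h
    qp: float                      # g PA / g DCW / h
    final_pa: float                # g/L
    dcw_factor: float | None = None


def od_to_dcw(a600: float, factor: float) -> float:
    """Convert absorbance at 600 nm to dry cell weight (g/L)."""
    if a600 < 0:
        raise ValueError(f"a600 must be >= 0, got {a600}")
    if not factor > 0:
        raise ValueError(f"factor must be > 0, got {factor}")
    return a600 * factor


def midexponential_window(times: Sequence[float], biomass: Sequence[float],
                          width: int = DEFAULT_WINDOW_POINTS,
                          ) -> tuple[float, float]:
    """Contiguous window of ``width`` points best explained by exponential
    growth.

    Scans every window of ``width`` consecutive points with strictly
    positive biomass, fits ln(biomass) against time, and returns the
    window maximising R² among those with positive slope.  Ties break to
    the earliest window, which makes the result deterministic on exact
    exponential data.
    """
    t = np.asarray(times, dtype=float)
    x = np.asarray(biomass, dtype=float)
    if len(t) != len(x):
        raise ValueError("times and biomass must have equal length")
    if len(t) < max(width, 5):
        raise ValueError(f"need at least {max(width, 5)} points, got {len(t)}")
    best: tuple[float, int] | None = None  # (-r2, start index)
    for i in range(len(t) - width + 1):
        tw, xw = t[i:i + width], x[i:i + width]
        if np.any(xw <= 0):
            continue
        fit = stats.linregress(tw, np.log(xw))
        if fit.slope <= 0:
            continue
        key = (-(fit.rvalue ** 2), i)
        if best is None or key < best:
            best = key
    if best is None:
        raise ValueError("no exponential phase: no window with positive slope")
    i = best[1]
    return float(t[i]), float(t[i + width - 1])


def specific_growth_rate_midexp(times: Sequence[float],
                                biomass: Sequence[float],
                                width: int = DEFAULT_WINDOW_POINTS) -> float:
    """Slope of ln(biomass) vs time on the mid-exponential window (h⁻¹)."""
    t = np.asarray(times, dtype=float)
    x = np.asarray(biomass, dtype=float)
    if len(t) == 2:  # degenerate two-point case: exact log difference
        if np.any(x <= 0):
            raise ValueError("biomass must be positive")
        return float((math.log(x[1]) - math.log(x[0])) / (t[1] - t[0]))
    lo, hi = midexponential_window(t, x, width=width)
    mask = (t >= lo) & (t <= hi)
    fit = stats.linregress(t[mask], np.log(x[mask]))
    return float(fit.slope)


def product_yield(total_product: float, consumed_substrate: float) -> float:
    """Yps = total product mass over consumed substrate mass (g/g)."""
    if not consumed_substrate > 0:
        raise ValueError(
            f"consumed substrate must be > 0, got {consumed_substrate}")
    return total_product / consumed_substrate


def acid_ratio(total_pa: float, total_other: float) -> float:
    """Ratio of total PA to another organic-acid total over the run."""
    if total_other <= 0:
        logger.warning("acid ratio denominator is %g; reporting inf",
                       total_other)
        return math.inf
    return total_pa / total_other


def volumetric_productivity(series: TimeSeries,
                            interval: tuple[float, float] = DEFAULT_PV_INTERVAL,
                            ) -> float:
    """Pv = ΔPA/Δt (g/L/h) over ``interval``, endpoints linearly
    interpolated between bracketing samples."""
    t_lo, t_hi = interval
    if not t_hi > t_lo:
        raise ValueError(f"interval must satisfy t_lo < t_hi, got {interval}")
    t = series.times
    if t_lo < t[0] or t_hi > t[-1]:
        raise ValueError(
            f"interval {interval} outside data range [{t[0]}, {t[-1]}]")
    pa = series.frame["PA"].to_numpy(dtype=float)
    pa_lo, pa_hi = np.interp([t_lo, t_hi], t, pa)
    return float((pa_hi - pa_lo) / (t_hi - t_lo))


def specific_rate_by_correlation(series: TimeSeries, species: str,
                                 mu: float,
                                 width: int = DEFAULT_WINDOW_POINTS) -> float:
    """qs or qp: |slope of species vs biomass| × µ on the mid-exp window.

    The linear correlation of sugar (or PA) with biomass over the
    exponential phase gives grams of substrate consumed (product formed)
    per gram of new biomass; multiplying by µ converts it to a specific
    rate.  Both consumption and production are reported as positive
    magnitudes.
    """
    if species not in series.frame.columns:
        raise ValueError(f"species {species!r} not present in series")
    t = series.times
    x = series.frame["X"].to_numpy(dtype=float)
    lo, hi = midexponential_window(t, x, width=width)
    mask = (t >= lo) & (t <= hi)
    xw = x[mask]
    yw = series.frame[species].to_numpy(dtype=float)[mask]
    if np.ptp(xw) == 0:
        raise ValueError("biomass constant over window; regression singular")
    fit = stats.linregress(xw, yw)
    return float(abs(fit.slope) * mu)


# ---------------------------------------------------------------------------
# volume-aware totals
# ---------------------------------------------------------------------------

def _volumes(series: TimeSeries) -> np.ndarray:
    if "V" in series.frame.columns:
        return series.frame["V"].to_numpy(dtype=float)
    return np.ones(len(series))


def product_produced(series: TimeSeries, species: str = "PA") -> float:
    """Total mass of a product formed over the run (g), volume-aware."""
    c = series.frame[species].to_numpy(dtype=float)
    v = _volumes(series)
    return float(c[-1] * v[-1] - c[0] * v[0])


def substrate_consumed(series: TimeSeries,
                       feed: FeedProfile | None = None) -> float:
    """Total sucrose mass consumed (g): initial + fed − residual."""
    s = series.frame["S"].to_numpy(dtype=float)
    v = _volumes(series)
    fed = feed.fed_sucrose(series.times[-1]) if feed is not None else 0.0
    return float(s[0] * v[0] + fed - s[-1] * v[-1])


def summarize(series: TimeSeries, feed: FeedProfile | None = None,
              pv_interval: tuple[float, float] = DEFAULT_PV_INTERVAL,
              width: int = DEFAULT_WINDOW_POINTS,
              dcw_factor: float | None = None) -> FermentationSummary:
    """Compute the full performance report for one run."""
    t = series.times
    x = series.frame["X"].to_numpy(dtype=float)
    mu = specific_growth_rate_midexp(t, x, width=width)
    pa_total = product_produced(series, "PA")
    consumed = substrate_consumed(series, feed)
    return FermentationSummary(
        mu=mu,
        Yps=product_yield(pa_total, consumed),
        ratio_pa_aa=acid_ratio(pa_total, product_produced(series, "AA")),
        ratio_pa_sa=acid_ratio(pa_total, product_produced(series, "SA")),
        Pv=volumetric_productivity(series, pv_interval),
        pv_interval=pv_interval,
        qs=specific_rate_by_correlation(series, "S", mu, width=width),
        qp=specific_rate_by_correlation(series, "PA", mu, width=width),
        final_pa=float(series.frame["PA"].iloc[-1]),
        dcw_factor=dcw_factor,
    )
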