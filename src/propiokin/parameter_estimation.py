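"""Nonlinear least-squares fitting of the kinetic model to time courses.

The objective stacks per-species residuals (observed − simulated),
normalised by the maximum observed value of each species so that sucrose
(tens of g/L) does not drown out pyruvate (≈1 g/L).  Minimisation uses
trust-region-reflective least squares with finite-difference Jacobians
and an optional multi-start around the initial guess.

Model reliability is quantified as the mean per-variable coefficient of
determination over the m fitted species:

    R² = (1/m) Σ_j (1 − SSE_j / SST_j)

with SSE = Σ (y_i − ŷ_i)² and SST = Σ (y_i − ȳ)² per species.  Species
with zero variance are excluded (m shrinks); a negative contribution is
legitimate and means the model does worse than the observed mean.

The Monod half-saturation constant Ks is typically fixed during the full
fit and estimated separately from serum-bottle uptake rates measured at
several sucrose levels, where products — and hence inhibition — are
negligible (``fit_monod_ks``).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy.optimize import curve_fit, least_squares

from .kinetic_model import (
    PARAM_NAMES,
    SPECIES,
    BETA_LOWER_BOUND,
    FeedProfile,
    FermentationState,
    IntegrationError,
    KineticParameters,
    TimeSeries,
    simulate,
)

__all__ = [
    "TimeSeries",
    "FitResult",
    "MonodFit",
    "DEFAULT_BOUNDS",
    "coefficient_of_determination",
    "objective_residuals",
    "fit_parameters",
    "fit_monod_ks",
]

logger = logging.getLogger("propiokin")

#: per-parameter default fitting bounds (lower, upper)
DEFAULT_BOUNDS: dict[str, tuple[float, float]] = {
    "rs_max": (1e-3, 20.0), "Ks": (1e-2, 200.0),
    "kipa": (0.1, 500.0), "kiaa": (0.1, 500.0),
    "Yxs": (1e-3, 1.5), "ms": (0.0, 5.0),
    "K1": (0.0, 50.0), "K2": (0.0, 50.0), "K3": (0.0, 50.0),
    "K4": (0.0, 50.0), "K5": (0.0, 50.0), "K6": (0.0, 50.0),
    "K7": (0.0, 50.0), "K_pyr": (1e-3, 50.0),
    "beta_pa": (BETA_LOWER_BOUND, 1.0), "beta_pyr": (BETA_LOWER_BOUND, 1.0),
    "beta_aa": (BETA_LOWER_BOUND, 1.0), "beta_sa": (BETA_LOWER_BOUND, 1.0),
}

_PENALTY = 1e3  # finite residual reported when a candidate simulation fails


@dataclass
class FitResult:
    """Outcome of a kinetic-model fit."""

    parameters: KineticParameters
    fixed_mask: dict[str, bool]
    per_variable_r2: dict[str, float]
    aggregate_r2: float
    residuals: dict[str, np.ndarray]
    objective: float
    converged: bool
    n_iterations: int
    message: str = ""


@dataclass
class MonodFit:
    """Monod constants from serum-bottle rate data, with standard errors."""

    Ks: float
    rs_max: float
    Ks_stderr: float
    rs_max_stderr: float


# ---------------------------------------------------------------------------
# reliability statistic
# ---------------------------------------------------------------------------

def coefficient_of_determination(
        observed: TimeSeries, simulated: TimeSeries,
        variables: Sequence[str] | None = None,
) -> tuple[float, dict[str, float]]:
    """Mean per-variable R² of ``simulated`` against ``observed``.

    Simulated values are taken at the observed times (linear
    interpolation, exact when the grids coincide).  Variables with zero
    variance are dropped with a warning, shrinking m; if nothing remains
    a ValueError is raised.
    """
    if variables is None:
        variables = [v for v in observed.species
                     if v in simulated.frame.columns and v != "V"]
    per_var: dict[str, float] = {}
    for var in variables:
        obs = observed.frame[var]
        mask = obs.notna().to_numpy()
        y = obs.to_numpy(dtype=float)[mask]
        t = observed.times[mask]
        if len(y) < 2:
            raise ValueError(f"variable {var!r} has fewer than 2 observations")
        sst = float(np.sum((y - y.mean()) ** 2))
        if sst == 0.0:
            logger.warning("variable %s has zero variance; excluded from R²", var)
            continue
        yhat = np.interp(t, simulated.times,
                         simulated.frame[var].to_numpy(dtype=float))
        sse = float(np.sum((y - yhat) ** 2))
        per_var[var] = 1.0 - sse / sst
    if not per_var:
        raise ValueError("no variable with nonzero variance; R² undefined")
    aggregate = float(np.mean(list(per_var.values())))
    return aggregate, per_var


# ---------------------------------------------------------------------------
# objective
# ---------------------------------------------------------------------------

def _observed_layout(data: TimeSeries) -> list[tuple[str, np.ndarray, np.ndarray]]:
    """Per-species (name, times, values) with missing rows dropped."""
    layout = []
    for var in data.species:
        if var == "V":
            continue
        col = data.frame[var]
        mask = col.notna().to_numpy()
        if mask.sum() == 0:
            continue
        layout.append((var, data.times[mask], col.to_numpy(dtype=float)[mask]))
    if not layout:
        raise ValueError("time series contains no model species")
    return layout


def default_weights(data: TimeSeries) -> dict[str, float]:
    """Per-species scale = max observed value (balances magnitudes)."""
    return {var: max(float(np.nanmax(np.abs(v))), 1e-12)
            for var, _, v in _observed_layout(data)}


def _initial_state_from(data: TimeSeries,
                        initial: FermentationState | None,
                        mode: str) -> FermentationState:
    if initial is not None:
        return initial
    row = data.frame.iloc[0]
    kwargs = {name: float(row[name]) if name in data.frame.columns
              and np.isfinite(row.get(name, np.nan)) else 0.0
              for name in SPECIES}
    V = float(row["V"]) if "V" in data.frame.columns else 1.0
    return FermentationState(**kwargs, V=V)


def objective_residuals(p: KineticParameters, data: TimeSeries,
                        weights: Mapping[str, float] | None = None, *,
                        initial: FermentationState | None = None,
                        mode: str = "batch",
                        feed: FeedProfile | None = None,
                        rtol: float = 1e-7, atol: float = 1e-9) -> np.ndarray:
    """Stacked weighted residual vector (obs − sim)/scale per species.

    A failed simulation yields a constant large finite penalty vector of
    the same length, keeping the optimizer alive.
    """
    layout = _observed_layout(data)
    if weights is None:
        weights = default_weights(data)
    n_total = sum(len(t) for _, t, _ in layout)
    init = _initial_state_from(data, initial, mode)
    t_all = np.unique(np.concatenate([t for _, t, _ in layout]))
    if len(t_all) < 2:
        raise ValueError("need at least 2 distinct observation times")
    try:
        sim = simulate(init, p, t_all, mode=mode, feed=feed,
                       rtol=rtol, atol=atol)
    except (IntegrationError, ValueError) as exc:
        logger.warning("simulation failed at candidate parameters: %s", exc)
        return np.full(n_total, _PENALTY)
    chunks = []
    for var, t, y in layout:
        yhat = np.interp(t, sim.times, sim.frame[var].to_numpy(dtype=float))
        chunks.append((y - yhat) / weights[var])
    return np.concatenate(chunks)


# ---------------------------------------------------------------------------
# full model fit
# ---------------------------------------------------------------------------

def fit_parameters(data: TimeSeries, initial_guess: KineticParameters,
                   bounds: Mapping[str, tuple[float, float]] | None = None,
                   fixed: Sequence[str] = ("Ks",), *,
                   weights: Mapping[str, float] | None = None,
                   initial: FermentationState | None = None,
                   mode: str = "batch", feed: FeedProfile | None = None,
                   n_starts: int = 5, jitter: float = 0.3,
                   seed: int = 0) -> FitResult:
    """Fit the free kinetic parameters to a time course.

    ``fixed`` names parameters held at their ``initial_guess`` value
    (by default Ks, which is estimated separately from serum-bottle
    data).  ``n_starts`` jittered restarts (log-normal, factor
    ``exp(N(0, jitter))``, deterministic in ``seed``) mitigate local
    minima; the best final objective wins.
    """
    fixed = set(fixed)
    unknown = fixed - set(PARAM_NAMES)
    if unknown:
        raise ValueError(f"unknown fixed parameter names: {sorted(unknown)}")
    free = [n for n in PARAM_NAMES if n not in fixed]
    if not free:
        raise ValueError("all parameters are fixed; nothing to fit")

    layout = _observed_layout(data)
    n_obs = sum(len(t) for _, t, _ in layout)
    if any(len(t) < 2 for _, t, _ in layout):
        raise ValueError("each fitted species needs at least 2 time points")
    if n_obs < len(free):
        raise ValueError(
            f"{n_obs} observations cannot determine {len(free)} parameters")

    all_bounds = dict(DEFAULT_BOUNDS)
    if bounds:
        all_bounds.update(bounds)
    lo = np.array([all_bounds[n][0] for n in free])
    hi = np.array([all_bounds[n][1] for n in free])
    if not np.all(np.isfinite(lo) & np.isfinite(hi)):
        raise ValueError("bounds must be finite")

    if weights is None:
        weights = default_weights(data)
    base = dict(initial_guess.as_dict())
    x0 = np.clip([base[n] for n in free], lo, hi)

    def unpack(x: np.ndarray) -> KineticParameters:
        d = dict(base)
        d.update({n: float(v) for n, v in zip(free, x)})
        return KineticParameters.from_dict(d)

    def fun(x: np.ndarray) -> np.ndarray:
        return objective_residuals(unpack(x), data, weights, initial=initial,
                                   mode=mode, feed=feed)

    rng = np.random.default_rng(seed)
    starts = [x0]
    for _ in range(max(0, n_starts - 1)):
        starts.append(np.clip(
            x0 * np.exp(rng.normal(0.0, jitter, size=len(free))), lo, hi))

    best = None
    for start in starts:
        sol = least_squares(fun, start, bounds=(lo, hi), method="trf",
                            x_scale=np.maximum(np.abs(x0), 1e-3),
                            xtol=1e-10, ftol=1e-10, gtol=1e-10)
        if best is None or sol.cost < best.cost:
            best = sol

    fitted = unpack(best.x)
    converged = bool(best.success)
    sim = None
    try:
        t_all = np.unique(np.concatenate([t for _, t, _ in layout]))
        sim = simulate(_initial_state_from(data, initial, mode), fitted,
                       t_all, mode=mode, feed=feed)
    except IntegrationError as exc:
        logger.warning("post-fit simulation failed: %s", exc)
        converged = False

    per_var: dict[str, float] = {}
    aggregate = float("nan")
    residuals: dict[str, np.ndarray] = {}
    if sim is not None:
        aggregate, per_var = coefficient_of_determination(data, sim)
        for var, t, y in layout:
            yhat = np.interp(t, sim.times,
                             sim.frame[var].to_numpy(dtype=float))
            residuals[var] = y - yhat

    return FitResult(
        parameters=fitted,
        fixed_mask={n: (n in fixed) for n in PARAM_NAMES},
        per_variable_r2=per_var,
        aggregate_r2=aggregate,
        residuals=residuals,
        objective=float(2.0 * best.cost),  # least_squares cost = 0.5*SSE
        converged=converged,
        n_iterations=int(best.nfev),
        message=str(best.message),
    )


# ---------------------------------------------------------------------------
# Monod fit from serum-bottle rates
# ---------------------------------------------------------------------------

def fit_monod_ks(substrate_levels: Sequence[float],
                 rates: Sequence[float]) -> MonodFit:
    """Least-squares Monod fit r = rs_max·S/(Ks+S) to rate measurements.

    Requires at least three distinct substrate levels with positive
    rates.  When the data carry no saturation signal (rates flat or
    non-increasing over the range) the Ks estimate is ill-determined;
    a warning is logged and the reported standard error is wide.
    """
    S = np.asarray(substrate_levels, dtype=float)
    r = np.asarray(rates, dtype=float)
    if S.shape != r.shape:
        raise ValueError("substrate_levels and rates must have equal length")
    if len(np.unique(S[r > 0])) < 3:
        raise ValueError("need >= 3 distinct substrate levels with positive rates")

    order = np.argsort(S)
    if r[order][-1] <= r[order][0]:
        logger.warning(
            "uptake rates do not increase with substrate; no saturation "
            "signal, Ks ill-determined")

    def monod(S, rs_max, Ks):
        return rs_max * S / (Ks + S)

    p0 = (float(r.max()) or 1.0, max(float(np.median(S)), 1e-6))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # flat data → singular covariance
        popt, pcov = curve_fit(monod, S, r, p0=p0,
                               bounds=([0.0, 0.0], [np.inf, np.inf]),
                               xtol=1e-14, ftol=1e-14, gtol=1e-14,
                               maxfev=20000)
    stderr = np.sqrt(np.diag(pcov)) if np.all(np.isfinite(pcov)) \
        else np.array([np.inf, np.inf])
    return MonodFit(Ks=float(popt[1]), rs_max=float(popt[0]),
                    Ks_stderr=float(stderr[1]), rs_max_stderr=float(stderr[0]))
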