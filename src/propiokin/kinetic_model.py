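"""Unstructured kinetic model of propionic-acid fermentation.

The model tracks biomass (X, g DCW/L), sucrose (S), propionic acid (PA),
pyruvic acid (PYR), acetic acid (AA) and succinic acid (SA), all in g/L,
plus broth volume V (L) in fed-batch mode.  Sucrose uptake follows Monod
kinetics with non-competitive product inhibition by PA and AA; growth is
tied to uptake through a yield and a maintenance term; each organic acid
is produced with a growth-associated coefficient (K) and a non-growth
rate (beta), in the Luedeking–Piret form.  Pyruvate is additionally
consumed through a shared Michaelis drain that feeds acetate and
succinate formation.

Batch rate equations (per litre of broth)::

    dX/dt   = u * X
    dS/dt   = -qs * X
    dPA/dt  = (K1*u + beta_pa) * X
    dPYR/dt = (K2*u + beta_pyr - K3*f) * X
    dAA/dt  = (K4*u + beta_aa + K5*f) * X
    dSA/dt  = (K6*u + beta_sa + K7*f) * X

with::

    qs = rs_max * S/(Ks+S) * kipa/(kipa+PA) * kiaa/(kiaa+AA)
    u  = qs*Yxs - ms*Yxs
    f  = PYR/(PYR + K_pyr)

In fed-batch mode a feed at rate F(t) (L/h) with sucrose concentration So
dilutes every species at rate D = F/V and adds substrate::

    dX/dt = u*X - D*X,   dS/dt = -qs*X + D*(So - S),
    d(acid)/dt = batch rate - D*acid,   dV/dt = F
"""

from __future__ import annotations

import hashlib
import logging
import math
from dataclasses import dataclass, field, fields, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp

__all__ = [
    "SPECIES",
    "PARAM_NAMES",
    "KineticParameters",
    "FermentationState",
    "FeedProfile",
    "TimeSeries",
    "IntegrationError",
    "substrate_uptake_rate",
    "growth_rate",
    "pyruvate_drain_term",
    "batch_derivatives",
    "fedbatch_derivatives",
    "simulate",
]

logger = logging.getLogger("propiokin")

#: canonical ordering of the concentration state variables
SPECIES = ("X", "S", "PA", "PYR", "AA", "SA")

#: canonical ordering of the kinetic parameter vector
PARAM_NAMES = (
    "rs_max", "Ks", "kipa", "kiaa", "Yxs", "ms",
    "K1", "K2", "K3", "K4", "K5", "K6", "K7", "K_pyr",
    "beta_pa", "beta_pyr", "beta_aa", "beta_sa",
)

#: lower bound allowed for the non-growth (beta) rates during fitting
BETA_LOWER_BOUND = -1.0

#: width (g/L) of the linear ramp that fades net product consumption to
#: zero as the product is exhausted, keeping trajectories non-negative
#: without introducing a discontinuous right-hand side
_EXHAUST_EPS = 1e-6


class IntegrationError(RuntimeError):
    """Raised when the ODE solver fails to produce a trajectory."""


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class KineticParameters:
    """Full parameter vector of the batch/fed-batch rate equations.

    Units: rs_max, ms, K3, K5, K7 and the beta terms are specific rates in
    g per g DCW per hour; Ks, kipa, kiaa and K_pyr are concentrations in
    g/L; Yxs is g DCW per g sucrose; K1, K2, K4 and K6 are g product per
    g DCW of new biomass (dimensionless mass ratios).
    """

    rs_max: float
    Ks: float
    kipa: float
    kiaa: float
    Yxs: float
    ms: float
    K1: float
    K2: float
    K3: float
    K4: float
    K5: float
    K6: float
    K7: float
    K_pyr: float
    beta_pa: float
    beta_pyr: float
    beta_aa: float
    beta_sa: float

    def __post_init__(self) -> None:
        for name in ("rs_max", "Ks", "kipa", "kiaa", "K_pyr"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be > 0, got {getattr(self, name)}")
        if not (0 < self.Yxs <= 1.5):
            raise ValueError(f"Yxs must lie in (0, 1.5], got {self.Yxs}")
        if self.ms < 0:
            raise ValueError(f"ms must be >= 0, got {self.ms}")
        for name in ("K1", "K2", "K3", "K4", "K5", "K6", "K7"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0, got {getattr(self, name)}")
        for name in ("beta_pa", "beta_pyr", "beta_aa", "beta_sa"):
            if getattr(self, name) < BETA_LOWER_BOUND:
                raise ValueError(
                    f"{name} must be >= {BETA_LOWER_BOUND}, got {getattr(self, name)}"
                )
        if self.K3 < self.K5 + self.K7:
            logger.warning(
                "pyruvate drain K3=%g is smaller than the pyruvate-fed gains "
                "K5+K7=%g; carbon balance of the pyruvate node is not enforced",
                self.K3, self.K5 + self.K7,
            )

    def to_array(self) -> np.ndarray:
        """Parameter values as a float vector in PARAM_NAMES order."""
        return np.array([getattr(self, n) for n in PARAM_NAMES], dtype=float)

    @classmethod
    def from_array(cls, values: Sequence[float]) -> "KineticParameters":
        if len(values) != len(PARAM_NAMES):
            raise ValueError(f"expected {len(PARAM_NAMES)} values, got {len(values)}")
        return cls(**{n: float(v) for n, v in zip(PARAM_NAMES, values)})

    def as_dict(self) -> dict[str, float]:
        return {n: float(getattr(self, n)) for n in PARAM_NAMES}

    @classmethod
    def from_dict(cls, mapping: Mapping[str, float]) -> "KineticParameters":
        unknown = set(mapping) - set(PARAM_NAMES)
        if unknown:
            raise ValueError(f"unknown parameter keys: {sorted(unknown)}")
        missing = set(PARAM_NAMES) - set(mapping)
        if missing:
            raise ValueError(f"missing parameter keys: {sorted(missing)}")
        return cls(**{n: float(mapping[n]) for n in PARAM_NAMES})

    def updated(self, **changes: float) -> "KineticParameters":
        return replace(self, **changes)

    def digest(self) -> str:
        """Short stable hash of the parameter values, for provenance."""
        payload = ",".join(f"{n}={getattr(self, n)!r}" for n in PARAM_NAMES)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]


@dataclass(frozen=True)
class FermentationState:
    """Instantaneous broth composition; V only matters in fed-batch mode."""

    X: float
    S: float
    PA: float = 0.0
    PYR: float = 0.0
    AA: float = 0.0
    SA: float = 0.0
    V: float = 1.0

    def __post_init__(self) -> None:
        for name in SPECIES:
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0, got {getattr(self, name)}")
        if not self.V > 0:
            raise ValueError(f"V must be > 0, got {self.V}")

    def to_array(self, include_volume: bool = False) -> np.ndarray:
        vals = [getattr(self, n) for n in SPECIES]
        if include_volume:
            vals.append(self.V)
        return np.array(vals, dtype=float)

    @classmethod
    def from_array(cls, values: Sequence[float], V: float | None = None) -> "FermentationState":
        values = list(values)
        if V is None:
            V = values[6] if len(values) == 7 else 1.0
        return cls(**{n: float(v) for n, v in zip(SPECIES, values)}, V=float(V))


@dataclass(frozen=True)
class FeedProfile:
    """Piecewise-constant feed: (t_start, t_end, F) segments in h and L/h.

    ``So`` is the sucrose concentration of the feed solution (g/L);
    ``medium_factor`` records how concentrated the feed medium is relative
    to the base medium (metadata only, it does not enter the equations).
    """

    segments: tuple[tuple[float, float, float], ...]
    So: float
    medium_factor: float = 1.0

    def __post_init__(self) -> None:
        segs = tuple(
            (float(a), float(b), float(f)) for a, b, f in self.segments
        )
        object.__setattr__(self, "segments", segs)
        if self.So < 0:
            raise ValueError(f"So must be >= 0, got {self.So}")
        prev_end = -math.inf
        for t0, t1, f in sorted(segs):
            if not t0 < t1:
                raise ValueError(f"segment ({t0}, {t1}) must have t_start < t_end")
            if f < 0:
                raise ValueError(f"feed rate must be >= 0, got {f}")
            if t0 < prev_end:
                raise ValueError("feed segments overlap")
            prev_end = t1

    @classmethod
    def constant(cls, F: float, t_start: float, t_end: float, So: float,
                 medium_factor: float = 1.0) -> "FeedProfile":
        """Single constant-rate segment — the realized fed-batch strategy."""
        return cls(segments=((t_start, t_end, F),), So=So, medium_factor=medium_factor)

    @classmethod
    def none(cls) -> "FeedProfile":
        return cls(segments=(), So=0.0)

    def rate(self, t: float) -> float:
        """F(t) in L/h; zero outside every segment (right-open intervals)."""
        for t0, t1, f in self.segments:
            if t0 <= t < t1:
                return f
        return 0.0

    def boundaries(self) -> list[float]:
        """Sorted distinct segment endpoints (hard solver restart points)."""
        pts = sorted({t for seg in self.segments for t in seg[:2]})
        return pts

    def fed_volume(self, t: float) -> float:
        """Cumulative feed volume ∫₀ᵗ F dτ in L (closed form)."""
        total = 0.0
        for t0, t1, f in self.segments:
            total += f * max(0.0, min(t, t1) - t0) if t > t0 else 0.0
        return total

    def fed_sucrose(self, t: float) -> float:
        """Cumulative sucrose mass fed by time t (g)."""
        return self.fed_volume(t) * self.So


@dataclass
class TimeSeries:
    """A multi-species concentration trajectory on a common time grid.

    ``frame`` is indexed by time in hours (name ``time_h``) with one column
    per species present (subset of X, S, PA, PYR, AA, SA, V plus arbitrary
    annotation columns such as lactate).  ``meta`` carries provenance:
    mode, parameter digest, solver tolerances, seed, strain label, …
    """

    frame: pd.DataFrame
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        t = np.asarray(self.frame.index, dtype=float)
        if len(t) >= 2 and not np.all(np.diff(t) > 0):
            raise ValueError("times must be strictly increasing")
        self.frame.index.name = "time_h"

    @property
    def times(self) -> np.ndarray:
        return np.asarray(self.frame.index, dtype=float)

    @property
    def species(self) -> list[str]:
        return [c for c in self.frame.columns if c in SPECIES + ("V",)]

    def values_for(self, name: str) -> np.ndarray:
        return self.frame[name].to_numpy(dtype=float)

    def __len__(self) -> int:
        return len(self.frame)


# ---------------------------------------------------------------------------
# rate laws
# ---------------------------------------------------------------------------

def substrate_uptake_rate(S: float, PA: float, AA: float,
                          p: KineticParameters) -> float:
    """Specific sucrose uptake qs (g sucrose / g DCW / h).

    Monod saturation in S multiplied by non-competitive inhibition terms
    for propionic and acetic acid; bounded by [0, rs_max].
    """
    if S < 0 or PA < 0 or AA < 0:
        raise ValueError("concentrations must be >= 0")
    return (
        p.rs_max
        * (S / (p.Ks + S))
        * (p.kipa / (p.kipa + PA))
        * (p.kiaa / (p.kiaa + AA))
    )


def growth_rate(qs: float, p: KineticParameters) -> float:
    """Specific growth rate u = qs*Yxs - ms*Yxs (h⁻¹).

    Negative when maintenance demand exceeds uptake (qs < ms).
    """
    return qs * p.Yxs - p.ms * p.Yxs


def pyruvate_drain_term(PYR: float, p: KineticParameters) -> float:
    """Saturation fraction PYR/(PYR + K_pyr) shared by the pyruvate sinks."""
    if PYR < 0:
        raise ValueError(f"PYR must be >= 0, got {PYR}")
    return PYR / (PYR + p.K_pyr)


# fast unchecked right-hand sides used by the integrator ---------------------

def _rates(y: np.ndarray, pa: np.ndarray) -> tuple[float, float, float]:
    """(qs, u, f) from a state vector, clamping negative concentrations.

    ``pa`` is the parameter vector in PARAM_NAMES order.  Clamping keeps
    qs and the pyruvate drain at zero once their substrate is exhausted,
    which keeps trajectories non-negative to solver tolerance without
    clipping the state itself.
    """
    S = max(y[1], 0.0)
    PA = max(y[2], 0.0)
    PYR = max(y[3], 0.0)
    AA = max(y[4], 0.0)
    qs = pa[0] * (S / (pa[1] + S)) * (pa[2] / (pa[2] + PA)) * (pa[3] / (pa[3] + AA))
    u = (qs - pa[5]) * pa[4]
    f = PYR / (PYR + pa[13])
    return qs, u, f


def _rhs_batch(y: np.ndarray, pa: np.ndarray) -> np.ndarray:
    qs, u, f = _rates(y, pa)
    X = y[0]
    d = np.array([
        u * X,
        -qs * X,
        (pa[6] * u + pa[14]) * X,
        (pa[7] * u + pa[15] - pa[8] * f) * X,
        (pa[9] * u + pa[16] + pa[10] * f) * X,
        (pa[11] * u + pa[17] + pa[12] * f) * X,
    ])
    # net consumption of an exhausted product halts at zero — the same
    # convention that zeroes qs and the pyruvate drain at zero substrate
    # (relevant when u < 0 turns a growth-associated term consumptive).
    # The ramp over the last _EXHAUST_EPS keeps the RHS continuous.
    for i in range(2, 6):
        if d[i] < 0.0 and y[i] < _EXHAUST_EPS:
            d[i] *= max(y[i], 0.0) / _EXHAUST_EPS
    return d


def _rhs_fedbatch(y: np.ndarray, pa: np.ndarray, F: float, So: float) -> np.ndarray:
    """State is (X, S, PA, PYR, AA, SA, V); dilution D = F/V."""
    V = y[6]
    D = F / V if F > 0 else 0.0
    d = _rhs_batch(y, pa)
    out = np.empty(7)
    out[0] = d[0] - D * y[0]
    out[1] = d[1] + D * (So - y[1])
    out[2:6] = d[2:6] - D * y[2:6]
    out[6] = F
    return out


def batch_derivatives(state: FermentationState,
                      p: KineticParameters) -> np.ndarray:
    """Batch time derivatives (g/L/h) in SPECIES order; V is ignored."""
    return _rhs_batch(state.to_array(), p.to_array())


def fedbatch_derivatives(state: FermentationState, p: KineticParameters,
                         feed: FeedProfile, t: float) -> np.ndarray:
    """Fed-batch derivatives in SPECIES + (V,) order, including dV/dt = F(t)."""
    if not state.V > 0:
        raise ValueError(f"V must be > 0, got {state.V}")
    return _rhs_fedbatch(state.to_array(include_volume=True), p.to_array(),
                         feed.rate(t), feed.So)


# ---------------------------------------------------------------------------
# integration
# ---------------------------------------------------------------------------

def simulate(initial: FermentationState, p: KineticParameters,
             t_grid: Sequence[float], mode: str = "batch",
             feed: FeedProfile | None = None, *,
             rtol: float = 1e-8, atol: float = 1e-10,
             method: str = "LSODA",
             track_mass_balance: bool = False) -> TimeSeries:
    """Integrate the model and return the trajectory at ``t_grid``.

    Feed-segment boundaries are treated as hard restart points so the
    adaptive solver never steps across a discontinuity in F(t).  With
    ``track_mass_balance`` the fed-batch run also integrates cumulative
    consumed sucrose mass (``consumed_g`` column, ∫ qs·X·V dt) and records
    cumulative fed mass (``fed_g``), enabling exact mass-closure checks.

    Parameters
    ----------
    t_grid
        Strictly increasing output times (h); the first entry is the
        initial time.
    mode
        ``"batch"`` or ``"fedbatch"``; fed-batch requires ``feed``.
    """
    t_grid = np.asarray(t_grid, dtype=float)
    if t_grid.ndim != 1 or len(t_grid) < 2:
        raise ValueError("t_grid must contain at least two times")
    if not np.all(np.diff(t_grid) > 0):
        raise ValueError("t_grid must be strictly increasing")
    if mode not in ("batch", "fedbatch"):
        raise ValueError(f"unknown mode {mode!r}")
    if mode == "fedbatch" and feed is None:
        raise ValueError("fed-batch simulation requires a feed profile")

    pa = p.to_array()
    t0, t_end = float(t_grid[0]), float(t_grid[-1])

    if mode == "batch":
        y0 = initial.to_array()

        def rhs(t, y):
            return _rhs_batch(y, pa)

        sol = solve_ivp(rhs, (t0, t_end), y0, method=method, t_eval=t_grid,
                        rtol=rtol, atol=atol)
        if not sol.success:
            raise IntegrationError(f"batch integration failed: {sol.message}")
        columns = dict(zip(SPECIES, sol.y))
    else:
        y0 = list(initial.to_array(include_volume=True))
        if track_mass_balance:
            y0.append(0.0)  # cumulative consumed sucrose mass (g)
        y0 = np.array(y0)

        # integrate piecewise between feed discontinuities
        cuts = [b for b in feed.boundaries() if t0 < b < t_end]
        edges = [t0] + cuts + [t_end]
        ts: list[np.ndarray] = []
        ys: list[np.ndarray] = []
        y = y0
        for a, b in zip(edges[:-1], edges[1:]):
            F = feed.rate(0.5 * (a + b))

            if track_mass_balance:
                def rhs(t, y, F=F):
                    d = _rhs_fedbatch(y[:7], pa, F, feed.So)
                    qs, _, _ = _rates(y, pa)
                    return np.append(d, qs * y[0] * y[6])
            else:
                def rhs(t, y, F=F):
                    return _rhs_fedbatch(y, pa, F, feed.So)

            # always evaluate the exact segment end so the next segment
            # restarts from it; grid points in (a, b] plus a at the start
            inner = t_grid[(t_grid > a) & (t_grid <= b)]
            t_eval = np.unique(np.concatenate([[a] if a == t0 else [],
                                               inner, [b]]))
            sol = solve_ivp(rhs, (a, b), y, method=method, t_eval=t_eval,
                            rtol=rtol, atol=atol)
            if not sol.success:
                raise IntegrationError(
                    f"fed-batch integration failed on [{a}, {b}]: {sol.message}")
            y = sol.y[:, -1]
            on_grid = np.isin(sol.t, t_grid)
            ts.append(sol.t[on_grid])
            ys.append(sol.y[:, on_grid])
        t_all = np.concatenate(ts)
        y_all = np.concatenate(ys, axis=1)
        if len(t_all) != len(t_grid) or not np.array_equal(t_all, t_grid):
            raise IntegrationError("output grid mismatch after segment stitching")
        columns = dict(zip(SPECIES + ("V",), y_all[:7]))
        if track_mass_balance:
            columns["consumed_g"] = y_all[7]
            columns["fed_g"] = np.array([feed.fed_sucrose(t) for t in t_all])

    # snap solver noise: magnitudes below the non-negativity ramp are
    # indistinguishable from zero
    for name in SPECIES:
        x = columns[name]
        columns[name] = np.where((x < 0) & (x > -_EXHAUST_EPS), 0.0, x)

    frame = pd.DataFrame(columns, index=pd.Index(t_grid, name="time_h"))
    meta = {
        "mode": mode,
        "params": p.as_dict(),
        "params_digest": p.digest(),
        "rtol": rtol,
        "atol": atol,
        "method": method,
        "source": "simulated",
    }
    if feed is not None:
        meta["feed"] = {"segments": list(feed.segments), "So": feed.So}
    return TimeSeries(frame=frame, meta=meta)
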