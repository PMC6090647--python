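"""Synthetic fermentation datasets with known ground truth.

Everything the other modules need for testing and demonstration is
generated here: noisy batch/fed-batch time courses from the bundled
reference parameter sets, serum-bottle Monod rate tables, and BCECF
calibration readings.  Every generator records the generating truth in
its output metadata and is deterministic under a fixed seed.

Two reference scenarios are bundled.  ``"wgs7-like"`` mimics a
high-performing acid-tolerant production strain (batch yield ≈ 0.6 g PA
per g sucrose, final titre ≈ 45 g/L from 80 g/L sucrose, and ≈ 73 g/L in
the fed-batch configuration); ``"wildtype-like"`` mimics its parent
(yield 0.45 g/g, titre ≈ 26 g/L).  The parameter values are frozen:
changing them is a breaking change, since downstream recovery tests and
worked examples quote numbers computed from them.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Iterable, Sequence

import numpy as np
import pandas as pd

from .kinetic_model import (
    SPECIES,
    FeedProfile,
    FermentationState,
    KineticParameters,
    TimeSeries,
    simulate,
)
from .ph_calibration import FluorescenceReading

__all__ = [
    "NoiseModel",
    "reference_parameters",
    "batch_scenario",
    "fedbatch_scenario",
    "generate_timeseries",
    "generate_monod_rates",
    "generate_calibration_readings",
]

# Frozen reference parameter sets (version-pinned; see module docstring).
_WGS7_LIKE = dict(
    rs_max=1.124, Ks=18.33, kipa=40.0, kiaa=40.0, Yxs=0.25, ms=0.260,
    K1=2.536, K2=0.2, K3=0.05, K4=0.0126, K5=0.02, K6=0.671, K7=0.015,
    K_pyr=0.25, beta_pa=0.149, beta_pyr=0.005, beta_aa=0.0279,
    beta_sa=0.0195,
)
_WILDTYPE_LIKE = dict(
    rs_max=2.984, Ks=29.91, kipa=10.06, kiaa=40.0, Yxs=0.0773, ms=0.3545,
    K1=8.728, K2=0.2, K3=0.05, K4=0.448, K5=0.02, K6=0.658, K7=0.015,
    K_pyr=0.25, beta_pa=0.101, beta_pyr=0.005, beta_aa=0.0813,
    beta_sa=0.0282,
)
_SCENARIOS = {"wgs7-like": _WGS7_LIKE, "wildtype-like": _WILDTYPE_LIKE}

#: inoculation absorbance and strain A600→DCW factors behind the X0 values
_INITIAL_BIOMASS = {"wgs7-like": 0.3 * 0.25, "wildtype-like": 0.3 * 0.29}

#: bundled fed-batch feeding strategy: 0.0066 L/h of 350 g/L sucrose
#: (fivefold-concentrated medium) from 40 h to 64 h into a 0.7-L culture
REFERENCE_FEED = FeedProfile.constant(F=0.0066, t_start=40.0, t_end=64.0,
                                      So=350.0, medium_factor=5.0)

BATCH_HORIZON_H = 72.0
FEDBATCH_HORIZON_H = 140.0
DEFAULT_SAMPLE_STEP_H = 4.0


def reference_parameters(scenario: str) -> KineticParameters:
    """Bundled kinetic parameter set for a named scenario.

    ``"wgs7-like"`` or ``"wildtype-like"``; values are frozen constants.
    """
    try:
        return KineticParameters(**_SCENARIOS[scenario])
    except KeyError:
        raise ValueError(
            f"unknown scenario {scenario!r}; expected one of {sorted(_SCENARIOS)}"
        ) from None


def batch_scenario(scenario: str = "wgs7-like",
                   step_h: float = DEFAULT_SAMPLE_STEP_H,
                   ) -> tuple[KineticParameters, FermentationState, np.ndarray]:
    """Reference batch run: 80 g/L initial sucrose, inoculum A600 0.3."""
    p = reference_parameters(scenario)
    initial = FermentationState(X=_INITIAL_BIOMASS[scenario], S=80.0)
    t_grid = np.arange(0.0, BATCH_HORIZON_H + step_h / 2, step_h)
    return p, initial, t_grid


def fedbatch_scenario(scenario: str = "wgs7-like",
                      step_h: float = DEFAULT_SAMPLE_STEP_H,
                      ) -> tuple[KineticParameters, FermentationState,
                                 FeedProfile, np.ndarray]:
    """Reference fed-batch run: 0.7-L working volume, constant feed 40–64 h."""
    p = reference_parameters(scenario)
    initial = FermentationState(X=_INITIAL_BIOMASS[scenario], S=80.0, V=0.7)
    t_grid = np.arange(0.0, FEDBATCH_HORIZON_H + step_h / 2, step_h)
    return p, initial, REFERENCE_FEED, t_grid


# ---------------------------------------------------------------------------
# noise
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class NoiseModel:
    """Measurement-noise description for synthetic observations.

    ``multiplicative-gaussian`` (default) scales each value by
    ``1 + N(0, cv)``, mimicking HPLC concentration measurements whose
    error grows with magnitude; ``additive-gaussian`` adds ``N(0, sd)``
    in g/L.  Values that land below ``detection_limit`` (g/L) are
    censored to zero, and negative draws are clipped to zero.
    """

    kind: str = "multiplicative-gaussian"
    cv_or_sd: float | dict[str, float] = 0.05
    seed: int = 0
    detection_limit: float = 0.05

    def __post_init__(self) -> None:
        if self.kind not in ("multiplicative-gaussian", "additive-gaussian"):
            raise ValueError(f"unknown noise kind {self.kind!r}")
        scales = (self.cv_or_sd.values()
                  if isinstance(self.cv_or_sd, dict) else [self.cv_or_sd])
        if any(s < 0 for s in scales):
            raise ValueError("noise scale must be >= 0")
        if self.detection_limit < 0:
            raise ValueError("detection_limit must be >= 0")

    def scale_for(self, species: str) -> float:
        if isinstance(self.cv_or_sd, dict):
            return float(self.cv_or_sd.get(species, 0.0))
        return float(self.cv_or_sd)

    def apply(self, frame: pd.DataFrame,
              columns: Iterable[str] | None = None) -> pd.DataFrame:
        """Return a noisy copy of ``frame`` (deterministic in the seed)."""
        rng = np.random.default_rng(self.seed)
        out = frame.copy()
        cols = list(columns) if columns is not None else [
            c for c in frame.columns if c in SPECIES]
        for col in cols:
            x = out[col].to_numpy(dtype=float)
            s = self.scale_for(col)
            if s == 0 and self.detection_limit == 0:
                continue  # exact identity for the noiseless configuration
            if s > 0:
                eps = rng.normal(0.0, s, size=len(x))
                x = x * (1.0 + eps) if self.kind.startswith("mult") else x + eps
            x = np.where(x < self.detection_limit, 0.0, x)
            out[col] = x
        return out


NOISELESS = NoiseModel(cv_or_sd=0.0, detection_limit=0.0)


# ---------------------------------------------------------------------------
# generators
# ---------------------------------------------------------------------------

def generate_timeseries(p: KineticParameters, initial: FermentationState,
                        mode: str = "batch", feed: FeedProfile | None = None,
                        sample_times: Sequence[float] | None = None,
                        noise: NoiseModel = NOISELESS) -> TimeSeries:
    """Simulate and then corrupt a trajectory; truth goes into ``meta``.

    With zero noise the returned frame equals the ``simulate`` output
    bit-for-bit.  ``meta["truth"]`` holds the noiseless frame,
    ``meta["noise"]`` the noise configuration including the seed.
    """
    if sample_times is None:
        horizon = BATCH_HORIZON_H if mode == "batch" else FEDBATCH_HORIZON_H
        sample_times = np.arange(0.0, horizon + 2.0, DEFAULT_SAMPLE_STEP_H)
    clean = simulate(initial, p, sample_times, mode=mode, feed=feed)
    frame = noise.apply(clean.frame)
    meta = dict(clean.meta)
    meta.update({
        "source": "synthetic",
        "truth": clean.frame,
        "noise": {"kind": noise.kind, "cv_or_sd": noise.cv_or_sd,
                  "seed": noise.seed,
                  "detection_limit": noise.detection_limit},
        "seed": noise.seed,
    })
    return TimeSeries(frame=frame, meta=meta)


def generate_monod_rates(Ks: float, rs_max: float,
                         S_levels: Sequence[float],
                         noise: NoiseModel = NOISELESS) -> pd.DataFrame:
    """Serum-bottle style uptake-rate table r = rs_max·S/(Ks+S) + noise.

    Products are absent in the serum-bottle condition, so no inhibition
    terms apply.  Columns: ``S_gL``, ``rate``, ``rate_true``; the
    generating constants ride along in ``DataFrame.attrs``.
    """
    S = np.asarray(S_levels, dtype=float)
    true = rs_max * S / (Ks + S)
    frame = pd.DataFrame({"S_gL": S, "rate": true, "rate_true": true})
    uncensored = NoiseModel(kind=noise.kind, cv_or_sd=noise.cv_or_sd,
                            seed=noise.seed, detection_limit=0.0)
    frame = uncensored.apply(frame, columns=["rate"])
    frame.attrs.update({"Ks": Ks, "rs_max": rs_max, "seed": noise.seed})
    return frame


def generate_calibration_readings(
        true_curve: Callable[[float], float],
        pH_levels: Sequence[float] = (4.0, 5.0, 6.0, 7.0, 8.0),
        noise: NoiseModel = NOISELESS,
        strain: str = "synthetic") -> list[FluorescenceReading]:
    """Fluorescence readings whose emission ratio equals true_curve(pH).

    The filtrate intensities are fixed (F490=150, F440=50 a.u.) so the
    denominator never degenerates; suspension intensities are constructed
    to produce the requested ratio, then perturbed by the noise model on
    the ratio scale.
    """
    rng = np.random.default_rng(noise.seed)
    F490, F440 = 150.0, 50.0
    S440 = 120.0
    readings = []
    for pH in pH_levels:
        r = float(true_curve(pH))
        s = noise.scale_for("R")
        if s > 0:
            r = r * (1.0 + rng.normal(0.0, s)) \
                if noise.kind.startswith("mult") else r + rng.normal(0.0, s)
        readings.append(FluorescenceReading(
            S490=S440 + r * (F490 - F440), S440=S440,
            F490=F490, F440=F440, pH_ex=float(pH), strain=strain))
    return readings
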