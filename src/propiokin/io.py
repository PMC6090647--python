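"""Readers and writers for trajectory CSVs, parameter files and run
configuration.

Trajectory CSV schema: comma-separated, UTF-8, '.' decimal, mandatory
header ``time_h,X_gL,S_gL,PA_gL,PYR_gL,AA_gL,SA_gL[,V_L]``; missing
values blank.  Unknown columns (for instance a lactate column ``LA_gL``)
are preserved as annotation columns.  An ``A600`` column is converted to
dry cell weight when a strain factor is supplied.

Parameter and config files are flat TOML key = value documents.
"""

from __future__ import annotations

import logging
import os
import tempfile
import tomllib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .kinetic_model import SPECIES, KineticParameters, TimeSeries
from .fermentation_metrics import DCW_FACTORS, od_to_dcw

__all__ = [
    "COLUMN_NAMES",
    "RunConfig",
    "read_timeseries_csv",
    "write_timeseries_csv",
    "read_parameters",
    "write_parameters",
    "read_config",
    "atomic_write_text",
]

logger = logging.getLogger("propiokin")

#: internal species name → CSV column header
COLUMN_NAMES = {"X": "X_gL", "S": "S_gL", "PA": "PA_gL", "PYR": "PYR_gL",
                "AA": "AA_gL", "SA": "SA_gL", "V": "V_L"}
_HEADER_TO_NAME = {v: k for k, v in COLUMN_NAMES.items()}


@dataclass
class RunConfig:
    """Execution settings shared by the command-line subcommands."""

    output_dir: Path = Path(".")
    rtol: float = 1e-8
    atol: float = 1e-10
    pv_interval: tuple[float, float] = (15.0, 30.0)
    dcw_factors: dict[str, float] = field(default_factory=lambda: dict(DCW_FACTORS))
    seed: int = 0
    verbosity: str = "info"

    def __post_init__(self) -> None:
        if not (self.rtol > 0 and self.atol > 0):
            raise ValueError("solver tolerances must be > 0")


def read_config(path: str | Path) -> RunConfig:
    with open(path, "rb") as fh:
        raw = tomllib.load(fh)
    kwargs = {}
    for key in ("rtol", "atol", "seed", "verbosity", "output_dir"):
        if key in raw:
            kwargs[key] = raw.pop(key)
    if "pv_interval" in raw:
        kwargs["pv_interval"] = tuple(raw.pop("pv_interval"))
    if "dcw_factors" in raw:
        kwargs["dcw_factors"] = dict(raw.pop("dcw_factors"))
    if raw:
        raise ValueError(f"unknown config keys: {sorted(raw)}")
    if "output_dir" in kwargs:
        kwargs["output_dir"] = Path(kwargs["output_dir"])
    return RunConfig(**kwargs)


def atomic_write_text(path: str | Path, text: str) -> None:
    """Write via a temp file + rename so readers never see partial output."""
    path = Path(path)
    fd, tmp = tempfile.mkstemp(dir=path.parent, suffix=".tmp")
    try:
        with os.fdopen(fd, "w", encoding="utf-8") as fh:
            fh.write(text)
        os.replace(tmp, path)
    except BaseException:
        if os.path.exists(tmp):
            os.unlink(tmp)
        raise


def write_timeseries_csv(ts: TimeSeries, path: str | Path) -> None:
    frame = ts.frame.rename(columns=COLUMN_NAMES)
    atomic_write_text(path, frame.to_csv(float_format="%.10g"))


def read_timeseries_csv(path: str | Path,
                        dcw_factor: float | None = None) -> TimeSeries:
    """Load a trajectory CSV into a validated TimeSeries.

    Rows must be strictly increasing in time; negative concentrations
    are rejected with the offending row number.  ``dcw_factor`` converts
    an ``A600`` column into the biomass column X (g DCW/L); without a
    factor the absorbance column is kept as an annotation.
    """
    frame = pd.read_csv(path)
    if frame.columns[0] != "time_h":
        raise ValueError(
            f"first column must be 'time_h', got {frame.columns[0]!r}")
    frame = frame.set_index("time_h")
    t = frame.index.to_numpy(dtype=float)
    bad = np.where(np.diff(t) <= 0)[0]
    if bad.size:
        raise ValueError(
            f"times not strictly increasing at data row {bad[0] + 3} "
            f"(t = {t[bad[0] + 1]!r})")
    frame = frame.rename(columns=_HEADER_TO_NAME)
    if "A600" in frame.columns and dcw_factor is not None:
        if "X" in frame.columns:
            raise ValueError("both X_gL and A600 columns present")
        frame["X"] = [od_to_dcw(a, dcw_factor) if np.isfinite(a) else np.nan
                      for a in frame["A600"].to_numpy(dtype=float)]
        frame = frame.drop(columns=["A600"])
    for col in frame.columns:
        if col not in SPECIES + ("V",):
            continue
        vals = frame[col].to_numpy(dtype=float)
        neg = np.where(vals < 0)[0]
        if neg.size:
            raise ValueError(
                f"negative {COLUMN_NAMES.get(col, col)} at data row "
                f"{neg[0] + 2}: {vals[neg[0]]}")
    meta = {"source": "observed", "path": str(path)}
    if dcw_factor is not None:
        meta["dcw_factor"] = dcw_factor
    return TimeSeries(frame=frame, meta=meta)


def write_parameters(p: KineticParameters, path: str | Path) -> None:
    lines = [f"{name} = {getattr(p, name)!r}" for name in p.as_dict()]
    atomic_write_text(path, "\n".join(lines) + "\n")


def read_parameters(path: str | Path) -> KineticParameters:
    """Flat key = value parameter file; keys must match the parameter
    names exactly, unknown keys are an error."""
    with open(path, "rb") as fh:
        raw = tomllib.load(fh)
    return KineticParameters.from_dict(raw)
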