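"""CSV/TSV schemas and configuration for the analysis pipeline.

Column names carry their units as suffixes (``holding_mV``,
``peak_pA``, ``conc_uM``); one header row; comma- or tab-separated by
file extension. Unknown columns warn but are preserved — never
silently dropped. Missing mandatory columns raise :class:`SchemaError`
naming the column.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import pandas as pd
import yaml

from .plate_pipeline import ConcentrationResponseTable, GatingCurve

__all__ = [
    "SCHEMA_VERSION",
    "SWEEP_COLUMNS",
    "CELL_COLUMNS",
    "SchemaError",
    "RunConfig",
    "read_sweep_table",
    "write_sweep_table",
    "read_cell_table",
    "write_cell_table",
    "read_gating_curve",
    "write_gating_curve",
    "read_conc_response",
    "write_conc_response",
    "load_run_config",
]

SCHEMA_VERSION = "1"

# per-sweep records: the universal exchange format of the package
SWEEP_COLUMNS = [
    "cell_id", "well", "protocol", "epoch", "sweep", "time_s",
    "holding_mV", "test_mV", "prepulse_ms", "peak_pA", "steady_pA",
    "temp_C", "compound", "conc_uM",
]

# per-cell QC metrics
CELL_COLUMNS = ["cell_id", "rm_MOhm", "rs_MOhm", "cap_pF", "baseline_peak_pA"]

GATING_COLUMNS = ["voltage_mV", "fraction", "kind"]
CONC_RESPONSE_COLUMNS = ["cell_id", "conc_uM", "inhibition"]


class SchemaError(ValueError):
    """A table does not match its documented schema."""


def _sep_for(path) -> str:
    return "\t" if str(path).endswith((".tsv", ".tab")) else ","


def _read_table(path, required: list[str], name: str) -> pd.DataFrame:
    path = Path(path)
    try:
        df = pd.read_csv(path, sep=_sep_for(path))
    except pd.errors.EmptyDataError:
        raise SchemaError(f"{name} file {path} is empty (no header row)")
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{name} file {path} is missing mandatory "
                          f"column(s): {', '.join(missing)}")
    extra = [c for c in df.columns if c not in required]
    if extra:
        warnings.warn(f"{name} file {path} has unrecognized column(s) "
                      f"{extra}; they are kept but ignored by the pipeline",
                      stacklevel=2)
    return df


def _write_table(df: pd.DataFrame, path, columns: list[str]) -> None:
    path = Path(path)
    extra = [c for c in df.columns if c not in columns]
    df.loc[:, columns + extra].to_csv(path, sep=_sep_for(path), index=False)


def read_sweep_table(path) -> pd.DataFrame:
    """Load per-sweep records; validates schema and basic invariants."""
    df = _read_table(path, SWEEP_COLUMNS, "sweep table")
    if len(df) and (df["time_s"] < 0).any():
        raise SchemaError("time_s must be non-negative")
    return df


def write_sweep_table(df: pd.DataFrame, path) -> None:
    missing = [c for c in SWEEP_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"sweep table missing column(s): {', '.join(missing)}")
    _write_table(df, path, SWEEP_COLUMNS)


def read_cell_table(path) -> pd.DataFrame:
    return _read_table(path, CELL_COLUMNS, "cell table")


def write_cell_table(df: pd.DataFrame, path) -> None:
    missing = [c for c in CELL_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"cell table missing column(s): {', '.join(missing)}")
    _write_table(df, path, CELL_COLUMNS)


def read_gating_curve(path) -> GatingCurve:
    df = _read_table(path, GATING_COLUMNS, "gating curve")
    kinds = df["kind"].unique()
    if len(kinds) != 1:
        raise SchemaError(f"gating curve must have a single kind, got {kinds}")
    return GatingCurve(df["voltage_mV"].to_numpy(float),
                       df["fraction"].to_numpy(float), kinds[0])


def write_gating_curve(curve: GatingCurve, path) -> None:
    _write_table(curve.to_frame(), path, GATING_COLUMNS)


def read_conc_response(path) -> ConcentrationResponseTable:
    """Read per-cell inhibition points and re-pool them."""
    from .plate_pipeline import pool_concentration_response
    df = _read_table(path, CONC_RESPONSE_COLUMNS, "concentration-response")
    return pool_concentration_response(df)


def write_conc_response(table: ConcentrationResponseTable, path) -> None:
    """Write the per-cell provenance rows (the pooled view is derived)."""
    _write_table(table.cells, path, CONC_RESPONSE_COLUMNS)


@dataclass
class RunConfig:
    """Analysis-run configuration (YAML on disk)."""

    seed: int = 0
    schema_version: str = SCHEMA_VERSION
    input_paths: dict = field(default_factory=dict)
    output_dir: str = "."
    fix_slope: Optional[float] = None
    pooling: str = "mean"            # "mean" or "cells"
    persist_fraction: float = 0.1    # persistent-current window
    verbosity: int = 0

    def __post_init__(self) -> None:
        if str(self.schema_version) != SCHEMA_VERSION:
            raise SchemaError(
                f"unsupported schema version {self.schema_version!r}; "
                f"this package reads version {SCHEMA_VERSION!r}")
        if self.pooling not in ("mean", "cells"):
            raise ValueError(f"pooling must be 'mean' or 'cells', "
                             f"got {self.pooling!r}")


def load_run_config(path) -> RunConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    known = {f for f in RunConfig.__dataclass_fields__}
    unknown = set(raw) - known
    if unknown:
        warnings.warn(f"config {path}: ignoring unknown key(s) "
                      f"{sorted(unknown)}", stacklevel=2)
    return RunConfig(**{k: v for k, v in raw.items() if k in known})
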