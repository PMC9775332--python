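"""Readers and writers for traces, profiles, and result tables.

A raw run is stored as a long-format CSV (``time_s, intensity``, header
mandatory) plus a YAML sidecar naming the baseline window, the sonication
cycles — either an explicit interval list or a regular pulse description —
the lysis time, and run metadata.  An XLSX workbook with one run per sheet is
accepted as an alternative, mirroring common spectrofluorometer spreadsheet
habits.  De-stepped profiles round-trip as two-column CSV (``t_us, cfr``).
"""

from __future__ import annotations

from pathlib import Path
from typing import Optional, Union

import numpy as np
import pandas as pd
import yaml

from .preprocess import FluorescenceTrace, ReleaseProfile

__all__ = [
    "read_trace",
    "write_trace",
    "read_profile",
    "write_profile",
    "read_traces_xlsx",
    "write_results",
]

PathLike = Union[str, Path]


def _cycles_from_config(cfg: dict) -> list[tuple[float, float]]:
    cycles = cfg.get("cycles")
    if isinstance(cycles, dict):
        on = float(cycles["on_duration"])
        off = float(cycles["off_duration"])
        n = int(cycles["n_cycles"])
        start = float(cycles.get("start", 0.0))
        return [
            (start + i * (on + off), start + i * (on + off) + on) for i in range(n)
        ]
    if isinstance(cycles, list):
        return [(float(a), float(b)) for a, b in cycles]
    raise ValueError(
        "config 'cycles' must be an interval list or a "
        "{on_duration, off_duration, n_cycles, start} mapping"
    )


def _trace_from_frame(df: pd.DataFrame, config: dict) -> FluorescenceTrace:
    missing = {"time_s", "intensity"} - set(df.columns)
    if missing:
        raise ValueError(f"trace table is missing columns: {sorted(missing)}")
    return FluorescenceTrace(
        time=df["time_s"].to_numpy(dtype=float),
        intensity=df["intensity"].to_numpy(dtype=float),
        baseline_window=tuple(float(x) for x in config["baseline_window"]),
        cycles=_cycles_from_config(config),
        lysis_time=float(config["lysis_time"]),
        meta=dict(config.get("meta", {})),
    )


def read_trace(csv_path: PathLike, config_path: PathLike) -> FluorescenceTrace:
    """Load a raw trace from a ``time_s,intensity`` CSV and its YAML sidecar."""
    df = pd.read_csv(csv_path)
    with open(config_path) as fh:
        config = yaml.safe_load(fh)
    return _trace_from_frame(df, config)


def write_trace(
    trace: FluorescenceTrace, csv_path: PathLike, config_path: PathLike
) -> None:
    """Write a trace as CSV plus YAML sidecar (the format ``read_trace`` reads)."""
    pd.DataFrame({"time_s": trace.time, "intensity": trace.intensity}).to_csv(
        csv_path, index=False
    )
    config = {
        "baseline_window": [float(x) for x in trace.baseline_window],
        "cycles": [[float(a), float(b)] for a, b in trace.cycles],
        "lysis_time": float(trace.lysis_time),
        "meta": _plain(trace.meta),
    }
    with open(config_path, "w") as fh:
        yaml.safe_dump(config, fh, sort_keys=False)


def _plain(obj):
    """Recursively coerce numpy scalars/containers to YAML-safe builtins."""
    if isinstance(obj, dict):
        return {str(k): _plain(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_plain(v) for v in obj]
    if isinstance(obj, np.generic):
        return obj.item()
    return obj


def read_traces_xlsx(
    xlsx_path: PathLike, configs: Union[dict, "dict[str, dict]"]
) -> dict[str, FluorescenceTrace]:
    """Load one run per sheet from an XLSX workbook.

    ``configs`` is either a single sidecar-style config applied to every
    sheet, or a mapping of sheet name to config.
    """
    sheets = pd.read_excel(xlsx_path, sheet_name=None)
    per_sheet = all(isinstance(v, dict) and "lysis_time" in v for v in configs.values())
    out = {}
    for name, df in sheets.items():
        cfg = configs[name] if per_sheet else configs
        out[name] = _trace_from_frame(df, cfg)
    return out


def read_profile(csv_path: PathLike) -> ReleaseProfile:
    """Load a de-stepped profile from a ``t_us,cfr`` CSV."""
    df = pd.read_csv(csv_path)
    missing = {"t_us", "cfr"} - set(df.columns)
    if missing:
        raise ValueError(f"profile table is missing columns: {sorted(missing)}")
    return ReleaseProfile(
        t_us=df["t_us"].to_numpy(dtype=float), cfr=df["cfr"].to_numpy(dtype=float)
    )


def write_profile(profile: ReleaseProfile, csv_path: PathLike) -> None:
    pd.DataFrame({"t_us": profile.t_us, "cfr": profile.cfr}).to_csv(
        csv_path, index=False
    )


def write_results(
    study,
    csv_path: Optional[PathLike] = None,
    xlsx_path: Optional[PathLike] = None,
    summary: Optional[pd.DataFrame] = None,
) -> pd.DataFrame:
    """Write a study's tidy results table as CSV and/or a two-sheet XLSX
    (results + replicate summary).  Returns the tidy frame."""
    df = study.to_frame()
    if csv_path is not None:
        df.to_csv(csv_path, index=False)
    if xlsx_path is not None:
        with pd.ExcelWriter(xlsx_path) as writer:
            df.to_excel(writer, sheet_name="results", index=False)
            if summary is not None:
                summary.to_excel(writer, sheet_name="summary", index=False)
    return df
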