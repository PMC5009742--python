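"""Plate/melt CSV and FASTA ingest, results writing, and run configuration.

The CSV dialect is deliberately minimal: UTF-8, '.' decimal, fixed headers
``well,time_min,rfu`` for amplification plates and ``well,temp_c,rfu`` for
melt runs.  Ingest errors carry 1-based data row numbers.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import SeqIO

from .curves import AMPLIFICATION, MELT, FluorescenceCurve
from .errors import ConfigError, IngestError

__all__ = [
    "RunConfig",
    "read_plate_csv",
    "write_plate_csv",
    "write_results_csv",
    "read_fasta",
    "read_config",
]

PLATE_HEADERS = ("well", "time_min", "rfu")
MELT_HEADERS = ("well", "temp_c", "rfu")


@dataclass(frozen=True)
class RunConfig:
    """End-to-end run settings (simulation truth, analysis thresholds, IO)."""

    seed: int = 0
    read_interval: float = 1.0  # minutes
    duration: float = 60.0  # minutes
    calibration_a: float = 28.3  # POI intercept, minutes
    calibration_b: float = 2.09  # minutes per decade (POI = a - b lg copies)
    range_min: float = 0.602  # copies
    range_max: float = 6.02e11  # copies
    replicates: int = 3
    smooth_window: int = 7
    poly_order: int = 2
    melt_prominence: float = 0.1
    amplification_floor: float = 0.1  # copies
    nonspecific_background: bool = False
    template_kind: str = "biotin"
    outdir: str = "exparkit_out"

    def __post_init__(self) -> None:
        if self.read_interval <= 0 or self.duration <= 0:
            raise ConfigError("read_interval and duration must be positive")
        if self.duration <= 10 * self.read_interval:
            raise ConfigError("duration must exceed 10 read intervals")
        if self.melt_prominence <= 0 or self.amplification_floor <= 0:
            raise ConfigError("thresholds must be positive")
        if self.template_kind not in ("standard", "biotin", "toehold_biotin"):
            raise ConfigError(f"unknown template kind '{self.template_kind}'")


def read_config(path) -> RunConfig:
    """Parse a plain-text ``key = value`` configuration file.

    Lines starting with '#' (and blank lines) are ignored; keys must match
    :class:`RunConfig` field names, and values are coerced to the field type.
    """
    fields = {f.name: f for f in dataclasses.fields(RunConfig)}
    kwargs: dict = {}
    for lineno, raw in enumerate(Path(path).read_text().splitlines(), start=1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        if "=" not in line:
            raise ConfigError(f"line {lineno}: expected 'key = value', got '{raw.strip()}'")
        key, value = (part.strip() for part in line.split("=", 1))
        if key not in fields:
            raise ConfigError(f"line {lineno}: unknown configuration key '{key}'")
        ftype = fields[key].type
        try:
            if ftype == "bool":
                kwargs[key] = value.lower() in ("1", "true", "yes", "on")
            elif ftype == "int":
                kwargs[key] = int(value)
            elif ftype == "float":
                kwargs[key] = float(value)
            else:
                kwargs[key] = value
        except ValueError as exc:
            raise ConfigError(f"line {lineno}: cannot parse '{value}' for '{key}'") from exc
    return RunConfig(**kwargs)


def read_plate_csv(path) -> list[FluorescenceCurve]:
    """Read a plate CSV into per-well curves, time-sorted.

    Accepts either the amplification (``well,time_min,rfu``) or the melt
    (``well,temp_c,rfu``) header set and tags the curves accordingly.
    Duplicate (well, time) pairs and non-numeric cells are rejected with the
    offending data row numbers.
    """
    df = pd.read_csv(path, dtype=str)
    cols = tuple(df.columns)
    if cols == PLATE_HEADERS:
        kind, xcol = AMPLIFICATION, "time_min"
    elif cols == MELT_HEADERS:
        kind, xcol = MELT, "temp_c"
    else:
        raise IngestError(
            f"unexpected headers {list(cols)}; need {list(PLATE_HEADERS)} or {list(MELT_HEADERS)}"
        )
    if len(df) == 0:
        raise IngestError("empty plate file")

    for col in (xcol, "rfu"):
        numeric = pd.to_numeric(df[col], errors="coerce")
        bad = df.index[numeric.isna()].tolist()
        if bad:
            rows = ", ".join(str(i + 1) for i in bad[:5])
            raise IngestError(f"non-numeric '{col}' values at data row(s) {rows}")
        df[col] = numeric

    dup_mask = df.duplicated(subset=["well", xcol], keep=False)
    if dup_mask.any():
        rows = ", ".join(str(i + 1) for i in df.index[dup_mask][:5])
        raise IngestError(f"duplicate (well, {xcol}) pairs at data row(s) {rows}")

    curves = []
    for well, grp in df.groupby("well", sort=True):
        grp = grp.sort_values(xcol)
        curves.append(
            FluorescenceCurve(
                well=str(well),
                times=grp[xcol].to_numpy(dtype=float),
                rfu=grp["rfu"].to_numpy(dtype=float),
                kind=kind,
            )
        )
    return curves


def write_plate_csv(curves, path) -> None:
    """Write curves in the plate/melt CSV dialect (kind inferred from curves)."""
    curves = list(curves)
    if not curves:
        raise IngestError("no curves to write")
    kinds = {c.kind for c in curves}
    if len(kinds) != 1:
        raise IngestError("cannot mix amplification and melt curves in one file")
    xcol = "time_min" if kinds.pop() == AMPLIFICATION else "temp_c"
    frames = [
        pd.DataFrame({"well": c.well, xcol: c.times, "rfu": c.rfu}) for c in curves
    ]
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def write_results_csv(results: pd.DataFrame, path) -> None:
    results.to_csv(path, index=False)


def read_fasta(path) -> dict[str, str]:
    """Read named sequences; names must be unique, sequences are uppercased."""
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise IngestError(f"no FASTA records in {path}")
    out: dict[str, str] = {}
    for rec in records:
        if rec.id in out:
            raise IngestError(f"duplicate sequence name '{rec.id}'")
        out[rec.id] = str(rec.seq).upper()
    return out
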