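"""Reading and writing datasets, count tables and generator configs.

The dataset CSV has one row per foal per occasion with columns
``foal_id, occasion, sucrose45_umol_l, sucrose90_umol_l, gl, gdl, sql,
csl`` and optionally ``latent_state`` (present only for simulated data,
where the true disease state is known).  ``occasion`` is "pre"/"post";
binary columns are 0/1.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import numpy as np
import pandas as pd

from .latent_class import CrossClassifiedCounts, pattern_index, POPULATIONS
from .simulate import FoalRecord, SimulationConfig, StudyDataset

REQUIRED_COLUMNS = ("foal_id", "occasion", "sucrose45_umol_l",
                    "sucrose90_umol_l", "gl", "gdl", "sql", "csl")


class SchemaError(ValueError):
    """Dataset file violates the schema; carries per-row detail."""


def write_dataset(dataset: StudyDataset, path) -> None:
    dataset.to_frame().to_csv(path, index=False)


def read_dataset(path) -> StudyDataset:
    """Read and validate a dataset CSV.

    Row numbers in error messages are 1-based data rows (header excluded).
    """
    path = Path(path)
    try:
        df = pd.read_csv(path, float_precision="round_trip")
    except pd.errors.EmptyDataError:
        raise SchemaError(f"{path}: file is empty") from None
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing columns {missing}")
    if df.empty:
        raise SchemaError(f"{path}: no data rows")

    errors: list[str] = []
    for col in ("sucrose45_umol_l", "sucrose90_umol_l"):
        bad = pd.to_numeric(df[col], errors="coerce")
        for i in df.index[bad.isna()]:
            errors.append(f"row {i + 1}: non-numeric {col} ({df.loc[i, col]!r})")
        for i in df.index[bad <= 0]:
            errors.append(f"row {i + 1}: non-positive {col}")
    for col in ("gl", "gdl", "sql", "csl"):
        vals = pd.to_numeric(df[col], errors="coerce")
        for i in df.index[~vals.isin((0, 1))]:
            errors.append(f"row {i + 1}: {col} must be 0 or 1")
    for i in df.index:
        occ = str(df.loc[i, "occasion"])
        if occ not in ("pre", "post"):
            errors.append(f"row {i + 1}: occasion must be 'pre'/'post', got {occ!r}")
    if not errors:
        sub_bad = (df[["gdl", "sql", "csl"]].astype(int).any(axis=1)
                   & (df["gl"].astype(int) == 0))
        for i in df.index[sub_bad]:
            errors.append(f"row {i + 1}: subtype lesion present but gl = 0")
        dupes = df.duplicated(subset=["foal_id", "occasion"], keep=False)
        for i in df.index[dupes]:
            errors.append(
                f"row {i + 1}: duplicate (foal_id, occasion) "
                f"({df.loc[i, 'foal_id']!r}, {df.loc[i, 'occasion']!r})"
            )
    if errors:
        raise SchemaError(f"{path}: " + "; ".join(errors[:20]))
    return StudyDataset.from_frame(df)


def write_counts(counts: CrossClassifiedCounts, path) -> None:
    counts.to_frame().to_csv(path, index=False)


def read_counts(path) -> CrossClassifiedCounts:
    df = pd.read_csv(path)
    required = {"t1", "t2", "t3", "population", "count"}
    if not required <= set(df.columns):
        raise SchemaError(f"{path}: counts CSV needs columns {sorted(required)}")
    return CrossClassifiedCounts.from_frame(df)


# ---------------------------------------------------------------------------
# Plain-text generator config (key = value, one per line; pairs comma-split)


def write_config(config: SimulationConfig, path) -> None:
    lines = []
    for f in dataclasses.fields(config):
        v = getattr(config, f.name)
        if isinstance(v, tuple):
            v = ", ".join(repr(x) for x in v)
        elif isinstance(v, dict):
            v = ", ".join(f"{k}:{p}" for k, p in v.items())
        lines.append(f"{f.name} = {v}")
    Path(path).write_text("\n".join(lines) + "\n")


def read_config(path) -> SimulationConfig:
    kwargs: dict = {}
    fields = {f.name: f for f in dataclasses.fields(SimulationConfig)}
    for raw in Path(path).read_text().splitlines():
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        if "=" not in line:
            raise SchemaError(f"{path}: malformed config line {raw!r}")
        key, val = (s.strip() for s in line.split("=", 1))
        if key not in fields:
            raise SchemaError(f"{path}: unknown config key {key!r}")
        if key in ("n_foals", "seed"):
            kwargs[key] = int(val)
        elif key == "subtype_probs":
            kwargs[key] = {k.strip(): float(p)
                           for k, p in (item.split(":") for item in val.split(","))}
        elif key.startswith("mean_sd"):
            m, s = (float(x) for x in val.split(","))
            kwargs[key] = (m, s)
        else:
            kwargs[key] = float(val)
    return SimulationConfig(**kwargs)
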