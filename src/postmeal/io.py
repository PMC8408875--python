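"""Readers and writers for the package's TSV schemas.

All tables are tab-separated with dot decimals.  Schemas:

* curves:        participant_id  analyte  time_min  value
* markers:       participant_id  marker   time_h    value
* covariates:    participant_id  age sex bmi weight vfm microbiome_pc1..10
* summary stats: snp effect_allele other_allele eaf beta se pval n
* features:      participant_id + the 13 named curve features + peak times

Writing then reading reproduces values to full precision (values are
serialized with repr-level precision).  Malformed rows raise with the
offending location.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .curves import (
    PostprandialCurve,
    extract_glycemic_features,
    extract_lipemic_features,
)
from .exceptions import SchemaError

__all__ = [
    "read_curves",
    "write_curves",
    "read_markers",
    "write_markers",
    "read_covariates",
    "write_covariates",
    "read_summary_stats",
    "write_summary_stats",
    "feature_table",
    "write_table",
    "read_table",
    "write_truth",
]

CURVE_COLUMNS = ["participant_id", "analyte", "time_min", "value"]
MARKER_COLUMNS = ["participant_id", "marker", "time_h", "value"]
SUMMARY_STAT_COLUMNS = ["snp", "effect_allele", "other_allele", "eaf", "beta", "se", "pval", "n"]

_FLOAT_FMT = "%.17g"


def _read_tsv(path, required: list[str], numeric: list[str]) -> pd.DataFrame:
    path = Path(path)
    try:
        df = pd.read_csv(path, sep="\t", comment="#", float_precision="round_trip")
    except pd.errors.EmptyDataError:
        raise SchemaError(f"{path}: file is empty") from None
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing required columns {missing}")
    if df.empty:
        raise SchemaError(f"{path}: no data rows")
    for col in numeric:
        parsed = pd.to_numeric(df[col], errors="coerce")
        bad = parsed.isna() & df[col].notna()
        if bad.any():
            line = int(bad.idxmax()) + 2  # header is line 1
            raise SchemaError(f"{path}: non-numeric value in column {col!r} at line {line}")
        df[col] = parsed
    return df


def write_table(df: pd.DataFrame, path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="\t", index=False, float_format=_FLOAT_FMT)
    return path


def read_table(path) -> pd.DataFrame:
    return _read_tsv(path, [], [])


def write_curves(curves: list[PostprandialCurve], path) -> Path:
    rows = []
    for c in curves:
        for t, v in zip(c.times, c.values):
            rows.append((c.participant_id, c.analyte, t, v))
    return write_table(pd.DataFrame(rows, columns=CURVE_COLUMNS), path)


def read_curves(path) -> list[PostprandialCurve]:
    df = _read_tsv(path, CURVE_COLUMNS, ["time_min", "value"])
    curves = []
    for (pid, analyte), grp in df.groupby(["participant_id", "analyte"], sort=True):
        grp = grp.sort_values("time_min")
        curves.append(
            PostprandialCurve(
                str(pid), str(analyte),
                grp["time_min"].to_numpy(float),
                grp["value"].to_numpy(float),
            )
        )
    return curves


def write_markers(markers: pd.DataFrame, path) -> Path:
    return write_table(markers[MARKER_COLUMNS], path)


def read_markers(path) -> pd.DataFrame:
    return _read_tsv(path, MARKER_COLUMNS, ["time_h", "value"])


def write_covariates(covariates: pd.DataFrame, path) -> Path:
    return write_table(covariates, path)


def read_covariates(path) -> pd.DataFrame:
    df = _read_tsv(path, ["participant_id"], [])
    numeric = [c for c in df.columns if c != "participant_id"]
    return _read_tsv(path, ["participant_id"], numeric)


def write_summary_stats(stats: pd.DataFrame, path) -> Path:
    return write_table(stats[SUMMARY_STAT_COLUMNS], path)


def read_summary_stats(path) -> pd.DataFrame:
    return _read_tsv(path, SUMMARY_STAT_COLUMNS, ["eaf", "beta", "se", "pval", "n"])


def feature_table(curves: list[PostprandialCurve]) -> pd.DataFrame:
    """Wide per-participant table of the 13 curve features (+ peak times)."""
    glu = {}
    tg = {}
    for c in curves:
        if c.analyte == "glucose":
            glu[c.participant_id] = extract_glycemic_features(c).as_dict()
        elif c.analyte == "tg":
            tg[c.participant_id] = extract_lipemic_features(c).as_dict()
    pids = sorted(set(glu) | set(tg))
    rows = []
    for pid in pids:
        row = {"participant_id": pid}
        row.update(glu.get(pid, {}))
        row.update(tg.get(pid, {}))
        rows.append(row)
    return pd.DataFrame(rows).set_index("participant_id")


def write_truth(truth: dict, path) -> Path:
    """Planted-parameter sidecar, as indented JSON."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)

    def _default(o):
        if isinstance(o, (np.floating, np.integer)):
            return o.item()
        if isinstance(o, np.ndarray):
            return o.tolist()
        raise TypeError(type(o))

    path.write_text(json.dumps(truth, indent=2, default=_default) + "\n")
    return path
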