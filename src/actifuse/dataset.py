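"""Assemble per-window feature vectors into labeled datasets, balance them,
and round-trip CSV/ARFF interchange formats.

A feature table is a pandas DataFrame with the metadata columns
``label, device, segment_id, window_index`` followed by the device schema's
feature columns in fixed order. ARFF output declares every feature numeric
and the class attribute nominal over the nine activity labels, with missing
values as ``?``.
"""

from __future__ import annotations

import io
from pathlib import Path

import numpy as np
import pandas as pd

from .features_inertial import (
    PHONE_FEATURE_NAMES,
    WATCH_FEATURE_NAMES,
    sensor_subset_columns,
)
from .signal_io import ACTIVITIES, ENVIRONMENTS

META_COLUMNS = ("label", "device", "segment_id", "window_index")

PHONE_SUBSETS = ("fused", "accelerometer", "magnetometer", "gyro", "pressure")
WATCH_SUBSETS = ("accelerometer",)


def feature_columns(table: pd.DataFrame) -> list[str]:
    return [c for c in table.columns if c not in META_COLUMNS]


def build_dataset(
    vectors, device: str, subset: str = "fused"
) -> pd.DataFrame:
    """Labeled feature table restricted to one sensor subset's columns.

    ``vectors`` is an iterable of dicts (metadata + features, as produced by
    the pipeline) or an existing full table. All rows must share the
    device's schema; rows are ordered by (segment, window index).
    """
    if device == "phone":
        schema, allowed = PHONE_FEATURE_NAMES, PHONE_SUBSETS
    elif device == "watch":
        schema, allowed = WATCH_FEATURE_NAMES, WATCH_SUBSETS
    else:
        raise ValueError(f"unknown device {device!r}")
    if subset not in allowed:
        raise ValueError(f"subset {subset!r} not available for {device}")
    df = vectors if isinstance(vectors, pd.DataFrame) else pd.DataFrame(list(vectors))
    if df.empty:
        return pd.DataFrame(columns=[*META_COLUMNS, *sensor_subset_columns(subset, schema)])
    missing = set(schema) - set(df.columns)
    if missing:
        raise ValueError(
            f"feature vectors do not match the {device} schema; missing "
            f"{sorted(missing)[:5]}..."
        )
    cols = sensor_subset_columns(subset, schema)
    out = df[[*META_COLUMNS, *cols]].copy()
    out = out.sort_values(["segment_id", "window_index"], kind="stable")
    return out.reset_index(drop=True)


def balance_dataset(table: pd.DataFrame, seed: int = 0) -> pd.DataFrame:
    """Subsample every class, without replacement, to the minimum class
    count. Deterministic under ``seed``; original row order is preserved
    among the retained rows."""
    if table.empty or "label" not in table.columns:
        raise ValueError("cannot balance an empty or unlabeled table")
    counts = table["label"].value_counts()
    if counts.empty or counts.min() < 1:
        empty = [l for l in counts.index if counts[l] == 0]
        raise ValueError(f"classes without instances: {empty or 'all'}")
    n_min = int(counts.min())
    rng = np.random.default_rng(seed)
    keep: list[np.ndarray] = []
    for label in sorted(counts.index):
        idx = table.index[table["label"] == label].to_numpy()
        keep.append(rng.choice(idx, size=n_min, replace=False))
    kept = np.sort(np.concatenate(keep))
    return table.loc[kept].reset_index(drop=True)


# ---------------------------------------------------------------------------
# interchange formats
# ---------------------------------------------------------------------------

def write_table(table: pd.DataFrame, path: str | Path, fmt: str = "csv") -> None:
    path = Path(path)
    if fmt == "csv":
        table.to_csv(path, index=False, float_format="%.17g")
    elif fmt == "arff":
        path.write_text(_to_arff(table))
    else:
        raise ValueError(f"unknown format {fmt!r}")


def read_table(path: str | Path, fmt: str | None = None) -> pd.DataFrame:
    path = Path(path)
    fmt = fmt or path.suffix.lstrip(".")
    if fmt == "csv":
        return pd.read_csv(path, float_precision="round_trip")
    if fmt == "arff":
        return _from_arff(path.read_text())
    raise ValueError(f"unknown format {fmt!r}")


def _class_values(labels) -> list[str]:
    observed = set(labels)
    if observed <= set(ACTIVITIES):
        return list(ACTIVITIES)
    if observed <= set(ENVIRONMENTS):
        return list(ENVIRONMENTS)
    return sorted(observed)


def _to_arff(table: pd.DataFrame, relation: str = "activity_windows") -> str:
    cols = [c for c in table.columns if c != "label"]
    buf = io.StringIO()
    buf.write(f"@relation {relation}\n\n")
    for c in cols:
        if table[c].dtype == object:
            values = ",".join(sorted(map(str, table[c].dropna().unique())))
            buf.write(f"@attribute {c} {{{values}}}\n")
        else:
            buf.write(f"@attribute {c} numeric\n")
    values = ",".join(_class_values(table["label"]))
    buf.write(f"@attribute class {{{values}}}\n\n@data\n")
    for _, row in table.iterrows():
        cells = []
        for c in cols:
            v = row[c]
            if isinstance(v, float) and np.isnan(v):
                cells.append("?")
            elif table[c].dtype == object:
                cells.append(str(v))
            else:
                cells.append(repr(float(v)) if isinstance(v, float) else str(v))
        cells.append(str(row["label"]))
        buf.write(",".join(cells) + "\n")
    return buf.getvalue()


def _from_arff(text: str) -> pd.DataFrame:
    names: list[str] = []
    nominal: dict[str, bool] = {}
    rows: list[list] = []
    in_data = False
    for line in text.splitlines():
        line = line.strip()
        if not line or line.startswith("%"):
            continue
        low = line.lower()
        if low.startswith("@attribute"):
            _, name, spec = line.split(None, 2)
            names.append(name)
            nominal[name] = spec.strip().startswith("{")
        elif low.startswith("@data"):
            in_data = True
        elif in_data:
            cells = [c.strip() for c in line.split(",")]
            parsed = []
            for name, c in zip(names, cells):
                if c == "?":
                    parsed.append(np.nan)
                elif nominal[name]:
                    parsed.append(c)
                else:
                    parsed.append(float(c))
            rows.append(parsed)
    df = pd.DataFrame(rows, columns=names)
    if "class" in df.columns:
        df = df.rename(columns={"class": "label"})
        # restore the conventional column order (label first)
        df = df[["label", *[c for c in df.columns if c != "label"]]]
    return df
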