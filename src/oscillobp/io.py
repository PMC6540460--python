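"""Measurement CSV schema and validated reading/writing.

The interchange format is a flat CSV with header::

    subject_id,meas_idx,MAP,AR,AE,EL,MA,SIG1,SIG2,MAPL,F9,F10,F11,ref_sbp,ref_dbp

one row per measurement, pressures in mmHg.  Validation reports the
offending column or row on failure.
"""

from __future__ import annotations

from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .cohort import FEATURE_NAMES, MeasurementRecord
from .errors import ValidationError

__all__ = ["CSV_COLUMNS", "read_measurements", "write_measurements"]

CSV_COLUMNS = ("subject_id", "meas_idx", *FEATURE_NAMES, "ref_sbp", "ref_dbp")


def _feature_columns(n_features: int) -> list[str]:
    names = list(FEATURE_NAMES[:n_features])
    if n_features > len(FEATURE_NAMES):
        names += [f"F{i + 1}" for i in range(len(FEATURE_NAMES), n_features)]
    return names


def write_measurements(
    records: Sequence[MeasurementRecord], path: str | Path
) -> None:
    """Write records to the measurement CSV schema."""
    if not records:
        raise ValidationError("no records to write")
    n_feat = len(records[0].features)
    feat_cols = _feature_columns(n_feat)
    rows = []
    for r in records:
        row = {"subject_id": r.subject_id, "meas_idx": r.meas_idx}
        row.update(dict(zip(feat_cols, r.features)))
        row["ref_sbp"] = r.ref_sbp
        row["ref_dbp"] = r.ref_dbp
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False)


def read_measurements(
    path: str | Path, n_measurements: int | None = None
) -> list[MeasurementRecord]:
    """Read and validate a measurement CSV.

    Checks: all schema columns present, all numeric cells parseable
    (reported with their row number), physiological ordering
    ``ref_sbp > ref_dbp > 0``, and — when ``n_measurements`` is given —
    that every subject has exactly that many rows.
    """
    df = pd.read_csv(path, float_precision="round_trip")
    missing = [c for c in CSV_COLUMNS if c not in df.columns]
    if missing:
        raise ValidationError(f"{path}: missing column(s) {', '.join(missing)}")
    numeric_cols = [c for c in CSV_COLUMNS if c != "subject_id"]
    for col in numeric_cols:
        converted = pd.to_numeric(df[col], errors="coerce")
        nan_rows = df.index[converted.isna()]
        if len(nan_rows):
            # +2: header line plus 1-based numbering
            raise ValidationError(
                f"{path}: non-numeric value in column {col!r} at row {nan_rows[0] + 2}"
            )
        df[col] = converted
    feat_cols = list(FEATURE_NAMES)
    records = []
    for i, row in df.iterrows():
        rec = MeasurementRecord(
            subject_id=str(row["subject_id"]),
            meas_idx=int(row["meas_idx"]),
            features=np.array([row[c] for c in feat_cols], dtype=float),
            ref_sbp=float(row["ref_sbp"]),
            ref_dbp=float(row["ref_dbp"]),
        )
        try:
            rec.validate()
        except ValidationError as exc:
            raise ValidationError(f"{path}: row {i + 2}: {exc}") from None
        records.append(rec)
    if n_measurements is not None:
        counts = df.groupby("subject_id").size()
        bad_subjects = counts[counts != n_measurements]
        if len(bad_subjects):
            sid = bad_subjects.index[0]
            raise ValidationError(
                f"{path}: subject {sid!r} has {bad_subjects.iloc[0]} rows, "
                f"expected {n_measurements}"
            )
    return records
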