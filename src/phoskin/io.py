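"""CSV schemas and readers/writers.

Measurement table: one row per sample, columns
``patient_id, modality, series, time_h, concentration_mmol_L`` with
modality in {SP, MP} and series in {blood, dialysate}. Patient constants
table: ``patient_id, Cd0_mmol_L, Vd0_L, Vb0_L``. Comma separator, UTF-8,
period decimal, header required.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .estimation import MeasurementSet
from .params import MPParameters

__all__ = [
    "read_measurements",
    "write_measurements",
    "read_constants",
    "write_constants",
    "write_truth",
]

MEASUREMENT_COLUMNS = [
    "patient_id",
    "modality",
    "series",
    "time_h",
    "concentration_mmol_L",
]
CONSTANTS_COLUMNS = ["patient_id", "Cd0_mmol_L", "Vd0_L", "Vb0_L"]


class SchemaError(ValueError):
    """A table violates the measurement or constants schema."""


def _check_columns(df: pd.DataFrame, expected: list[str], path) -> None:
    missing = [c for c in expected if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing column(s) {missing}")


def read_constants(path) -> dict[str, dict[str, float]]:
    """Read the per-patient fixed clinical quantities."""
    df = pd.read_csv(path, float_precision="round_trip")
    _check_columns(df, CONSTANTS_COLUMNS, path)
    out: dict[str, dict[str, float]] = {}
    for idx, row in df.iterrows():
        pid = str(row["patient_id"])
        if pid in out:
            raise SchemaError(f"{path}: duplicate patient_id {pid!r} at row {idx}")
        for col in ("Vd0_L", "Vb0_L"):
            if not row[col] > 0:
                raise SchemaError(f"{path}: row {idx}, column {col}: must be > 0")
        if row["Cd0_mmol_L"] < 0:
            raise SchemaError(f"{path}: row {idx}, column Cd0_mmol_L: negative")
        out[pid] = {
            "Cd0": float(row["Cd0_mmol_L"]),
            "Vd0": float(row["Vd0_L"]),
            "Vb0": float(row["Vb0_L"]),
        }
    return out


def read_measurements(path, constants_path=None) -> dict[str, MeasurementSet]:
    """Read, validate and group a measurement table by patient.

    Rows may appear in any order; series are sorted by time. When
    ``constants_path`` is given the per-patient fixed quantities are joined
    in (they are required later for fitting).
    """
    df = pd.read_csv(path, float_precision="round_trip")
    _check_columns(df, MEASUREMENT_COLUMNS, path)
    for idx, row in df.iterrows():
        if row["modality"] not in ("SP", "MP"):
            raise SchemaError(
                f"{path}: row {idx}, column modality: {row['modality']!r}"
            )
        if row["series"] not in ("blood", "dialysate"):
            raise SchemaError(f"{path}: row {idx}, column series: {row['series']!r}")
        if row["modality"] == "SP" and row["series"] == "dialysate":
            raise SchemaError(
                f"{path}: row {idx}: SP sessions have no dialysate series"
            )
        if not np.isfinite(row["time_h"]) or row["time_h"] < 0:
            raise SchemaError(f"{path}: row {idx}, column time_h: {row['time_h']!r}")
        if not np.isfinite(row["concentration_mmol_L"]) or row["concentration_mmol_L"] < 0:
            raise SchemaError(
                f"{path}: row {idx}, column concentration_mmol_L: "
                f"{row['concentration_mmol_L']!r}"
            )
    dup = df.duplicated(subset=["patient_id", "modality", "series", "time_h"])
    if dup.any():
        raise SchemaError(f"{path}: duplicate sample at row {int(np.flatnonzero(dup)[0])}")

    constants = read_constants(constants_path) if constants_path else {}
    sets: dict[str, MeasurementSet] = {}
    for pid, group in df.groupby("patient_id", sort=True):
        pid = str(pid)
        kwargs: dict = {"patient_id": pid}
        sp = group[group["modality"] == "SP"].sort_values("time_h")
        if len(sp):
            kwargs["t_sp"] = sp["time_h"].to_numpy(float)
            kwargs["z"] = sp["concentration_mmol_L"].to_numpy(float)
        mp = group[group["modality"] == "MP"]
        if len(mp):
            blood = mp[mp["series"] == "blood"].sort_values("time_h")
            dial = mp[mp["series"] == "dialysate"].sort_values("time_h")
            if not np.array_equal(
                blood["time_h"].to_numpy(float), dial["time_h"].to_numpy(float)
            ):
                raise SchemaError(
                    f"{path}: patient {pid}: MP blood and dialysate series "
                    "must share one time grid"
                )
            kwargs["t_mp"] = blood["time_h"].to_numpy(float)
            kwargs["x"] = blood["concentration_mmol_L"].to_numpy(float)
            kwargs["y"] = dial["concentration_mmol_L"].to_numpy(float)
        if pid in constants:
            kwargs.update(
                Cd0=constants[pid]["Cd0"],
                Vd0=constants[pid]["Vd0"],
                Vb0_clinical=constants[pid]["Vb0"],
            )
        try:
            sets[pid] = MeasurementSet(**kwargs)
        except ValueError as err:
            raise SchemaError(f"{path}: patient {pid}: {err}") from err
    return sets


def _measurement_rows(ms: MeasurementSet) -> list[dict]:
    rows = []
    if ms.t_sp is not None:
        for t, c in zip(ms.t_sp, ms.z):
            rows.append(
                dict(patient_id=ms.patient_id, modality="SP", series="blood",
                     time_h=t, concentration_mmol_L=c)
            )
    if ms.t_mp is not None:
        for series, values in (("blood", ms.x), ("dialysate", ms.y)):
            for t, c in zip(ms.t_mp, values):
                rows.append(
                    dict(patient_id=ms.patient_id, modality="MP", series=series,
                         time_h=t, concentration_mmol_L=c)
                )
    return rows


def write_measurements(sets, path) -> None:
    """Write measurement sets (iterable or mapping) to the CSV schema."""
    if isinstance(sets, dict):
        sets = sets.values()
    rows = [row for ms in sets for row in _measurement_rows(ms)]
    pd.DataFrame(rows, columns=MEASUREMENT_COLUMNS).to_csv(path, index=False)


def write_constants(sets, path) -> None:
    if isinstance(sets, dict):
        sets = sets.values()
    rows = [
        dict(patient_id=ms.patient_id, Cd0_mmol_L=ms.Cd0, Vd0_L=ms.Vd0,
             Vb0_L=ms.Vb0_clinical)
        for ms in sets
    ]
    pd.DataFrame(rows, columns=CONSTANTS_COLUMNS).to_csv(path, index=False)


def write_truth(cohort: list[tuple[MPParameters, MeasurementSet]], path) -> None:
    """Truth table for a synthetic cohort: patient id + generating parameters."""
    rows = [
        dict(patient_id=ms.patient_id, Ks_L_h=p.Ks, Kb_L_h=p.Kb, Q_L_h=p.Q,
             Cs_mmol_L=p.Cs, Cd0_mmol_L=p.Cd0, Vb0_L=p.Vb0, Vd0_L=p.Vd0,
             x0_mmol_L=p.x0, y0_mmol_L=p.y0)
        for p, ms in cohort
    ]
    pd.DataFrame(rows).to_csv(path, index=False)


def ensure_parent(path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
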