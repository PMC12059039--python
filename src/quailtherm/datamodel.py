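"""Study data model, tabular I/O, and morphometric calibration adjustment.

The canonical on-disk layout is a directory of three UTF-8 CSV files with
header rows and "." decimal separators:

``individuals.csv``
    ``id, batch, rearing, sex`` — one row per bird.  ``batch`` is the egg
    batch (1..3), ``rearing`` the developmental temperature treatment
    (``cold`` = 10 degC, ``mild`` = 20 degC, ``warm`` = 30 degC).
``morphometry.csv``
    ``id, age_weeks, mass_g, tarsus_mm, bill_mm, calibration`` — weekly
    measurements.  ``calibration`` records how photographed lengths were
    calibrated (``grid-under`` is the reference placement).
``respirometry.csv``
    ``id, age_class, temperature_c, vo2_ml_min, ewl_ml_min, body_temp_c`` —
    one reduced measurement per bird x age class x chamber temperature.

A JSON column-mapping file (canonical name -> actual column name, per table)
lets a differently-labelled deposit be read without code changes.  Rows that
violate domain invariants are rejected, never silently dropped: every reject
carries a machine-readable reason code and its source row index.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .errors import ConfigurationError, SchemaError, ValidationError

REARING_LEVELS = ("cold", "mild", "warm")
REARING_TEMPERATURE_C = {"cold": 10.0, "mild": 20.0, "warm": 30.0}
AGE_CLASSES = ("juvenile", "adult")
MEASUREMENT_TEMPERATURES_C = (10.0, 20.0, 30.0, 40.0)

#: Reference calibration placement: lengths need no adjustment.
REFERENCE_CALIBRATION = "grid-under"

CALIBRATION_TYPES = ("grid-under", "grid-beside", "grid-over", "ruler")

# Mass recorded to the nearest 0.1 g; photographed lengths kept to 0.001 mm.
MASS_DECIMALS = 1
LENGTH_DECIMALS = 3

INDIVIDUAL_COLUMNS = ("id", "batch", "rearing", "sex")
MORPHOMETRY_COLUMNS = ("id", "age_weeks", "mass_g", "tarsus_mm", "bill_mm", "calibration")
RESPIROMETRY_COLUMNS = ("id", "age_class", "temperature_c", "vo2_ml_min", "ewl_ml_min", "body_temp_c")

FILE_NAMES = {
    "individuals": "individuals.csv",
    "morphometry": "morphometry.csv",
    "respirometry": "respirometry.csv",
}


@dataclass(frozen=True)
class Individual:
    id: str
    batch: int
    rearing: str
    sex: str | None = None

    def __post_init__(self) -> None:
        if self.rearing not in REARING_LEVELS:
            raise ValidationError(f"unknown rearing treatment {self.rearing!r}")


@dataclass(frozen=True)
class MorphometryRecord:
    id: str
    age_weeks: int
    mass_g: float
    tarsus_mm: float | None = None
    bill_mm: float | None = None
    calibration: str = REFERENCE_CALIBRATION


@dataclass(frozen=True)
class RespirometryRecord:
    id: str
    age_class: str
    temperature_c: float
    vo2_ml_min: float
    ewl_ml_min: float | None = None
    body_temp_c: float | None = None


@dataclass(frozen=True)
class RejectedRow:
    table: str
    row_index: int
    reason: str


@dataclass(frozen=True)
class CalibrationOffsets:
    """Additive length offsets (mm) per (trait, calibration placement).

    The deposited offsets are the posterior mean calibration-type effects of
    a categorical-age model of photographed lengths; the reference placement
    (grid under the appendage) has offset 0 by definition.  Offsets are
    treated as fixed constants: re-estimating them would need the raw image
    subsample.
    """

    offsets: Mapping[tuple[str, str], float] = field(
        default_factory=lambda: dict(DEFAULT_CALIBRATION_OFFSETS)
    )

    def offset(self, trait: str, calibration: str) -> float:
        if calibration == REFERENCE_CALIBRATION:
            return 0.0
        try:
            return self.offsets[(trait, calibration)]
        except KeyError:
            raise ConfigurationError(
                f"no calibration offset for trait={trait!r}, calibration={calibration!r}"
            ) from None


#: Posterior-mean calibration-type effects (mm) for non-reference placements.
DEFAULT_CALIBRATION_OFFSETS: dict[tuple[str, str], float] = {
    ("bill", "grid-beside"): 2.099,
    ("bill", "ruler"): 3.079,
    ("tarsus", "grid-over"): 3.260,
    ("tarsus", "ruler"): 2.406,
}


def calibration_adjust(
    record: MorphometryRecord, offsets: CalibrationOffsets | None = None
) -> MorphometryRecord:
    """Subtract the calibration-placement effect from photographed lengths.

    Lengths measured against the reference placement are returned unchanged.
    Raises :class:`ConfigurationError` when the record's calibration type has
    no offset entry for a present trait.
    """
    offsets = offsets or CalibrationOffsets()
    if record.calibration == REFERENCE_CALIBRATION:
        return record
    if record.calibration not in CALIBRATION_TYPES:
        raise ConfigurationError(f"unknown calibration type {record.calibration!r}")
    updates: dict[str, float] = {}
    for trait, column in (("tarsus", "tarsus_mm"), ("bill", "bill_mm")):
        value = getattr(record, column)
        if value is not None and not (isinstance(value, float) and np.isnan(value)):
            adjusted = value - offsets.offset(trait, record.calibration)
            updates[column] = round(adjusted, LENGTH_DECIMALS)
    if not updates:
        return record
    return dataclasses.replace(record, **updates)


@dataclass
class StudyData:
    """The three canonical tables plus the reject log of the read that built them."""

    individuals: pd.DataFrame
    morphometry: pd.DataFrame
    respirometry: pd.DataFrame
    rejects: list[RejectedRow] = field(default_factory=list)

    def individual_records(self) -> list[Individual]:
        return [
            Individual(str(r.id), int(r.batch), str(r.rearing), _none_if_na(r.sex))
            for r in self.individuals.itertuples(index=False)
        ]

    def morphometry_records(self) -> list[MorphometryRecord]:
        return [
            MorphometryRecord(
                str(r.id),
                int(r.age_weeks),
                float(r.mass_g),
                _none_if_na(r.tarsus_mm),
                _none_if_na(r.bill_mm),
                str(r.calibration),
            )
            for r in self.morphometry.itertuples(index=False)
        ]

    def respirometry_records(self) -> list[RespirometryRecord]:
        return [
            RespirometryRecord(
                str(r.id),
                str(r.age_class),
                float(r.temperature_c),
                float(r.vo2_ml_min),
                _none_if_na(r.ewl_ml_min),
                _none_if_na(r.body_temp_c),
            )
            for r in self.respirometry.itertuples(index=False)
        ]

    def adjust_calibration(self, offsets: CalibrationOffsets | None = None) -> "StudyData":
        """Return a copy with calibration-placement effects removed from lengths."""
        offsets = offsets or CalibrationOffsets()
        morph = self.morphometry.copy()
        for trait, column in (("tarsus", "tarsus_mm"), ("bill", "bill_mm")):
            for calib in morph["calibration"].dropna().unique():
                if calib == REFERENCE_CALIBRATION:
                    continue
                # Placements were trait-specific (e.g. grid-beside occurs only
                # for bill photographs); combinations without an estimated
                # offset are left unchanged.
                offset = offsets.offsets.get((trait, str(calib)))
                if offset is None:
                    continue
                mask = (morph["calibration"] == calib) & morph[column].notna()
                if mask.any():
                    morph.loc[mask, column] = (
                        morph.loc[mask, column] - offset
                    ).round(LENGTH_DECIMALS)
        return StudyData(self.individuals.copy(), morph, self.respirometry.copy(), list(self.rejects))


def _none_if_na(value):
    if value is None:
        return None
    if isinstance(value, float) and np.isnan(value):
        return None
    if pd.isna(value):
        return None
    return value if not isinstance(value, (int, float, np.floating)) else float(value)


def _load_column_map(column_map: str | Path | Mapping | None) -> dict:
    if column_map is None:
        return {}
    if isinstance(column_map, (str, Path)):
        with open(column_map, encoding="utf-8") as fh:
            return json.load(fh)
    return dict(column_map)


def _read_table(
    path: Path, table: str, required: Iterable[str], column_map: Mapping
) -> pd.DataFrame:
    if not path.exists():
        raise SchemaError(f"missing table file: {path}")
    frame = pd.read_csv(path)
    mapping = column_map.get(table, {})
    if mapping:
        frame = frame.rename(columns={v: k for k, v in mapping.items()})
    missing = [c for c in required if c not in frame.columns]
    if missing:
        raise SchemaError(f"{table} table missing columns {missing} in {path}")
    return frame


def _coerce_numeric(frame, column, table, rejects, keep):
    values = pd.to_numeric(frame[column], errors="coerce")
    bad = values.isna() & frame[column].notna()
    for idx in frame.index[bad]:
        rejects.append(RejectedRow(table, int(idx), f"non_numeric:{column}"))
    keep &= ~bad
    frame[column] = values
    return keep


def read_dataset(
    path: str | Path,
    column_map: str | Path | Mapping | None = None,
) -> StudyData:
    """Read a study directory into typed, validated canonical tables.

    Invalid rows are dropped and logged on ``StudyData.rejects`` with a
    reason code; a missing column or file raises :class:`SchemaError`.
    """
    path = Path(path)
    cmap = _load_column_map(column_map)
    rejects: list[RejectedRow] = []

    ind = _read_table(path / FILE_NAMES["individuals"], "individuals", ("id", "batch", "rearing"), cmap)
    if "sex" not in ind.columns:
        ind["sex"] = pd.NA
    keep = pd.Series(True, index=ind.index)
    keep = _coerce_numeric(ind, "batch", "individuals", rejects, keep)
    for idx, row in ind.iterrows():
        if not keep[idx]:
            continue
        if pd.isna(row["id"]) or str(row["id"]) == "":
            rejects.append(RejectedRow("individuals", int(idx), "missing_id"))
            keep[idx] = False
        elif pd.isna(row["batch"]):
            rejects.append(RejectedRow("individuals", int(idx), "missing_batch"))
            keep[idx] = False
        elif row["rearing"] not in REARING_LEVELS:
            rejects.append(RejectedRow("individuals", int(idx), "unknown_rearing"))
            keep[idx] = False
    ind = ind.loc[keep, list(INDIVIDUAL_COLUMNS)].reset_index(drop=True)
    dup = ind["id"].astype(str).duplicated()
    for idx in ind.index[dup]:
        rejects.append(RejectedRow("individuals", int(idx), "duplicate_id"))
    ind = ind.loc[~dup].reset_index(drop=True)
    ind["id"] = ind["id"].astype(str)
    ind["batch"] = ind["batch"].astype(int)

    morph = _read_table(
        path / FILE_NAMES["morphometry"], "morphometry", ("id", "age_weeks", "mass_g"), cmap
    )
    for optional in ("tarsus_mm", "bill_mm"):
        if optional not in morph.columns:
            morph[optional] = np.nan
    if "calibration" not in morph.columns:
        morph["calibration"] = REFERENCE_CALIBRATION
    keep = pd.Series(True, index=morph.index)
    for column in ("age_weeks", "mass_g", "tarsus_mm", "bill_mm"):
        keep = _coerce_numeric(morph, column, "morphometry", rejects, keep)
    for idx, row in morph.iterrows():
        if not keep[idx]:
            continue
        if pd.isna(row["mass_g"]) or row["mass_g"] <= 0:
            rejects.append(RejectedRow("morphometry", int(idx), "nonpositive_mass"))
            keep[idx] = False
        elif pd.isna(row["age_weeks"]) or row["age_weeks"] < 0:
            rejects.append(RejectedRow("morphometry", int(idx), "negative_age"))
            keep[idx] = False
        elif any(
            pd.notna(row[c]) and row[c] <= 0 for c in ("tarsus_mm", "bill_mm")
        ):
            rejects.append(RejectedRow("morphometry", int(idx), "nonpositive_length"))
            keep[idx] = False
        elif pd.notna(row["calibration"]) and row["calibration"] not in CALIBRATION_TYPES:
            rejects.append(RejectedRow("morphometry", int(idx), "unknown_calibration"))
            keep[idx] = False
    morph = morph.loc[keep, list(MORPHOMETRY_COLUMNS)].reset_index(drop=True)
    morph["id"] = morph["id"].astype(str)
    morph["age_weeks"] = morph["age_weeks"].astype(int)
    morph["calibration"] = morph["calibration"].fillna(REFERENCE_CALIBRATION)

    resp = _read_table(
        path / FILE_NAMES["respirometry"],
        "respirometry",
        ("id", "age_class", "temperature_c", "vo2_ml_min"),
        cmap,
    )
    for optional in ("ewl_ml_min", "body_temp_c"):
        if optional not in resp.columns:
            resp[optional] = np.nan
    keep = pd.Series(True, index=resp.index)
    for column in ("temperature_c", "vo2_ml_min", "ewl_ml_min", "body_temp_c"):
        keep = _coerce_numeric(resp, column, "respirometry", rejects, keep)
    for idx, row in resp.iterrows():
        if not keep[idx]:
            continue
        if row["age_class"] not in AGE_CLASSES:
            rejects.append(RejectedRow("respirometry", int(idx), "unknown_age_class"))
            keep[idx] = False
        elif pd.isna(row["vo2_ml_min"]) or row["vo2_ml_min"] <= 0:
            rejects.append(RejectedRow("respirometry", int(idx), "nonpositive_vo2"))
            keep[idx] = False
        elif pd.isna(row["temperature_c"]):
            rejects.append(RejectedRow("respirometry", int(idx), "missing_temperature"))
            keep[idx] = False
    resp = resp.loc[keep, list(RESPIROMETRY_COLUMNS)].reset_index(drop=True)
    dup = resp.duplicated(subset=["id", "age_class", "temperature_c"])
    for idx in resp.index[dup]:
        rejects.append(RejectedRow("respirometry", int(idx), "duplicate_measurement_key"))
    resp = resp.loc[~dup].reset_index(drop=True)
    resp["id"] = resp["id"].astype(str)

    return StudyData(ind, morph, resp, rejects)


def write_dataset(data: StudyData, path: str | Path) -> None:
    """Write canonical CSVs, rounding to the stated storage precision."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    ind = data.individuals.loc[:, list(INDIVIDUAL_COLUMNS)]
    ind.to_csv(path / FILE_NAMES["individuals"], index=False)

    morph = data.morphometry.loc[:, list(MORPHOMETRY_COLUMNS)].copy()
    morph["mass_g"] = morph["mass_g"].round(MASS_DECIMALS)
    for column in ("tarsus_mm", "bill_mm"):
        morph[column] = morph[column].round(LENGTH_DECIMALS)
    morph.to_csv(path / FILE_NAMES["morphometry"], index=False)

    resp = data.respirometry.loc[:, list(RESPIROMETRY_COLUMNS)].copy()
    resp.to_csv(path / FILE_NAMES["respirometry"], index=False)
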