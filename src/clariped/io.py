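"""CSV readers/writers and the frozen encounter-file schema.

All files are plain UTF-8 CSV with deterministic column order, so that
``write_*`` followed by the matching reader round-trips the data model.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from pydantic import ValidationError

from .agreement import KappaResult, RaterMatrix
from .classify import RowError, TriageResult
from .discriminators import DiscriminatorCatalog, Encounter
from .errors import SchemaError
from .levels import LEVELS_ASCENDING, UrgencyLevel
from .synthetic import LabeledEncounter
from .validity import RESOURCE_BINS, ContingencyTable

__all__ = [
    "ENCOUNTER_COLUMNS",
    "REQUIRED_COLUMNS",
    "read_encounters",
    "write_encounters",
    "write_results",
    "read_results",
    "write_labels",
    "read_ratings",
    "write_kappa",
    "read_binned_table",
    "write_table",
]

#: Column order of the encounter CSV dialect.  Ages are in days, rates in
#: events/min, temperatures in Celsius, CBG in mg/dL, BP in mmHg;
#: `findings` is a semicolon-separated list of vocabulary codes.
ENCOUNTER_COLUMNS: tuple[str, ...] = (
    "id",
    "age_days",
    "rr",
    "hr",
    "spo2",
    "axtemp_c",
    "pain_level",
    "general_appearance",
    "fever_report_max_c",
    "returns_24h",
    "returns_72h",
    "findings",
    "cbg_mg_dl",
    "bp_systolic",
    "bp_diastolic",
    "injury_age_hours",
    "burn_category",
    "resource_count",
)

REQUIRED_COLUMNS: tuple[str, ...] = ("age_days",)

_INT_COLUMNS = {"age_days", "pain_level", "returns_24h", "returns_72h", "resource_count"}
_FLOAT_COLUMNS = {
    "rr",
    "hr",
    "spo2",
    "axtemp_c",
    "fever_report_max_c",
    "cbg_mg_dl",
    "bp_systolic",
    "bp_diastolic",
    "injury_age_hours",
}


def _parse_cell(column: str, raw: str):
    raw = raw.strip()
    if raw == "":
        return None
    if column in _INT_COLUMNS:
        return int(float(raw))
    if column in _FLOAT_COLUMNS:
        return float(raw)
    return raw


def read_encounters(
    path, catalog: Optional[DiscriminatorCatalog] = None
) -> tuple[list[Encounter], list[RowError]]:
    """Parse an encounter CSV; invalid rows are reported, not fatal.

    A missing required column is a fatal :class:`SchemaError`.  When a
    catalog is supplied, finding codes are validated against its
    vocabulary and rows with unknown codes are rejected by name.
    """
    encounters: list[Encounter] = []
    errors: list[RowError] = []
    with open(path, "r", encoding="utf-8", newline="") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None:
            raise SchemaError(f"{path}: missing header row")
        missing = [c for c in REQUIRED_COLUMNS if c not in reader.fieldnames]
        if missing:
            raise SchemaError(f"{path}: missing required columns {missing}")
        unknown_cols = [c for c in reader.fieldnames if c not in ENCOUNTER_COLUMNS]
        if unknown_cols:
            raise SchemaError(f"{path}: unknown columns {unknown_cols}")
        for i, row in enumerate(reader):
            rid = row.get("id") or None
            try:
                data = {c: _parse_cell(c, v or "") for c, v in row.items()}
                data = {c: v for c, v in data.items() if v is not None}
                data.setdefault("returns_24h", 0)
                data.setdefault("returns_72h", 0)
                enc = Encounter(**data)
                if catalog is not None:
                    bad = enc.findings - catalog.vocabulary
                    if bad:
                        raise ValueError(f"unknown finding codes: {sorted(bad)}")
                encounters.append(enc)
            except (ValueError, ValidationError) as exc:
                errors.append(RowError(index=i, encounter_id=rid, message=_short_reason(exc)))
    return encounters, errors


def _short_reason(exc: Exception) -> str:
    if isinstance(exc, ValidationError):
        parts = [
            f"{'.'.join(str(p) for p in err['loc'])}: {err['msg']}" for err in exc.errors()
        ]
        return "; ".join(parts)
    return str(exc)


def _fmt(v) -> str:
    if v is None:
        return ""
    if isinstance(v, frozenset):
        return ";".join(sorted(v))
    if isinstance(v, UrgencyLevel):
        return v.name
    if isinstance(v, bool):
        return str(int(v))
    if isinstance(v, float) and v.is_integer():
        return str(int(v))
    if hasattr(v, "value"):  # str enums
        return str(v.value)
    return str(v)


def write_encounters(path, encounters: Iterable[Encounter]) -> None:
    with open(path, "w", encoding="utf-8", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(ENCOUNTER_COLUMNS)
        for enc in encounters:
            writer.writerow([_fmt(getattr(enc, c)) for c in ENCOUNTER_COLUMNS])


RESULT_COLUMNS: tuple[str, ...] = (
    "id",
    "vipe_total",
    "vipe_color",
    "final_level",
    "max_wait_minutes",
    "destination",
    "triggered_codes",
    "fast_path",
)


def write_results(path, results: Iterable[TriageResult]) -> None:
    with open(path, "w", encoding="utf-8", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(RESULT_COLUMNS)
        for r in results:
            writer.writerow(
                [
                    _fmt(r.encounter_id),
                    r.vipe.total,
                    r.vipe.color.name,
                    r.final_level.name,
                    r.max_wait_minutes,
                    r.destination,
                    ";".join(r.triggered_codes),
                    int(r.fast_path),
                ]
            )


def read_results(path) -> list[dict]:
    with open(path, "r", encoding="utf-8", newline="") as fh:
        return list(csv.DictReader(fh))


def write_errors(path, errors: Iterable[RowError]) -> None:
    with open(path, "w", encoding="utf-8", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["row_index", "id", "reason"])
        for e in errors:
            writer.writerow([e.index, _fmt(e.encounter_id), e.message])


def write_labels(path, labeled: Iterable[LabeledEncounter]) -> None:
    with open(path, "w", encoding="utf-8", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["id", "intended_level", "resource_bin"])
        for rec in labeled:
            writer.writerow([_fmt(rec.encounter.id), rec.intended_level.name, rec.resource_bin])


# ---------------------------------------------------------------------
# Rater matrices

_COUNT_HEADER = tuple(f"n_{lv.name.lower()}" for lv in LEVELS_ASCENDING)


def read_ratings(path) -> RaterMatrix:
    """Read a rater matrix CSV, auto-detecting its form from the header.

    Count form: ``case, n_blue, n_green, n_yellow, n_orange, n_red``.
    Long form: ``case, rater, category`` (one row per rating).
    """
    df = pd.read_csv(path)
    cols = [c.strip().lower() for c in df.columns]
    df.columns = cols
    if set(_COUNT_HEADER) <= set(cols):
        counts = df[list(_COUNT_HEADER)].to_numpy(dtype=np.int64)
    elif {"case", "rater", "category"} <= set(cols):
        df["category"] = df["category"].map(lambda s: UrgencyLevel.from_name(str(s)).name)
        pivot = (
            df.pivot_table(index="case", columns="category", values="rater", aggfunc="count")
            .reindex(columns=[lv.name for lv in LEVELS_ASCENDING])
            .fillna(0)
        )
        counts = pivot.to_numpy(dtype=np.int64)
    else:
        raise SchemaError(
            f"{path}: header must be either {('case',) + _COUNT_HEADER} or (case, rater, category)"
        )
    return RaterMatrix(counts=counts, categories=tuple(lv.name for lv in LEVELS_ASCENDING))


def write_ratings(path, ratings: RaterMatrix) -> None:
    with open(path, "w", encoding="utf-8", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(("case",) + _COUNT_HEADER)
        for i, row in enumerate(ratings.counts):
            writer.writerow([i + 1, *row.tolist()])


def write_kappa(path, result: KappaResult) -> None:
    payload = {
        "overall": result.overall,
        "per_category": dict(result.per_category),
        "se_overall": result.se_overall,
        "z": result.z,
        "p_value": result.p_value,
    }
    Path(path).write_text(json.dumps(payload, indent=2) + "\n", encoding="utf-8")


# ---------------------------------------------------------------------
# Contingency tables

_BIN_HEADER = ("res_0", "res_1", "res_2", "res_3plus")


def read_binned_table(path) -> ContingencyTable:
    """Read pre-binned counts: ``level, res_0, res_1, res_2, res_3plus``.

    An optional row with level ``MISSING`` carries the missing-record
    count in ``res_0``.
    """
    counts = np.zeros((len(LEVELS_ASCENDING), 4), dtype=np.int64)
    missing = 0
    with open(path, "r", encoding="utf-8", newline="") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None or not set(("level",) + _BIN_HEADER) <= set(reader.fieldnames):
            raise SchemaError(f"{path}: expected columns {('level',) + _BIN_HEADER}")
        for row in reader:
            name = row["level"].strip().upper()
            values = [int(row[c] or 0) for c in _BIN_HEADER]
            if name == "MISSING":
                missing = values[0]
            else:
                counts[int(UrgencyLevel.from_name(name))] = values
    return ContingencyTable(
        row_labels=tuple(lv.name for lv in LEVELS_ASCENDING),
        col_labels=RESOURCE_BINS,
        counts=counts,
        missing_count=missing,
    )


def write_table(path, table: ContingencyTable) -> None:
    with open(path, "w", encoding="utf-8", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(("level",) + _BIN_HEADER)
        for label, row in zip(table.row_labels, table.counts):
            writer.writerow([label, *row.tolist()])
        if table.missing_count:
            writer.writerow(["MISSING", table.missing_count, 0, 0, 0])
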