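"""Delimited-text readers and writers for claims tables.

Files are comma- or tab-separated (auto-detected from the extension: ``.tsv``
or ``.tab`` means tab, anything else comma) with a header row and ISO-8601
dates.  Because claims exports rarely share a layout, readers accept a
column-mapping ``schema`` from canonical field names to the file's column
names.  Rows violating record invariants are rejected with 1-based data-row
indices; duplicate rows are kept unless ``deduplicate=True`` (repeat claims
are legitimate).
"""

from __future__ import annotations

from datetime import date
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .records import ClinicalEventRecord, EventKind, PrescriptionRecord, Route

PRESCRIPTION_FIELDS = (
    "patient_id",
    "drug_code",
    "ingredient",
    "route",
    "dispense_date",
    "days_supplied",
    "daily_dose",
)
EVENT_FIELDS = ("patient_id", "code", "event_date", "kind")


class SchemaError(ValueError):
    """A required column is absent from the file."""


class RowParseError(ValueError):
    """One or more data rows could not be converted to valid records."""

    def __init__(self, row_errors: Sequence[tuple[int, str]]):
        self.row_errors = list(row_errors)
        lines = "; ".join(f"row {i}: {msg}" for i, msg in self.row_errors)
        super().__init__(f"{len(self.row_errors)} invalid row(s): {lines}")


def _sep_for(path: str | Path) -> str:
    return "\t" if str(path).lower().endswith((".tsv", ".tab")) else ","


def _load_table(path: str | Path, fields: Sequence[str], schema: Mapping[str, str] | None) -> pd.DataFrame:
    schema = dict(schema or {})
    colmap = {f: schema.get(f, f) for f in fields}
    df = pd.read_csv(path, sep=_sep_for(path), dtype=str, keep_default_na=False)
    missing = [c for c in colmap.values() if c not in df.columns]
    if missing:
        raise SchemaError(f"missing column(s) {missing} in {path}")
    out = df[[colmap[f] for f in fields]].copy()
    out.columns = list(fields)
    return out


def _parse_date(text: str) -> date:
    return date.fromisoformat(text.strip())


def read_prescriptions(
    path: str | Path,
    schema: Mapping[str, str] | None = None,
    deduplicate: bool = False,
) -> list[PrescriptionRecord]:
    """Read a prescription table; row order is preserved.

    Raises :class:`SchemaError` if a mapped column is missing and
    :class:`RowParseError` collecting every bad row (1-based data rows).
    """
    df = _load_table(path, PRESCRIPTION_FIELDS, schema)
    records: list[PrescriptionRecord] = []
    errors: list[tuple[int, str]] = []
    for i, row in enumerate(df.itertuples(index=False), start=1):
        try:
            records.append(
                PrescriptionRecord(
                    patient_id=row.patient_id,
                    drug_code=row.drug_code,
                    ingredient=row.ingredient,
                    route=Route(row.route),
                    dispense_date=_parse_date(row.dispense_date),
                    days_supplied=int(row.days_supplied),
                    daily_dose=float(row.daily_dose),
                )
            )
        except (ValueError, TypeError) as exc:
            errors.append((i, str(exc)))
    if errors:
        raise RowParseError(errors)
    if deduplicate:
        records = list(dict.fromkeys(records))
    return records


def read_clinical_events(
    path: str | Path,
    schema: Mapping[str, str] | None = None,
    deduplicate: bool = False,
) -> list[ClinicalEventRecord]:
    df = _load_table(path, EVENT_FIELDS, schema)
    records: list[ClinicalEventRecord] = []
    errors: list[tuple[int, str]] = []
    for i, row in enumerate(df.itertuples(index=False), start=1):
        try:
            records.append(
                ClinicalEventRecord(
                    patient_id=row.patient_id,
                    code=row.code,
                    event_date=_parse_date(row.event_date),
                    kind=EventKind(row.kind),
                )
            )
        except (ValueError, TypeError) as exc:
            errors.append((i, str(exc)))
    if errors:
        raise RowParseError(errors)
    if deduplicate:
        records = list(dict.fromkeys(records))
    return records


def prescriptions_to_frame(records: Iterable[PrescriptionRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "patient_id": r.patient_id,
                "drug_code": r.drug_code,
                "ingredient": r.ingredient,
                "route": r.route.value,
                "dispense_date": r.dispense_date.isoformat(),
                "days_supplied": r.days_supplied,
                "daily_dose": r.daily_dose,
            }
            for r in records
        ],
        columns=list(PRESCRIPTION_FIELDS),
    )


def events_to_frame(records: Iterable[ClinicalEventRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "patient_id": r.patient_id,
                "code": r.code,
                "event_date": r.event_date.isoformat(),
                "kind": r.kind.value,
            }
            for r in records
        ],
        columns=list(EVENT_FIELDS),
    )


def write_prescriptions(records: Iterable[PrescriptionRecord], path: str | Path) -> None:
    prescriptions_to_frame(records).to_csv(path, sep=_sep_for(path), index=False)


def write_clinical_events(records: Iterable[ClinicalEventRecord], path: str | Path) -> None:
    events_to_frame(records).to_csv(path, sep=_sep_for(path), index=False)
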