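"""Read, validate and write clinical-costing event extracts.

The extract mirrors what a hospital clinical-costing system exports: one
sheet per contact type plus a patient sheet, linked by patient and
encounter IDs.  Here each sheet is a UTF-8 CSV with a header row:

* ``patients.csv``:  ``patient_id,gender,age_at_first_contact``
* ``inpatient.csv``: ``patient_id,encounter_id,admit_dt,discharge_dt``
* ``outpatient.csv``: ``patient_id,encounter_id,start_dt``
* ``emergency.csv``: ``patient_id,encounter_id,start_dt,end_dt``

Timestamps are timezone-naive ISO 8601 at minute precision
(``YYYY-MM-DDTHH:MM``).  Outpatient appointments carry no end time in the
raw data; a nominal duration is imputed downstream when journeys are
built.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from datetime import datetime
from pathlib import Path
from typing import Optional

import pandas as pd

logger = logging.getLogger(__name__)

DATETIME_FORMAT = "%Y-%m-%dT%H:%M"

CONTACT_TYPES = ("I", "O", "E")
GENDERS = ("M", "F")

SHEET_COLUMNS = {
    "patients": ["patient_id", "gender", "age_at_first_contact"],
    "inpatient": ["patient_id", "encounter_id", "admit_dt", "discharge_dt"],
    "outpatient": ["patient_id", "encounter_id", "start_dt"],
    "emergency": ["patient_id", "encounter_id", "start_dt", "end_dt"],
}


class ExtractError(ValueError):
    """Base class for extract validation failures."""


class ExtractParseError(ExtractError):
    """A field failed to parse; names the file and row."""


class ReferentialIntegrityError(ExtractError):
    """An event references a patient_id absent from the patient sheet."""


@dataclass(frozen=True, order=True, slots=True)
class ContactEvent:
    """One timestamped contact of type I, O or E for one patient.

    ``end`` is ``None`` for outpatient appointments, whose end times are
    not recorded by the costing system.
    """

    start: datetime
    contact_type: str
    encounter_id: str
    patient_id: str
    end: Optional[datetime] = None

    def __post_init__(self) -> None:
        if self.contact_type not in CONTACT_TYPES:
            raise ExtractError(
                f"unknown contact type {self.contact_type!r} "
                f"(encounter {self.encounter_id})"
            )
        if self.contact_type == "O" and self.end is not None:
            raise ExtractError(
                f"outpatient encounter {self.encounter_id} must not carry an "
                "end time in raw form"
            )
        if self.end is not None and self.end < self.start:
            raise ExtractError(
                f"encounter {self.encounter_id}: end {self.end} precedes "
                f"start {self.start}"
            )


@dataclass(frozen=True, order=True, slots=True)
class PatientRecord:
    patient_id: str
    gender: str
    age_at_first_contact: int

    def __post_init__(self) -> None:
        if self.gender not in GENDERS:
            raise ExtractError(
                f"patient {self.patient_id}: unknown gender code "
                f"{self.gender!r}"
            )
        if self.age_at_first_contact < 0:
            raise ExtractError(
                f"patient {self.patient_id}: negative age "
                f"{self.age_at_first_contact}"
            )


@dataclass
class EventCollection:
    """A validated patient sheet plus event list.

    Events and patients are canonically ordered on construction — events by
    (start, contact type, encounter id), patients by patient id — so that a
    write/read round trip reproduces an equal collection.
    """

    patients: list[PatientRecord] = field(default_factory=list)
    events: list[ContactEvent] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.patients = sorted(self.patients, key=lambda p: p.patient_id)
        self.events = sorted(
            self.events,
            key=lambda e: (e.start, e.contact_type, e.encounter_id),
        )
        self.validate()

    def validate(self) -> None:
        ids = [p.patient_id for p in self.patients]
        known = set(ids)
        if len(ids) != len(known):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise ExtractError(f"duplicate patient_id(s): {dupes}")
        for ev in self.events:
            if ev.patient_id not in known:
                raise ReferentialIntegrityError(
                    f"event {ev.encounter_id} references unknown patient "
                    f"{ev.patient_id!r}"
                )
        for sheet_type in CONTACT_TYPES:
            encs = [
                e.encounter_id for e in self.events
                if e.contact_type == sheet_type
            ]
            if len(encs) != len(set(encs)):
                dupes = sorted({i for i in encs if encs.count(i) > 1})
                raise ExtractError(
                    f"duplicate encounter_id(s) in sheet {sheet_type}: {dupes}"
                )

    def events_of_type(self, contact_type: str) -> list[ContactEvent]:
        return [e for e in self.events if e.contact_type == contact_type]

    def events_for_patient(self, patient_id: str) -> list[ContactEvent]:
        return [e for e in self.events if e.patient_id == patient_id]

    @property
    def n_patients(self) -> int:
        return len(self.patients)

    @property
    def n_events(self) -> int:
        return len(self.events)


def _parse_dt(value: str, *, path: Path, row: int, column: str,
              fmt: str) -> datetime:
    try:
        return datetime.strptime(value, fmt)
    except (TypeError, ValueError) as exc:
        raise ExtractParseError(
            f"{path}, row {row}, column {column}: cannot parse "
            f"{value!r} with format {fmt!r}"
        ) from exc


def _read_sheet(path: Path, sheet: str) -> pd.DataFrame:
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    expected = SHEET_COLUMNS[sheet]
    missing = [c for c in expected if c not in df.columns]
    if missing:
        raise ExtractParseError(
            f"{path}: missing column(s) {missing}; expected {expected}"
        )
    return df


def read_extract(
    inpatient_path: str | Path,
    outpatient_path: str | Path,
    emergency_path: str | Path,
    patient_path: str | Path,
    datetime_format: str = DATETIME_FORMAT,
) -> EventCollection:
    """Read and validate a four-CSV extract into an :class:`EventCollection`.

    Raises :class:`ExtractParseError` for unparseable fields (naming file
    and row), :class:`ReferentialIntegrityError` for events whose
    patient_id is absent from the patient sheet, and :class:`ExtractError`
    for invariant violations (end before start, duplicate IDs).
    """
    patient_path = Path(patient_path)
    pdf = _read_sheet(patient_path, "patients")
    patients = []
    for row, rec in enumerate(pdf.itertuples(index=False), start=2):
        try:
            age = int(rec.age_at_first_contact)
        except ValueError as exc:
            raise ExtractParseError(
                f"{patient_path}, row {row}: cannot parse age "
                f"{rec.age_at_first_contact!r}"
            ) from exc
        patients.append(PatientRecord(rec.patient_id, rec.gender, age))

    events: list[ContactEvent] = []
    specs = [
        (Path(inpatient_path), "inpatient", "I", "admit_dt", "discharge_dt"),
        (Path(outpatient_path), "outpatient", "O", "start_dt", None),
        (Path(emergency_path), "emergency", "E", "start_dt", "end_dt"),
    ]
    for path, sheet, ctype, start_col, end_col in specs:
        df = _read_sheet(path, sheet)
        for row, rec in enumerate(df.itertuples(index=False), start=2):
            start = _parse_dt(getattr(rec, start_col), path=path, row=row,
                              column=start_col, fmt=datetime_format)
            end = None
            if end_col is not None:
                end = _parse_dt(getattr(rec, end_col), path=path, row=row,
                                column=end_col, fmt=datetime_format)
            events.append(ContactEvent(
                start=start, contact_type=ctype,
                encounter_id=rec.encounter_id, patient_id=rec.patient_id,
                end=end,
            ))
        logger.info(
            "%s: %d rows, %d distinct patients", path, len(df),
            df["patient_id"].nunique(),
        )

    return EventCollection(patients=patients, events=events)


def write_extract(collection: EventCollection,
                  out_dir: str | Path) -> dict[str, Path]:
    """Write the four-CSV extract; inverse of :func:`read_extract`.

    Returns the sheet-name -> path mapping.  Emits header-only files for
    empty sheets so the extract is always complete.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    fmt = DATETIME_FORMAT

    paths = {name: out_dir / f"{name}.csv" for name in SHEET_COLUMNS}

    pd.DataFrame(
        [(p.patient_id, p.gender, p.age_at_first_contact)
         for p in collection.patients],
        columns=SHEET_COLUMNS["patients"],
    ).to_csv(paths["patients"], index=False)

    def rows(ctype: str, with_end: bool) -> list[tuple]:
        out = []
        for e in collection.events_of_type(ctype):
            base = (e.patient_id, e.encounter_id, e.start.strftime(fmt))
            if with_end:
                base += (e.end.strftime(fmt),)
            out.append(base)
        return out

    pd.DataFrame(rows("I", True), columns=SHEET_COLUMNS["inpatient"]
                 ).to_csv(paths["inpatient"], index=False)
    pd.DataFrame(rows("O", False), columns=SHEET_COLUMNS["outpatient"]
                 ).to_csv(paths["outpatient"], index=False)
    pd.DataFrame(rows("E", True), columns=SHEET_COLUMNS["emergency"]
                 ).to_csv(paths["emergency"], index=False)
    return paths


def read_extract_dir(extract_dir: str | Path,
                     datetime_format: str = DATETIME_FORMAT
                     ) -> EventCollection:
    """Read an extract from a directory using the standard sheet names."""
    d = Path(extract_dir)
    return read_extract(
        d / "inpatient.csv", d / "outpatient.csv", d / "emergency.csv",
        d / "patients.csv", datetime_format=datetime_format,
    )
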