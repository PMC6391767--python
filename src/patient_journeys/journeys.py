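"""Build per-patient journeys from raw contact events.

A journey is the time-ordered sequence of a patient's contacts.  Each
step carries the contact's duration and the gap to the next contact —
the sojourn in the no-contact state N.  Outpatient appointments have no
recorded end time, so they are given a configurable nominal duration
(default one hour) which also keeps the N state from silently absorbing
outpatient time.  The gap after a patient's final contact is censored
(no observed endpoint) and is excluded from all waiting-time statistics.

Patients are stratified by gender and by age at first recorded contact
(Young below the cutoff, default 65; Old at or above it), giving the
four groups MY, MO, FY, FO; AP denotes the pool of all patients.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from datetime import datetime, timedelta
from typing import Optional, Sequence, Union

import pandas as pd

from .events_io import ContactEvent, EventCollection, ExtractError, \
    PatientRecord

logger = logging.getLogger(__name__)

DAY = timedelta(days=1)

#: Default nominal outpatient duration: one hour, in days.
DEFAULT_OUTPATIENT_DURATION_DAYS = 1.0 / 24.0

DEFAULT_AGE_CUTOFF_YEARS = 65

#: At identical start times, emergency presentations sort before the
#: inpatient admissions they typically trigger, which sort before
#: outpatient appointments.
DEFAULT_TIE_BREAK = ("E", "I", "O")


@dataclass(frozen=True)
class JourneyConfig:
    outpatient_duration_days: float = DEFAULT_OUTPATIENT_DURATION_DAYS
    age_cutoff_years: int = DEFAULT_AGE_CUTOFF_YEARS
    tie_break: tuple[str, ...] = DEFAULT_TIE_BREAK


@dataclass(frozen=True)
class GroupLabel:
    """An age x gender stratum, rendered as MY/MO/FY/FO."""

    gender: str  # M | F
    age_class: str  # Y | O

    def __post_init__(self) -> None:
        if self.gender not in ("M", "F"):
            raise ExtractError(f"unknown gender code {self.gender!r}")
        if self.age_class not in ("Y", "O"):
            raise ValueError(f"unknown age class {self.age_class!r}")

    @property
    def label(self) -> str:
        return self.gender + self.age_class

    def __str__(self) -> str:
        return self.label

    @classmethod
    def parse(cls, label: str) -> "GroupLabel":
        return cls(gender=label[0], age_class=label[1])


@dataclass
class JourneyStep:
    """One contact plus the no-contact gap that follows it.

    ``gap_after_days`` is ``None`` when censored, i.e. for the patient's
    last observed contact.
    """

    contact_type: str
    start: datetime
    end: datetime
    duration_days: float
    gap_after_days: Optional[float] = None


@dataclass
class PatientJourney:
    patient_id: str
    group: GroupLabel
    steps: list[JourneyStep] = field(default_factory=list)

    @property
    def n_steps(self) -> int:
        return len(self.steps)

    @property
    def types(self) -> list[str]:
        return [s.contact_type for s in self.steps]

    @property
    def transitions(self) -> list[tuple[str, str]]:
        """Consecutive (previous, next) contact-type pairs."""
        t = self.types
        return list(zip(t[:-1], t[1:]))


def assign_group(patient: PatientRecord,
                 age_cutoff: int = DEFAULT_AGE_CUTOFF_YEARS) -> GroupLabel:
    """Stratify a patient: Young below the age cutoff, Old at or above."""
    age_class = "Y" if patient.age_at_first_contact < age_cutoff else "O"
    return GroupLabel(gender=patient.gender, age_class=age_class)


def build_journey(events: Sequence[ContactEvent], patient: PatientRecord,
                  config: JourneyConfig = JourneyConfig()) -> PatientJourney:
    """Order one patient's events into a journey with durations and gaps.

    Events are sorted by start time; simultaneous events break ties by
    the configured type precedence and then encounter id.  Outpatient
    steps get the nominal duration.  Gaps are ``next.start - this.end``
    in fractional days, clamped at zero when contacts overlap (the
    transition is still recorded); the final gap is censored.
    """
    for ev in events:
        if ev.patient_id != patient.patient_id:
            raise ExtractError(
                f"event {ev.encounter_id} belongs to {ev.patient_id!r}, "
                f"not {patient.patient_id!r}"
            )
    group = assign_group(patient, config.age_cutoff_years)
    rank = {t: i for i, t in enumerate(config.tie_break)}
    ordered = sorted(
        events,
        key=lambda e: (e.start, rank[e.contact_type], e.encounter_id),
    )
    steps: list[JourneyStep] = []
    for ev in ordered:
        if ev.contact_type == "O":
            duration = config.outpatient_duration_days
            end = ev.start + timedelta(days=duration)
        else:
            end = ev.end if ev.end is not None else ev.start
            duration = (end - ev.start) / DAY
        steps.append(JourneyStep(
            contact_type=ev.contact_type, start=ev.start, end=end,
            duration_days=duration,
        ))
    for prev, nxt in zip(steps[:-1], steps[1:]):
        prev.gap_after_days = max(0.0, (nxt.start - prev.end) / DAY)
    return PatientJourney(patient_id=patient.patient_id, group=group,
                          steps=steps)


def build_all(collection: EventCollection,
              config: JourneyConfig = JourneyConfig()
              ) -> list[PatientJourney]:
    """One journey per patient with at least one event.

    Patients without events are excluded from the analysis (a journey of
    zero contacts carries no information for any statistic) and logged.
    """
    by_patient: dict[str, list[ContactEvent]] = {
        p.patient_id: [] for p in collection.patients
    }
    for ev in collection.events:
        by_patient[ev.patient_id].append(ev)
    journeys = []
    for patient in collection.patients:
        evs = by_patient[patient.patient_id]
        if not evs:
            logger.warning(
                "patient %s has no events; excluded from journeys",
                patient.patient_id,
            )
            continue
        journeys.append(build_journey(evs, patient, config))
    return journeys


FRAME_COLUMNS = [
    "patient_id", "group", "seq_index", "contact_type", "start", "end",
    "duration_days", "gap_after_days",
]


def journeys_to_frame(
    journeys: Union[Sequence[PatientJourney], pd.DataFrame]
) -> pd.DataFrame:
    """Long-format journey table, one row per step.

    ``gap_after_days`` is NaN for censored (final) steps.  Accepts an
    already-converted frame unchanged, so summary functions can take
    either representation.
    """
    if isinstance(journeys, pd.DataFrame):
        missing = [c for c in FRAME_COLUMNS if c not in journeys.columns]
        if missing:
            raise ValueError(f"journey frame missing column(s) {missing}")
        return journeys
    rows = []
    for j in journeys:
        for i, s in enumerate(j.steps):
            rows.append((
                j.patient_id, j.group.label, i, s.contact_type, s.start,
                s.end, s.duration_days,
                float("nan") if s.gap_after_days is None
                else s.gap_after_days,
            ))
    return pd.DataFrame(rows, columns=FRAME_COLUMNS)


def write_journeys_csv(journeys: Sequence[PatientJourney],
                       path) -> pd.DataFrame:
    """Export journeys to the long-format CSV; returns the frame."""
    frame = journeys_to_frame(journeys)
    out = frame.copy()
    from .events_io import DATETIME_FORMAT
    for col in ("start", "end"):
        out[col] = pd.to_datetime(out[col]).dt.strftime(DATETIME_FORMAT)
    out.to_csv(path, index=False)
    return frame


def read_journeys_csv(path) -> pd.DataFrame:
    """Read a long-format journey CSV back into the analysis frame."""
    frame = pd.read_csv(path)
    for col in ("start", "end"):
        frame[col] = pd.to_datetime(frame[col])
    return frame


def group_sizes(journeys: Sequence[PatientJourney]) -> dict[str, int]:
    """Patients per group among the built journeys."""
    sizes: dict[str, int] = {}
    for j in journeys:
        sizes[j.group.label] = sizes.get(j.group.label, 0) + 1
    return sizes
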