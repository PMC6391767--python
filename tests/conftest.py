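"""Shared fixtures: hand-built event collections and scaled-down cohorts."""

from __future__ import annotations

import dataclasses
from datetime import datetime, timedelta

import pytest

from patient_journeys import (
    ContactEvent,
    EventCollection,
    PatientRecord,
    default_sim_config,
)


def dt(day: float) -> datetime:
    """Fractional days after 2015-01-01 00:00, at minute precision."""
    base = datetime(2015, 1, 1)
    return (base + timedelta(days=day)).replace(second=0, microsecond=0)


@pytest.fixture
def tiny_collection() -> EventCollection:
    """Two patients, five events covering all three contact types."""
    patients = [
        PatientRecord("p1", "M", 55),
        PatientRecord("p2", "F", 72),
    ]
    events = [
        ContactEvent(start=dt(0.0), contact_type="I", encounter_id="I1",
                     patient_id="p1", end=dt(0.5)),
        ContactEvent(start=dt(2.5), contact_type="O", encounter_id="O1",
                     patient_id="p1"),
        ContactEvent(start=dt(4.0), contact_type="E", encounter_id="E1",
                     patient_id="p1", end=dt(4.1)),
        ContactEvent(start=dt(1.0), contact_type="I", encounter_id="I2",
                     patient_id="p2", end=dt(3.0)),
        ContactEvent(start=dt(5.0), contact_type="O", encounter_id="O2",
                     patient_id="p2"),
    ]
    return EventCollection(patients=patients, events=events)


def scaled_config(n_per_group: int = 10, window_days: int = 120,
                  seed: int = 0):
    """The default cohort parameterisation at reduced size."""
    cfg = default_sim_config(seed=seed)
    return dataclasses.replace(
        cfg,
        group_sizes={g: n_per_group for g in cfg.group_sizes},
        window_end=cfg.window_start + timedelta(days=window_days),
    )


@pytest.fixture
def small_config():
    return scaled_config()
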