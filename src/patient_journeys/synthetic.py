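"""Semi-Markov synthetic cohort generator with known ground truth.

The hospital event data behind the published dialysis-cohort tables are
not deposited, so every stage of the analysis is exercised against a
synthetic cohort instead.  Each patient's journey is simulated as a
semi-Markov process: the sequence of contact types (I/O/E) is a Markov
chain with a group-specific transition matrix, each contact has a
duration drawn from a per-type sojourn law, and between contacts the
patient sits in the no-contact state N for a gap drawn conditionally on
the *previous* contact type — exactly the conditioning structure the
downstream estimators assume.

The default configuration reproduces the published cohort's structure:
group sizes, per-group transition rows, per-group gap means, pooled
contact durations, and the two-year observation window.  Sojourn laws are
lognormal with coefficient of variation 1 (only means are published);
outpatient appointments have a fixed nominal duration.
"""

from __future__ import annotations

import copy
import json
from dataclasses import dataclass, field, asdict
from datetime import datetime, timedelta
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from .events_io import (
    DATETIME_FORMAT,
    ContactEvent,
    EventCollection,
    PatientRecord,
)
from .reference import (
    CONTACT_TYPES,
    GROUP_SIZES,
    GROUPS,
    WINDOW_END,
    WINDOW_START,
    contact_type_mix,
    gap_means,
    state_times,
    transition_likelihoods,
)

OUTPATIENT_DURATION_DAYS = 1.0 / 24.0

_MINUTE = timedelta(minutes=1)


class SimConfigError(ValueError):
    """Invalid simulation configuration."""


@dataclass(frozen=True)
class DistSpec:
    """A positive sojourn/gap law: lognormal(mean, sd) or a fixed constant.

    ``mean`` and ``sd`` are in days on the natural (not log) scale.
    """

    kind: str  # "lognormal" | "fixed"
    mean: float
    sd: float = 0.0

    def __post_init__(self) -> None:
        if self.kind not in ("lognormal", "fixed"):
            raise SimConfigError(f"unknown distribution kind {self.kind!r}")
        if self.mean <= 0:
            raise SimConfigError(f"distribution mean must be > 0 ({self})")
        if self.kind == "lognormal" and self.sd <= 0:
            raise SimConfigError(f"lognormal sd must be > 0 ({self})")

    def draw(self, rng: np.random.Generator) -> float:
        if self.kind == "fixed":
            return self.mean
        # convert natural-scale mean/sd to log-scale parameters
        sigma2 = np.log1p((self.sd / self.mean) ** 2)
        mu = np.log(self.mean) - sigma2 / 2.0
        return float(rng.lognormal(mean=mu, sigma=np.sqrt(sigma2)))


@dataclass
class SimConfig:
    """Full parameterisation of the synthetic cohort.

    ``transition_matrix`` and ``initial_state_probs`` are per-group nested
    dicts keyed by contact type; ``gap_model`` is per group and previous
    contact type; ``duration_model`` is per contact type.
    """

    group_sizes: dict[str, int]
    initial_state_probs: dict[str, dict[str, float]]
    transition_matrix: dict[str, dict[str, dict[str, float]]]
    duration_model: dict[str, DistSpec]
    gap_model: dict[str, dict[str, DistSpec]]
    window_start: datetime
    window_end: datetime
    seed: int = 0

    def validate(self) -> None:
        if self.window_end <= self.window_start:
            raise SimConfigError("window_end must be after window_start")
        for g, n in self.group_sizes.items():
            if g not in GROUPS:
                raise SimConfigError(f"unknown group {g!r}")
            if n < 0:
                raise SimConfigError(f"negative group size for {g}")
        for g in self.group_sizes:
            for label, dist in [("initial", self.initial_state_probs[g])] + [
                (f"transition row {prev}", row)
                for prev, row in self.transition_matrix[g].items()
            ]:
                total = sum(dist[t] for t in CONTACT_TYPES)
                if abs(total - 1.0) > 1e-12:
                    raise SimConfigError(
                        f"group {g} {label} sums to {total!r}, not 1"
                    )
                if any(dist[t] < 0 for t in CONTACT_TYPES):
                    raise SimConfigError(f"group {g} {label}: negative mass")

    def transition_frame(self, group: str) -> pd.DataFrame:
        """The group's transition matrix as a types x types DataFrame."""
        rows = self.transition_matrix[group]
        return pd.DataFrame(
            [[rows[p][n] for n in CONTACT_TYPES] for p in CONTACT_TYPES],
            index=list(CONTACT_TYPES), columns=list(CONTACT_TYPES),
        )

    # -- serialisation ----------------------------------------------------

    def to_dict(self) -> dict:
        d = asdict(self)
        d["window_start"] = self.window_start.strftime(DATETIME_FORMAT)
        d["window_end"] = self.window_end.strftime(DATETIME_FORMAT)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SimConfig":
        d = copy.deepcopy(d)
        d["window_start"] = datetime.strptime(d["window_start"],
                                              DATETIME_FORMAT)
        d["window_end"] = datetime.strptime(d["window_end"], DATETIME_FORMAT)
        d["duration_model"] = {
            t: DistSpec(**s) for t, s in d["duration_model"].items()
        }
        d["gap_model"] = {
            g: {t: DistSpec(**s) for t, s in rows.items()}
            for g, rows in d["gap_model"].items()
        }
        cfg = cls(**d)
        cfg.validate()
        return cfg

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SimConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))


@dataclass
class TrueParameters:
    """Ground truth for recovery tests: the config plus realised tallies.

    ``transition_counts[g][prev][next]`` counts the simulated type
    transitions per group; ``event_counts[g][type]`` the emitted events.
    """

    config: SimConfig
    transition_counts: dict[str, dict[str, dict[str, int]]]
    event_counts: dict[str, dict[str, int]]

    def transition_count_frame(self, group: str) -> pd.DataFrame:
        rows = self.transition_counts[group]
        return pd.DataFrame(
            [[rows[p][n] for n in CONTACT_TYPES] for p in CONTACT_TYPES],
            index=list(CONTACT_TYPES), columns=list(CONTACT_TYPES),
        )

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps({
            "config": self.config.to_dict(),
            "transition_counts": self.transition_counts,
            "event_counts": self.event_counts,
        }, indent=2, default=str))


def default_sim_config(seed: int = 0) -> SimConfig:
    """The published-cohort parameterisation.

    Group sizes, per-group transition rows and per-group mean gaps come
    from the published tables; rows are renormalised so they sum to 1 at
    machine precision.  Durations use the pooled published means; the
    initial contact type follows each group's published contact-type mix.
    """
    trans = transition_likelihoods()
    mix = contact_type_mix()
    gaps = gap_means()
    times = state_times()

    transition_matrix: dict[str, dict[str, dict[str, float]]] = {}
    initial: dict[str, dict[str, float]] = {}
    gap_model: dict[str, dict[str, DistSpec]] = {}
    for g in GROUPS:
        mat: dict[str, dict[str, float]] = {}
        for prev in CONTACT_TYPES:
            row = {n: float(trans.loc[(prev, n), g]) for n in CONTACT_TYPES}
            total = sum(row.values())
            mat[prev] = {n: p / total for n, p in row.items()}
        transition_matrix[g] = mat
        mix_g = {t: float(mix.loc[t, g]) for t in CONTACT_TYPES}
        total = sum(mix_g.values())
        initial[g] = {t: p / total for t, p in mix_g.items()}
        gap_model[g] = {
            prev: DistSpec("lognormal", mean=float(gaps.loc[prev, g]),
                           sd=float(gaps.loc[prev, g]))
            for prev in CONTACT_TYPES
        }

    duration_model = {
        "I": DistSpec("lognormal", mean=float(times.loc["I", "AP"]),
                      sd=float(times.loc["I", "AP"])),
        "O": DistSpec("fixed", mean=OUTPATIENT_DURATION_DAYS),
        "E": DistSpec("lognormal", mean=float(times.loc["E", "AP"]),
                      sd=float(times.loc["E", "AP"])),
    }

    return SimConfig(
        group_sizes=dict(GROUP_SIZES),
        initial_state_probs=initial,
        transition_matrix=transition_matrix,
        duration_model=duration_model,
        gap_model=gap_model,
        window_start=datetime.strptime(WINDOW_START, DATETIME_FORMAT),
        window_end=datetime.strptime(WINDOW_END, DATETIME_FORMAT),
        seed=seed,
    )


_AGE_RANGES = {"Y": (20, 65), "O": (65, 91)}  # integers, half-open


def _floor_minute(dt: datetime) -> datetime:
    return dt.replace(second=0, microsecond=0)


def _draw_cat(rng: np.random.Generator, cum: np.ndarray) -> int:
    """Inverse-CDF draw from a categorical given cumulative probabilities."""
    return int(np.searchsorted(cum, rng.random(), side="right"))


def generate_cohort(config: SimConfig
                    ) -> tuple[EventCollection, TrueParameters]:
    """Simulate one cohort; returns the extract plus its ground truth.

    For each patient: draw an initial contact type and a start time
    uniform in the first 30 days of the window, then alternate contact
    (duration from the per-type law) and no-contact gap (conditional on
    the previous type) until the next contact would start after the
    window's end.  Timestamps are floored to minute precision on
    emission.  Output is a pure function of the config (which carries the
    seed).
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    types = list(CONTACT_TYPES)

    patients: list[PatientRecord] = []
    events: list[ContactEvent] = []
    transition_counts = {
        g: {p: {n: 0 for n in types} for p in types} for g in GROUPS
    }
    event_counts = {g: {t: 0 for t in types} for g in GROUPS}
    enc_counter = {t: 0 for t in types}

    window_days = (config.window_end - config.window_start
                   ) / timedelta(days=1)
    horizon = min(30.0, window_days)
    pid = 0
    for g in GROUPS:
        init_cum = np.cumsum(
            [config.initial_state_probs[g][t] for t in types])
        trans_cum = {
            p: np.cumsum([config.transition_matrix[g][p][n] for n in types])
            for p in types
        }
        init_cum[-1] = 1.0
        for cum in trans_cum.values():
            cum[-1] = 1.0
        for _ in range(config.group_sizes.get(g, 0)):
            pid += 1
            patient_id = f"P{pid:05d}"
            lo, hi = _AGE_RANGES[g[1]]
            patients.append(PatientRecord(
                patient_id=patient_id, gender=g[0],
                age_at_first_contact=int(rng.integers(lo, hi)),
            ))
            state = types[_draw_cat(rng, init_cum)]
            t = float(rng.uniform(0.0, horizon))  # days since window start
            while True:
                duration = config.duration_model[state].draw(rng)
                start_dt = _floor_minute(
                    config.window_start + timedelta(days=t))
                end_dt = _floor_minute(
                    config.window_start + timedelta(days=t + duration))
                enc_counter[state] += 1
                events.append(ContactEvent(
                    start=start_dt, contact_type=state,
                    encounter_id=f"{state}{enc_counter[state]:07d}",
                    patient_id=patient_id,
                    end=None if state == "O" else end_dt,
                ))
                event_counts[g][state] += 1
                gap = config.gap_model[g][state].draw(rng)
                t_next = t + duration + gap
                if t_next > window_days:
                    break
                next_state = types[_draw_cat(rng, trans_cum[state])]
                transition_counts[g][state][next_state] += 1
                state = next_state
                t = t_next

    collection = EventCollection(patients=patients, events=events)
    truth = TrueParameters(
        config=config,
        transition_counts=transition_counts,
        event_counts=event_counts,
    )
    return collection, truth


def sample_waiting_records(
    means: dict[str, dict[str, float]],
    n_per_cell: int,
    seed: Optional[int] = None,
    rng: Optional[np.random.Generator] = None,
    cv: float = 1.0,
    kind: str = "between_contacts",
) -> pd.DataFrame:
    """Draw waiting-time records directly, for calibration studies.

    ``means[group][contact_type]`` gives the lognormal mean (days) for
    each group x type cell; every cell yields ``n_per_cell`` records.
    Passing identical per-type means for every group gives a null
    generator with no group effect, used to check the size of the group
    F-test.  Returns a records frame with columns ``group``,
    ``contact_type``, ``waiting_time_days``, ``kind``.
    """
    if rng is None:
        rng = np.random.default_rng(seed)
    rows = []
    for g, per_type in means.items():
        for t, mean in per_type.items():
            spec = DistSpec("lognormal", mean=mean, sd=cv * mean)
            for _ in range(n_per_cell):
                rows.append((g, t, spec.draw(rng), kind))
    return pd.DataFrame(
        rows, columns=["group", "contact_type", "waiting_time_days", "kind"]
    )
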