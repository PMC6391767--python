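"""Group-level journey summaries.

Every table follows the published layout: contact types (and the
no-contact state N where relevant) as rows, groups as columns in the
order AP, MY, MO, FY, FO, where AP is the pool of all patients.  Pooled
(AP) statistics are always computed from the pooled step data, never by
averaging per-group statistics.

Cells with no observations (zero denominators) are NaN — "undefined" —
which is distinct from an observed zero: a group can genuinely show a
0% transition likelihood while another simply contributed no
observations to that row.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence, Union

import numpy as np
import pandas as pd

from .journeys import PatientJourney, journeys_to_frame
from .reference import CONTACT_TYPES, GROUPS

JourneyData = Union[Sequence[PatientJourney], pd.DataFrame]

TABLE_COLUMNS = ("AP",) + GROUPS


def _frame(journeys: JourneyData) -> pd.DataFrame:
    return journeys_to_frame(journeys)


def contact_counts(journeys: JourneyData) -> pd.DataFrame:
    """Contacts by type and group; the AP column is the row sum.

    The per-group cells equal the generator's realised event counts on
    synthetic data, and the per-type totals equal the extract's sheet
    row counts.
    """
    frame = _frame(journeys)
    table = (
        frame.pivot_table(index="contact_type", columns="group",
                          values="patient_id", aggfunc="count",
                          fill_value=0)
        .reindex(index=list(CONTACT_TYPES), columns=list(GROUPS),
                 fill_value=0)
        .astype(int)
    )
    table.insert(0, "AP", table.sum(axis=1))
    table.index.name = None
    table.columns.name = None
    return table


def with_totals(table: pd.DataFrame) -> pd.DataFrame:
    """Append the 'All' row (column sums) in the published layout."""
    out = table.copy()
    out.loc["All"] = out.sum(axis=0)
    return out


def average_contacts(counts: pd.DataFrame,
                     group_sizes: Mapping[str, int]) -> pd.DataFrame:
    """Mean contacts per patient: counts / group size.

    AP divides by the total patient count.  Groups of size zero yield
    NaN (undefined), not an error.
    """
    sizes = pd.Series(
        {g: group_sizes.get(g, 0) for g in GROUPS}, dtype=float)
    sizes["AP"] = sizes.sum()
    sizes = sizes.replace(0.0, np.nan)
    return counts / sizes.reindex(counts.columns)


def contact_proportions(counts: pd.DataFrame) -> pd.DataFrame:
    """Share of each contact type within a group (fractions in [0, 1]).

    Columns sum to 1; a group with no contacts yields an undefined
    (NaN) column.
    """
    totals = counts.sum(axis=0).astype(float).replace(0.0, np.nan)
    return counts / totals


@dataclass
class TransitionMatrix:
    """Next-contact likelihoods conditional on the previous contact type.

    ``counts[i, j]`` is the number of consecutive step pairs (type i
    then type j) pooled over the journeys in scope; ``probs`` is the
    row-normalised counts, with rows of zero total left undefined (NaN).
    """

    counts: pd.DataFrame
    probs: pd.DataFrame
    row_totals: pd.Series

    @property
    def n_transitions(self) -> int:
        return int(self.row_totals.sum())


def estimate_transition_matrix(journeys: JourneyData) -> TransitionMatrix:
    """Estimate the embedded-chain transition matrix from journeys.

    Each patient's sequence of contact types is treated as a realisation
    of a Markov chain; pairs are pooled over patients, so patients with
    longer journeys contribute proportionally more pairs.  The final
    step of each journey has no successor and contributes no pair.
    """
    frame = _frame(journeys).sort_values(["patient_id", "seq_index"])
    prev = frame["contact_type"]
    nxt = frame.groupby("patient_id")["contact_type"].shift(-1)
    pairs = pd.DataFrame({"previous": prev, "next": nxt}).dropna()
    counts = (
        pd.crosstab(pairs["previous"], pairs["next"])
        .reindex(index=list(CONTACT_TYPES), columns=list(CONTACT_TYPES),
                 fill_value=0)
        .astype(int)
    )
    counts.index.name = None
    counts.columns.name = None
    row_totals = counts.sum(axis=1)
    denom = row_totals.astype(float).replace(0.0, np.nan)
    probs = counts.div(denom, axis=0)
    return TransitionMatrix(counts=counts, probs=probs,
                            row_totals=row_totals)


def transition_matrices(journeys: JourneyData
                        ) -> dict[str, TransitionMatrix]:
    """Per-group transition matrices plus the pooled AP matrix."""
    frame = _frame(journeys)
    out = {"AP": estimate_transition_matrix(frame)}
    for g in GROUPS:
        out[g] = estimate_transition_matrix(frame[frame["group"] == g])
    return out


def transition_table(journeys: JourneyData) -> pd.DataFrame:
    """Long-format transition likelihoods in the published layout.

    One row per (previous, next) pair in E/I/O order; columns AP, MY,
    MO, FY, FO; values are probabilities.
    """
    mats = transition_matrices(journeys)
    order = ["E", "I", "O"]
    index = pd.MultiIndex.from_product([order, order],
                                       names=["previous", "next"])
    table = pd.DataFrame(index=index, columns=list(TABLE_COLUMNS),
                         dtype=float)
    for col, mat in mats.items():
        for p in order:
            for n in order:
                table.loc[(p, n), col] = mat.probs.loc[p, n]
    return table


def mean_time_in_state(journeys: JourneyData) -> pd.Series:
    """Mean days in each state I/O/E/N for the journeys in scope.

    I/O/E are means of step durations; N is the mean of all
    non-censored inter-contact gaps.
    """
    frame = _frame(journeys)
    means = (
        frame.groupby("contact_type")["duration_days"].mean()
        .reindex(list(CONTACT_TYPES))
    )
    means["N"] = frame["gap_after_days"].mean()  # NaN-aware
    means.name = "mean_days"
    means.index.name = None
    return means


def state_time_table(journeys: JourneyData) -> pd.DataFrame:
    """Mean time in state by group (rows I, O, E, N; columns AP..FO)."""
    frame = _frame(journeys)
    table = pd.DataFrame({"AP": mean_time_in_state(frame)})
    for g in GROUPS:
        table[g] = mean_time_in_state(frame[frame["group"] == g])
    return table


def mean_gap_by_previous(journeys: JourneyData) -> pd.Series:
    """Mean non-censored gap (days) conditional on the previous type."""
    frame = _frame(journeys)
    means = (
        frame.dropna(subset=["gap_after_days"])
        .groupby("contact_type")["gap_after_days"].mean()
        .reindex(list(CONTACT_TYPES))
    )
    means.name = "mean_gap_days"
    means.index.name = None
    return means


def gap_table(journeys: JourneyData) -> pd.DataFrame:
    """Conditional mean gaps by group (rows I, O, E; columns AP..FO)."""
    frame = _frame(journeys)
    table = pd.DataFrame({"AP": mean_gap_by_previous(frame)})
    for g in GROUPS:
        table[g] = mean_gap_by_previous(frame[frame["group"] == g])
    return table
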