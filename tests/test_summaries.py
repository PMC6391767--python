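"""Summary tables: counts, averages, proportions, transitions, times."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from patient_journeys import (
    average_contacts,
    build_all,
    contact_counts,
    contact_proportions,
    estimate_transition_matrix,
    gap_table,
    generate_cohort,
    journeys_to_frame,
    mean_gap_by_previous,
    mean_time_in_state,
    state_time_table,
)
from patient_journeys.journeys import group_sizes
from patient_journeys.reference import GROUP_SIZES, GROUPS
from patient_journeys.reference import contact_counts as published_counts
from patient_journeys.summaries import with_totals

from conftest import scaled_config


def _frame_for(steps_by_patient: dict[str, tuple[str, list[str]]]
               ) -> pd.DataFrame:
    """Minimal journey frame: {patient: (group, [types])}."""
    rows = []
    for pid, (group, types) in steps_by_patient.items():
        for i, t in enumerate(types):
            gap = np.nan if i == len(types) - 1 else 1.0
            rows.append((pid, group, i, t, None, None, 0.1, gap))
    return pd.DataFrame(rows, columns=[
        "patient_id", "group", "seq_index", "contact_type", "start",
        "end", "duration_days", "gap_after_days"])


class TestCounts:
    def test_direct_count_single_patient(self):
        frame = _frame_for({"p1": ("MY", ["I", "I", "O"])})
        counts = contact_counts(frame)
        assert counts.loc["I", "MY"] == 2
        assert counts.loc["O", "MY"] == 1
        assert counts.loc["E", "MY"] == 0

    def test_ap_column_is_sum_of_group_columns(self, small_config):
        coll, _ = generate_cohort(small_config)
        counts = contact_counts(build_all(coll))
        assert (counts["AP"] ==
                counts[list(GROUPS)].sum(axis=1)).all()
        totals = with_totals(counts)
        assert (totals.loc["All"] == counts.sum(axis=0)).all()

    def test_counts_equal_generator_tally(self, small_config):
        coll, truth = generate_cohort(small_config)
        counts = contact_counts(build_all(coll))
        for g in GROUPS:
            for t in "IOE":
                assert counts.loc[t, g] == truth.event_counts[g][t]


class TestAveragesAndProportions:
    def test_published_average_cells_recomputed(self):
        """40,416/393 patients -> 102.84 mean admissions; 21,353/130 ->
        164.25 mean contacts for older men."""
        counts = with_totals(published_counts())
        counts.insert(0, "AP", counts.sum(axis=1))
        avg = average_contacts(counts, GROUP_SIZES)
        assert round(avg.loc["I", "AP"], 2) == 102.84
        assert round(avg.loc["All", "MO"], 2) == 164.25

    def test_zero_contacts_average_zero(self):
        frame = _frame_for({"p1": ("MY", ["O"])})
        counts = contact_counts(frame)
        avg = average_contacts(counts, {"MY": 1})
        assert avg.loc["E", "MY"] == 0.0

    def test_empty_group_average_is_undefined_not_error(self):
        frame = _frame_for({"p1": ("MY", ["O"])})
        avg = average_contacts(contact_counts(frame), {"MY": 1, "FO": 0})
        assert np.isnan(avg.loc["O", "FO"])

    def test_averages_times_sizes_reproduce_counts(self, small_config):
        coll, _ = generate_cohort(small_config)
        journeys = build_all(coll)
        counts = contact_counts(journeys)
        sizes = group_sizes(journeys)
        avg = average_contacts(counts, sizes)
        for g in GROUPS:
            back = avg[g] * sizes[g]
            assert np.allclose(back, counts[g])

    def test_published_proportion_cells_recomputed(self):
        counts = published_counts()
        counts.insert(0, "AP", counts.sum(axis=1))
        prop = contact_proportions(counts)
        assert round(prop.loc["I", "AP"] * 100, 2) == 78.58
        assert round(prop.loc["I", "MY"] * 100, 2) == 72.85
        assert round(prop.loc["E", "MY"] * 100, 2) == 2.16

    def test_proportions_sum_to_one_per_group(self, small_config):
        coll, _ = generate_cohort(small_config)
        prop = contact_proportions(contact_counts(build_all(coll)))
        assert np.allclose(prop.sum(axis=0), 1.0, atol=1e-12)

    def test_degenerate_group_with_only_outpatient_contacts(self):
        frame = _frame_for({"p1": ("FY", ["O", "O", "O"])})
        prop = contact_proportions(contact_counts(frame))
        assert prop["FY"].tolist() == [0.0, 1.0, 0.0]  # I, O, E


class TestTransitions:
    def test_two_pair_journey(self):
        frame = _frame_for({"p1": ("MY", ["I", "I", "O"])})
        tm = estimate_transition_matrix(frame)
        assert tm.counts.loc["I", "I"] == 1
        assert tm.counts.loc["I", "O"] == 1
        assert tm.probs.loc["I", "I"] == pytest.approx(0.5)
        assert tm.probs.loc["I", "O"] == pytest.approx(0.5)

    def test_pooling_across_journeys(self):
        """[E,I] and [E,O] pooled give P(E->I) = P(E->O) = 1/2."""
        frame = _frame_for({"p1": ("MY", ["E", "I"]),
                            "p2": ("MY", ["E", "O"])})
        tm = estimate_transition_matrix(frame)
        assert tm.probs.loc["E", "I"] == pytest.approx(0.5)
        assert tm.probs.loc["E", "O"] == pytest.approx(0.5)
        assert tm.n_transitions == 2

    def test_rows_without_observations_are_undefined(self):
        frame = _frame_for({"p1": ("MY", ["I", "I", "I"])})
        tm = estimate_transition_matrix(frame)
        assert tm.probs.loc["I", "I"] == 1.0
        assert tm.probs.loc["O"].isna().all()
        assert tm.probs.loc["E"].isna().all()

    def test_transition_total_is_steps_minus_journeys(self, small_config):
        coll, _ = generate_cohort(small_config)
        journeys = build_all(coll)
        tm = estimate_transition_matrix(journeys)
        expected = sum(j.n_steps - 1 for j in journeys)
        assert tm.n_transitions == expected

    def test_ap_transition_counts_are_group_sums(self, small_config):
        from patient_journeys import transition_matrices
        coll, _ = generate_cohort(small_config)
        mats = transition_matrices(build_all(coll))
        summed = sum(mats[g].counts for g in GROUPS)
        assert (mats["AP"].counts == summed).all().all()


class TestStateTimes:
    def test_single_half_day_admission(self):
        frame = pd.DataFrame(
            [("p1", "MY", 0, "I", None, None, 0.5, np.nan)],
            columns=["patient_id", "group", "seq_index", "contact_type",
                     "start", "end", "duration_days", "gap_after_days"])
        means = mean_time_in_state(frame)
        assert means["I"] == pytest.approx(0.5)
        assert np.isnan(means["N"])  # only censored gaps

    def test_gap_mean_is_arithmetic_mean(self):
        frame = pd.DataFrame(
            [("p1", "MY", 0, "I", None, None, 0.5, 1.0),
             ("p1", "MY", 1, "I", None, None, 0.5, 3.0),
             ("p1", "MY", 2, "I", None, None, 0.5, np.nan)],
            columns=["patient_id", "group", "seq_index", "contact_type",
                     "start", "end", "duration_days", "gap_after_days"])
        assert mean_time_in_state(frame)["N"] == pytest.approx(2.0)

    def test_outpatient_row_equals_configured_duration(self, small_config):
        coll, _ = generate_cohort(small_config)
        table = state_time_table(build_all(coll))
        assert np.allclose(table.loc["O"], 1 / 24, atol=1e-9)

    def test_single_step_journeys_leave_gap_table_undefined(self):
        frame = _frame_for({"p1": ("MY", ["I"]), "p2": ("FO", ["O"])})
        assert mean_gap_by_previous(frame).isna().all()

    def test_gap_decomposition_identity(self, small_config):
        """The N mean is the gap-count-weighted mean of the per-previous-
        type gap means, exactly."""
        coll, _ = generate_cohort(small_config)
        frame = journeys_to_frame(build_all(coll))
        gaps = frame.dropna(subset=["gap_after_days"])
        n_by_prev = gaps.groupby("contact_type").size()
        by_prev = mean_gap_by_previous(frame)
        weighted = (by_prev * n_by_prev).sum() / n_by_prev.sum()
        assert weighted == pytest.approx(
            mean_time_in_state(frame)["N"], abs=1e-9)

    def test_gap_table_by_group_matches_manual_filter(self, small_config):
        coll, _ = generate_cohort(small_config)
        frame = journeys_to_frame(build_all(coll))
        table = gap_table(frame)
        manual = mean_gap_by_previous(frame[frame["group"] == "FO"])
        assert np.allclose(table["FO"].dropna(), manual.dropna())
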