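"""Chi-squared and ANOVA group contrasts, checked against brute force."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from patient_journeys import (
    pairwise_anova,
    pairwise_group_tests,
    pearson_chi_squared,
    sample_waiting_records,
    waiting_time_anova,
)
from patient_journeys.inference import DegenerateTableError
from patient_journeys.reference import GROUPS

from _oracles import anova_oracle, chi_squared_oracle


def _table(values, rows=None, cols=None) -> pd.DataFrame:
    values = np.asarray(values)
    return pd.DataFrame(
        values,
        index=rows or [f"r{i}" for i in range(values.shape[0])],
        columns=cols or [f"c{j}" for j in range(values.shape[1])])


class TestChiSquared:
    def test_hand_evaluated_two_by_two(self):
        """[[10,20],[20,10]]: statistic 20/3 by the cell-sum formula."""
        res = pearson_chi_squared(_table([[10, 20], [20, 10]]))
        assert res.statistic == pytest.approx(20 / 3, abs=1e-9)
        assert res.degrees_of_freedom == 1

    def test_proportional_rows_give_zero_statistic(self):
        res = pearson_chi_squared(_table([[10, 20, 30], [20, 40, 60]]))
        assert res.statistic == pytest.approx(0.0, abs=1e-9)
        assert res.p_value == pytest.approx(1.0)

    @pytest.mark.parametrize("seed", range(8))
    def test_matches_cell_sum_oracle_on_random_tables(self, seed):
        rng = np.random.default_rng(seed)
        shape = (int(rng.integers(2, 5)), int(rng.integers(2, 6)))
        table = rng.integers(1, 200, size=shape)
        res = pearson_chi_squared(_table(table))
        stat, df = chi_squared_oracle(table)
        assert res.statistic == pytest.approx(stat, rel=1e-12)
        assert res.degrees_of_freedom == df

    def test_invariant_under_row_and_column_permutation(self):
        rng = np.random.default_rng(3)
        table = rng.integers(1, 100, size=(3, 4))
        base = pearson_chi_squared(_table(table)).statistic
        perm = table[np.argsort(rng.random(3))][:,
                                                np.argsort(rng.random(4))]
        assert pearson_chi_squared(_table(perm)).statistic == \
            pytest.approx(base, rel=1e-12)

    def test_zero_margin_raises_naming_the_margin(self):
        with pytest.raises(DegenerateTableError, match="row"):
            pearson_chi_squared(_table([[0, 0], [5, 5]],
                                       rows=["E", "I"]))
        with pytest.raises(DegenerateTableError, match="column"):
            pearson_chi_squared(_table([[0, 5], [0, 5]],
                                       cols=["FY", "FO"]))


class TestPairwise:
    def test_six_pairs_for_four_groups(self):
        rng = np.random.default_rng(0)
        counts = _table(rng.integers(5, 100, size=(3, 4)),
                        rows=list("IOE"), cols=list(GROUPS))
        results = pairwise_group_tests(counts)
        assert len(results) == 6
        labels = {r.comparison_label for r in results}
        assert "MY vs FY" in labels

    def test_identical_distributions_give_zero_statistic(self):
        counts = _table([[10, 10], [20, 20], [5, 5]],
                        rows=list("IOE"), cols=["MY", "FY"])
        res = pairwise_group_tests(counts)[0]
        assert res.statistic == pytest.approx(0.0, abs=1e-9)
        assert res.p_value == pytest.approx(1.0)

    def test_ap_column_ignored(self):
        counts = _table([[30, 10, 20], [60, 20, 40]],
                        rows=["I", "O"], cols=["AP", "MY", "FO"])
        results = pairwise_group_tests(counts)
        assert len(results) == 1
        assert results[0].comparison_label == "MY vs FO"


def _records(cells: dict[tuple[str, str], list[float]],
             kind: str = "between_contacts") -> pd.DataFrame:
    rows = [(g, t, w, kind)
            for (g, t), ws in cells.items() for w in ws]
    return pd.DataFrame(rows, columns=["group", "contact_type",
                                       "waiting_time_days", "kind"])


class TestAnova:
    def test_constant_response_gives_zero_f_unit_p(self):
        rec = _records({("MY", "I"): [2.0] * 5, ("MY", "O"): [2.0] * 5,
                        ("FO", "I"): [2.0] * 5, ("FO", "O"): [2.0] * 5})
        res = waiting_time_anova(rec)
        assert res.F_group == 0.0
        assert res.p_group == 1.0

    @pytest.mark.parametrize("seed", range(6))
    def test_matches_sums_of_squares_oracle(self, seed):
        rng = np.random.default_rng(100 + seed)
        cells = {}
        for g in ("A", "B", "C"):
            for t in ("I", "O"):
                n = int(rng.integers(5, 15))
                cells[(g, t)] = list(rng.lognormal(0.5, 0.8, size=n))
        rec = _records(cells)
        res = waiting_time_anova(rec, alpha_drop=1.1)  # never drop
        oracle = anova_oracle(rec)
        assert res.F_group == pytest.approx(oracle["F_group"], rel=1e-8)
        assert res.F_interaction == pytest.approx(
            oracle["F_interaction"], rel=1e-8)
        assert res.df_group == oracle["df_group"]
        assert res.df_interaction == oracle["df_interaction"]

    def test_additive_data_drops_interaction(self):
        # identical noise in every cell makes the cell means exactly
        # additive, so the interaction sum of squares is exactly zero
        noise = np.random.default_rng(7).normal(0, 1, 40)
        cells = {}
        for gi, g in enumerate(("A", "B")):
            for ti, t in enumerate(("I", "O")):
                cells[(g, t)] = list(5.0 + 2.0 * gi + 1.0 * ti + noise)
        res = waiting_time_anova(_records(cells))
        assert res.interaction_dropped
        assert res.F_interaction is None
        assert res.p_interaction is None
        assert res.p_group < 0.001  # the additive group effect remains

    def test_strong_interaction_is_retained(self):
        rng = np.random.default_rng(8)
        cells = {
            ("A", "I"): list(rng.normal(1, 0.5, 50)),
            ("A", "O"): list(rng.normal(5, 0.5, 50)),
            ("B", "I"): list(rng.normal(5, 0.5, 50)),
            ("B", "O"): list(rng.normal(1, 0.5, 50)),
        }
        res = waiting_time_anova(_records(cells))
        assert not res.interaction_dropped
        assert res.p_interaction < 0.001

    def test_single_contact_type_fits_main_effect_only(self):
        rng = np.random.default_rng(9)
        rec = _records({("A", "I"): list(rng.normal(1, 1, 30)),
                        ("B", "I"): list(rng.normal(3, 1, 30))})
        res = waiting_time_anova(rec)
        assert res.F_interaction is None
        assert res.interaction_dropped
        assert res.p_group < 0.001

    def test_fewer_than_two_groups_rejected(self):
        rec = _records({("A", "I"): [1.0, 2.0], ("A", "O"): [2.0, 3.0]})
        with pytest.raises(ValueError, match="two groups"):
            waiting_time_anova(rec)

    def test_group_effect_detected_at_cohort_scale(self):
        """Group-dependent gap means at realistic n: p < 0.01."""
        from patient_journeys.reference import gap_means
        means = {g: {t: float(gap_means().loc[t, g]) for t in "IOE"}
                 for g in GROUPS}
        rec = sample_waiting_records(means, n_per_cell=300, seed=11)
        res = waiting_time_anova(rec)
        assert res.p_group < 0.01


class TestPairwiseAnova:
    def test_duplicated_group_labels_give_null_result(self):
        rng = np.random.default_rng(12)
        base = {t: list(rng.lognormal(0.5, 0.6, 40)) for t in ("I", "O")}
        cells = {(g, t): base[t] for g in ("A", "B") for t in ("I", "O")}
        res = pairwise_anova(_records(cells), ("A", "B"))
        assert res.F_group == pytest.approx(0.0, abs=1e-9)

    def test_age_effect_only_pattern(self):
        """Means depending on age class alone: MY-vs-MO significant,
        MY-vs-FY not (the published qualitative pattern)."""
        young = {"I": 2.3, "O": 6.9, "E": 2.5}
        old = {"I": 1.7, "O": 5.2, "E": 1.2}
        means = {"MY": young, "FY": young, "MO": old, "FO": old}
        rec = sample_waiting_records(means, n_per_cell=250, seed=13)
        assert pairwise_anova(rec, ("MY", "MO")).p_group < 0.01
        assert pairwise_anova(rec, ("MY", "FY")).p_group > 0.05

    def test_missing_group_rejected(self):
        rec = _records({("A", "I"): [1.0, 2.0], ("B", "I"): [2.0, 3.0]})
        with pytest.raises(ValueError, match="absent"):
            pairwise_anova(rec, ("A", "Z"))
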