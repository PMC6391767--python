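"""Statistical tests on journey summaries.

Two families of tests mirror the published analysis:

* Pearson chi-squared on the contact-type x group contingency table —
  overall across the four groups, and on every unordered pair of groups
  to locate the source of an overall difference.  No continuity
  correction; p-values from the chi-squared survival function.
* Two-way ANOVA for waiting times: an OLS regression of waiting time on
  contact type, group, and their interaction, with F-tests computed by
  hierarchical model comparison (extra sum of squares).  The interaction
  is tested against the main-effects model; if it is not significant at
  ``alpha_drop`` the model is refit without it.  The group main effect is
  tested against the contact-type-only model.

Waiting times come in two kinds: ``in_contact`` (step durations,
labelled by the step's own type) and ``between_contacts`` (non-censored
gaps, labelled by the *previous* contact type).  Observations are
treated as independent — the regression carries no per-patient random
effect, a deliberate simplification documented in the methods note.
"""

from __future__ import annotations

import itertools
import logging
import warnings
from dataclasses import dataclass
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.formula.api import ols

from .journeys import PatientJourney, journeys_to_frame
from .reference import GROUPS

logger = logging.getLogger(__name__)

JourneyData = Union[Sequence[PatientJourney], pd.DataFrame]

WAITING_KINDS = ("in_contact", "between_contacts")


@dataclass(frozen=True)
class TestResult:
    comparison_label: str
    statistic: float
    degrees_of_freedom: int
    p_value: float

    @property
    def significant_at_01(self) -> bool:
        return self.p_value < 0.01

    @property
    def significant_at_10(self) -> bool:
        return self.p_value < 0.10


@dataclass
class AnovaResult:
    comparison_label: str
    kind: str
    F_group: float
    df_group: tuple[int, int]
    p_group: float
    interaction_dropped: bool
    F_interaction: Optional[float] = None
    df_interaction: Optional[tuple[int, int]] = None
    p_interaction: Optional[float] = None
    alpha_drop: float = 0.05
    n_obs: int = 0


class DegenerateTableError(ValueError):
    """A contingency table has an all-zero row or column margin."""


def pearson_chi_squared(table: pd.DataFrame,
                        label: str = "overall") -> TestResult:
    """Pearson chi-squared test of independence on a counts table.

    ``table`` is any r x c table of nonnegative counts (e.g. contact
    types x groups).  Expected counts are the product of margins over
    the grand total; the statistic is the usual cell sum, df =
    (r-1)(c-1), with no continuity correction.
    """
    values = np.asarray(table, dtype=float)
    row_margins = values.sum(axis=1)
    col_margins = values.sum(axis=0)
    if (row_margins == 0).any():
        bad = list(np.asarray(table.index)[row_margins == 0])
        raise DegenerateTableError(f"all-zero row margin(s): {bad}")
    if (col_margins == 0).any():
        bad = list(np.asarray(table.columns)[col_margins == 0])
        raise DegenerateTableError(f"all-zero column margin(s): {bad}")
    stat, p, df, _ = stats.chi2_contingency(values, correction=False)
    return TestResult(comparison_label=label, statistic=float(stat),
                      degrees_of_freedom=int(df), p_value=float(p))


def pairwise_group_tests(counts: pd.DataFrame) -> list[TestResult]:
    """Chi-squared on every unordered pair of group columns.

    ``counts`` is the contact-type x group table; an AP column, if
    present, is ignored.  Raw p-values are reported — no multiplicity
    correction — with significance readable at 1% and 10% via the
    result's flags.
    """
    groups = [g for g in counts.columns if g != "AP"]
    if len(groups) < 2:
        raise ValueError("need at least two groups for pairwise tests")
    results = []
    for a, b in itertools.combinations(groups, 2):
        pair = counts[[a, b]]
        empty = pair.sum(axis=1) == 0
        if empty.any():
            # a type unobserved in both groups carries no information
            # for this contrast
            logger.warning("%s vs %s: dropping empty type row(s) %s",
                           a, b, list(pair.index[empty]))
            pair = pair.loc[~empty]
        results.append(pearson_chi_squared(pair, label=f"{a} vs {b}"))
    return results


def waiting_time_records(journeys: JourneyData) -> pd.DataFrame:
    """Assemble the waiting-time regression records from journeys.

    Returns one row per observation with columns ``patient_id``,
    ``group``, ``contact_type``, ``waiting_time_days``, ``kind``:
    every step contributes an ``in_contact`` record (its duration,
    labelled by its own type) and every non-censored gap contributes a
    ``between_contacts`` record labelled by the previous contact type.
    """
    frame = journeys_to_frame(journeys)
    durations = frame[
        ["patient_id", "group", "contact_type", "duration_days"]
    ].rename(columns={"duration_days": "waiting_time_days"})
    durations["kind"] = "in_contact"
    gaps = frame.dropna(subset=["gap_after_days"])[
        ["patient_id", "group", "contact_type", "gap_after_days"]
    ].rename(columns={"gap_after_days": "waiting_time_days"})
    gaps["kind"] = "between_contacts"
    return pd.concat([durations, gaps], ignore_index=True)


def _compare_f(restricted, full
               ) -> tuple[float, tuple[int, int], float]:
    """Extra-sum-of-squares F-test of ``full`` against ``restricted``.

    Degenerate data (zero residual variance in the full model) yields
    F = 0, p = 1 when the models fit equally well.
    """
    ss_diff = restricted.ssr - full.ssr
    df_diff = int(round(full.df_model - restricted.df_model))
    df_resid = int(round(full.df_resid))
    if df_diff <= 0:
        raise ValueError("full model adds no estimable parameters")
    scale = max(restricted.ssr, 1.0)
    if ss_diff <= 1e-12 * scale:
        # no explainable variance gained (includes all-constant data)
        return 0.0, (df_diff, df_resid), 1.0
    F = (ss_diff / df_diff) / (full.ssr / df_resid)
    p = float(stats.f.sf(F, df_diff, df_resid))
    return float(F), (df_diff, df_resid), p


def waiting_time_anova(records: pd.DataFrame,
                       kind: str = "between_contacts",
                       alpha_drop: float = 0.05,
                       label: str = "overall") -> AnovaResult:
    """Two-way ANOVA of waiting time on contact type and group.

    Fits ``waiting_time ~ contact_type + group + contact_type:group`` by
    OLS on treatment-coded factors.  The interaction F compares the full
    model with the main-effects model; if its p-value is at least
    ``alpha_drop`` (or the interaction is inestimable), the interaction
    is dropped and only the main-effects model is reported.  The group F
    always compares the main-effects model with the type-only model.
    """
    if kind not in WAITING_KINDS:
        raise ValueError(f"unknown waiting-time kind {kind!r}")
    data = records[records["kind"] == kind].copy()
    n_groups = data["group"].nunique()
    n_types = data["contact_type"].nunique()
    if n_groups < 2:
        raise ValueError(
            f"need at least two groups, found {n_groups}"
        )
    with warnings.catch_warnings():
        # zero-variance fixtures trigger harmless divide warnings in the
        # statsmodels summary machinery
        warnings.simplefilter("ignore", RuntimeWarning)
        if n_types >= 2:
            m_type = ols("waiting_time_days ~ C(contact_type)", data).fit()
            m_main = ols(
                "waiting_time_days ~ C(contact_type) + C(group)", data
            ).fit()
        else:
            m_type = ols("waiting_time_days ~ 1", data).fit()
            m_main = ols("waiting_time_days ~ C(group)", data).fit()
        F_group, df_group, p_group = _compare_f(m_type, m_main)

        F_int = df_int = p_int = None
        dropped = True
        if n_types >= 2:
            m_full = ols(
                "waiting_time_days ~ C(contact_type) * C(group)", data
            ).fit()
            df_int_expected = (n_types - 1) * (n_groups - 1)
            df_gain = int(round(m_full.df_model - m_main.df_model))
            if df_gain < df_int_expected or m_full.df_resid <= 0:
                logger.warning(
                    "%s (%s): interaction inestimable (empty cells); "
                    "dropped", label, kind,
                )
            else:
                F_int, df_int, p_int = _compare_f(m_main, m_full)
                dropped = p_int >= alpha_drop
                if dropped:
                    F_int = df_int = p_int = None
    return AnovaResult(
        comparison_label=label, kind=kind,
        F_group=F_group, df_group=df_group, p_group=p_group,
        interaction_dropped=dropped,
        F_interaction=F_int, df_interaction=df_int, p_interaction=p_int,
        alpha_drop=alpha_drop, n_obs=len(data),
    )


def pairwise_anova(records: pd.DataFrame, group_pair: tuple[str, str],
                   kind: str = "between_contacts",
                   alpha_drop: float = 0.05) -> AnovaResult:
    """The waiting-time ANOVA restricted to two groups."""
    a, b = group_pair
    subset = records[records["group"].isin([a, b])]
    present = set(subset["group"])
    missing = {a, b} - present
    if missing:
        raise ValueError(f"group(s) {sorted(missing)} absent from records")
    return waiting_time_anova(subset, kind=kind, alpha_drop=alpha_drop,
                              label=f"{a} vs {b}")


def all_pairwise_anovas(records: pd.DataFrame,
                        kind: str = "between_contacts",
                        alpha_drop: float = 0.05,
                        groups: Sequence[str] = GROUPS
                        ) -> list[AnovaResult]:
    present = [g for g in groups if (records["group"] == g).any()]
    return [
        pairwise_anova(records, (a, b), kind=kind, alpha_drop=alpha_drop)
        for a, b in itertools.combinations(present, 2)
    ]
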