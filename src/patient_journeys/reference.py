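"""Published summary tables from the motivating two-year dialysis cohort.

A 393-patient cohort of dialysis patients at a single Australian hospital
service, observed 2015-01-01 to 2016-12-31, stratified into four groups by
gender (M/F) and age at first contact (Young < 65, Old >= 65).  The raw
event-level data are not public; what is public are the group-level summary
tables: contact counts by type, next-contact transition likelihoods, mean
time in each contact state, and mean inter-contact gaps conditional on the
previous contact type.

These tables serve two purposes here:

* they parameterise :func:`patient_journeys.synthetic.default_sim_config`,
  so the default synthetic cohort mimics the published cohort's statistical
  structure; and
* the arithmetic identities among them (counts -> averages -> proportions,
  and the chi-squared test on the counts) are exactly recomputable, which
  the test suite and acceptance script exploit.

Column order follows the published layout: AP (all patients pooled) first,
then MY, MO, FY, FO.
"""

from __future__ import annotations

import pandas as pd

#: Age/gender strata, in the published column order.
GROUPS = ("MY", "MO", "FY", "FO")

#: Contact types: I inpatient admission, O outpatient appointment,
#: E emergency-department presentation.
CONTACT_TYPES = ("I", "O", "E")

#: Number of patients per stratum (rows of the group-membership table).
GROUP_SIZES = {"MY": 127, "MO": 130, "FY": 81, "FO": 55}

#: Observation window of the cohort.
WINDOW_START = "2015-01-01T00:00"
WINDOW_END = "2016-12-31T00:00"


def contact_counts() -> pd.DataFrame:
    """Contact counts by type and group (types x MY/MO/FY/FO).

    The AP column of the published table is the row sum and is therefore
    not stored; derive it with ``df.sum(axis=1)``.
    """
    return pd.DataFrame(
        {
            "MY": [10171, 3489, 302],
            "MO": [17422, 3637, 294],
            "FY": [5417, 1976, 163],
            "FO": [7406, 1042, 116],
        },
        index=list(CONTACT_TYPES),
    )


def transition_likelihoods() -> pd.DataFrame:
    """Next-contact likelihoods conditional on the previous contact type.

    Long format: one row per (previous, next) pair in the published
    E/I/O ordering; columns AP, MY, MO, FY, FO; values are probabilities
    (the published percentages divided by 100).
    """
    rows = [
        # prev, next,  AP      MY      MO      FY      FO
        ("E", "E", 0.0149, 0.0331, 0.0034, 0.0123, 0.0000),
        ("E", "I", 0.9300, 0.8974, 0.9658, 0.9202, 0.9386),
        ("E", "O", 0.0551, 0.0695, 0.0308, 0.0675, 0.0614),
        ("I", "E", 0.0141, 0.0183, 0.0109, 0.0196, 0.0118),
        ("I", "I", 0.8918, 0.8628, 0.9033, 0.8641, 0.9246),
        ("I", "O", 0.0941, 0.1189, 0.0858, 0.1163, 0.0636),
        ("O", "E", 0.0267, 0.0280, 0.0266, 0.0261, 0.0242),
        ("O", "I", 0.3559, 0.3261, 0.3920, 0.2982, 0.4385),
        ("O", "O", 0.6174, 0.6459, 0.5814, 0.6757, 0.5373),
    ]
    df = pd.DataFrame(rows, columns=["previous", "next", "AP", *GROUPS])
    return df.set_index(["previous", "next"])


def state_times() -> pd.DataFrame:
    """Mean time (days) in each state I/O/E/N, by group; AP first."""
    return pd.DataFrame(
        {
            "AP": [0.4072, 0.0417, 0.1595, 2.9954],
            "MY": [0.4225, 0.0417, 0.1512, 3.4587],
            "MO": [0.3987, 0.0417, 0.1703, 2.6679],
            "FY": [0.4386, 0.0417, 0.1558, 3.5059],
            "FO": [0.3861, 0.0417, 0.1586, 2.6733],
        },
        index=["I", "O", "E", "N"],
    )


def gap_means() -> pd.DataFrame:
    """Mean gap (days) until the next contact, by previous type and group."""
    return pd.DataFrame(
        {
            "AP": [2.1686, 6.3742, 1.7419],
            "MY": [2.2946, 6.8603, 2.5646],
            "MO": [2.1158, 5.4942, 0.5813],
            "FY": [2.1919, 6.7701, 2.0865],
            "FO": [2.1135, 7.0854, 1.5585],
        },
        index=list(CONTACT_TYPES),
    )


def contact_type_mix() -> pd.DataFrame:
    """Share of each contact type in a group's contacts (fractions).

    Derived from :func:`contact_counts` by column normalisation; published
    as percentages rounded to two decimals, recomputed here at full
    precision so the columns sum to exactly 1.
    """
    counts = contact_counts()
    return counts / counts.sum(axis=0)
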