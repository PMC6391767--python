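"""Independent brute-force oracles used to cross-check the implementation.

These deliberately avoid scipy.stats.chi2_contingency and statsmodels:
the chi-squared oracle evaluates the cell-sum formula with explicit
loops, and the ANOVA oracle assembles one-hot design matrices by hand
and compares residual sums of squares via numpy lstsq.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats


def chi_squared_oracle(table: np.ndarray) -> tuple[float, int]:
    """Pearson statistic by explicit cell summation; df = (r-1)(c-1)."""
    table = np.asarray(table, dtype=float)
    r, c = table.shape
    grand = table.sum()
    stat = 0.0
    for i in range(r):
        for j in range(c):
            expected = table[i].sum() * table[:, j].sum() / grand
            stat += (table[i, j] - expected) ** 2 / expected
    return stat, (r - 1) * (c - 1)


def _design(data: pd.DataFrame, *, types: bool, groups: bool,
            interaction: bool) -> np.ndarray:
    """One-hot (treatment-coded) design matrix with an intercept."""
    n = len(data)
    cols = [np.ones(n)]
    t_levels = sorted(data["contact_type"].unique())[1:]
    g_levels = sorted(data["group"].unique())[1:]
    t_cols = {t: (data["contact_type"] == t).to_numpy(float)
              for t in t_levels}
    g_cols = {g: (data["group"] == g).to_numpy(float) for g in g_levels}
    if types:
        cols += [t_cols[t] for t in t_levels]
    if groups:
        cols += [g_cols[g] for g in g_levels]
    if interaction:
        cols += [t_cols[t] * g_cols[g] for t in t_levels for g in g_levels]
    return np.column_stack(cols)


def _sse(X: np.ndarray, y: np.ndarray) -> float:
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    return float(resid @ resid)


def anova_oracle(data: pd.DataFrame) -> dict:
    """Hierarchical F-tests for group and interaction from raw SSEs.

    Mirrors the model hierarchy (type-only -> main effects -> full) but
    through an entirely separate code path.
    """
    y = data["waiting_time_days"].to_numpy(float)
    n = len(data)
    n_t = data["contact_type"].nunique()
    n_g = data["group"].nunique()

    sse_type = _sse(_design(data, types=True, groups=False,
                            interaction=False), y)
    sse_main = _sse(_design(data, types=True, groups=True,
                            interaction=False), y)
    sse_full = _sse(_design(data, types=True, groups=True,
                            interaction=True), y)

    df_group = n_g - 1
    df_int = (n_t - 1) * (n_g - 1)
    df_resid_main = n - (1 + (n_t - 1) + (n_g - 1))
    df_resid_full = df_resid_main - df_int

    F_group = ((sse_type - sse_main) / df_group) / (sse_main
                                                    / df_resid_main)
    F_int = ((sse_main - sse_full) / df_int) / (sse_full / df_resid_full)
    return {
        "F_group": F_group,
        "p_group": float(stats.f.sf(F_group, df_group, df_resid_main)),
        "F_interaction": F_int,
        "p_interaction": float(stats.f.sf(F_int, df_int, df_resid_full)),
        "df_group": (df_group, df_resid_main),
        "df_interaction": (df_int, df_resid_full),
    }
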