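"""Small statistical helpers shared by the analysis modules.

Paired t-tests come from scipy; the one-way repeated-measures F is computed
from closed-form sums of squares (with statsmodels' AnovaRM available as an
independent cross-check in the test suite); the two-way between-subjects
ANOVA goes through statsmodels OLS.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats as sps


def paired_t(x: np.ndarray, y: np.ndarray) -> tuple[float, float, int]:
    """Paired t-test; returns (t, p, df)."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.shape != y.shape:
        raise ValueError("paired samples must have equal length")
    res = sps.ttest_rel(x, y)
    return float(res.statistic), float(res.pvalue), x.size - 1


def repeated_measures_f(data: np.ndarray) -> tuple[float, float, int, int]:
    """One-way repeated-measures ANOVA from closed-form sums of squares.

    ``data`` is (subjects, conditions).  Returns (F, p, df_effect, df_error).
    Degenerate zero-variance inputs return F = 0.
    """
    data = np.asarray(data, float)
    n, k = data.shape
    grand = data.mean()
    ss_cond = n * np.sum((data.mean(axis=0) - grand) ** 2)
    ss_subj = k * np.sum((data.mean(axis=1) - grand) ** 2)
    ss_tot = np.sum((data - grand) ** 2)
    ss_err = ss_tot - ss_cond - ss_subj
    df_cond = k - 1
    df_err = (n - 1) * (k - 1)
    if ss_err <= 0 or df_err <= 0:
        return 0.0, 1.0, df_cond, df_err
    f = (ss_cond / df_cond) / (ss_err / df_err)
    p = float(sps.f.sf(f, df_cond, df_err))
    return float(f), p, df_cond, df_err


def two_way_anova(
    df: pd.DataFrame, value: str, factor_a: str, factor_b: str
) -> pd.DataFrame:
    """Two-way between-subjects ANOVA with interaction (type II)."""
    import statsmodels.api as sm
    import statsmodels.formula.api as smf

    d = df.rename(columns={value: "_y", factor_a: "_a", factor_b: "_b"})
    idx = ["C(_a)", "C(_b)", "C(_a):C(_b)", "Residual"]
    degenerate = pd.DataFrame(
        {"F": [0.0, 0.0, 0.0, np.nan], "PR(>F)": [1.0, 1.0, 1.0, np.nan]}, index=idx
    )
    y = d["_y"].to_numpy(float)
    if np.var(y) <= 1e-18 * (1.0 + np.max(np.abs(y)) ** 2):  # no variance anywhere
        return degenerate
    n_cells = d["_a"].nunique() * d["_b"].nunique()
    if len(d) <= n_cells:  # saturated design, no residual degrees of freedom
        return degenerate
    model = smf.ols("_y ~ C(_a) * C(_b)", data=d).fit()
    try:
        return sm.stats.anova_lm(model, typ=2)
    except (ValueError, np.linalg.LinAlgError):
        return degenerate
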