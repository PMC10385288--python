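"""Univariate screen and the cross-sectional clinical correlation matrix.

Two-sample t-tests (equal-variance by default, Welch behind a flag) select
diet-responsive variables at either time point; Mann-Whitney and chi-square
tests back the cohort-characteristics table; Pearson correlations between
selected metabolic variables and clinical covariates are computed
pairwise-complete and deliberately left uncorrected for multiplicity (an
exploratory screen) — report writers should say so.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .tables import FeatureTable

__all__ = [
    "t_test",
    "mann_whitney",
    "chi2_test",
    "select_mouse_variables",
    "correlation_matrix",
]


def t_test(a, b, equal_var: bool = True) -> tuple[float, float]:
    """Two-sample t-test; returns (t, two-sided p)."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs n >= 2")
    if not (np.all(np.isfinite(a)) and np.all(np.isfinite(b))):
        raise ValueError("non-finite values in input")
    if a.std(ddof=1) == 0 and b.std(ddof=1) == 0:
        if a.mean() == b.mean():
            return 0.0, 1.0
        raise ValueError("both groups constant with different means: t undefined")
    t, p = sps.ttest_ind(a, b, equal_var=equal_var)
    return float(t), float(p)


def mann_whitney(a, b) -> tuple[float, float]:
    """Mann-Whitney U (of the first group) with two-sided p.

    Exact enumeration when n_A + n_B <= 12 and the pooled data are tie-free;
    otherwise the tie-corrected normal approximation.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) < 1 or len(b) < 1:
        raise ValueError("each group needs n >= 1")
    pooled = np.concatenate([a, b])
    ties = len(np.unique(pooled)) < len(pooled)
    method = "exact" if (len(pooled) <= 12 and not ties) else "asymptotic"
    res = sps.mannwhitneyu(a, b, alternative="two-sided", method=method)
    return float(res.statistic), float(res.pvalue)


def chi2_test(table, yates: bool = False) -> tuple[float, float]:
    """Pearson chi-square on a 2x2 (or larger) contingency table."""
    res = sps.chi2_contingency(np.asarray(table), correction=yates)
    return float(res.statistic), float(res.pvalue)


def select_mouse_variables(
    tables: dict[object, tuple[pd.DataFrame, pd.Series]],
    alpha: float = 0.05,
    equal_var: bool = True,
) -> list[str]:
    """Union of variables significant (t-test p < alpha) at any time point.

    ``tables`` maps a time-point key to ``(samples x variables frame, group
    label per sample)``; within each time point the two group levels are
    compared. Variables missing at a time point are simply not tested there.
    """
    hit: set[str] = set()
    order: list[str] = []
    for _, (df, groups) in tables.items():
        levels = pd.unique(groups)
        if len(levels) != 2:
            raise ValueError("each time point needs exactly 2 group levels")
        ga, gb = (groups == levels[0]).to_numpy(), (groups == levels[1]).to_numpy()
        order.extend(v for v in df.columns if v not in order)
        X = df.to_numpy(dtype=float)
        _, p = sps.ttest_ind(X[ga], X[gb], axis=0, equal_var=equal_var)
        hit |= set(df.columns[np.asarray(p) < alpha])
    return [v for v in order if v in hit]


@dataclass
class CorrelationResult:
    """Long-format Pearson screen: one row per (variable, covariate) cell."""

    table: pd.DataFrame  # columns: variable, covariate, r, p, n

    def pivot(self, value: str = "r") -> pd.DataFrame:
        return self.table.pivot(index="variable", columns="covariate", values=value)


def correlation_matrix(
    variables: pd.DataFrame, clinical: pd.DataFrame, min_n: int = 3
) -> CorrelationResult:
    """Pairwise-complete Pearson r with two-sided p (t transform, n-2 df).

    Cells with fewer than ``min_n`` complete pairs, or with a constant
    vector, are flagged with NaN r/p (n still recorded). p-values are
    intentionally uncorrected.
    """
    clinical = clinical.reindex(variables.index)
    rows = []
    for var in variables.columns:
        x_all = variables[var].to_numpy(dtype=float)
        for cov in clinical.columns:
            y_all = clinical[cov].to_numpy(dtype=float)
            ok = np.isfinite(x_all) & np.isfinite(y_all)
            n = int(ok.sum())
            if n < min_n or np.std(x_all[ok]) == 0 or np.std(y_all[ok]) == 0:
                rows.append({"variable": var, "covariate": cov, "r": np.nan, "p": np.nan, "n": n})
                continue
            r, p = sps.pearsonr(x_all[ok], y_all[ok])
            rows.append({"variable": var, "covariate": cov, "r": float(r), "p": float(p), "n": n})
    return CorrelationResult(pd.DataFrame(rows))
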