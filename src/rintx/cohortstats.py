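"""Cohort-level demographic statistics.

Welch (unequal-variance) two-sample t-tests, computable either from raw
values or from printed summary statistics (n, mean, SD), and exact
hypergeometric tests on 2x2 contingency tables.  These are the tests used
to compare dementia and control donors on continuous variables (age, RIN,
Braak stage, ...) and on categorical ones (sex, APOE e4 carriage).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats


@dataclass(frozen=True)
class SummaryStats:
    """Group summary as printed in a demographics table: n, mean, SD."""

    n: int
    mean: float
    sd: float

    def __post_init__(self) -> None:
        if self.n < 2:
            raise ValueError(f"n must be >= 2, got {self.n}")
        if self.sd < 0:
            raise ValueError(f"sd must be >= 0, got {self.sd}")


def summarize(values) -> SummaryStats:
    """Summarize a sample as (n, mean, sd) with the unbiased SD."""
    x = np.asarray(values, dtype=float)
    x = x[~np.isnan(x)]
    if x.size < 2:
        raise ValueError("need at least 2 non-missing values")
    return SummaryStats(n=int(x.size), mean=float(x.mean()), sd=float(x.std(ddof=1)))


def welch_t_from_summary(a: SummaryStats, b: SummaryStats):
    """Welch t-test from group summaries.

    Returns (t, df, p_two_sided) with the Welch-Satterthwaite degrees of
    freedom.  Degenerate case: both SDs zero gives t=0, p=1 when the means
    agree and p=0 (with a warning) when they differ.
    """
    va, vb = a.sd**2 / a.n, b.sd**2 / b.n
    if va + vb == 0.0:
        if a.mean == b.mean:
            return 0.0, float(a.n + b.n - 2), 1.0
        warnings.warn("zero variance in both groups with unequal means; p=0 is degenerate")
        return np.inf if a.mean > b.mean else -np.inf, float(a.n + b.n - 2), 0.0
    t = (a.mean - b.mean) / np.sqrt(va + vb)
    df = (va + vb) ** 2 / (va**2 / (a.n - 1) + vb**2 / (b.n - 1))
    p = 2.0 * stats.t.sf(abs(t), df)
    return float(t), float(df), float(p)


def welch_t(values_a, values_b):
    """Welch t-test from raw values; identical to the summary-based form."""
    return welch_t_from_summary(summarize(values_a), summarize(values_b))


def contingency_test(table, convention: str = "upper_tail") -> float:
    """Exact hypergeometric test of a 2x2 table with fixed margins.

    With the table [[a, b], [c, d]], the distribution of the top-left cell
    given all margins is Hypergeometric(M=a+b+c+d, n=a+b, N=a+c).

    convention:
      - ``upper_tail``: P(X >= a).
      - ``two_sided_fisher``: sum of point probabilities <= P(X = a)
        (Fisher's exact two-sided rule).
      - ``mid_p``: P(X >= a) - P(X = a)/2.
    """
    t = np.asarray(table, dtype=float)
    if t.shape != (2, 2):
        raise ValueError("table must be 2x2")
    if np.any(t < 0) or not np.all(t == np.round(t)):
        raise ValueError("counts must be non-negative integers")
    a, b = int(t[0, 0]), int(t[0, 1])
    c, d = int(t[1, 0]), int(t[1, 1])
    total = a + b + c + d
    if total == 0:
        raise ValueError("table total must be > 0")
    row1, col1 = a + b, a + c
    lo = max(0, col1 - (c + d))
    hi = min(row1, col1)
    # exact integer enumeration of the margin-fixed table weights
    weights = {
        k: math.comb(row1, k) * math.comb(total - row1, col1 - k)
        for k in range(lo, hi + 1)
    }
    denom = math.comb(total, col1)
    w_obs = weights[a]
    if convention == "upper_tail":
        num = sum(w for k, w in weights.items() if k >= a)
        p = num / denom
    elif convention == "two_sided_fisher":
        num = sum(w for w in weights.values() if w <= w_obs)
        p = num / denom
    elif convention == "mid_p":
        num = sum(w for k, w in weights.items() if k >= a)
        p = (num - 0.5 * w_obs) / denom
    else:
        raise ValueError(f"unknown convention: {convention!r}")
    return float(min(p, 1.0))


def demographic_table(
    donors: pd.DataFrame,
    continuous_vars: list[str],
    categorical_vars: list[str],
    group_col: str = "dementia",
) -> pd.DataFrame:
    """Dementia-vs-control demographic summary table.

    Continuous variables get group means/SDs and a Welch p-value;
    categorical (binary) variables get 2x2 counts and an upper-tail
    hypergeometric p.  A Bonferroni star column flags p < 0.05 after
    correcting over all tests in the table.  Missing values are dropped
    pairwise and counted.
    """
    if group_col not in donors.columns:
        raise ValueError(f"missing group column {group_col!r}")
    grp = donors[group_col].astype(bool)
    if grp.nunique() < 2:
        warnings.warn("single-group input; p-values not computed")
    rows = []
    for var in continuous_vars:
        x = pd.to_numeric(donors[var], errors="coerce")
        a, b = x[~grp].dropna(), x[grp].dropna()
        n_missing = int(x.isna().sum())
        if grp.nunique() < 2 or len(a) < 2 or len(b) < 2:
            p = np.nan
        else:
            _, _, p = welch_t(a.to_numpy(), b.to_numpy())
        rows.append(
            dict(variable=var, kind="continuous",
                 mean_control=a.mean() if len(a) else np.nan,
                 sd_control=a.std(ddof=1) if len(a) > 1 else np.nan,
                 mean_case=b.mean() if len(b) else np.nan,
                 sd_case=b.std(ddof=1) if len(b) > 1 else np.nan,
                 n_control=len(a), n_case=len(b), n_missing=n_missing, p=p)
        )
    for var in categorical_vars:
        x = donors[var]
        ok = x.notna()
        n_missing = int((~ok).sum())
        xb = x[ok].astype(bool)
        g = grp[ok]
        a11 = int((xb & g).sum())      # case & attribute
        a10 = int((~xb & g).sum())
        a01 = int((xb & ~g).sum())
        a00 = int((~xb & ~g).sum())
        if g.nunique() < 2:
            p = np.nan
        else:
            p = contingency_test([[a11, a10], [a01, a00]])
        rows.append(
            dict(variable=var, kind="categorical",
                 mean_control=a01, sd_control=a00,
                 mean_case=a11, sd_case=a10,
                 n_control=int((~g).sum()), n_case=int(g.sum()),
                 n_missing=n_missing, p=p)
        )
    out = pd.DataFrame(rows)
    n_tests = out["p"].notna().sum()
    out["bonferroni_significant"] = (out["p"] * max(n_tests, 1)) < 0.05
    return out
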