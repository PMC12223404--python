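"""Headline inferential comparisons for cohort metrics.

Welch's unequal-variance t-test for group differences in ischemic burden,
Spearman rank correlation (exact permutation p at small n, t-approximation
otherwise) for agreement between early imaging metrics and outcomes, and
simple linear regression with a 95% CI on the intercept ("offset") for the
between-modality comparisons.  No multiple-testing correction is applied:
comparisons are reported per-pair, matching how such headline contrasts are
usually presented.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import permutations
from math import factorial

import numpy as np
from scipy import stats as sps


@dataclass
class WelchResult:
    t_stat: float
    df: float
    p_two_sided: float
    degenerate: bool = False


@dataclass
class SpearmanResult:
    rho: float
    p: float
    method: str  # "exact_perm" | "t_approx"


@dataclass
class RegressionResult:
    slope: float
    intercept: float
    r_squared: float
    ci95_intercept: tuple[float, float]


def welch_t_test(a, b) -> WelchResult:
    """Welch two-sample t with Satterthwaite df and two-sided p.

    Degenerate zero-variance cases follow the convention: equal means → p=1,
    different means → p=0 (flagged).
    """
    a = np.asarray(a, dtype=np.float64)
    b = np.asarray(b, dtype=np.float64)
    if a.size < 2 or b.size < 2:
        raise ValueError("each sample needs at least two observations")
    va, vb = a.var(ddof=1), b.var(ddof=1)
    if va == 0 and vb == 0:
        same = np.isclose(a.mean(), b.mean())
        return WelchResult(0.0 if same else np.inf, np.nan, 1.0 if same else 0.0, True)
    res = sps.ttest_ind(a, b, equal_var=False)
    df = (va / a.size + vb / b.size) ** 2 / (
        (va / a.size) ** 2 / (a.size - 1) + (vb / b.size) ** 2 / (b.size - 1)
    )
    return WelchResult(float(res.statistic), float(df), float(res.pvalue))


def _rank(x: np.ndarray) -> np.ndarray:
    return sps.rankdata(x)  # midranks for ties


def _rho_of_ranks(rx: np.ndarray, ry: np.ndarray) -> float:
    dx = rx - rx.mean()
    dy = ry - ry.mean()
    den = np.sqrt((dx @ dx) * (dy @ dy))
    if den == 0:
        return np.nan
    return float(dx @ dy / den)


def spearman_corr(x, y, p_method: str | None = None) -> SpearmanResult:
    """Spearman rho with exact-permutation p for n ≤ 8, else t-approximation.

    rho is the Pearson correlation of midranks.  The exact p enumerates all
    n! orderings of y and counts |rho| at least as extreme as observed
    (tie-adjusted statistic throughout).
    """
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    n = x.size
    if n != y.size or n < 3:
        raise ValueError("need equal-length samples with n >= 3")
    rx, ry = _rank(x), _rank(y)
    rho = _rho_of_ranks(rx, ry)
    if np.isnan(rho):
        raise ValueError("constant sample: Spearman correlation undefined")
    if p_method is None:
        p_method = "exact_perm" if n <= 8 else "t_approx"
    if p_method == "exact_perm":
        if n > 8:
            raise ValueError("exact permutation p limited to n <= 8")
        perms = np.array(list(permutations(range(n))))
        ry_perm = ry[perms]  # (n!, n)
        dx = rx - rx.mean()
        dyp = ry_perm - ry_perm.mean(axis=1, keepdims=True)
        den = np.sqrt((dx @ dx) * (dyp * dyp).sum(axis=1))
        rhos = (dyp @ dx) / den
        count = int((np.abs(rhos) >= abs(rho) - 1e-12).sum())
        p = count / factorial(n)
    elif p_method == "t_approx":
        if abs(rho) >= 1.0:
            p = 0.0
        else:
            tstat = rho * np.sqrt((n - 2) / (1.0 - rho**2))
            p = float(2.0 * sps.t.sf(abs(tstat), df=n - 2))
    else:
        raise ValueError(f"unknown p_method {p_method!r}")
    return SpearmanResult(rho, float(p), p_method)


def simple_regression(x, y) -> RegressionResult:
    """OLS of y on x with a 95% t-interval on the intercept."""
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if x.size < 3 or x.size != y.size:
        raise ValueError("need equal-length samples with n >= 3")
    if x.var() == 0:
        raise ValueError("zero variance in x: regression undefined")
    res = sps.linregress(x, y)
    n = x.size
    tcrit = sps.t.ppf(0.975, df=n - 2)
    ci = (
        float(res.intercept - tcrit * res.intercept_stderr),
        float(res.intercept + tcrit * res.intercept_stderr),
    )
    return RegressionResult(
        float(res.slope), float(res.intercept), float(res.rvalue**2), ci
    )
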