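"""Cohort statistics: normality screening, group comparisons, correlations,
collinearity, stepwise linear regression, and two-means sample size.

This is the statistical battery a morphometric cohort study runs over a
per-femur table: Kolmogorov-Smirnov normality screening (Lilliefors-corrected,
since mean and SD are estimated from the sample), Student's t tests between
genders (independent, pooled variance) and between sides (paired),
Mann-Whitney U for non-normal measures, a Pearson correlation matrix,
variance-inflation factors as the collinearity screen, and
forward-backward stepwise OLS with p-to-enter / p-to-remove thresholds.

Binary codings throughout: gender female=1/male=0, laterality left=1/right=0.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.stats as st
import statsmodels.api as sm

from .errors import InputError, ParameterError

__all__ = [
    "TestResult",
    "RegressionModel",
    "SampleSize",
    "ks_normality",
    "compare_groups",
    "pearson_matrix",
    "stepwise_regression",
    "vif",
    "sample_size_two_means",
]


@dataclass(frozen=True)
class TestResult:
    statistic: float
    p_value: float
    test_name: str
    n: int
    n2: int | None = None
    degenerate: bool = False
    extra: dict = field(default_factory=dict)

    def __post_init__(self):
        if not (np.isnan(self.p_value) or 0.0 <= self.p_value <= 1.0):
            raise ParameterError("p_value must lie in [0, 1]")


# cached Monte Carlo null distributions of the Lilliefors statistic,
# keyed by (n, n_mc, seed)
_LILLIEFORS_NULL: dict = {}


def _lilliefors_null(n: int, n_mc: int, seed: int) -> np.ndarray:
    key = (n, n_mc, seed)
    if key not in _LILLIEFORS_NULL:
        rng = np.random.default_rng(seed)
        stats = np.empty(n_mc)
        for i in range(n_mc):
            x = rng.standard_normal(n)
            stats[i] = st.kstest(x, "norm", args=(x.mean(), x.std(ddof=1))).statistic
        _LILLIEFORS_NULL[key] = np.sort(stats)
    return _LILLIEFORS_NULL[key]


def ks_normality(x, n_mc: int = 10000, seed: int = 0) -> TestResult:
    """One-sample K-S test against a normal with estimated mean/SD.

    Because the null parameters are estimated from the sample, the naive K-S
    p-value is anti-conservative; the primary p-value is therefore computed
    against a seeded Monte Carlo null of the Lilliefors statistic (cached per
    sample size), with the asymptotic K-S p reported in ``extra``.
    """
    x = np.asarray(x, dtype=float)
    if len(x) < 8:
        raise InputError("need n >= 8 for the normality screen")
    if np.any(~np.isfinite(x)):
        raise InputError("missing/non-finite values are not allowed")
    sd = x.std(ddof=1)
    if sd == 0:
        return TestResult(
            statistic=math.inf,
            p_value=0.0,
            test_name="ks_lilliefors",
            n=len(x),
            degenerate=True,
        )
    res = st.kstest(x, "norm", args=(x.mean(), sd))
    null = _lilliefors_null(len(x), n_mc, seed)
    # add-one Monte Carlo p
    p_mc = (1.0 + np.sum(null >= res.statistic)) / (n_mc + 1.0)
    return TestResult(
        statistic=float(res.statistic),
        p_value=float(p_mc),
        test_name="ks_lilliefors",
        n=len(x),
        extra={"p_asymptotic": float(res.pvalue)},
    )


def compare_groups(x, y, mode: str, equal_var: bool = True) -> TestResult:
    """Two-sided two-group comparison.

    ``independent_t`` is the classic pooled-variance Student's t (Welch's
    form behind ``equal_var=False``); ``paired_t`` requires equal lengths;
    ``mann_whitney`` is the two-sided Mann-Whitney U.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 2 or len(y) < 2:
        raise InputError("need at least 2 observations per group")
    if mode == "independent_t":
        res = st.ttest_ind(x, y, equal_var=equal_var)
        return TestResult(
            float(res.statistic), float(res.pvalue), "independent_t",
            len(x), len(y),
        )
    if mode == "paired_t":
        if len(x) != len(y):
            raise InputError("paired test requires equal lengths")
        d = x - y
        if d.std(ddof=1) == 0:
            if np.allclose(d, 0):
                return TestResult(0.0, 1.0, "paired_t", len(x), len(y))
            return TestResult(
                math.copysign(math.inf, d.mean()), 0.0, "paired_t",
                len(x), len(y), degenerate=True,
            )
        res = st.ttest_rel(x, y)
        return TestResult(
            float(res.statistic), float(res.pvalue), "paired_t", len(x), len(y)
        )
    if mode == "mann_whitney":
        res = st.mannwhitneyu(x, y, alternative="two-sided")
        return TestResult(
            float(res.statistic), float(res.pvalue), "mann_whitney",
            len(x), len(y),
        )
    raise ParameterError(f"unknown mode {mode!r}")


@dataclass
class CorrelationMatrix:
    """Pearson r and p matrices plus a combined table: r above the diagonal,
    p below, unit diagonal — the conventional compact cohort layout."""

    r: pd.DataFrame
    p: pd.DataFrame

    @property
    def combined(self) -> pd.DataFrame:
        names = list(self.r.columns)
        out = pd.DataFrame(np.eye(len(names)), index=names, columns=names)
        for i, a in enumerate(names):
            for j, b in enumerate(names):
                if i < j:
                    out.loc[a, b] = self.r.loc[a, b]
                elif i > j:
                    out.loc[a, b] = self.p.loc[a, b]
        return out


def pearson_matrix(table: pd.DataFrame, variables: list) -> CorrelationMatrix:
    """Pairwise Pearson correlations with two-sided p (t transform).

    Zero-variance columns yield NaN in their row/column.
    """
    data = table[list(variables)].dropna()
    if len(data) < 3:
        raise InputError("need at least 3 complete rows")
    k = len(variables)
    r = np.eye(k)
    p = np.zeros((k, k))
    for i in range(k):
        for j in range(i + 1, k):
            xi = data[variables[i]].to_numpy()
            xj = data[variables[j]].to_numpy()
            if xi.std() == 0 or xj.std() == 0:
                r[i, j] = r[j, i] = np.nan
                p[i, j] = p[j, i] = np.nan
                continue
            res = st.pearsonr(xi, xj)
            r[i, j] = r[j, i] = res.statistic
            p[i, j] = p[j, i] = res.pvalue
    return CorrelationMatrix(
        r=pd.DataFrame(r, index=variables, columns=variables),
        p=pd.DataFrame(p, index=variables, columns=variables),
    )


@dataclass
class RegressionModel:
    """Stepwise-selected OLS model with its step log."""

    response: str
    terms: list
    coefficients: dict  # includes "intercept"
    r_squared: float
    steps: list  # [(action, term, p_value), ...]
    std_errors: dict = field(default_factory=dict)
    conf_int: dict = field(default_factory=dict)
    n: int = 0

    def __post_init__(self):
        if not 0.0 <= self.r_squared <= 1.0:
            raise ParameterError("r_squared must lie in [0, 1]")
        if len(self.coefficients) != len(self.terms) + 1:
            raise ParameterError("coefficient count must equal terms + 1")

    def predict(self, table: pd.DataFrame) -> np.ndarray:
        out = np.full(len(table), self.coefficients["intercept"])
        for t in self.terms:
            out = out + self.coefficients[t] * table[t].to_numpy()
        return out


def _ols(y: np.ndarray, X: pd.DataFrame):
    return sm.OLS(y, sm.add_constant(X, has_constant="add")).fit()


def stepwise_regression(
    table: pd.DataFrame,
    response: str,
    candidates: list,
    p_enter: float = 0.05,
    p_remove: float = 0.10,
    max_steps: int = 100,
) -> RegressionModel:
    """Forward-backward stepwise OLS.

    At each iteration the excluded candidate with the smallest partial-F p
    (equivalently, its coefficient's t-test p in the augmented model) enters
    if p <= p_enter; then any included term with p >= p_remove is removed
    (worst first).  Stops when neither step changes the model.  With no
    entering candidate the intercept-only model is returned.
    """
    candidates = list(candidates)
    if len(table) < len(candidates) + 10:
        raise InputError("need at least candidates + 10 rows")
    y = table[response].to_numpy(dtype=float)
    included: list = []
    steps: list = []
    for _ in range(max_steps):
        changed = False
        excluded = [c for c in candidates if c not in included]
        if excluded:
            best_p, best_c = np.inf, None
            for c in excluded:
                fit = _ols(y, table[included + [c]])
                pv = float(fit.pvalues[c])
                if pv < best_p:
                    best_p, best_c = pv, c
            if best_p <= p_enter:
                included.append(best_c)
                steps.append(("enter", best_c, best_p))
                changed = True
        if included:
            fit = _ols(y, table[included])
            pv = fit.pvalues[included]
            worst = pv.idxmax()
            if float(pv[worst]) >= p_remove:
                included.remove(worst)
                steps.append(("remove", worst, float(pv[worst])))
                changed = True
        if not changed:
            break

    if included:
        fit = _ols(y, table[included])
        coefs = {"intercept": float(fit.params["const"])}
        ses = {"intercept": float(fit.bse["const"])}
        ci = fit.conf_int()
        cis = {"intercept": tuple(map(float, ci.loc["const"]))}
        for t in included:
            coefs[t] = float(fit.params[t])
            ses[t] = float(fit.bse[t])
            cis[t] = tuple(map(float, ci.loc[t]))
        r2 = float(fit.rsquared)
    else:
        coefs = {"intercept": float(np.mean(y))}
        ses = {"intercept": float(np.std(y, ddof=1) / math.sqrt(len(y)))}
        cis = {}
        r2 = 0.0
    return RegressionModel(
        response=response,
        terms=list(included),
        coefficients=coefs,
        r_squared=r2,
        steps=steps,
        std_errors=ses,
        conf_int=cis,
        n=len(y),
    )


def vif(table: pd.DataFrame, candidates: list) -> dict:
    """Variance-inflation factor per candidate (1 / (1 - R^2) against the
    others); ``inf`` under perfect collinearity.  Screen flag at VIF > 10."""
    out = {}
    for c in candidates:
        others = [o for o in candidates if o != c]
        if not others:
            out[c] = 1.0
            continue
        fit = _ols(table[c].to_numpy(dtype=float), table[others])
        r2 = float(fit.rsquared)
        out[c] = math.inf if r2 >= 1.0 - 1e-12 else 1.0 / (1.0 - r2)
    return out


@dataclass(frozen=True)
class SampleSize:
    """Two-means sample size: normal-approximation and t-refined values.

    ``n`` (the reported value) is the t-refined one: the normal formula
    n = 2 ((z_{1-a/2} + z_{pow}) sd / diff)^2 ignores that the test statistic
    is Student-t at finite n, which loses a unit or two of sample size.
    """

    normal: int
    t_refined: int

    @property
    def n(self) -> int:
        return self.t_refined


def _power_two_sample_t(n: int, alpha: float, sd: float, diff: float) -> float:
    df = 2 * n - 2
    if df < 1:
        return 0.0
    ncp = diff / (sd * math.sqrt(2.0 / n))
    tcrit = st.t.ppf(1.0 - alpha / 2.0, df)
    return float(
        1.0 - st.nct.cdf(tcrit, df, ncp) + st.nct.cdf(-tcrit, df, ncp)
    )


def sample_size_two_means(
    alpha: float = 0.05, power: float = 0.80, sd: float = 20.0, diff: float = 10.0
) -> SampleSize:
    """Per-group n to detect a mean difference (two-sided two-sample test)."""
    if not 0.0 < alpha < 1.0:
        raise ParameterError("alpha must lie in (0, 1)")
    if not 0.0 < power < 1.0:
        raise ParameterError("power must lie in (0, 1)")
    if not (sd > 0 and diff > 0):
        raise ParameterError("sd and diff must be > 0")
    za = st.norm.ppf(1.0 - alpha / 2.0)
    zb = st.norm.ppf(power)
    n_normal = max(2, math.ceil(2.0 * (za + zb) ** 2 * (sd / diff) ** 2))
    n = max(2, n_normal - 2)
    while _power_two_sample_t(n, alpha, sd, diff) < power:
        n += 1
    return SampleSize(normal=n_normal, t_refined=n)
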