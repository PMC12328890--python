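"""Descriptive and variability statistics for intergestural timing.

The study's statistical surface has four parts:

* grouped descriptive tables (count, mean, SD per speaker x consonant
  class, with a count-weighted pooled Total column);
* median-based Levene tests - equivalent to the Brown-Forsythe test -
  for homogeneity of variance between consonant classes: a one-way
  ANOVA on the absolute deviations of observations from their group
  median;
* a modified signed likelihood-ratio test (M-SLRT) for equality of
  coefficients of variation under normal models, useful when groups
  differ in mean;
* Pearson correlations between intergestural lags and individual
  gesture duration, which index whether relative timing is preserved
  when gesture duration varies.

Mixed-effects regressions (speaker/item random effects) are delegated
to statsmodels at contract level; this module does not re-implement
restricted-likelihood estimation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats


# --------------------------------------------------------------------------
# descriptive tables
# --------------------------------------------------------------------------

def pooled_weighted_mean(means, counts) -> float:
    """Count-weighted mean of group means: sum(n_i * m_i) / sum(n_i)."""
    means = np.asarray(means, dtype=float)
    counts = np.asarray(counts, dtype=float)
    if means.shape != counts.shape:
        raise ValueError("means and counts must have the same length")
    if np.any(counts <= 0):
        raise ValueError("counts must be positive")
    return float(np.dot(means, counts) / counts.sum())


def group_summary(
    table: pd.DataFrame,
    measure: str,
    grouping: tuple[str, ...] = ("class", "speaker"),
) -> pd.DataFrame:
    """Count / mean / sample-SD per group cell plus a pooled Total row.

    The Total row per outer group carries the count-weighted mean of the
    cell means and the SD of the pooled sample.  Cells with a single
    observation report a missing SD; empty cells are absent (count 0 has
    no mean).
    """
    if table.empty:
        raise ValueError("empty measure table")
    sub = table.dropna(subset=[measure])
    out = (
        sub.groupby(list(grouping), observed=True)[measure]
        .agg(count="count", mean="mean", sd=lambda x: x.std(ddof=1))
        .reset_index()
    )
    outer = grouping[0]
    totals = []
    for key, grp in out.groupby(outer, observed=True):
        pooled = sub[sub[outer] == key][measure]
        totals.append(
            {
                outer: key,
                grouping[1]: "Total",
                "count": int(grp["count"].sum()),
                "mean": pooled_weighted_mean(grp["mean"], grp["count"]),
                "sd": pooled.std(ddof=1) if len(pooled) > 1 else math.nan,
            }
        )
    return pd.concat([out, pd.DataFrame(totals)], ignore_index=True)


# --------------------------------------------------------------------------
# Brown-Forsythe (median-based Levene) homogeneity-of-variance test
# --------------------------------------------------------------------------

@dataclass
class VarianceTestResult:
    statistic: float
    df1: int
    df2: int
    p_value: float
    groups: tuple[str, ...] = ()
    measure: str = ""


def brown_forsythe(groups: list[np.ndarray], labels: tuple[str, ...] = ()) -> VarianceTestResult:
    """One-way ANOVA F on |x_ij - median(group_j)|, df (k-1, N-k).

    Identical within-group deviation profiles give F = 0; zero residual
    variance with equal deviation means is reported as F = 0, p = 1.
    """
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    groups = [np.asarray(g, dtype=float) for g in groups]
    if any(len(g) < 2 for g in groups):
        raise ValueError("each group needs at least two observations")
    z = [np.abs(g - np.median(g)) for g in groups]
    k = len(z)
    n = np.array([len(g) for g in z])
    N = int(n.sum())
    zbar = np.array([g.mean() for g in z])
    grand = np.concatenate(z).mean()
    ss_between = float(np.dot(n, (zbar - grand) ** 2))
    ss_within = float(sum(((g - m) ** 2).sum() for g, m in zip(z, zbar)))
    df1, df2 = k - 1, N - k
    if ss_within == 0.0:
        if ss_between == 0.0:
            return VarianceTestResult(0.0, df1, df2, 1.0, labels)
        return VarianceTestResult(math.inf, df1, df2, 0.0, labels)
    F = (ss_between / df1) / (ss_within / df2)
    p = float(stats.f.sf(F, df1, df2))
    return VarianceTestResult(F, df1, df2, p, labels)


# --------------------------------------------------------------------------
# equality of coefficients of variation (signed likelihood-ratio test)
# --------------------------------------------------------------------------

@dataclass
class CVTestResult:
    statistic: float
    p_value: float
    cvs: tuple[float, ...] = ()
    df: int = 1
    method: str = "mslrt"


def _normal_loglik(x: np.ndarray, mu: float, sigma: float) -> float:
    n = len(x)
    return -n * math.log(sigma) - float(((x - mu) ** 2).sum()) / (2.0 * sigma**2)


def _profile_loglik_common_cv(samples: list[np.ndarray], tau: float) -> float:
    """Profile log-likelihood at common CV ``tau`` (mu_i profiled out).

    With sigma_i = tau * mu_i the per-group score in mu reduces to the
    quadratic n*tau^2*mu^2 + S1*mu - S2 = 0 with S1 = sum x, S2 = sum x^2,
    giving a closed-form positive root.
    """
    ll = 0.0
    for x in samples:
        n, s1, s2 = len(x), float(x.sum()), float((x**2).sum())
        mu = (-s1 + math.sqrt(s1**2 + 4.0 * n * tau**2 * s2)) / (2.0 * n * tau**2)
        ll += _normal_loglik(x, mu, tau * mu)
    return ll


def cv_equality_test(groups: list[np.ndarray], labels: tuple[str, ...] = ()) -> CVTestResult:
    """Test equality of normal coefficients of variation across groups.

    For two groups the statistic is the signed likelihood root
    ``r = sign(cv1-cv2) * sqrt(2 * (l_unrestricted - l_restricted))``
    with a small-sample modification ``r* = r - log(r/q)/r`` where ``q``
    is the Wald-type quantity built from the delta-method variance of
    the sample CV; the p-value is two-sided standard normal.  For more
    than two groups the unmodified likelihood ratio against chi-square
    with k-1 df is used.  Groups whose mean is near zero (|CV| > 10)
    make the CV unstable and are rejected.
    """
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    samples = [np.asarray(g, dtype=float) for g in groups]
    if any(len(x) < 3 for x in samples):
        raise ValueError("each group needs at least three observations")
    mus = [float(x.mean()) for x in samples]
    sigmas = [float(x.std(ddof=0)) for x in samples]
    if any(m == 0 or abs(s / m) > 10 for m, s in zip(mus, sigmas)):
        raise ValueError("group mean too close to zero: CV is unstable")
    cvs = tuple(s / m for s, m in zip(sigmas, mus))

    l_unres = sum(_normal_loglik(x, m, s) for x, m, s in zip(samples, mus, sigmas))
    tau0 = float(np.mean(np.abs(cvs)))
    res = optimize.minimize_scalar(
        lambda tau: -_profile_loglik_common_cv(samples, tau),
        bounds=(max(1e-6, tau0 / 50.0), abs(tau0) * 50.0 + 1.0),
        method="bounded",
        options={"xatol": 1e-10},
    )
    l_res = -float(res.fun)
    lrt = max(0.0, 2.0 * (l_unres - l_res))

    if len(samples) > 2:
        df = len(samples) - 1
        return CVTestResult(lrt, float(stats.chi2.sf(lrt, df)), cvs, df, "lrt")

    sign = math.copysign(1.0, cvs[0] - cvs[1]) if cvs[0] != cvs[1] else 0.0
    r = sign * math.sqrt(lrt)
    # Wald-type q from the delta-method variance of the sample CV:
    # Var(cv_hat) ~ cv^2 (1/2 + cv^2) / n
    var = sum(c**2 * (0.5 + c**2) / len(x) for c, x in zip(cvs, samples))
    q = (cvs[0] - cvs[1]) / math.sqrt(var)
    if abs(r) < 1e-8 or q == 0.0 or r * q <= 0:
        rstar = r
    else:
        rstar = r - math.log(r / q) / r
    p = 2.0 * float(stats.norm.sf(abs(rstar)))
    return CVTestResult(rstar, min(1.0, p), cvs, 1, "mslrt")


# --------------------------------------------------------------------------
# lag-duration correlation
# --------------------------------------------------------------------------

@dataclass
class CorrelationResult:
    label: str
    r: float
    p_value: float
    n: int
    defined: bool = True


def lag_duration_correlation(
    table: pd.DataFrame,
    lag_measure: str,
    duration_measure: str = "lx_duration_ms",
    by: str = "consonant",
) -> list[CorrelationResult]:
    """Pearson R (two-sided p) between a lag and gesture duration, per group."""
    results = []
    for key, grp in table.groupby(by, observed=True):
        pair = grp[[lag_measure, duration_measure]].dropna()
        if len(pair) < 3:
            continue
        x = pair[lag_measure].to_numpy()
        y = pair[duration_measure].to_numpy()
        if np.ptp(x) == 0 or np.ptp(y) == 0:
            results.append(CorrelationResult(str(key), math.nan, math.nan, len(pair), False))
            continue
        r, p = stats.pearsonr(x, y)
        results.append(CorrelationResult(str(key), float(r), float(p), len(pair)))
    return results


# --------------------------------------------------------------------------
# mixed-effects contract (delegated to statsmodels)
# --------------------------------------------------------------------------

@dataclass
class ModelResult:
    fixed_wald_stat: float
    fixed_df: int
    p_value: float
    params: dict[str, float] = field(default_factory=dict)
    random_effect_var: float = math.nan
    singular: bool = False
    converged: bool = True


def mixed_model_contract(
    table: pd.DataFrame,
    measure: str,
    fixed: str = "class",
    group: str = "speaker",
) -> ModelResult:
    """Random-intercept mixed model ``measure ~ C(fixed)``, groups = speaker.

    Delegated to statsmodels MixedLM; returns the joint Wald chi-square
    for the fixed factor.  Singular (boundary) random-effect variances
    are flagged, not dropped.
    """
    import statsmodels.formula.api as smf

    data = table.dropna(subset=[measure]).copy()
    if data[fixed].nunique() < 2:
        raise ValueError("fixed factor needs at least two levels")
    fixed_term = f"C(Q('{fixed}'))"
    model = smf.mixedlm(f"{measure} ~ {fixed_term}", data, groups=data[group])
    with np.errstate(all="ignore"):
        fit = model.fit(reml=True, method="lbfgs")
    names = [n for n in fit.params.index if n.startswith(fixed_term)]
    idx = [list(fit.params.index).index(n) for n in names]
    beta = fit.params.iloc[idx].to_numpy()
    cov = fit.cov_params().iloc[idx, idx].to_numpy()
    if names:
        wald = float(beta @ np.linalg.solve(cov, beta))
        p = float(stats.chi2.sf(wald, len(names)))
    else:
        wald, p = 0.0, 1.0
    re_var = float(np.asarray(fit.cov_re).ravel()[0])
    return ModelResult(
        fixed_wald_stat=wald,
        fixed_df=len(names),
        p_value=p,
        params={n: float(fit.params[n]) for n in fit.params.index},
        random_effect_var=re_var,
        singular=re_var < 1e-8,
        converged=bool(fit.converged),
    )
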