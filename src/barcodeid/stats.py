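"""Statistical layer for the benchmarking experiments.

Covers the balanced two-way mixed-model ANOVA (fixed identification
criterion x random taxonomic order) with Cochran's C homogeneity check and
Student-Newman-Keuls multiple comparisons, first-order exponential-decay
regression of success against fragment length with extra-sum-of-squares
F-tests between curves, Benjamini-Hochberg FDR correction, and ordinary
linear regression for the taxon-coverage series.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import optimize
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

__all__ = [
    "anova_2way_mixed",
    "cochran_c",
    "cell_variances",
    "snk_test",
    "SnkResult",
    "DecayFit",
    "fit_exp_decay",
    "pairwise_f_test",
    "compare_decay_curves",
    "fdr_correct",
    "LinearFit",
    "fit_linear",
]


def _stars(p: float) -> str:
    if not np.isfinite(p):
        return ""
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return "n.s."


def anova_2way_mixed(
    table: pd.DataFrame,
    response: str = "proportion_correct",
    fixed: str = "criterion",
    random: str = "order",
    replicate: str = "replicate",
) -> pd.DataFrame:
    """Balanced two-way mixed-model ANOVA (fixed x random, n replicates).

    The fixed factor is tested against the interaction mean square; the
    random factor and the interaction against the residual.  With 3
    criteria x 6 orders x 3 replicates the df column is (2, 5, 10, 36),
    total 53.  Raises on unbalanced input.
    """
    piv = table.pivot_table(
        index=fixed, columns=[random, replicate], values=response, aggfunc="first"
    )
    a = piv.shape[0]
    levels_b = table[random].nunique()
    n = table[replicate].nunique()
    if piv.isna().any().any() or piv.shape[1] != levels_b * n:
        raise ValueError("design must be balanced and complete")
    y = piv.to_numpy().reshape(a, levels_b, n)
    b = levels_b
    grand = y.mean()
    m_a = y.mean(axis=(1, 2))
    m_b = y.mean(axis=(0, 2))
    m_ab = y.mean(axis=2)
    ss_a = b * n * float(((m_a - grand) ** 2).sum())
    ss_b = a * n * float(((m_b - grand) ** 2).sum())
    ss_ab = n * float(((m_ab - m_a[:, None] - m_b[None, :] + grand) ** 2).sum())
    ss_tot = float(((y - grand) ** 2).sum())
    ss_res = ss_tot - ss_a - ss_b - ss_ab
    df_a, df_b = a - 1, b - 1
    df_ab = df_a * df_b
    df_res = a * b * (n - 1)
    ms_a, ms_b, ms_ab = ss_a / df_a, ss_b / df_b, ss_ab / df_ab
    ms_res = ss_res / df_res if df_res else math.nan

    # mean squares below floating-point dust (relative to the grand mean's
    # scale) mean the data are constant along that axis: F is undefined
    tiny = 1e-24 * max(grand * grand, 1.0)

    def _f(ms_num, ms_den, dfn, dfd):
        if not (np.isfinite(ms_den) and ms_den > tiny):
            return math.nan, math.nan
        F = ms_num / ms_den
        return F, float(sps.f.sf(F, dfn, dfd))

    f_a, p_a = _f(ms_a, ms_ab, df_a, df_ab)
    f_b, p_b = _f(ms_b, ms_res, df_b, df_res)
    f_ab, p_ab = _f(ms_ab, ms_res, df_ab, df_res)
    rows = [
        ("Cr", df_a, ss_a, ms_a, f_a, p_a, "Cr x Or"),
        ("Or", df_b, ss_b, ms_b, f_b, p_b, "Residual"),
        ("Cr x Or", df_ab, ss_ab, ms_ab, f_ab, p_ab, "Residual"),
        ("Residual", df_res, ss_res, ms_res, math.nan, math.nan, ""),
        ("Total", a * b * n - 1, ss_tot, math.nan, math.nan, math.nan, ""),
    ]
    out = pd.DataFrame(
        rows, columns=["source", "df", "SS", "MS", "F", "p", "denominator"]
    ).set_index("source")
    out["stars"] = [_stars(p) for p in out["p"]]
    return out


def cell_variances(
    table: pd.DataFrame,
    response: str = "proportion_correct",
    cell: Sequence[str] = ("criterion", "order"),
) -> np.ndarray:
    """Replicate variance of every design cell (ddof=1)."""
    return table.groupby(list(cell))[response].var(ddof=1).to_numpy()


def cochran_c(
    variances: np.ndarray, df: int, alpha: float = 0.05
) -> tuple[float, float, bool]:
    """Cochran's C homogeneity test: largest variance over the variance sum.

    ``df`` is the within-cell degrees of freedom (replicates - 1).  The
    critical value comes from the F-distribution relation
    ``C_crit = 1 / (1 + (k - 1) / F_{alpha/k}(df, (k-1) df))``.
    Returns ``(C, critical value, significant flag)``.
    """
    v = np.asarray(variances, float)
    total = v.sum()
    if total <= 0:
        return math.nan, math.nan, False
    k = v.size
    C = float(v.max() / total)
    f_crit = sps.f.isf(alpha / k, df, (k - 1) * df)
    crit = 1.0 / (1.0 + (k - 1) / f_crit)
    return C, float(crit), C > crit


@dataclass
class SnkResult:
    """Ranked means, homogeneous subsets, and a relation string."""

    labels: list[str]  # sorted by decreasing mean
    means: list[float]
    subsets: list[list[str]]
    relation: str


def snk_test(
    means: Mapping[str, float],
    ms_error: float,
    df_error: int,
    n_per_mean: int,
    alpha: float = 0.05,
) -> SnkResult:
    """Student-Newman-Keuls stepwise multiple comparison of means.

    Means are ranked and spans of size p compared against
    ``q(alpha, p, df_error) * sqrt(ms_error / n_per_mean)``; a span inside
    an already-accepted homogeneous span is never re-tested.
    """
    if df_error < 1:
        raise ValueError("df_error must be >= 1")
    items = sorted(means.items(), key=lambda kv: -kv[1])
    labels = [k for k, _ in items]
    vals = np.array([v for _, v in items], float)
    k = len(vals)
    se = math.sqrt(ms_error / n_per_mean)
    nonsig: list[tuple[int, int]] = []
    for p in range(k, 1, -1):
        qcrit = sps.studentized_range.isf(alpha, p, df_error)
        for i in range(0, k - p + 1):
            j = i + p - 1
            if any(a <= i and j <= b for a, b in nonsig):
                continue
            if vals[i] - vals[j] <= qcrit * se:
                nonsig.append((i, j))
    covered = set()
    subsets: list[list[str]] = []
    for a, b in sorted(nonsig):
        subsets.append(labels[a : b + 1])
        covered.update(range(a, b + 1))
    for i in range(k):
        if i not in covered:
            subsets.append([labels[i]])
    subsets.sort(key=lambda s: labels.index(s[0]))
    # relation string is well-defined when subsets do not overlap
    spans = [(labels.index(s[0]), labels.index(s[-1])) for s in subsets]
    chain = all(spans[i][1] < spans[i + 1][0] for i in range(len(spans) - 1))
    if chain:
        relation = " > ".join(" = ".join(s) for s in subsets)
    else:
        relation = "; ".join("{" + " = ".join(s) + "}" for s in subsets)
    return SnkResult(labels, list(vals), subsets, relation)


@dataclass
class DecayFit:
    """First-order exponential decay fit y = y0 + a * exp(-x / t)."""

    y0: float
    a: float
    t: float
    se: tuple[float, float, float]
    r2: float
    rss: float
    n: int

    def predict(self, x: np.ndarray) -> np.ndarray:
        return self.y0 + self.a * np.exp(-np.asarray(x, float) / self.t)


def _decay(x, y0, a, t):
    return y0 + a * np.exp(-x / t)


def fit_exp_decay(
    x: Sequence[float],
    y: Sequence[float],
    t_starts: Sequence[float] = (25.0, 50.0, 100.0, 200.0),
) -> DecayFit:
    """Least-squares fit of ``y0 + a exp(-x/t)`` with multi-start in t.

    Starting values: y0 at the data maximum, a at the offset of the
    shortest-x point, t over ``t_starts``; the start with the lowest
    residual sum of squares and positive t wins.  No sign constraint on a.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.size < 4:
        raise ValueError("need at least 4 points")
    if np.any(x <= 0):
        raise ValueError("x values must be > 0")
    y0_0 = float(y.max())
    a_0 = float(y[np.argmin(x)] - y0_0)
    if a_0 == 0.0:
        a_0 = -1e-3
    best = None
    errors = []
    for t0 in t_starts:
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", optimize.OptimizeWarning)
                popt, pcov = optimize.curve_fit(
                    _decay, x, y, p0=[y0_0, a_0, t0], method="lm",
                    maxfev=20000, xtol=1e-15, ftol=1e-15,
                )
        except RuntimeError as err:
            errors.append(f"t0={t0}: {err}")
            continue
        if popt[2] <= 0 or not np.all(np.isfinite(popt)):
            errors.append(f"t0={t0}: converged to non-positive time constant")
            continue
        rss = float(((y - _decay(x, *popt)) ** 2).sum())
        if best is None or rss < best[0]:
            best = (rss, popt, pcov)
    if best is None:
        raise RuntimeError("exponential-decay fit failed for all starts: " + "; ".join(errors))
    rss, popt, pcov = best
    tss = float(((y - y.mean()) ** 2).sum())
    r2 = 1.0 - rss / tss if tss > 0 else 0.0
    se = tuple(float(s) for s in np.sqrt(np.clip(np.diag(pcov), 0, np.inf)))
    return DecayFit(float(popt[0]), float(popt[1]), float(popt[2]), se, r2, rss, int(x.size))


def pairwise_f_test(fit_a: DecayFit, fit_b: DecayFit, pooled: DecayFit) -> tuple[float, float]:
    """Extra-sum-of-squares F-test between two decay curves.

    ``pooled`` must be fitted on the union of both datasets with the same
    model.  F = [(RSS_pooled - RSS_sep)/(df_pooled - df_sep)] /
    [RSS_sep/df_sep] with RSS_sep = RSS_a + RSS_b.
    """
    rss_sep = fit_a.rss + fit_b.rss
    n = fit_a.n + fit_b.n
    df_sep = n - 6
    df_pooled = n - 3
    if df_sep <= 0:
        raise ValueError("not enough points for the separate-fits model")
    F = ((pooled.rss - rss_sep) / (df_pooled - df_sep)) / (rss_sep / df_sep)
    F = max(F, 0.0)
    return float(F), float(sps.f.sf(F, df_pooled - df_sep, df_sep))


def compare_decay_curves(
    x_a: Sequence[float], y_a: Sequence[float], x_b: Sequence[float], y_b: Sequence[float]
) -> tuple[float, float]:
    """Convenience wrapper: fit A, B and pooled, then F-test the curves."""
    fa = fit_exp_decay(x_a, y_a)
    fb = fit_exp_decay(x_b, y_b)
    pooled = fit_exp_decay(np.concatenate([x_a, x_b]), np.concatenate([y_a, y_b]))
    return pairwise_f_test(fa, fb, pooled)


def fdr_correct(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values."""
    p = np.asarray(p_values, float)
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


@dataclass
class LinearFit:
    """OLS line y = a + b x with inference on both coefficients."""

    a: float
    b: float
    se_a: float
    se_b: float
    t_a: float
    t_b: float
    F: float
    r2: float
    p_F: float
    n: int


def fit_linear(x: Sequence[float], y: Sequence[float]) -> LinearFit:
    """Ordinary least squares with intercept (taxon-coverage regression)."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.size < 3:
        raise ValueError("need at least 3 points")
    if np.ptp(x) == 0:
        raise ValueError("x is degenerate (no variation)")
    model = sm.OLS(y, sm.add_constant(x)).fit()
    tss = float(((y - y.mean()) ** 2).sum())
    if tss == 0:  # constant response: a perfect flat line, no variance to explain
        return LinearFit(
            a=float(y.mean()), b=0.0, se_a=0.0, se_b=0.0, t_a=math.nan, t_b=math.nan,
            F=math.nan, r2=0.0, p_F=math.nan, n=int(x.size),
        )
    return LinearFit(
        a=float(model.params[0]),
        b=float(model.params[1]),
        se_a=float(model.bse[0]),
        se_b=float(model.bse[1]),
        t_a=float(model.tvalues[0]),
        t_b=float(model.tvalues[1]),
        F=float(model.fvalue),
        r2=float(model.rsquared),
        p_F=float(model.f_pvalue),
        n=int(x.size),
    )
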