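"""Elevational trend tests: AIC-selected polynomial regression and a
from-scratch Hoeffding's D with a permutation null.

Metrics whose residuals behave well under a transformation are tested by
ordinary least squares against elevation (degree 1 vs 2 chosen by AIC);
the remainder use Hoeffding's D, a rank-based dependence statistic that is
sensitive to non-monotonic association.  The pipeline's metric -> method
mapping: connectance is square-root transformed and regressed, generality
log transformed and regressed, richness regressed untransformed, while
vulnerability, H2' and modularity use Hoeffding's D.
"""

from __future__ import annotations

import warnings
import zlib
from dataclasses import dataclass

import numpy as np
import statsmodels.api as sm
from scipy.stats import rankdata

#: metric name -> (method, transformation) used by the pipeline
DEFAULT_TREND_SPECS = {
    "plant_richness": ("regression", "none"),
    "ant_richness": ("regression", "none"),
    "connectance": ("regression", "sqrt"),
    "generality": ("regression", "log"),
    "vulnerability": ("hoeffding", "none"),
    "h2_prime": ("hoeffding", "none"),
    "modularity_q": ("hoeffding", "none"),
}


@dataclass
class TrendTestResult:
    """One metric's elevational trend test."""

    metric: str
    method: str                    # "regression" or "hoeffding"
    transformation: str = "none"   # none | sqrt | log
    chosen_degree: int | None = None
    statistic: float = float("nan")    # F (regression) or D (hoeffding)
    r_squared: float = float("nan")
    p_value: float = float("nan")
    n: int = 0

    @property
    def defined(self) -> bool:
        return not np.isnan(self.statistic)


def _drop_undefined(x, y):
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    keep = ~(np.isnan(x) | np.isnan(y))
    return x[keep], y[keep]


def _transform(x, y, transformation: str):
    if transformation == "none":
        return y
    if transformation == "sqrt":
        if (y < 0).any():
            bad = x[y < 0][0]
            raise ValueError(f"sqrt transform of negative value at {bad:g} m")
        return np.sqrt(y)
    if transformation == "log":
        if (y <= 0).any():
            bad = x[y <= 0][0]
            raise ValueError(f"log transform of non-positive value at {bad:g} m")
        return np.log(y)
    raise ValueError(f"unknown transformation {transformation!r}")


def fit_trend(x, y, transformation: str = "none", max_degree: int = 2,
              metric: str = "") -> TrendTestResult:
    """OLS of a (transformed) metric on elevation, degree chosen by AIC.

    AIC = n ln(RSS/n) + 2k with k = degree + 2 (intercept, slope
    coefficients and error variance); additive constants cancel in the
    comparison.  The F statistic, r^2 and p-value of the selected model
    come from standard OLS theory.  Undefined metric values are dropped
    pairwise; too few points yields an undefined (NaN) result.
    """
    x, y = _drop_undefined(x, y)
    n = len(x)
    yt = _transform(x, y, transformation)
    # center/scale elevation for conditioning; fit statistics are invariant
    z = (x - x.mean()) / 100.0 if n else x

    tss = float(((yt - yt.mean()) ** 2).sum()) if n else 0.0
    # RSS below numerical noise counts as an exact fit, so the AIC ln term
    # ties and the +2k penalty prefers the simpler model
    rss_floor = max(tss * 1e-12, 1e-300)
    best = None
    for degree in range(1, max_degree + 1):
        if n < degree + 2:
            continue
        design = sm.add_constant(np.column_stack([z ** p for p in range(1, degree + 1)]))
        res = sm.OLS(yt, design).fit()
        rss = max(float(res.ssr), rss_floor)
        aic = n * np.log(rss / n) + 2 * (degree + 2)
        if best is None or aic < best[0] - 1e-12:
            best = (aic, degree, res)
    if best is None:
        return TrendTestResult(metric, "regression", transformation, None,
                               float("nan"), float("nan"), float("nan"), n)
    _, degree, res = best
    fval = float(res.fvalue)
    pval = float(res.f_pvalue)
    if not np.isfinite(fval):          # exact fit
        fval, pval = float("inf"), 0.0
    return TrendTestResult(metric, "regression", transformation, degree,
                           fval, float(res.rsquared), pval, n)


# ---------------------------------------------------------------------------
# Hoeffding's D
# ---------------------------------------------------------------------------

def hoeffding_d(x, y) -> float:
    """Hoeffding's D dependence statistic (classical scaling, in [-0.5, 1]).

    With midranks R_i, S_i and bivariate ranks Q_i (points tied on one
    coordinate count 1/2, on both 1/4):

        D1 = sum (Q_i-1)(Q_i-2)
        D2 = sum (R_i-1)(R_i-2)(S_i-1)(S_i-2)
        D3 = sum (R_i-2)(S_i-2)(Q_i-1)
        D  = 30 [(n-2)(n-3) D1 + D2 - 2(n-2) D3]
             / [n(n-1)(n-2)(n-3)(n-4)]

    Constant x or y has no rank variation; D = 0 by convention (warned).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y):
        raise ValueError("x and y must have equal length")
    n = len(x)
    if n < 5:
        raise ValueError("Hoeffding's D requires at least 5 observations")
    if np.all(x == x[0]) or np.all(y == y[0]):
        warnings.warn("constant input: Hoeffding's D set to 0 by convention")
        return 0.0
    r = rankdata(x, method="average")
    s = rankdata(y, method="average")
    # bivariate rank: 1 + strict-below-left count with half/quarter tie credit
    lx = (x[None, :] < x[:, None]).astype(float) + 0.5 * (x[None, :] == x[:, None])
    ly = (y[None, :] < y[:, None]).astype(float) + 0.5 * (y[None, :] == y[:, None])
    prod = lx * ly
    np.fill_diagonal(prod, 0.0)
    # self term contributed 0.25 via the double half-credit; diagonal removed
    q = 1.0 + prod.sum(axis=1)
    d1 = float(((q - 1) * (q - 2)).sum())
    d2 = float(((r - 1) * (r - 2) * (s - 1) * (s - 2)).sum())
    d3 = float(((r - 2) * (s - 2) * (q - 1)).sum())
    denom = n * (n - 1) * (n - 2) * (n - 3) * (n - 4)
    return float(30.0 * ((n - 2) * (n - 3) * d1 + d2 - 2 * (n - 2) * d3) / denom)


def hoeffding_test(x, y, n_perm: int = 10000, rng=None, seed: int | None = None,
                   metric: str = "") -> TrendTestResult:
    """Permutation test of Hoeffding's D (one-tailed on large D).

    y is permuted ``n_perm`` times; p uses the add-one estimator, so the
    smallest attainable p is 1/(n_perm + 1).
    """
    x, y = _drop_undefined(x, y)
    n = len(x)
    if n < 5:
        return TrendTestResult(metric, "hoeffding", "none", None,
                               float("nan"), float("nan"), float("nan"), n)
    if rng is None:
        rng = np.random.default_rng(seed)
    d_obs = hoeffding_d(x, y)
    count = 0
    obs_r = np.round(d_obs, 12)
    for _ in range(n_perm):
        d_perm = hoeffding_d(x, rng.permutation(y))
        if np.round(d_perm, 12) >= obs_r:
            count += 1
    p = (1 + count) / (n_perm + 1)
    return TrendTestResult(metric, "hoeffding", "none", None, d_obs,
                           float("nan"), float(p), n)


def trend_table(metrics_frame, trend_specs=None, n_perm: int = 10000,
                seed: int = 0):
    """Trend tests for every metric column of a per-elevation metric table.

    ``metrics_frame`` is indexed by elevation with one column per metric.
    Returns a list of TrendTestResult (one per mapped metric).
    """
    import pandas as pd

    trend_specs = trend_specs or DEFAULT_TREND_SPECS
    x = metrics_frame.index.to_numpy(dtype=float)
    results = []
    for metric, (method, transformation) in trend_specs.items():
        if metric not in metrics_frame.columns:
            continue
        y = metrics_frame[metric].to_numpy(dtype=float)
        if method == "regression":
            results.append(fit_trend(x, y, transformation, metric=metric))
        else:
            stream = zlib.crc32(metric.encode()) % (2 ** 31)
            results.append(hoeffding_test(
                x, y, n_perm=n_perm,
                rng=np.random.default_rng([int(seed), stream]),
                metric=metric))
    return results


def trends_frame(results) -> "pd.DataFrame":
    import pandas as pd

    return pd.DataFrame([{
        "metric": t.metric, "method": t.method,
        "transformation": t.transformation, "degree": t.chosen_degree,
        "statistic": t.statistic, "r2": t.r_squared, "p": t.p_value,
        "n": t.n,
    } for t in results])
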