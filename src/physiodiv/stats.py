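"""Terminal statistics: series alignment, Pearson correlation, and the
multivariate diversity regression with ANOVA.

The regression relates a (normalized) diversity curve to the physiographic
variety P_VAR and the cumulative sediment cover S_COV by ordinary least
squares with an intercept; the ANOVA table uses sequential (type I) sums
of squares.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats as sps


@dataclass
class RegressionResult:
    coefficients: dict
    r_squared: float
    f_pvalue: float
    anova: pd.DataFrame
    n_obs: int
    model: object = field(default=None, repr=False)

    def to_dict(self) -> dict:
        return dict(
            coefficients=self.coefficients,
            r_squared=self.r_squared,
            f_pvalue=self.f_pvalue,
            n_obs=self.n_obs,
            anova=self.anova.reset_index().to_dict(orient="records"),
        )


def resample_align(
    ages_a: np.ndarray,
    values_a: np.ndarray,
    ages_b: np.ndarray,
    values_b: np.ndarray,
    target_ages: np.ndarray,
) -> dict:
    """Linearly interpolate two series onto common target ages.

    Extrapolation is forbidden: target ages outside the overlap of the two
    series are dropped (their count is reported).  Returns a dict with the
    clipped age vector and both interpolated series.
    """
    def _prep(ages, values):
        a = np.asarray(ages, float)
        v = np.asarray(values, float)
        if a.size < 2:
            raise ValueError("each series needs at least 2 points")
        order = np.argsort(a)
        return a[order], v[order]

    a1, v1 = _prep(ages_a, values_a)
    a2, v2 = _prep(ages_b, values_b)
    lo = max(a1[0], a2[0])
    hi = min(a1[-1], a2[-1])
    t = np.asarray(target_ages, float)
    keep = (t >= lo) & (t <= hi)
    if not keep.any():
        raise ValueError("no overlap between the two series on the target ages")
    tt = t[keep]
    return dict(
        ages=tt,
        a=np.interp(tt, a1, v1),
        b=np.interp(tt, a2, v2),
        n_dropped=int((~keep).sum()),
    )


def pearson_correlation(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Product-moment correlation with its two-sided p-value (t, n-2 d.f.)."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.size != y.size or x.size < 3:
        raise ValueError("need two series of equal length n >= 3")
    for name, v in (("x", x), ("y", y)):
        if np.ptp(v) == 0:
            raise ValueError(f"series {name} has zero variance")
    r, p = sps.pearsonr(x, y)
    return float(r), float(p)


def minmax_normalize(v: np.ndarray) -> np.ndarray:
    v = np.asarray(v, float)
    span = np.ptp(v)
    if span == 0:
        raise ValueError("cannot min-max normalize a constant series")
    return (v - v.min()) / span


def fit_diversity_regression(
    diversity: np.ndarray,
    pvar: np.ndarray,
    scov: np.ndarray,
) -> RegressionResult:
    """OLS fit diversity ~ intercept + b_pvar*PVAR + b_scov*SCOV with a
    sequential-sum-of-squares ANOVA.

    Inputs are expected already normalized (min-max to [0, 1] over the
    analysis window; see ``minmax_normalize``).  Perfectly collinear
    predictors raise.
    """
    d = np.asarray(diversity, float)
    p = np.asarray(pvar, float)
    s = np.asarray(scov, float)
    n = d.size
    if not (p.size == s.size == n):
        raise ValueError("all series must have equal length")
    if n < 10:
        raise ValueError("need at least 10 observations")

    x = np.column_stack([np.ones(n), p, s])
    if np.linalg.matrix_rank(x) < 3:
        raise ValueError("predictors are perfectly collinear")

    model = sm.OLS(d, x).fit()
    coeffs = dict(intercept=float(model.params[0]),
                  b_pvar=float(model.params[1]),
                  b_scov=float(model.params[2]))

    # sequential (type I) ANOVA: add PVAR first, then SCOV
    def rss(cols):
        xx = x[:, cols]
        beta, *_ = np.linalg.lstsq(xx, d, rcond=None)
        resid = d - xx @ beta
        return float(resid @ resid)

    rss0 = rss([0])
    rss1 = rss([0, 1])
    rss2 = rss([0, 1, 2])
    df_resid = n - 3
    mse = rss2 / df_resid
    rows = []
    for name, ss in (("pvar", rss0 - rss1), ("scov", rss1 - rss2)):
        f = ss / mse if mse > 0 else np.inf
        pval = float(sps.f.sf(f, 1, df_resid)) if np.isfinite(f) else 0.0
        rows.append(dict(term=name, sum_sq=ss, df=1, F=f, p=pval))
    rows.append(dict(term="residual", sum_sq=rss2, df=df_resid, F=np.nan, p=np.nan))
    anova = pd.DataFrame(rows).set_index("term")

    return RegressionResult(
        coefficients=coeffs,
        r_squared=float(model.rsquared),
        f_pvalue=float(model.f_pvalue),
        anova=anova,
        n_obs=n,
        model=model,
    )


__all__ = [
    "RegressionResult",
    "resample_align",
    "pearson_correlation",
    "minmax_normalize",
    "fit_diversity_regression",
]
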