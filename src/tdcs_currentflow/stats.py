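"""Paired t-tests and simple linear regression used throughout the analysis.

The t-distribution tail probability is evaluated through the regularized
incomplete beta function: for T ~ t(df),

    P(|T| > t) = I_{df / (df + t^2)}(df/2, 1/2),

which is the closed form behind every p-value reported here (two-sided
throughout, no multiple-testing correction).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import special

from .errors import ValidationError


def t_two_sided_p(t: float, df: int) -> float:
    """Two-sided tail probability of the t distribution."""
    if df < 1:
        raise ValidationError("degrees of freedom must be >= 1")
    t = float(t)
    if t == 0.0:
        return 1.0
    x = df / (df + t * t)
    return float(special.betainc(df / 2.0, 0.5, x))


@dataclass
class TTestResult:
    t: float
    df: int
    p: float
    mean_difference: float

    def to_row(self, name: str = "") -> dict:
        return {"test": name, "t": self.t, "df": self.df, "p": self.p,
                "mean_difference": self.mean_difference}


@dataclass
class RegressionResult:
    slope: float
    intercept: float
    r_squared: float
    p: float
    n: int

    def to_row(self, name: str = "") -> dict:
        return {"test": name, "slope": self.slope, "intercept": self.intercept,
                "r_squared": self.r_squared, "p": self.p, "n": self.n}


def paired_t_test(x: np.ndarray, y: np.ndarray) -> TTestResult:
    """Paired t-test of x against y: t = mean(d) / (sd(d)/sqrt(n)), d = x - y."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValidationError("paired samples must be equal-length vectors")
    n = x.size
    if n < 3:
        raise ValidationError("need at least 3 pairs")
    d = x - y
    sd = d.std(ddof=1)
    if sd == 0:
        raise ValidationError("zero variance of paired differences")
    t = d.mean() / (sd / np.sqrt(n))
    return TTestResult(t=float(t), df=n - 1, p=t_two_sided_p(t, n - 1),
                       mean_difference=float(d.mean()))


def linear_regression(x: np.ndarray, y: np.ndarray) -> RegressionResult:
    """Ordinary least squares of y on x with R^2 and the slope's two-sided p."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValidationError("x and y must be equal-length vectors")
    n = x.size
    if n < 3:
        raise ValidationError("need at least 3 observations")
    sxx = np.sum((x - x.mean()) ** 2)
    if sxx == 0:
        raise ValidationError("constant predictor")
    sxy = np.sum((x - x.mean()) * (y - y.mean()))
    slope = sxy / sxx
    intercept = y.mean() - slope * x.mean()
    resid = y - (intercept + slope * x)
    ss_res = np.sum(resid**2)
    ss_tot = np.sum((y - y.mean()) ** 2)
    r2 = 0.0 if ss_tot == 0 else 1.0 - ss_res / ss_tot
    df = n - 2
    sigma2 = ss_res / df
    if sigma2 == 0:
        p = 0.0 if slope != 0 else 1.0
    else:
        se = np.sqrt(sigma2 / sxx)
        p = t_two_sided_p(slope / se, df)
    return RegressionResult(slope=float(slope), intercept=float(intercept),
                            r_squared=float(np.clip(r2, 0.0, 1.0)), p=float(p), n=n)
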