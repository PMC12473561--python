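"""Statistical comparisons for gait metrics.

Three analyses: pooled-variance two-sample t-tests between groups (e.g. the
sex comparison of subject-level metric means), ordinary least-squares
regression of each metric on gait speed, and a within-subject two-session
comparison run at stride level (stride-level samples are what give a single
subject enough power for per-metric tests).  With 13 metrics under test, the
significance threshold is Bonferroni-corrected to alpha/13.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import statsmodels.api as sm
from scipy import stats as sps


def bonferroni_threshold(alpha: float, m: int) -> float:
    """Corrected per-comparison significance level alpha/m."""
    if not 0.0 < alpha < 1.0:
        raise ValueError(f"alpha must be in (0, 1), got {alpha}")
    if m < 1:
        raise ValueError(f"number of comparisons must be >= 1, got {m}")
    return alpha / m


@dataclass(frozen=True)
class TTestResult:
    metric: str
    mean_a: float
    sd_a: float
    mean_b: float
    sd_b: float
    t: float
    df: int
    p: float
    significant: bool

    def row(self) -> dict:
        return {
            "metric": self.metric,
            "mean_a": self.mean_a,
            "sd_a": self.sd_a,
            "mean_b": self.mean_b,
            "sd_b": self.sd_b,
            "t": self.t,
            "df": self.df,
            "p": self.p,
            "significant": self.significant,
        }


@dataclass(frozen=True)
class RegressionResult:
    metric: str
    slope: float
    se: float
    t: float
    p: float
    r_squared: float

    def row(self) -> dict:
        return {
            "metric": self.metric,
            "beta_speed": self.slope,
            "se": self.se,
            "t": self.t,
            "p": self.p,
            "r_squared": self.r_squared,
        }


def two_sample_ttest(
    values_a, values_b, metric: str = "", threshold: float = 0.05
) -> TTestResult:
    """Pooled-variance (Student) two-sided two-sample t-test.

    df = n_a + n_b − 2.  The degenerate case of zero variance in both groups
    with equal means is reported as t = 0, p = 1 by convention.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs at least 2 values")
    df = a.size + b.size - 2
    if a.std(ddof=1) == 0.0 and b.std(ddof=1) == 0.0:
        if a.mean() == b.mean():
            t, p = 0.0, 1.0
        else:
            t, p = math.copysign(math.inf, a.mean() - b.mean()), 0.0
    else:
        res = sps.ttest_ind(a, b, equal_var=True)
        t, p = float(res.statistic), float(res.pvalue)
    return TTestResult(
        metric=metric,
        mean_a=float(a.mean()),
        sd_a=float(a.std(ddof=1)),
        mean_b=float(b.mean()),
        sd_b=float(b.std(ddof=1)),
        t=t,
        df=df,
        p=p,
        significant=p < threshold,
    )


def regress_on_speed(metric_values, speeds, metric: str = "") -> RegressionResult:
    """OLS of a subject-level metric on gait speed, with intercept.

    Reports the speed slope, its SE, t, two-sided p and R².  A constant
    regressor is a degenerate design and raises.
    """
    y = np.asarray(metric_values, dtype=float)
    x = np.asarray(speeds, dtype=float)
    if y.size != x.size:
        raise ValueError("metric values and speeds must have equal length")
    if y.size < 3:
        raise ValueError("need at least 3 subjects for the regression")
    if np.ptp(x) == 0.0:
        raise ValueError("speed is constant across subjects: degenerate design")
    model = sm.OLS(y, sm.add_constant(x)).fit()
    return RegressionResult(
        metric=metric,
        slope=float(model.params[1]),
        se=float(model.bse[1]),
        t=float(model.tvalues[1]),
        p=float(model.pvalues[1]),
        r_squared=float(model.rsquared),
    )


def compare_sessions(
    session1: dict[str, list[float]],
    session2: dict[str, list[float]],
    metrics: tuple[str, ...] | None = None,
    threshold: float = 0.05,
) -> dict[str, TTestResult]:
    """Per-metric unpaired t-tests between two recordings of one subject,
    across stride-level values.  Metrics with fewer than 2 strides in either
    session are skipped with a warning."""
    if metrics is None:
        metrics = tuple(k for k in session1 if k in session2)
    out: dict[str, TTestResult] = {}
    for m in metrics:
        a = [v for v in session1.get(m, []) if not math.isnan(v)]
        b = [v for v in session2.get(m, []) if not math.isnan(v)]
        if len(a) < 2 or len(b) < 2:
            warnings.warn(f"metric {m!r}: fewer than 2 strides in a session; skipped", stacklevel=2)
            continue
        out[m] = two_sample_ttest(a, b, metric=m, threshold=threshold)
    return out
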