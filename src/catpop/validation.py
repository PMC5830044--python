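"""Model-fit statistics for predicted vs observed abundances.

Two checks are provided: an ordinary least squares regression of
observed on predicted abundance testing the 1:1 line (intercept = 0 and
slope = 1, each with a t test on n - 2 df), and exact binomial
confidence intervals for observed sterile proportions.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from statsmodels.stats.proportion import proportion_confint

__all__ = [
    "ComparisonPair",
    "RegressionResult",
    "one_to_one_regression",
    "binomial_ci",
    "pairs_from_frame",
]


@dataclass(frozen=True)
class ComparisonPair:
    """One city's model prediction matched to an observed estimate.

    ``observed_min``/``observed_max`` hold an expert range where one was
    published; ``successes``/``trials`` hold the counts behind an
    observed proportion.
    """

    city: str
    predicted: float
    observed: float
    observed_min: float | None = None
    observed_max: float | None = None
    successes: int | None = None
    trials: int | None = None

    def __post_init__(self) -> None:
        if self.observed_min is not None and self.observed_max is not None:
            if not self.observed_min <= self.observed <= self.observed_max:
                raise ValueError(
                    f"{self.city}: observed {self.observed} outside "
                    f"[{self.observed_min}, {self.observed_max}]"
                )
        if self.trials is not None:
            if self.trials <= 0:
                raise ValueError(f"{self.city}: trials must be > 0")
            if self.successes is None or not 0 <= self.successes <= self.trials:
                raise ValueError(f"{self.city}: successes must be in [0, trials]")


@dataclass(frozen=True)
class RegressionResult:
    """OLS fit of observed on predicted with 1:1-line hypothesis tests.

    ``t_slope``/``p_slope`` test slope = 1 (not the usual slope = 0);
    ``perfect_fit`` flags an (essentially) zero-residual fit, for which
    the standard errors are degenerate.
    """

    n: int
    intercept: float
    slope: float
    se_intercept: float
    se_slope: float
    t_intercept: float
    p_intercept: float
    t_slope: float
    p_slope: float
    perfect_fit: bool

    def summary(self) -> str:
        return (
            f"observed ~ predicted (n = {self.n})\n"
            f"  intercept {self.intercept:12.4f}  (SE {self.se_intercept:.4f}, "
            f"t = {self.t_intercept:.3f} vs 0, p = {self.p_intercept:.4f})\n"
            f"  slope     {self.slope:12.4f}  (SE {self.se_slope:.4f}, "
            f"t = {self.t_slope:.3f} vs 1, p = {self.p_slope:.4f})"
            + ("\n  [perfect fit: zero residual variance]" if self.perfect_fit else "")
        )


def one_to_one_regression(
    predicted: np.ndarray, observed: np.ndarray
) -> RegressionResult:
    """Test whether (predicted, observed) pairs follow the 1:1 line.

    Ordinary least squares of observed on predicted; the intercept is
    tested against 0 and the slope against 1, two-sided on the t
    distribution with n - 2 degrees of freedom.  Needs at least three
    pairs and non-degenerate predictor variance.
    """
    x = np.asarray(predicted, dtype=float)
    y = np.asarray(observed, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("predicted and observed must be equal-length 1-d arrays")
    n = x.size
    if n < 3:
        raise ValueError(f"need at least 3 pairs, got {n}")
    if np.isclose(np.var(x), 0.0):
        raise ValueError("predictor variance is zero")
    fit = sm.OLS(y, sm.add_constant(x)).fit()
    intercept, slope = float(fit.params[0]), float(fit.params[1])
    se_i, se_s = float(fit.bse[0]), float(fit.bse[1])
    df = n - 2
    # Zero residual variance makes the t statistics 0/0 or x/0; flag it.
    tss = float(np.sum((y - y.mean()) ** 2))
    perfect = bool(fit.ssr <= 1e-12 * max(tss, 1.0))
    if perfect:
        t_i = 0.0 if math.isclose(intercept, 0.0, abs_tol=1e-9) else math.inf
        t_s = 0.0 if math.isclose(slope, 1.0, abs_tol=1e-9) else math.inf
        p_i = 1.0 if t_i == 0.0 else 0.0
        p_s = 1.0 if t_s == 0.0 else 0.0
    else:
        t_i = intercept / se_i
        t_s = (slope - 1.0) / se_s
        p_i = 2.0 * float(stats.t.sf(abs(t_i), df))
        p_s = 2.0 * float(stats.t.sf(abs(t_s), df))
    return RegressionResult(
        n=n,
        intercept=intercept,
        slope=slope,
        se_intercept=se_i,
        se_slope=se_s,
        t_intercept=t_i,
        p_intercept=p_i,
        t_slope=t_s,
        p_slope=p_s,
        perfect_fit=perfect,
    )


def binomial_ci(
    successes: int, trials: int, level: float = 0.95, method: str = "clopper-pearson"
) -> tuple[float, float]:
    """Binomial confidence interval for an observed proportion.

    Clopper-Pearson (exact, conservative) by default; Wilson score by
    ``method="wilson"``.  Endpoints are exact at the boundaries: the
    lower bound is 0 for 0 successes, the upper bound 1 for all
    successes.
    """
    if trials < 1:
        raise ValueError("trials must be >= 1")
    if not 0 <= successes <= trials:
        raise ValueError("successes must be in [0, trials]")
    if not 0.0 < level < 1.0:
        raise ValueError("level must be in (0, 1)")
    sm_method = {"clopper-pearson": "beta", "wilson": "wilson"}.get(method)
    if sm_method is None:
        raise ValueError(f"unknown method {method!r}")
    lo, hi = proportion_confint(successes, trials, alpha=1.0 - level, method=sm_method)
    return float(lo), float(hi)


def pairs_from_frame(frame: pd.DataFrame) -> list[ComparisonPair]:
    """Build comparison pairs from a frame with columns ``city``,
    ``predicted``, ``observed`` and optional range/count columns."""
    required = {"city", "predicted", "observed"}
    missing = required - set(frame.columns)
    if missing:
        raise ValueError(f"missing column(s): {sorted(missing)}")
    out = []
    for row in frame.itertuples(index=False):
        get = lambda name: getattr(row, name, None)  # noqa: E731

        def _opt(name, cast=float):
            v = get(name)
            return None if v is None or (isinstance(v, float) and math.isnan(v)) else cast(v)

        out.append(
            ComparisonPair(
                city=str(row.city),
                predicted=float(row.predicted),
                observed=float(row.observed),
                observed_min=_opt("observed_min"),
                observed_max=_opt("observed_max"),
                successes=_opt("successes", int),
                trials=_opt("trials", int),
            )
        )
    return out
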