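"""Lactation dynamics: median (tau = 0.5) regression of log concentration
on month, with rank-score confidence intervals and BH q-values.

The slope/intercept pair minimises the least-absolute-deviation criterion
``sum |y - a - b x|`` exactly, via the standard linear-programming
formulation (an optimal L1 line always interpolates at least two data
points).  Inference on the slope uses the quantile rank-score (sign-score)
test: under H0 ``b = b0`` the centred-regressor sum of residual signs is
asymptotically normal, and the confidence interval is obtained by inverting
the test over a slope grid.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import linprog
from scipy.stats import norm
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.utils.validation import check_is_fitted

from .hmotable import HMOTable
from .panel import DEFAULT_PANEL, HMOPanel
from .stats import benjamini_hochberg, class_sums, log_transform, substitute_censored

logger = logging.getLogger(__name__)

#: Grid resolution for the rank-inversion confidence bounds.
CI_GRID = 1e-3


def _l1_line(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Exact LAD line fit via linear programming (HiGHS)."""
    n = len(x)
    # variables: a, b, u_1..u_n ; minimise sum(u)
    c = np.concatenate([[0.0, 0.0], np.ones(n)])
    A = np.zeros((2 * n, n + 2))
    bvec = np.zeros(2 * n)
    A[:n, 0] = -1.0
    A[:n, 1] = -x
    A[:n, 2:] = -np.eye(n)
    bvec[:n] = -y
    A[n:, 0] = 1.0
    A[n:, 1] = x
    A[n:, 2:] = -np.eye(n)
    bvec[n:] = y
    bounds = [(None, None), (None, None)] + [(0, None)] * n
    res = linprog(c, A_ub=A, b_ub=bvec, bounds=bounds, method="highs")
    if not res.success:
        raise RuntimeError(f"L1 regression LP failed: {res.message}")
    return float(res.x[0]), float(res.x[1])


def rank_score_p(x: np.ndarray, y: np.ndarray, slope: float) -> float:
    """Two-sided sign-score test p-value for H0: slope equals ``slope``."""
    z = y - slope * x
    resid = z - np.median(z)
    signs = np.sign(resid)
    xc = x - x.mean()
    t = float(np.sum(xc * signs))
    v = float(np.sum((xc[signs != 0]) ** 2))
    if v <= 0:
        return 1.0
    zstat = t / np.sqrt(v)
    return float(2.0 * norm.sf(abs(zstat)))


def _invert_rank_test(
    x: np.ndarray, y: np.ndarray, slope: float, alpha: float = 0.05
) -> tuple[float, float]:
    """Confidence bounds by walking the slope grid away from the estimate."""
    span = max(abs(slope), np.std(y) / (np.std(x) + 1e-12), 1.0)
    step = CI_GRID

    def walk(direction: int) -> float:
        b = slope
        limit = slope + direction * 10.0 * span
        while rank_score_p(x, y, b) >= alpha:
            b += direction * step
            if (direction > 0 and b > limit) or (direction < 0 and b < limit):
                return b
        return b - direction * step

    lo, hi = walk(-1), walk(+1)
    # the point estimate always lies inside the reported interval, even if
    # the discrete sign-score test rejects at the LP optimum itself
    return min(lo, slope), max(hi, slope)


def median_regression(
    x, y, ci_alpha: float = 0.05
) -> tuple[float, float, tuple[float, float]]:
    """Median regression of y on x with a rank-inversion CI for the slope.

    Returns ``(slope, intercept, (ci_low, ci_high))``.

    Raises
    ------
    ValueError
        For fewer than 3 points or a constant regressor.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 3:
        raise ValueError("median regression needs at least 3 points")
    if np.unique(x).size < 2:
        raise ValueError("regressor is constant; slope undefined")
    a, b = _l1_line(x, y)
    ci = _invert_rank_test(x, y, b, ci_alpha)
    return b, a, ci


class MedianSlopeRegressor(BaseEstimator, RegressorMixin):
    """Scikit-learn style median (LAD) line regressor for a single covariate.

    Parameters
    ----------
    ci_alpha : float
        Significance level of the rank-inversion confidence interval.

    Attributes
    ----------
    coef_ : ndarray of shape (1,)
        Fitted slope.
    intercept_ : float
    ci_ : tuple of float
        (lower, upper) rank-inversion bounds for the slope.
    pvalue_ : float
        Sign-score test p-value for slope = 0.
    """

    def __init__(self, ci_alpha: float = 0.05):
        self.ci_alpha = ci_alpha

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        if X.ndim == 1:
            X = X[:, None]
        if X.shape[1] != 1:
            raise ValueError("MedianSlopeRegressor handles exactly one covariate")
        y = np.asarray(y, dtype=float)
        slope, intercept, ci = median_regression(X[:, 0], y, self.ci_alpha)
        self.coef_ = np.array([slope])
        self.intercept_ = intercept
        self.ci_ = ci
        self.pvalue_ = rank_score_p(X[:, 0], y, 0.0)
        self.n_features_in_ = 1
        return self

    def predict(self, X):
        check_is_fitted(self)
        X = np.asarray(X, dtype=float)
        if X.ndim == 1:
            X = X[:, None]
        return self.intercept_ + X[:, 0] * self.coef_[0]


@dataclass
class DynamicsFit:
    """Fitted lactation trend for one analyte/class within one stratum."""

    target: str
    milk_group: int | str
    coefficient: float
    intercept: float
    ci_low: float
    ci_high: float
    p: float
    q: float = float("nan")


def dynamics_table(
    table: HMOTable,
    milk_groups: dict[str, int | str],
    panel: HMOPanel = DEFAULT_PANEL,
    policy: str = "half_loq",
    q_threshold: float = 0.1,
    min_obs: int = 3,
) -> pd.DataFrame:
    """Median-regression lactation trends per (analyte, milk group) and per
    pooled HMO class, with BH q-values over the whole table.

    Repeated measures are treated as independent observations.  Strata with
    fewer than ``min_obs`` observations or a single represented month are
    skipped with a warning.  The returned frame has columns target,
    milk_group, coefficient, ci_low, ci_high, p, q and ``significant``
    (q below ``q_threshold``).
    """
    df = substitute_censored(table, policy, panel)
    df["log_value"] = log_transform(df["value"])
    df["group"] = df["sample_id"].map(milk_groups)

    fits: list[DynamicsFit] = []

    def fit_stratum(target: str, group, x: np.ndarray, y: np.ndarray) -> None:
        if len(x) < min_obs or np.unique(x).size < 2:
            logger.warning(
                "stratum (%s, %s) skipped: %d observation(s), %d month(s)",
                target, group, len(x), np.unique(x).size,
            )
            return
        slope, intercept, (lo, hi) = median_regression(x, y)
        fits.append(DynamicsFit(target, group, slope, intercept, lo, hi,
                                rank_score_p(x, y, 0.0)))

    for (analyte, group), sub in df.groupby(["analyte", "group"]):
        fit_stratum(analyte, group,
                    sub["month"].to_numpy(float), sub["log_value"].to_numpy())

    sums = class_sums(table, panel, policy="zero")
    for cls in ("core", "fucosylated", "sialylated", "total"):
        y = log_transform(sums[cls])
        fit_stratum(cls, "all", sums["month"].to_numpy(float), y)

    out = pd.DataFrame([vars(f) for f in fits])
    if len(out):
        out["q"] = benjamini_hochberg(out["p"])
        out["significant"] = out["q"] < q_threshold
    return out
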