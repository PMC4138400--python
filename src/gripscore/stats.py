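"""Analysis statistics: percent change, correlation, influence, agreement.

These are the building blocks of the pre/post assessment: percent improvement
of the tracking score, Pearson correlation between the tracking MAE and the
ODI, a simple-regression Cook's-distance screen for influential points, the
Bland–Altman method-agreement summary, and two-sample t-tests for group
contrasts.

Cook's distance is computed two ways and cross-asserted: by literally
refitting the regression without each point and summing the squared shifts of
the fitted values,

    d_i = Σ_j (ŷ_j − ŷ_{j(−i)})² / ((k+1)·s²),

and by the equivalent closed form e_i²·h_ii / ((k+1)·s²·(1−h_ii)²).  A point
is flagged as an outlier when d_i ≥ 4/(n−(k+1)); for a simple regression
(k = 1) the threshold is 4/(n−2).
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
from scipy import stats as sps

from .exceptions import (
    DegenerateInputError,
    InvalidDataError,
    InvalidParameterError,
    ShapeMismatchError,
)

__all__ = [
    "PairedScores",
    "RegressionDiagnostics",
    "CorrelationResult",
    "AgreementResult",
    "GroupComparison",
    "percent_improvement",
    "improvement_magnitude",
    "pearson",
    "fit_simple_regression",
    "cooks_distance",
    "flag_outliers",
    "bland_altman",
    "welch_t_test",
]

Z_95 = 1.96  # normal multiplier for 95% limits


@dataclass(frozen=True, eq=False)
class PairedScores:
    """Per-(subject, visit) pairs of tracking MAE and ODI on a common 0–1 scale.

    The tracking MAE in %MVC is divided by 100 before any comparison with the
    ODI so both measures live on [0, 1].
    """

    subject_ids: tuple[str, ...]
    mae_fraction: np.ndarray
    odi: np.ndarray

    def __post_init__(self) -> None:
        m = np.asarray(self.mae_fraction, dtype=float)
        o = np.asarray(self.odi, dtype=float)
        if not (len(self.subject_ids) == m.size == o.size):
            raise ShapeMismatchError("subject_ids, mae_fraction and odi must align")
        if m.size and (m.min() < 0 or m.max() > 1 or o.min() < 0 or o.max() > 1):
            raise InvalidDataError("paired scores must lie in [0, 1]")
        object.__setattr__(self, "mae_fraction", m)
        object.__setattr__(self, "odi", o)

    def __len__(self) -> int:
        return int(self.mae_fraction.size)


@dataclass(frozen=True, eq=False)
class RegressionDiagnostics:
    """OLS fit of y on x with intercept, plus influence diagnostics."""

    slope: float
    intercept: float
    fitted_values: np.ndarray
    residuals: np.ndarray
    rmse_s: float
    leverage: np.ndarray
    cooks_d: np.ndarray
    outlier_flags: np.ndarray
    n: int
    k: int = 1


@dataclass(frozen=True)
class CorrelationResult:
    r: float
    p_value: float
    n: int


@dataclass(frozen=True, eq=False)
class AgreementResult:
    """Bland–Altman summary of agreement between two measures.

    ``bias`` is the mean difference in the stated ``direction``; the limits
    of agreement bias ± 1.96·SD are expected to bracket ~95% of individual
    differences.  ``means``/``diffs`` carry the per-point plot coordinates.
    """

    bias: float
    bias_ci: tuple[float, float]
    loa_lower: float
    loa_upper: float
    sd_diff: float
    n: int
    direction: str
    means: np.ndarray = field(repr=False, default=None)
    diffs: np.ndarray = field(repr=False, default=None)


@dataclass(frozen=True)
class GroupComparison:
    mean_a: float
    sd_a: float
    n_a: int
    mean_b: float
    sd_b: float
    n_b: int
    t_statistic: float
    dof: float
    p_value: float
    variant: str = "welch"


def percent_improvement(mae_pre: float, mae_post: float) -> float:
    """(post − pre)/pre: the signed fractional change of the tracking score.

    Negative values mean the error decreased (performance improved).  Use
    :func:`improvement_magnitude` when reporting improvement as a positive
    number.
    """
    if mae_pre == 0:
        raise InvalidParameterError("percent improvement undefined for mae_pre = 0")
    return (mae_post - mae_pre) / mae_pre


def improvement_magnitude(mae_pre: float, mae_post: float) -> float:
    """−(post − pre)/pre: positive when the error decreased.

    Group tables conventionally report a drop in error as a positive
    "% Improvement"; this accessor negates the raw formula accordingly.
    """
    return -percent_improvement(mae_pre, mae_post)


def _as_paired_vectors(x: Sequence[float], y: Sequence[float], min_n: int):
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ShapeMismatchError(f"x and y must be equal-length vectors, got {x.shape}, {y.shape}")
    if x.size < min_n:
        raise InvalidParameterError(f"need at least {min_n} pairs, got {x.size}")
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise InvalidDataError("non-finite values in input")
    return x, y


def pearson(x: Sequence[float], y: Sequence[float]) -> CorrelationResult:
    """Pearson product-moment correlation with a two-sided p-value.

    p comes from t = r·√((n−2)/(1−r²)) on n−2 degrees of freedom.
    """
    x, y = _as_paired_vectors(x, y, min_n=3)
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise DegenerateInputError("pearson undefined for zero-variance input")
    res = sps.pearsonr(x, y)
    return CorrelationResult(r=float(res.statistic), p_value=float(res.pvalue), n=int(x.size))


def fit_simple_regression(x: Sequence[float], y: Sequence[float]) -> RegressionDiagnostics:
    """Ordinary least squares y = a + b·x with influence diagnostics.

    Returns fitted values, residuals, the residual RMSE s = √(Σe²/(n−k−1)),
    hat-diagonal leverages, Cook's distances (dual-route, see
    :func:`cooks_distance`) and the 4/(n−(k+1)) outlier flags.
    """
    x, y = _as_paired_vectors(x, y, min_n=4)
    n = x.size
    sxx = float(np.sum((x - x.mean()) ** 2))
    if sxx == 0:
        raise DegenerateInputError("x is constant; slope undefined")
    slope = float(np.sum((x - x.mean()) * (y - y.mean())) / sxx)
    intercept = float(y.mean() - slope * x.mean())
    fitted = intercept + slope * x
    resid = y - fitted
    k = 1
    s = float(np.sqrt(np.sum(resid**2) / (n - k - 1)))
    leverage = 1.0 / n + (x - x.mean()) ** 2 / sxx
    diag = RegressionDiagnostics(
        slope=slope,
        intercept=intercept,
        fitted_values=fitted,
        residuals=resid,
        rmse_s=s,
        leverage=leverage,
        cooks_d=np.full(n, np.nan),
        outlier_flags=np.zeros(n, dtype=bool),
        n=n,
        k=k,
    )
    d = cooks_distance(diag, x, y)
    flags = flag_outliers(d, n=n, k=k)
    object.__setattr__(diag, "cooks_d", d)
    object.__setattr__(diag, "outlier_flags", flags)
    return diag


def cooks_distance(
    diag: RegressionDiagnostics, x: Sequence[float], y: Sequence[float]
) -> np.ndarray:
    """Cook's distance of every point, by literal leave-one-out refitting.

    For each i the regression is refitted without point i and the fitted
    values of the full model are compared with the reduced model's
    predictions at all n original x's:

        d_i = Σ_j (ŷ_j − ŷ_{j(−i)})² / ((k+1)·s²).

    The closed form e_i²·h_ii/((k+1)·s²·(1−h_ii)²) is computed alongside and
    the two routes are asserted to agree; disagreement would indicate a
    numerically broken fit and raises.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n, k = diag.n, diag.k
    if n - 1 <= k + 1:
        raise DegenerateInputError(f"cannot refit with a point removed at n={n}, k={k}")
    if diag.rmse_s == 0:
        # perfect fit: removing any point cannot move it
        return np.zeros(n)
    denom = (k + 1) * diag.rmse_s**2

    d_loo = np.empty(n)
    for i in range(n):
        keep = np.ones(n, dtype=bool)
        keep[i] = False
        xi, yi = x[keep], y[keep]
        sxx = float(np.sum((xi - xi.mean()) ** 2))
        if sxx == 0:
            raise DegenerateInputError(f"x becomes constant when point {i} is removed")
        b = float(np.sum((xi - xi.mean()) * (yi - yi.mean())) / sxx)
        a = float(yi.mean() - b * xi.mean())
        fitted_loo = a + b * x  # reduced fit evaluated at all n original points
        d_loo[i] = float(np.sum((diag.fitted_values - fitted_loo) ** 2)) / denom

    h = diag.leverage
    d_closed = diag.residuals**2 * h / (denom * (1.0 - h) ** 2)
    if not np.allclose(d_loo, d_closed, rtol=1e-8, atol=1e-10):
        raise AssertionError(
            "leave-one-out and closed-form Cook's distances disagree; "
            f"max abs diff {np.max(np.abs(d_loo - d_closed)):.3e}"
        )
    return d_loo


def flag_outliers(cooks_d: Sequence[float], n: int, k: int = 1) -> np.ndarray:
    """Flag points with d_i ≥ 4/(n−(k+1)); the inequality is inclusive.

    ``n`` is the sample size of the regression the distances came from (the
    quantity entering the threshold), so a subset of distances can be
    screened against the full-fit rule.
    """
    d = np.asarray(cooks_d, dtype=float)
    if n <= k + 1:
        raise InvalidParameterError(f"threshold undefined for n={n} ≤ k+1={k + 1}")
    threshold = 4.0 / (n - (k + 1))
    return d >= threshold


def bland_altman(
    a: Sequence[float],
    b: Sequence[float],
    ci_method: Literal["normal", "t"] = "normal",
) -> AgreementResult:
    """Bland–Altman agreement between paired measures, direction a − b.

    bias = mean(a−b); limits of agreement bias ± 1.96·SD(a−b); the 95% CI of
    the bias uses ±1.96·SD/√n (``ci_method="normal"``) or the t-quantile on
    n−1 df (``ci_method="t"``).
    """
    a, b = _as_paired_vectors(a, b, min_n=3)
    diffs = a - b
    means = 0.5 * (a + b)
    n = diffs.size
    bias = float(diffs.mean())
    sd = float(diffs.std(ddof=1))
    if ci_method == "t":
        mult = float(sps.t.ppf(0.975, n - 1))
    else:
        mult = Z_95
    half_ci = mult * sd / np.sqrt(n)
    return AgreementResult(
        bias=bias,
        bias_ci=(bias - half_ci, bias + half_ci),
        loa_lower=bias - Z_95 * sd,
        loa_upper=bias + Z_95 * sd,
        sd_diff=sd,
        n=int(n),
        direction="first-second",
        means=means,
        diffs=diffs,
    )


def welch_t_test(
    sample_a: Sequence[float],
    sample_b: Sequence[float],
    variant: Literal["welch", "pooled"] = "welch",
) -> GroupComparison:
    """Two-sample t-test, Welch's unequal-variance form by default.

    Welch's form is the default because the groups being contrasted have
    grossly different spreads; ``variant="pooled"`` gives the classical
    equal-variance test.
    """
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    if a.ndim != 1 or b.ndim != 1:
        raise ShapeMismatchError("samples must be 1-D")
    if a.size < 2 or b.size < 2:
        raise InvalidParameterError("each sample needs at least 2 observations")
    if not (np.all(np.isfinite(a)) and np.all(np.isfinite(b))):
        raise InvalidDataError("non-finite values in sample")
    res = sps.ttest_ind(a, b, equal_var=(variant == "pooled"))
    return GroupComparison(
        mean_a=float(a.mean()),
        sd_a=float(a.std(ddof=1)),
        n_a=int(a.size),
        mean_b=float(b.mean()),
        sd_b=float(b.std(ddof=1)),
        n_b=int(b.size),
        t_statistic=float(res.statistic),
        dof=float(res.df),
        p_value=float(res.pvalue),
        variant=variant,
    )
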