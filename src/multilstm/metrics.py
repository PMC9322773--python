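"""Forecast evaluation metrics, each in two formula variants.

The reference results this package is benchmarked against define RMSE
with an (n - 1) denominator and R² as the explained-sum-of-squares
ratio Σ(ŷ-ȳ)²/Σ(y-ȳ)² — both different from the common conventions
(divisor n; 1 - SS_res/SS_tot).  Both variants of each are
implemented; the variant used is recorded in every report so
downstream numbers are unambiguous.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict

import numpy as np
from scipy import stats

__all__ = [
    "MetricsReport",
    "rmse",
    "mae",
    "r_squared",
    "spearman_rho",
    "paired_difference_test",
    "evaluate_predictions",
]


@dataclass
class MetricsReport:
    rmse: float
    mae: float
    r_squared: float
    spearman_rho: float
    n: int
    rmse_denominator: str  # "n-1" (sample variant) or "n"
    r2_formula: str  # "explained_ss" or "one_minus_residual_ss"
    direction: str | None = None
    n_components: int | None = None

    def to_json(self) -> str:
        return json.dumps(asdict(self))


def _pair(y, yhat) -> tuple[np.ndarray, np.ndarray]:
    a = np.asarray(y, dtype=float).ravel()
    b = np.asarray(yhat, dtype=float).ravel()
    if a.size != b.size:
        raise ValueError(f"length mismatch: {a.size} vs {b.size}")
    return a, b


def rmse(y, yhat, variant: str = "sample") -> float:
    """Root-mean-square error.

    sample variant: sqrt(Σ(y-ŷ)² / (n-1)), analogous to the sample
    standard deviation; standard variant: divisor n.
    """
    a, b = _pair(y, yhat)
    n = a.size
    ss = float(np.sum((a - b) ** 2))
    if variant == "sample":
        if n < 2:
            raise ValueError("sample-variant RMSE requires n >= 2")
        return float(np.sqrt(ss / (n - 1)))
    if variant == "standard":
        if n < 1:
            raise ValueError("empty input")
        return float(np.sqrt(ss / n))
    raise ValueError(f"unknown RMSE variant {variant!r}")


def mae(y, yhat) -> float:
    """Mean absolute error: opposite-sign errors do not cancel."""
    a, b = _pair(y, yhat)
    if a.size == 0:
        raise ValueError("empty input")
    return float(np.mean(np.abs(a - b)))


def r_squared(y, yhat, variant: str = "explained") -> float:
    """Coefficient of determination.

    explained variant: Σ(ŷ-ȳ)² / Σ(y-ȳ)² (explained-SS ratio, >= 0);
    conventional variant: 1 - Σ(y-ŷ)²/Σ(y-ȳ)².  The two agree for a
    least-squares linear fit but can disagree for arbitrary predictions.
    """
    a, b = _pair(y, yhat)
    ybar = float(np.mean(a))
    ss_tot = float(np.sum((a - ybar) ** 2))
    if ss_tot == 0.0:
        raise ValueError("zero total sum of squares (constant truth)")
    if variant == "explained":
        return float(np.sum((b - ybar) ** 2) / ss_tot)
    if variant == "conventional":
        return float(1.0 - np.sum((a - b) ** 2) / ss_tot)
    raise ValueError(f"unknown R² variant {variant!r}")


def spearman_rho(a, b) -> float:
    """Spearman rank correlation (average ranks for ties).

    Returns NaN for constant inputs, where ranks carry no information.
    """
    x, y = _pair(a, b)
    if x.size < 3:
        raise ValueError("need n >= 3 for a rank correlation")
    if np.all(x == x[0]) or np.all(y == y[0]):
        return float("nan")
    rho, _ = stats.spearmanr(x, y)
    return float(rho)


def paired_difference_test(y, yhat, method: str = "ttest") -> float:
    """Two-sided paired test of prediction-vs-truth location difference.

    Default is the paired t-test; Wilcoxon signed-rank is selectable.
    All-zero differences yield p = 1 (no evidence of difference).
    """
    a, b = _pair(y, yhat)
    if a.size < 3:
        raise ValueError("need n >= 3 for a paired test")
    d = a - b
    if np.all(d == 0):
        return 1.0
    if method == "ttest":
        if np.std(d, ddof=1) == 0:
            # constant nonzero shift: t is infinite, p -> 0
            return 0.0
        res = stats.ttest_rel(a, b)
        return float(res.pvalue)
    if method == "wilcoxon":
        res = stats.wilcoxon(a, b)
        return float(res.pvalue)
    raise ValueError(f"unknown test method {method!r}")


def evaluate_predictions(
    y,
    yhat,
    rmse_variant: str = "sample",
    r2_variant: str = "explained",
    direction: str | None = None,
    n_components: int | None = None,
) -> MetricsReport:
    """Bundle RMSE/MAE/R²/Spearman into a report with variant flags."""
    a, b = _pair(y, yhat)
    return MetricsReport(
        rmse=rmse(a, b, rmse_variant),
        mae=mae(a, b),
        r_squared=r_squared(a, b, r2_variant),
        spearman_rho=spearman_rho(a, b) if a.size >= 3 else float("nan"),
        n=a.size,
        rmse_denominator="n-1" if rmse_variant == "sample" else "n",
        r2_formula="explained_ss" if r2_variant == "explained" else "one_minus_residual_ss",
        direction=direction,
        n_components=n_components,
    )
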