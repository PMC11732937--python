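"""Intraclass correlation coefficients for observer-agreement analysis.

Implements the absolute-agreement, single-measure ICC from a two-way ANOVA
(McGraw-Wong ICC(A,1)), which covers both the two-way *mixed* model used for
intra-observer agreement and the two-way *random* model used for
inter-observer agreement — the point estimator and the F-based confidence
interval coincide for the two models in the absolute-agreement single-score
case. Values are classified on the conventional four-level scale:
poor < 0.50, moderate 0.50-0.74, good 0.75-0.89, excellent >= 0.90.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = ["RatingsTable", "ICCResult", "icc", "classify_icc"]

MODELS = ("two_way_mixed_absolute_single", "two_way_random_absolute_single")


@dataclass(frozen=True)
class RatingsTable:
    """Complete n x k matrix of measurements: rows = subjects, columns = raters
    (or measurement occasions)."""

    values: np.ndarray

    def __post_init__(self) -> None:
        vals = np.asarray(self.values, dtype=float)
        if vals.ndim != 2 or vals.shape[0] < 2 or vals.shape[1] < 2:
            raise ValueError("ratings must be an n x k matrix with n >= 2, k >= 2")
        if not np.all(np.isfinite(vals)):
            raise ValueError("ratings table must be complete (no missing cells)")
        object.__setattr__(self, "values", vals)

    @property
    def n(self) -> int:
        return self.values.shape[0]

    @property
    def k(self) -> int:
        return self.values.shape[1]


@dataclass(frozen=True)
class ICCResult:
    icc: float
    ci_low: float
    ci_high: float
    model: str
    alpha: float
    classification: str | None
    defined: bool = True
    note: str = ""


def _mean_squares(x: np.ndarray) -> tuple[float, float, float]:
    """Two-way ANOVA mean squares: rows (subjects), columns (raters), error."""
    n, k = x.shape
    grand = x.mean()
    row_means = x.mean(axis=1)
    col_means = x.mean(axis=0)
    ss_rows = k * np.sum((row_means - grand) ** 2)
    ss_cols = n * np.sum((col_means - grand) ** 2)
    ss_total = np.sum((x - grand) ** 2)
    ss_err = ss_total - ss_rows - ss_cols
    msr = ss_rows / (n - 1)
    msc = ss_cols / (k - 1)
    mse = ss_err / ((n - 1) * (k - 1))
    return float(msr), float(msc), float(mse)


def icc(
    table: RatingsTable | np.ndarray,
    model: str = "two_way_mixed_absolute_single",
    alpha: float = 0.05,
) -> ICCResult:
    """Absolute-agreement single-measure ICC with an F-based confidence interval.

    ICC(A,1) = (MSR - MSE) / (MSR + (k-1) MSE + (k/n)(MSC - MSE)), with the
    confidence interval built from the F distribution following the standard
    absolute-agreement construction. A constant table has no defined ICC and
    is returned flagged rather than raising.
    """
    if model not in MODELS:
        raise ValueError(f"model must be one of {MODELS}")
    if not isinstance(table, RatingsTable):
        table = RatingsTable(table)
    x = table.values
    n, k = table.n, table.k
    msr, msc, mse = _mean_squares(x)

    denom = msr + (k - 1) * mse + (k / n) * (msc - mse)
    if abs(denom) < 1e-300 or np.allclose(x, x.flat[0]):
        return ICCResult(
            icc=float("nan"), ci_low=float("nan"), ci_high=float("nan"),
            model=model, alpha=alpha, classification=None, defined=False,
            note="ICC undefined for a constant table (zero variance)",
        )
    value = (msr - mse) / denom

    # Satterthwaite degrees of freedom for the absolute-agreement interval
    a = (k * value) / (n * (1.0 - value)) if value < 1.0 else np.inf
    b = 1.0 + (k * value * (n - 1)) / (n * (1.0 - value)) if value < 1.0 else np.inf
    if np.isfinite(a) and np.isfinite(b):
        num = (a * msc + b * mse) ** 2
        den = (a * msc) ** 2 / (k - 1) + (b * mse) ** 2 / ((n - 1) * (k - 1))
        v_df = num / den if den > 0 else (n - 1.0)
        f1 = stats.f.ppf(1 - alpha / 2, n - 1, v_df)
        f2 = stats.f.ppf(1 - alpha / 2, v_df, n - 1)
        lo = n * (msr - f1 * mse) / (
            f1 * (k * msc + (k * n - k - n) * mse) + n * msr
        )
        hi = n * (f2 * msr - mse) / (
            k * msc + (k * n - k - n) * mse + n * f2 * msr
        )
    else:  # perfect agreement
        lo = hi = 1.0

    value = float(np.clip(value, -1.0, 1.0))
    lo = float(np.clip(lo, -1.0, value))
    hi = float(np.clip(hi, value, 1.0))
    return ICCResult(
        icc=value, ci_low=lo, ci_high=hi, model=model, alpha=alpha,
        classification=classify_icc(value) if value >= -1.0 else None,
    )


def classify_icc(value: float) -> str:
    """Four-level reliability label for an ICC value.

    poor < 0.50; moderate [0.50, 0.75); good [0.75, 0.90); excellent >= 0.90.
    The bands are half-open so every value in [-1, 1] gets exactly one label
    (e.g. 0.899 is good, 0.90 excellent).
    """
    if not -1.0 <= value <= 1.0:
        raise ValueError(f"ICC must lie in [-1, 1], got {value}")
    if value < 0.50:
        return "poor"
    if value < 0.75:
        return "moderate"
    if value < 0.90:
        return "good"
    return "excellent"
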