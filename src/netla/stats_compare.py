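"""Comparing resampling-based models: corrected resampled t-test.

Repeated train/test resampling reuses subjects across repetitions, so the
per-repetition metric differences between two models are positively
correlated and the naive resampled t-test underestimates their variance.
The corrected resampled t-test (Nadeau & Bengio) inflates the variance term
from ``1/J`` to ``1/J + n_test/n_train``::

    t = mean(d) / sqrt((1/J + n_test/n_train) * var(d))

with ``var`` the unbiased sample variance and a Student-t reference with
``J - 1`` degrees of freedom. Bonferroni adjustment handles families of such
comparisons (e.g., alpha/6 = 0.00833 for all pairs of four models).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = ["ComparisonResult", "corrected_resampled_ttest", "bonferroni_alpha", "compare_models"]


@dataclass
class ComparisonResult:
    """Outcome of one corrected resampled t-test between two models."""

    label_a: str
    label_b: str
    differences: np.ndarray  # per-repetition metric differences, a - b
    t: float
    df: int
    p: float
    alpha_adjusted: float
    significant: bool


def corrected_resampled_ttest(
    differences: np.ndarray, n_train: int, n_test: int
) -> tuple[float, float]:
    """Corrected t statistic and two-sided p for per-repetition differences.

    Zero variance with a nonzero mean yields ``t = +/-inf, p = 0``; the
    all-zero case yields ``t = 0, p = 1``.
    """
    d = np.asarray(differences, dtype=float)
    j = d.shape[0]
    if j < 2:
        raise ValueError("need at least 2 repetitions")
    if n_train <= 0 or n_test <= 0:
        raise ValueError("n_train and n_test must be positive")
    mean = d.mean()
    var = d.var(ddof=1)
    if var == 0:
        if mean == 0:
            return 0.0, 1.0
        return float(np.sign(mean) * np.inf), 0.0
    t = mean / np.sqrt((1.0 / j + n_test / n_train) * var)
    p = 2.0 * stats.t.sf(abs(t), df=j - 1)
    return float(t), float(p)


def bonferroni_alpha(alpha: float, n_tests: int) -> float:
    """Bonferroni-adjusted significance level ``alpha / n_tests``."""
    if n_tests < 1:
        raise ValueError("n_tests must be >= 1")
    return alpha / n_tests


def compare_models(
    metrics_a: np.ndarray,
    metrics_b: np.ndarray,
    n_train: int,
    n_test: int,
    label_a: str = "A",
    label_b: str = "B",
    alpha: float = 0.05,
    n_tests: int = 1,
) -> ComparisonResult:
    """Corrected resampled t-test on paired per-repetition metrics."""
    a = np.asarray(metrics_a, dtype=float)
    b = np.asarray(metrics_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("the two metric series must have equal length")
    d = a - b
    t, p = corrected_resampled_ttest(d, n_train, n_test)
    alpha_adj = bonferroni_alpha(alpha, n_tests)
    return ComparisonResult(
        label_a=label_a,
        label_b=label_b,
        differences=d,
        t=t,
        df=d.shape[0] - 1,
        p=p,
        alpha_adjusted=alpha_adj,
        significant=bool(p < alpha_adj),
    )
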