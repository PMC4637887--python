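"""Small least-squares helpers used by the association models.

All tests in the package reduce to full-vs-reduced OLS comparisons; these
helpers keep that machinery in one place (numpy lstsq + the F distribution)
so the model classes stay readable and fast inside scans.
"""

from __future__ import annotations

import numpy as np
from scipy import stats


def fit_sse(X: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, float, int]:
    """OLS fit; returns (coefficients, residual SSE, rank of X)."""
    beta, _, rank, _ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    return beta, float(resid @ resid), int(rank)


def nested_f_test(
    sse_reduced: float, rank_reduced: int, sse_full: float, rank_full: int, n: int
) -> tuple[float, float]:
    """F statistic and p-value comparing nested OLS fits.

    Degrees of freedom come from matrix ranks, so aliased columns do not
    inflate the numerator df.  Returns (nan, nan) when the comparison is
    degenerate (no added rank or no residual df).
    """
    df_num = rank_full - rank_reduced
    df_den = n - rank_full
    if df_num <= 0 or df_den <= 0:
        return float("nan"), float("nan")
    num = (sse_reduced - sse_full) / df_num
    den = sse_full / df_den
    if den <= 0.0:
        # perfect fit: any improvement is infinitely significant
        return (float("inf"), 0.0) if num > 0 else (float("nan"), float("nan"))
    f = num / den
    p = float(stats.f.sf(f, df_num, df_den))
    return float(f), p


def column_estimable(X: np.ndarray, j: int) -> bool:
    """True when column j is not aliased by the remaining columns."""
    rank_full = np.linalg.matrix_rank(X)
    rank_wo = np.linalg.matrix_rank(np.delete(X, j, axis=1))
    return rank_full > rank_wo
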