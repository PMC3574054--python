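"""Cross-task and model-vs-data comparison statistics.

Bias curves from different tasks (or from a neural-population
prediction) are compared with rank correlation, an errors-in-both-
variables regression slope, and R-squared against an external
prediction.  For paired heading-bias sets the straight-ahead and
straight-back headings (0 and 180 deg) are conventionally excluded by
the caller, since both tasks are unbiased there by symmetry.
"""

from __future__ import annotations

import numpy as np
from scipy import stats

from .errors import DegenerateInputError

__all__ = ["spearman_rho", "type2_slope", "r2_vs_prediction"]


def spearman_rho(x, y):
    """Spearman rank correlation with average ranks on ties.

    Returns (rho, two-sided p) using the large-sample approximation.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("need paired samples of equal length >= 3")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise DegenerateInputError("constant input: correlation undefined")
    rho, p = stats.spearmanr(x, y)
    return float(rho), float(p)


def type2_slope(x, y, variant: str = "sma") -> float:
    """Type II (errors-in-both-variables) regression slope.

    ``variant="sma"`` (default): standardized major axis,
    slope = sign(r) * SD(y)/SD(x) — symmetric under axis exchange up to
    the reciprocal.  ``variant="ma"``: major axis (eigenvector of the
    covariance matrix).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("need paired samples of equal length >= 3")
    sx, sy = np.std(x, ddof=1), np.std(y, ddof=1)
    if sx == 0 or sy == 0:
        raise DegenerateInputError("zero variance: slope undefined")
    r = float(np.corrcoef(x, y)[0, 1])
    sign = 1.0 if r >= 0 else -1.0
    if variant == "sma":
        return float(sign * sy / sx)
    if variant == "ma":
        cov = np.cov(x, y)
        d = cov[1, 1] - cov[0, 0]
        return float((d + np.sqrt(d**2 + 4.0 * cov[0, 1] ** 2)) / (2.0 * cov[0, 1]))
    raise ValueError(f"unknown variant {variant!r}")


def r2_vs_prediction(observed, predicted, about: str = "mean") -> float:
    """Goodness of an external prediction: 1 - SS_res / SS_tot.

    SS_tot is taken about the mean of the observed values (``about="zero"``
    uses raw sums of squares instead).  Negative values mean the
    prediction explains the data worse than the observed mean does; the
    statistic is 1 exactly when the prediction is exact.
    """
    obs = np.asarray(observed, dtype=float)
    pred = np.asarray(predicted, dtype=float)
    if obs.size != pred.size or obs.size < 2:
        raise ValueError("need equal-length sequences of >= 2 values")
    center = obs.mean() if about == "mean" else 0.0
    ss_tot = float(np.sum((obs - center) ** 2))
    if ss_tot == 0:
        raise DegenerateInputError("zero total sum of squares: R^2 undefined")
    return 1.0 - float(np.sum((obs - pred) ** 2)) / ss_tot
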