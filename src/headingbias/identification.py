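"""Reduction of heading-identification trial logs to bias curves.

Per stimulus heading: a single-pass Chauvenet-style outlier exclusion
(responses deviating more than 2.4 circular SD from the circular mean of
the presentations are dropped), then the circular mean and circular SD
of the kept responses.  Bias is the wrapped signed difference between
the mean indicated direction and the stimulus.  A degree-12 polynomial
interpolates the (stimulus, mean response) relation so that the physical
stimulus giving rise to any perceived direction can be read off and
compared with discrimination-task PSEs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from numpy.polynomial import Polynomial

from .angles import circular_mean_deg, circular_sd_deg, wrap_deg
from .errors import DegenerateInputError, OutOfDomainError

__all__ = [
    "chauvenet_filter",
    "summarize_identification",
    "ResponseCurveFit",
    "fit_response_curve",
    "bias_at_physical",
]

DEFAULT_CHAUVENET_K = 2.4


def chauvenet_filter(angles_deg, k: float = DEFAULT_CHAUVENET_K):
    """Single-pass outlier exclusion on a sample of response angles.

    Computes the circular mean m and circular SD sigma of *all* angles,
    then excludes every angle whose wrapped deviation from m exceeds
    k * sigma.  Not iterated.  A sample of identical angles has sigma = 0
    and deviations 0, so nothing is excluded.

    Returns
    -------
    (kept, excluded) : pair of ndarray
    """
    a = np.asarray(angles_deg, dtype=float)
    if a.size < 3:
        raise ValueError(f"need at least 3 angles, got {a.size}")
    m = circular_mean_deg(a)
    sigma = circular_sd_deg(a)
    dev = np.abs(wrap_deg(a - m))
    # tiny absolute slack so rounding error in the circular mean cannot
    # exclude a perfectly concentrated sample (sigma == 0, dev ~ 1e-14)
    keep = dev <= k * sigma + 1e-9
    return a[keep], a[~keep]


def summarize_identification(
    log: pd.DataFrame, k: float = DEFAULT_CHAUVENET_K
) -> pd.DataFrame:
    """Per-heading bias/variability summary of an identification log.

    Parameters
    ----------
    log : DataFrame
        Trial log with at least ``stimulus_deg`` and ``response_deg``
        columns (multiple subjects may be concatenated; all responses to
        a stimulus are pooled).

    Returns
    -------
    DataFrame ordered by stimulus with columns ``stimulus_deg,
    mean_response_deg, bias_deg, circ_sd_deg, n_kept, n_excluded,
    degenerate``.  Headings whose kept responses have a vanishing mean
    resultant are flagged ``degenerate`` with NaN summaries rather than
    silently dropped.  Groups with fewer than 3 responses skip the
    outlier pass.
    """
    if log.empty:
        raise ValueError("empty trial log")
    rows = []
    for stim, grp in log.groupby("stimulus_deg"):
        resp = grp["response_deg"].to_numpy(dtype=float)
        if resp.size >= 3:
            kept, excl = chauvenet_filter(resp, k=k)
        else:
            kept, excl = resp, np.array([])
        try:
            m = circular_mean_deg(kept)
            sd = circular_sd_deg(kept)
            rows.append(
                (stim, m, wrap_deg(m - stim), sd, kept.size, excl.size, False)
            )
        except DegenerateInputError:
            rows.append(
                (stim, np.nan, np.nan, np.nan, kept.size, excl.size, True)
            )
    out = pd.DataFrame(
        rows,
        columns=[
            "stimulus_deg",
            "mean_response_deg",
            "bias_deg",
            "circ_sd_deg",
            "n_kept",
            "n_excluded",
            "degenerate",
        ],
    )
    return out.sort_values("stimulus_deg", ignore_index=True)


@dataclass(frozen=True)
class ResponseCurveFit:
    """Degree-12 polynomial interpolation of mean response vs stimulus.

    The polynomial is fit to *unwrapped* responses (stimulus plus wrapped
    bias), so it is continuous and close to the identity line across the
    whole heading circle; extrapolation outside the fitted stimulus
    range is refused.
    """

    poly: Polynomial
    domain_deg: tuple
    residual_rmse_deg: float

    @property
    def coefficients(self) -> np.ndarray:
        """Coefficients in the ordinary power basis."""
        return self.poly.convert().coef

    def __call__(self, stimulus_deg):
        s = np.asarray(stimulus_deg, dtype=float)
        lo, hi = self.domain_deg
        if np.any(s < lo) or np.any(s > hi):
            raise OutOfDomainError(
                f"stimulus outside fitted domain [{lo}, {hi}]"
            )
        out = self.poly(s)
        return float(out) if np.ndim(stimulus_deg) == 0 else out


def fit_response_curve(curve: pd.DataFrame, degree: int = 12) -> ResponseCurveFit:
    """Least-squares polynomial fit to a per-heading summary.

    ``curve`` is a summary frame from :func:`summarize_identification`
    (needs ``stimulus_deg`` and ``bias_deg``).  Responses are unwrapped
    to ``stimulus + bias`` — continuous and near the identity — before
    fitting, because a raw polynomial cannot model the 360 deg wrap.
    """
    ok = curve.loc[~curve["bias_deg"].isna()]
    x = np.sort(wrap_deg(ok["stimulus_deg"].to_numpy(dtype=float)))
    order = np.argsort(wrap_deg(ok["stimulus_deg"].to_numpy(dtype=float)))
    y = (
        wrap_deg(ok["stimulus_deg"].to_numpy(dtype=float))
        + ok["bias_deg"].to_numpy(dtype=float)
    )[order]
    if np.unique(x).size < degree + 1:
        raise ValueError(
            f"need at least {degree + 1} distinct headings, got {np.unique(x).size}"
        )
    poly = Polynomial.fit(x, y, deg=degree)
    resid = poly(x) - y
    return ResponseCurveFit(
        poly=poly,
        domain_deg=(float(x.min()), float(x.max())),
        residual_rmse_deg=float(np.sqrt(np.mean(resid**2))),
    )


def bias_at_physical(fit: ResponseCurveFit, physical_deg: float) -> float:
    """Interpolated bias at a physical stimulus angle.

    wrap(fit(physical) - physical): the signed error a subject would
    make for that physical heading, used to pair identification data
    with discrimination PSEs subject by subject.
    """
    return float(wrap_deg(fit(physical_deg) - physical_deg))
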