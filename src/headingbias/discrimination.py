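"""Adaptive up-down staircases and psychometric fitting.

The discrimination control task finds, for each investigated heading,
the physical stimulus perceived as equal to it.  Transformed up-down
staircases drive the stimulus: the 1U1D rule converges to the 50% point
of the psychometric function (the PSE), while 2U1D and 1U2D converge to
its ~29.3% and ~70.7% points.  PSE is estimated both from the mean of
late staircase reversals and from a maximum-likelihood cumulative
Gaussian fit, whose mean and SD are the PSE and JND.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .angles import wrap_deg
from .errors import EstimationError, NonIdentifiableError
from .synthetic import Simulated2AFCObserver, respond_2afc

__all__ = [
    "StaircaseRule",
    "StaircaseBlock",
    "PsychometricFit",
    "staircase_update",
    "run_block",
    "pse_from_reversals",
    "fit_cumulative_gaussian",
    "discrimination_bias",
    "RULE_1U1D",
    "RULE_2U1D",
    "RULE_1U2D",
]


@dataclass(frozen=True)
class StaircaseRule:
    """Transformed up-down rule: n_up consecutive "less-than" responses
    raise the stimulus by one step, n_down consecutive "greater-than"
    responses lower it.  Consecutive-response counters reset whenever a
    step is taken."""

    n_up: int
    n_down: int
    step_deg: float = 4.0

    def __post_init__(self):
        if self.n_up not in (1, 2) or self.n_down not in (1, 2):
            raise ValueError("n_up and n_down must be 1 or 2")
        if self.step_deg <= 0:
            raise ValueError("step_deg must be positive")


RULE_1U1D = StaircaseRule(1, 1)
RULE_2U1D = StaircaseRule(2, 1)
RULE_1U2D = StaircaseRule(1, 2)


def staircase_update(rule: StaircaseRule, current_deg, recent_responses) -> float:
    """Next stimulus level given the responses since the last step.

    ``recent_responses`` are booleans, True = "clockwise"/"greater than
    the investigated direction" (which drives the stimulus *down*),
    False = "less than" (drives it *up*).
    """
    r = list(recent_responses)
    if not r:
        raise ValueError("recent_responses must be non-empty")
    if len(r) >= rule.n_up and not any(r[-rule.n_up :]):
        return float(current_deg) + rule.step_deg
    if len(r) >= rule.n_down and all(r[-rule.n_down :]):
        return float(current_deg) - rule.step_deg
    return float(current_deg)


@dataclass(frozen=True)
class StaircaseBlock:
    """One block of two interleaved staircases sharing an investigated
    direction.  ``trials`` has one row per trial with columns
    ``trial, staircase_id, stimulus_deg, response_cw, is_reversal``;
    reversal rows also carry the level at which the track turned."""

    investigated_deg: float
    rule: StaircaseRule
    n_trials: int
    start_offset_deg: float
    trials: pd.DataFrame

    def reversal_levels(self, staircase_id: int) -> np.ndarray:
        t = self.trials
        sel = (t["staircase_id"] == staircase_id) & (t["is_reversal"] == 1)
        return t.loc[sel, "stimulus_deg"].to_numpy(dtype=float)


class _Track:
    """Internal state of a single staircase track."""

    def __init__(self, start_level: float, rule: StaircaseRule):
        self.level = start_level
        self.rule = rule
        self.since_step: list[bool] = []
        self.last_direction = 0  # -1 down, +1 up, 0 no step yet

    def step(self, response_cw: bool) -> tuple[float, bool]:
        """Register a response; return (level presented, was a reversal)."""
        presented = self.level
        self.since_step.append(response_cw)
        new = staircase_update(self.rule, self.level, self.since_step)
        reversal = False
        if new != self.level:
            direction = 1 if new > self.level else -1
            reversal = self.last_direction == -direction
            self.last_direction = direction
            self.since_step = []
            self.level = new
        return presented, reversal


def run_block(
    observer: Simulated2AFCObserver,
    investigated_deg: float,
    rule: StaircaseRule,
    n_trials: int,
    start_offset_deg: float,
    seed: int,
) -> StaircaseBlock:
    """Run two interleaved staircases against a simulated observer.

    The descending track starts at investigated + offset, the ascending
    one at investigated - offset; trials strictly alternate between the
    two tracks (``n_trials`` each).  A trial is flagged a reversal when
    it makes its track's step direction change; the recorded reversal
    level is the stimulus at the turn.
    """
    if n_trials < 10:
        raise ValueError("need at least 10 trials per staircase")
    rng = np.random.default_rng(seed)
    tracks = [
        _Track(investigated_deg + start_offset_deg, rule),
        _Track(investigated_deg - start_offset_deg, rule),
    ]
    rows = []
    for t in range(n_trials):
        for sid, track in enumerate(tracks):
            stim = track.level
            cw = respond_2afc(observer, stim, rng)
            _, reversal = track.step(cw)
            rows.append((2 * t + sid + 1, sid, stim, int(cw), int(reversal)))
    trials = pd.DataFrame(
        rows,
        columns=["trial", "staircase_id", "stimulus_deg", "response_cw", "is_reversal"],
    )
    return StaircaseBlock(
        investigated_deg=float(investigated_deg),
        rule=rule,
        n_trials=int(n_trials),
        start_offset_deg=float(start_offset_deg),
        trials=trials,
    )


def pse_from_reversals(block: StaircaseBlock, n_ignore: int = 4) -> float:
    """PSE estimate: mean of reversal levels, discarding the first
    ``n_ignore`` reversals of each staircase track."""
    kept = []
    total = 0
    for sid in sorted(block.trials["staircase_id"].unique()):
        revs = block.reversal_levels(sid)
        total += revs.size
        kept.extend(revs[n_ignore:])
    if total < n_ignore + 2 or not kept:
        raise EstimationError(
            f"too few reversals ({total}) to estimate a PSE", n_reversals=total
        )
    return float(np.mean(kept))


@dataclass(frozen=True)
class PsychometricFit:
    """Cumulative-Gaussian psychometric function P(cw|x) = Phi((x-PSE)/JND)."""

    pse_deg: float
    jnd_deg: float
    n_trials_used: int
    lapse_rate: float = 0.0


def fit_cumulative_gaussian(
    levels, n_cw, n_total, lapse_rate: float = 0.0
) -> PsychometricFit:
    """Maximum-likelihood cumulative-Gaussian fit to grouped 2AFC data.

    Binomial likelihood of "clockwise" counts at each stimulus level under
    P(cw|x) = lapse/2 + (1 - lapse) * Phi((x - PSE)/JND).  No lapse by
    default; a small fixed lapse (e.g. 0.01) can be supplied for
    robustness to stray responses.

    Raises
    ------
    NonIdentifiableError
        If fewer than 3 distinct levels, the levels have no span, or the
        responses never leave one category.
    """
    x = np.asarray(levels, dtype=float)
    cw = np.asarray(n_cw, dtype=float)
    n = np.asarray(n_total, dtype=float)
    if not (x.shape == cw.shape == n.shape):
        raise ValueError("levels, n_cw and n_total must have equal length")
    if np.unique(x).size < 3 or np.ptp(x) <= 0:
        raise NonIdentifiableError("need >= 3 distinct stimulus levels")
    if cw.sum() == 0 or cw.sum() == n.sum():
        raise NonIdentifiableError("responses are all in one category")

    span = max(np.ptp(x), 1e-6)

    def nll(params):
        pse, log_jnd = params
        p = stats.norm.cdf((x - pse) / np.exp(log_jnd))
        p = lapse_rate / 2.0 + (1.0 - lapse_rate) * p
        p = np.clip(p, 1e-12, 1.0 - 1e-12)
        return -np.sum(cw * np.log(p) + (n - cw) * np.log1p(-p))

    # moment-style start: PSE near the 50% crossing, JND from the span
    p_obs = cw / np.maximum(n, 1.0)
    pse0 = float(np.interp(0.5, np.sort(p_obs), x[np.argsort(p_obs)]))
    x0 = np.array([pse0, np.log(span / 4.0)])
    res = optimize.minimize(
        nll, x0, method="Nelder-Mead",
        options={"xatol": 1e-10, "fatol": 1e-12, "maxiter": 20000, "maxfev": 20000},
    )
    pse, jnd = float(res.x[0]), float(np.exp(res.x[1]))
    return PsychometricFit(
        pse_deg=pse, jnd_deg=jnd, n_trials_used=int(n.sum()), lapse_rate=lapse_rate
    )


def discrimination_bias(investigated_deg: float, pse_deg: float) -> float:
    """Signed discrimination-task bias: wrap(investigated - PSE).

    An investigated direction of -90 with a PSE of -75 gives -15, i.e.
    a 15 deg overestimation of heading eccentricity.
    """
    return float(wrap_deg(investigated_deg - pse_deg))
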