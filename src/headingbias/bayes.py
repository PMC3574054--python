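"""Bayesian observer with a bimodal lateral prior.

The model explains heading bias as maximum-a-posteriori estimation: an
unbiased Gaussian likelihood centered on the stimulus, whose SD grows
with heading eccentricity, is multiplied by a prior that is the sum of
two equal Gaussians centered at +90 and -90 deg.  The single free
parameter is the common SD of the prior components, sigma_prior.  A
narrow prior pulls estimates toward lateral headings, reproducing the
overestimation of forward headings; the flat-prior limit reproduces the
identity.

Both likelihood and prior are wrapped onto the circle and the posterior
is maximized on a dense grid over (-180, 180].  The model is exactly
left/right symmetric, so predicted bias is antisymmetric in heading and
zero at 0 and 180 (symmetric posterior ties resolve to the stimulus).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .angles import wrap_deg

__all__ = [
    "LikelihoodProfile",
    "BimodalPrior",
    "ModelFit",
    "likelihood_sd",
    "map_estimate",
    "predict_bias_curve",
    "fit_sigma_prior",
    "vestibular_likelihood_default",
    "visual_likelihood_default",
]

DEFAULT_GRID_STEP_DEG = 0.1


@dataclass(frozen=True)
class LikelihoodProfile:
    """Heading-dependent likelihood SD, piecewise linear in |heading|.

    ``nodes`` is a sequence of (heading_deg, sd_deg) pairs on [0, 180];
    the profile is symmetric about straight ahead by construction.
    """

    nodes: tuple

    def __post_init__(self):
        nodes = tuple(sorted((float(h), float(s)) for h, s in self.nodes))
        if not nodes:
            raise ValueError("need at least one node")
        if any(s <= 0 for _, s in nodes):
            raise ValueError("likelihood SDs must be positive")
        if nodes[0][0] < 0 or nodes[-1][0] > 180:
            raise ValueError("nodes must lie on [0, 180] degrees")
        object.__setattr__(self, "nodes", nodes)

    def sd(self, heading_deg):
        h = np.abs(wrap_deg(heading_deg))
        xs = np.array([n[0] for n in self.nodes])
        ys = np.array([n[1] for n in self.nodes])
        out = np.interp(h, xs, ys)
        return float(out) if np.ndim(heading_deg) == 0 else out


def likelihood_sd(profile: LikelihoodProfile, heading_deg: float) -> float:
    """Likelihood SD at a heading (piecewise-linear interpolation on |heading|)."""
    return profile.sd(heading_deg)


def vestibular_likelihood_default() -> LikelihoodProfile:
    """Illustrative vestibular likelihood-SD table (editable config).

    Shape: lowest noise straight ahead, increasing with eccentricity.
    The node values are plausible magnitudes chosen for simulation; they
    are not a published table.
    """
    return LikelihoodProfile(((0.0, 12.0), (45.0, 18.0), (90.0, 26.0),
                              (135.0, 33.0), (180.0, 38.0)))


def visual_likelihood_default() -> LikelihoodProfile:
    """Illustrative visual likelihood-SD table (lower noise than vestibular,
    with extrapolated backward-heading values)."""
    return LikelihoodProfile(((0.0, 4.0), (45.0, 8.0), (90.0, 12.0),
                              (135.0, 16.0), (180.0, 20.0)))


@dataclass(frozen=True)
class BimodalPrior:
    """Sum of two equal-weight Gaussians at +/-90 deg with common SD."""

    sigma_prior_deg: float
    peak_locations_deg: tuple = (90.0, -90.0)

    def __post_init__(self):
        if self.sigma_prior_deg <= 0:
            raise ValueError("sigma_prior_deg must be positive")


def _grid(step_deg: float) -> np.ndarray:
    n = int(round(360.0 / step_deg))
    # (-180, 180]: symmetric about 0 apart from the single endpoint at 180
    return wrap_deg((np.arange(n) + 1) * step_deg - 180.0)


def _wrapped_gaussian(grid: np.ndarray, mu: float, sd: float) -> np.ndarray:
    """Unnormalized wrapped Gaussian density on the grid (k = -3..3 images)."""
    out = np.zeros_like(grid)
    for k in range(-3, 4):
        out += np.exp(-((grid - mu + 360.0 * k) ** 2) / (2.0 * sd**2))
    return out


def _prior_density(prior: BimodalPrior, grid: np.ndarray) -> np.ndarray:
    dens = np.zeros_like(grid)
    for mu in prior.peak_locations_deg:
        dens += _wrapped_gaussian(grid, mu, prior.sigma_prior_deg)
    return dens


def map_estimate(
    stimulus_deg: float,
    prior: BimodalPrior,
    lik: LikelihoodProfile,
    grid_step_deg: float = DEFAULT_GRID_STEP_DEG,
) -> float:
    """Maximum-a-posteriori heading estimate for one stimulus.

    The likelihood is a wrapped Gaussian centered on the stimulus with
    SD evaluated at the stimulus angle.  Posterior ties (relative
    plateau within 1e-9 of the maximum) are broken toward the stimulus;
    an exactly symmetric pair of maxima returns the stimulus itself.
    """
    if grid_step_deg > 0.5:
        raise ValueError("grid_step_deg must be <= 0.5 for a usable argmax")
    s = wrap_deg(stimulus_deg)
    grid = _grid(grid_step_deg)
    post = _wrapped_gaussian(grid, s, lik.sd(s)) * _prior_density(prior, grid)
    m = post.max()
    cand = grid[post >= m * (1.0 - 1e-9)]
    dist = np.abs(wrap_deg(cand - s))
    best = dist.min()
    near = cand[dist <= best + grid_step_deg / 2.0]
    if near.size > 1:
        signs = np.sign(wrap_deg(near - s))
        if (signs > 0).any() and (signs < 0).any():
            return float(s)  # symmetric tie -> no bias
    return float(cand[np.argmin(dist)])


def predict_bias_curve(
    prior: BimodalPrior,
    lik: LikelihoodProfile,
    headings_deg,
    grid_step_deg: float = DEFAULT_GRID_STEP_DEG,
) -> pd.DataFrame:
    """Predicted MAP bias at each heading.

    The model is exactly mirror-symmetric, so the curve is computed for
    |heading| and antisymmetrized (bias(-h) = -bias(h); 0 at 0 and 180),
    which also guarantees the symmetry holds to the last bit.
    """
    stim = wrap_deg(np.asarray(headings_deg, dtype=float))
    mag = np.unique(np.abs(stim))
    bias_mag = {}
    for h in mag:
        if h in (0.0, 180.0):
            bias_mag[h] = 0.0
        else:
            bias_mag[h] = wrap_deg(
                map_estimate(h, prior, lik, grid_step_deg) - h
            )
    bias = np.array([np.sign(s) * bias_mag[abs(s)] if abs(s) in bias_mag else 0.0
                     for s in stim])
    # sign(180) is positive already; sign(0) zeroes the entry as required
    return pd.DataFrame({"stimulus_deg": stim, "bias_deg": bias})


@dataclass(frozen=True)
class ModelFit:
    """Result of the one-parameter prior fit."""

    sigma_prior_hat_deg: float
    r_squared: float
    residuals_deg: np.ndarray
    at_boundary: bool
    scanned_sigmas_deg: np.ndarray = field(repr=False, default=None)
    scanned_sse: np.ndarray = field(repr=False, default=None)


def _likelihood_matrix(
    headings: np.ndarray, lik: LikelihoodProfile, grid: np.ndarray
) -> np.ndarray:
    return np.stack([_wrapped_gaussian(grid, h, lik.sd(h)) for h in headings])


def fit_sigma_prior(
    observed: pd.DataFrame,
    lik: LikelihoodProfile,
    search_range_deg: tuple = (5.0, 120.0),
    scan_step_deg: float = 0.5,
    grid_step_deg: float = DEFAULT_GRID_STEP_DEG,
) -> ModelFit:
    """Least-squares fit of sigma_prior to an observed bias curve.

    Dense scan of sigma_prior over ``search_range_deg`` at
    ``scan_step_deg`` resolution, minimizing the sum of squared
    differences between observed and predicted per-heading bias.
    R^2 = 1 - SS_res / SS_tot about the mean observed bias (negative
    when the model does worse than that mean; 0 by convention when the
    observed biases are constant).  A minimum on the edge of the search
    range sets ``at_boundary``.
    """
    stim = wrap_deg(observed["stimulus_deg"].to_numpy(dtype=float))
    obs = observed["bias_deg"].to_numpy(dtype=float)
    if stim.size < 8:
        raise ValueError("need at least 8 headings to constrain the prior")

    grid = _grid(grid_step_deg)
    # exploit mirror symmetry: predict only positive heading magnitudes
    mags = np.unique(np.abs(stim))
    free = np.array([m for m in mags if m not in (0.0, 180.0)])
    L = _likelihood_matrix(free, lik, grid)

    sigmas = np.arange(
        search_range_deg[0], search_range_deg[1] + scan_step_deg / 2, scan_step_deg
    )
    sse = np.empty(sigmas.size)
    pred_cache = {}
    for i, sig in enumerate(sigmas):
        dens = _prior_density(BimodalPrior(sig), grid)
        post = L * dens[None, :]
        est = grid[np.argmax(post, axis=1)]
        bias_mag = dict(zip(free, wrap_deg(est - free)))
        bias_mag[0.0] = 0.0
        bias_mag[180.0] = 0.0
        pred = np.array([np.sign(s) * bias_mag[abs(s)] if s != 180.0
                         else 0.0 for s in stim])
        pred_cache[i] = pred
        sse[i] = np.sum((obs - pred) ** 2)

    # ties resolve to the largest sigma: the flattest prior consistent
    # with the data (an all-zero bias curve lands on the flat boundary)
    i_best = int(np.where(sse <= sse.min() + 1e-12)[0][-1])
    pred = pred_cache[i_best]
    ss_tot = float(np.sum((obs - obs.mean()) ** 2))
    r2 = 0.0 if ss_tot == 0.0 else 1.0 - float(sse[i_best]) / ss_tot
    return ModelFit(
        sigma_prior_hat_deg=float(sigmas[i_best]),
        r_squared=r2,
        residuals_deg=obs - pred,
        at_boundary=i_best in (0, sigmas.size - 1),
        scanned_sigmas_deg=sigmas,
        scanned_sse=sse,
    )
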