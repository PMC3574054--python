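"""Synthetic observers, experiment designs and neural populations.

No behavioral data from the original experiments are deposited anywhere,
so the pipeline is exercised end-to-end on simulated inputs:

* identification observers that report a heading equal to the stimulus
  plus a systematic lateral bias and wrapped circular noise,
* 2AFC observers with a cumulative-Gaussian response rule (the standard
  signal-detection model behind staircase discrimination),
* direction-tuned neural populations — otolith-afferent-like units whose
  horizontal polarization azimuths cluster near +/-50 deg, and
  cortical-like (MSTd analog) cosine-tuned units clustering near
  +/-90 deg.

Every simulation takes an explicit integer seed; there is no global RNG
state, and identical seeds reproduce identical outputs byte for byte.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .angles import wrap_deg

__all__ = [
    "IdentificationDesign",
    "SimulatedIdentificationObserver",
    "Simulated2AFCObserver",
    "Neuron",
    "NeuralPopulation",
    "default_bias_fn",
    "simulate_identification",
    "respond_2afc",
    "make_afferent_population",
    "make_cosine_population",
]

#: default lateral-bias amplitude (deg); the largest behavioral biases are
#: on the order of |6| deg, peaking between forward and lateral headings
DEFAULT_BIAS_AMPLITUDE_DEG = 6.0


def default_bias_fn(heading_deg):
    """Lateral-attraction bias b(theta) = 6 sin(2 theta) degrees.

    Positive (overestimation, pushed toward +/-90) for forward-oblique
    headings, negative for backward-oblique ones, zero at 0, +/-90, 180.
    """
    return DEFAULT_BIAS_AMPLITUDE_DEG * np.sin(2.0 * np.deg2rad(heading_deg))


def _default_headings() -> np.ndarray:
    return wrap_deg(np.arange(0.0, 360.0, 7.5))


@dataclass(frozen=True)
class IdentificationDesign:
    """Heading-identification session layout.

    Defaults follow the standard design: 5 blocks, each containing two
    repetitions of 48 headings spanning the full circle in 7.5 deg steps
    (480 trials per subject, 10 presentations per heading).
    """

    headings_deg: np.ndarray = field(default_factory=_default_headings)
    n_blocks: int = 5
    reps_per_block: int = 2

    @property
    def n_trials(self) -> int:
        return self.n_blocks * self.reps_per_block * len(self.headings_deg)


@dataclass(frozen=True)
class SimulatedIdentificationObserver:
    """Generative model of an identification subject.

    response = wrap(stimulus + bias_fn(stimulus) + N(0, noise_sd_fn(stimulus)))
    with probability ``lapse_rate`` the response is replaced by a uniform
    draw on (-180, 180] (an accidental early button press).
    """

    bias_fn: Callable = default_bias_fn
    noise_sd_fn: Callable = lambda theta: np.full_like(
        np.asarray(theta, dtype=float), 5.0
    )
    lapse_rate: float = 0.0

    def __post_init__(self):
        if not 0.0 <= self.lapse_rate < 1.0:
            raise ValueError(f"lapse_rate must be in [0, 1), got {self.lapse_rate}")


@dataclass(frozen=True)
class Simulated2AFCObserver:
    """Cumulative-Gaussian 2AFC observer.

    P(respond "clockwise" | stimulus s) = Phi((s - pse_true) / jnd_true).
    """

    pse_true_deg: float
    jnd_true_deg: float

    def __post_init__(self):
        if self.jnd_true_deg <= 0:
            raise ValueError(f"jnd_true_deg must be positive, got {self.jnd_true_deg}")

    def p_clockwise(self, stimulus_deg):
        z = (np.asarray(stimulus_deg, dtype=float) - self.pse_true_deg) / (
            self.jnd_true_deg
        )
        return stats.norm.cdf(z)


def simulate_identification(
    observer: SimulatedIdentificationObserver,
    design: IdentificationDesign,
    seed: int,
) -> pd.DataFrame:
    """Simulate one subject's identification session.

    Returns a trial log with one row per trial and columns
    ``block, presentation, stimulus_deg, response_deg``.  Presentation
    order is randomized independently within each block.
    """
    rng = np.random.default_rng(seed)
    rows = []
    headings = np.asarray(design.headings_deg, dtype=float)
    for block in range(1, design.n_blocks + 1):
        stims = np.tile(headings, design.reps_per_block)
        rng.shuffle(stims)
        sd = np.asarray(observer.noise_sd_fn(stims), dtype=float)
        resp = wrap_deg(
            stims + np.asarray(observer.bias_fn(stims), dtype=float)
            + rng.normal(0.0, 1.0, size=stims.size) * sd
        )
        if observer.lapse_rate > 0.0:
            lapse = rng.random(stims.size) < observer.lapse_rate
            resp = np.where(lapse, wrap_deg(rng.uniform(-180.0, 180.0, stims.size)), resp)
        for i, (s, r) in enumerate(zip(stims, resp), start=1):
            rows.append((block, i, s, r))
    return pd.DataFrame(
        rows, columns=["block", "presentation", "stimulus_deg", "response_deg"]
    )


def respond_2afc(
    observer: Simulated2AFCObserver, stimulus_deg: float, rng: np.random.Generator
) -> bool:
    """One Bernoulli 2AFC response: True = "clockwise of the reference"."""
    return bool(rng.random() < observer.p_clockwise(stimulus_deg))


# ---------------------------------------------------------------------------
# neural populations
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Neuron:
    """Direction-tuned unit in the linear otolith-afferent firing model
    d = s (F . P) + d0.

    polarization_vec is the unit vector P of maximal sensitivity in
    head-fixed coordinates (x forward, y leftward, z up); ``sensitivity``
    s is in spikes/s per g and ``resting_discharge`` d0 in spikes/s.
    """

    polarization_vec: np.ndarray
    sensitivity: float
    resting_discharge: float

    def __post_init__(self):
        p = np.asarray(self.polarization_vec, dtype=float)
        if p.shape != (3,):
            raise ValueError("polarization_vec must be a 3-vector")
        if abs(np.linalg.norm(p) - 1.0) > 1e-9:
            raise ValueError("polarization_vec must be a unit vector")
        if self.sensitivity <= 0:
            raise ValueError("sensitivity must be positive")
        if self.resting_discharge < 0:
            raise ValueError("resting_discharge must be non-negative")
        object.__setattr__(self, "polarization_vec", p)

    @classmethod
    def from_angles(
        cls,
        azimuth_deg: float,
        elevation_deg: float,
        sensitivity: float,
        resting_discharge: float,
    ) -> "Neuron":
        """Build a neuron from its polarization azimuth/elevation.

        Azimuth follows the heading convention (positive = rightward);
        elevation is positive upward.
        """
        az = np.deg2rad(azimuth_deg)
        el = np.deg2rad(elevation_deg)
        p = np.array(
            [np.cos(el) * np.cos(az), -np.cos(el) * np.sin(az), np.sin(el)]
        )
        return cls(p, sensitivity, resting_discharge)

    @property
    def azimuth_deg(self) -> float:
        x, y, _ = self.polarization_vec
        return wrap_deg(np.rad2deg(np.arctan2(-y, x)))

    @property
    def elevation_deg(self) -> float:
        return float(np.rad2deg(np.arcsin(np.clip(self.polarization_vec[2], -1, 1))))


@dataclass(frozen=True)
class NeuralPopulation:
    """A list of neurons plus a laterality tag.

    ``laterality`` is "left-only" for a single-labyrinth population or
    "bilateral" once mirrored about the mid-sagittal plane.
    """

    neurons: tuple
    laterality: str = "left-only"

    def __post_init__(self):
        if self.laterality not in ("left-only", "bilateral"):
            raise ValueError(f"unknown laterality {self.laterality!r}")
        object.__setattr__(self, "neurons", tuple(self.neurons))

    def __len__(self) -> int:
        return len(self.neurons)

    @property
    def azimuths_deg(self) -> np.ndarray:
        return np.array([n.azimuth_deg for n in self.neurons])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "azimuth_deg": [n.azimuth_deg for n in self.neurons],
                "elevation_deg": [n.elevation_deg for n in self.neurons],
                "sensitivity": [n.sensitivity for n in self.neurons],
                "resting_discharge": [n.resting_discharge for n in self.neurons],
            }
        )


def make_afferent_population(
    n: int,
    azimuth_peak_deg: float = 50.0,
    azimuth_spread_deg: float = 30.0,
    elevation_limit_deg: float = 60.0,
    mean_sensitivity: float = 35.0,
    mean_resting: float = 90.0,
    seed: int = 0,
) -> NeuralPopulation:
    """Left-labyrinth otolith-afferent-like population.

    Horizontal-projection azimuths are drawn from a von Mises
    distribution centered at ``azimuth_peak_deg`` (default +50 deg; the
    bilateral mirror supplies the -50 deg peak).  Elevations are uniform
    within +/-``elevation_limit_deg``; sensitivities and resting
    discharges are drawn around plausible otolith-afferent magnitudes
    (they cancel or scale uniformly in the decoder, so their exact
    distributions do not move decoded angles).
    """
    if n < 1:
        raise ValueError("need at least one neuron")
    rng = np.random.default_rng(seed)
    kappa = 1.0 / np.deg2rad(azimuth_spread_deg) ** 2
    az = np.rad2deg(
        rng.vonmises(np.deg2rad(azimuth_peak_deg), kappa, size=n)
    )
    el = rng.uniform(-elevation_limit_deg, elevation_limit_deg, size=n)
    s = np.clip(rng.normal(mean_sensitivity, mean_sensitivity / 4.0, size=n), 1.0, None)
    d0 = np.clip(rng.normal(mean_resting, mean_resting / 4.0, size=n), 0.0, None)
    neurons = [
        Neuron.from_angles(a, e, si, d)
        for a, e, si, d in zip(az, el, s, d0)
    ]
    return NeuralPopulation(neurons, laterality="left-only")


def make_cosine_population(
    n: int,
    azimuth_peaks_deg: Sequence[float] = (90.0, -90.0),
    azimuth_spread_deg: float = 35.0,
    seed: int = 0,
) -> NeuralPopulation:
    """Bilateral cosine-tuned population (cortical MSTd analog).

    Preferred directions form a mirror-symmetric two-component circular
    mixture: n/2 azimuths are drawn from a von Mises component centered
    at the first peak and each is paired with its mid-sagittal mirror,
    so the bilateral symmetry is exact by construction.  Units are
    horizontal (elevation 0) with unit sensitivity and zero resting
    discharge, which makes the peak-to-trough response exactly
    cosine-tuned in heading.

    ``azimuth_spread_deg = inf`` gives the uniform special case: the
    n/2 base azimuths are placed on an even grid over the circle, so the
    population covers all directions with no sampling clumps.
    """
    if n < 2:
        raise ValueError("need at least two neurons")
    if n % 2:
        raise ValueError("bilateral population size must be even")
    rng = np.random.default_rng(seed)
    half = n // 2
    if np.isinf(azimuth_spread_deg):
        base = wrap_deg(np.arange(half) * 360.0 / half + 180.0 / half)
    else:
        kappa = 1.0 / np.deg2rad(azimuth_spread_deg) ** 2
        base = np.rad2deg(
            rng.vonmises(np.deg2rad(azimuth_peaks_deg[0]), kappa, size=half)
        )
    neurons = []
    for a in base:
        neurons.append(Neuron.from_angles(a, 0.0, 1.0, 0.0))
        neurons.append(Neuron.from_angles(-a, 0.0, 1.0, 0.0))
    return NeuralPopulation(neurons, laterality="bilateral")
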