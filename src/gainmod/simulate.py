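"""Generative model of speed-modulated, direction-tuned neurons.

Each simulated neuron pools 1 or 2 von-Mises direction subunits.  A subunit's
response to a grating drifting at angle ``phi`` is

    r_i(phi) = exp(kappa * (cos(phi - phi_i) - 1)),

the von-Mises profile normalized so its maximum is 1 (``phi_i`` preferred
direction, ``kappa = 4`` tuning width).  The gain of each subunit depends on
running speed ``s`` through a modulator

    m_i(s) = sum_j w_ij * exp(-(s - s_j)^2 / sigma^2),

a linear combination of 8 Gaussian radial basis functions with peaks linearly
spaced on [0, 20] cm/s and width ``sigma^2 = 10``.  The modulator acts
multiplicatively after exponentiation, so the trial response is

    r(s, phi) = sum_i r_i(phi) * exp(m_i(s)) + eta,

with additive Gaussian noise eta (sd 0.2 by default).  Two-subunit neurons
come in two flavours: *shared* modulation (both subunits use the same
modulator, yielding symmetric orientation tuning) and *independent*
modulation (separate random modulators; the weaker subunit's basis weights
are reduced by a single Uniform[0, 0.2] draw to create a strength asymmetry).

The module also emulates trial tables in the format of the two-photon
recordings the analysis was designed for: long-format rows of
(neuron, response, direction, temporal frequency, running speed, duration).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .binning import DIRECTIONS_DEG, DIRECTIONS_RAD, SPEED_MAX, TF_HZ

__all__ = [
    "SimSubunit",
    "SimNeuron",
    "TRIAL_COLUMNS",
    "speed_basis",
    "modulator_value",
    "sample_neuron",
    "simulate_response",
    "generate_trials",
    "uniform_speed_sampler",
    "rest_lognormal_speed_sampler",
]

#: Column schema of a trial table.
TRIAL_COLUMNS = [
    "neuron_id",
    "response",
    "direction_deg",
    "tf_hz",
    "speed_cmps",
    "duration_s",
]

N_BASIS = 8
BASIS_WIDTH = 10.0  # sigma^2 of the Gaussian radial basis functions
DEFAULT_KAPPA = 4.0
DEFAULT_NOISE_SD = 0.2
DEFAULT_FRAME_PERIOD_S = 1.0 / 30.0


def speed_basis(n_basis: int = N_BASIS, speed_range=(0.0, SPEED_MAX), width: float = BASIS_WIDTH):
    """Peak positions of the speed-modulator radial basis, linearly spaced
    over ``speed_range`` inclusive of both endpoints.

    ``width`` is the (shared) squared width sigma^2 of the Gaussian bumps; it
    does not affect the peak positions but is validated here because the two
    always travel together.
    """
    if n_basis < 2:
        raise ValueError("need at least 2 basis functions")
    if width <= 0:
        raise ValueError("basis width must be positive")
    lo, hi = speed_range
    return np.linspace(lo, hi, n_basis)


def modulator_value(weights, s, peaks=None, width: float = BASIS_WIDTH):
    """Evaluate a speed modulator m(s) = sum_j w_j exp(-(s - s_j)^2 / sigma^2).

    Parameters
    ----------
    weights : (8,) array_like
        Basis coefficients.
    s : float or array_like
        Running speed(s), cm/s.
    peaks : array_like, optional
        Basis peak positions; defaults to :func:`speed_basis`.
    width : float
        Squared basis width sigma^2 (default 10).
    """
    w = np.asarray(weights, dtype=float)
    if peaks is None:
        peaks = speed_basis(len(w), width=width)
    s = np.asarray(s, dtype=float)
    if not np.all(np.isfinite(s)):
        raise ValueError("speed must be finite")
    if width <= 0:
        raise ValueError("basis width must be positive")
    # basis matrix: (..., n_basis)
    phi = np.exp(-((s[..., None] - peaks) ** 2) / width)
    return phi @ w


@dataclass
class SimSubunit:
    """One von-Mises direction subunit with a speed modulator.

    Attributes
    ----------
    preferred_direction : float
        Preferred drift direction, radians on [-pi, pi).
    kappa : float
        von-Mises concentration (tuning width); must be positive.
    weights : (8,) ndarray
        Coefficients of the speed-modulator radial basis.
    """

    preferred_direction: float
    kappa: float = DEFAULT_KAPPA
    weights: np.ndarray = field(default_factory=lambda: np.zeros(N_BASIS))

    def __post_init__(self):
        self.weights = np.asarray(self.weights, dtype=float)
        if self.kappa <= 0:
            raise ValueError("kappa must be positive")
        if self.weights.shape != (N_BASIS,):
            raise ValueError(f"weights must have shape ({N_BASIS},)")
        if not np.all(np.isfinite(self.weights)):
            raise ValueError("weights must be finite")
        # wrap to [-pi, pi)
        self.preferred_direction = float(
            math.remainder(self.preferred_direction, 2 * math.pi)
        )
        if self.preferred_direction == math.pi:
            self.preferred_direction = -math.pi

    def tuning(self, phi):
        """Max-normalized von-Mises direction tuning at angle(s) ``phi``."""
        phi = np.asarray(phi, dtype=float)
        return np.exp(self.kappa * (np.cos(phi - self.preferred_direction) - 1.0))

    def modulator(self, s):
        """Speed modulator m(s) of this subunit."""
        return modulator_value(self.weights, s)


@dataclass
class SimNeuron:
    """A simulated neuron pooling 1 or 2 speed-modulated subunits.

    ``modulation_mode`` records how the subunit modulators were generated:
    ``"none"`` (zero weights, flat gain), ``"shared"`` (identical modulators,
    enforced) or ``"independent"``.  ``tf_gain`` optionally scales responses
    by a per-temporal-frequency factor (all ones leaves the generative model
    untouched; it exists so frequency-coverage QC filters can be exercised).
    """

    subunits: Sequence[SimSubunit]
    modulation_mode: str = "independent"
    noise_sd: float = DEFAULT_NOISE_SD
    tf_gain: np.ndarray = field(default_factory=lambda: np.ones(len(TF_HZ)))

    def __post_init__(self):
        self.subunits = list(self.subunits)
        if len(self.subunits) not in (1, 2):
            raise ValueError("a neuron has 1 or 2 subunits")
        if self.modulation_mode not in ("none", "shared", "independent"):
            raise ValueError(f"unknown modulation mode {self.modulation_mode!r}")
        if self.modulation_mode == "shared" and len(self.subunits) == 2:
            if not np.array_equal(self.subunits[0].weights, self.subunits[1].weights):
                raise ValueError("shared mode requires identical subunit weights")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        self.tf_gain = np.asarray(self.tf_gain, dtype=float)
        if self.tf_gain.shape != (len(TF_HZ),):
            raise ValueError(f"tf_gain must have shape ({len(TF_HZ)},)")
        if np.any(self.tf_gain < 0):
            raise ValueError("tf_gain entries must be non-negative")

    def mean_response(self, phi, s):
        """Noiseless response: sum over subunits of tuning * exp(modulator)."""
        phi = np.asarray(phi, dtype=float)
        s = np.asarray(s, dtype=float)
        out = np.zeros(np.broadcast(phi, s).shape)
        for su in self.subunits:
            out = out + su.tuning(phi) * np.exp(su.modulator(s))
        return out

    def response_grid(self, phis, speeds):
        """Noiseless responses on the outer grid ``phis`` x ``speeds``.

        Returns an array of shape ``(len(phis), len(speeds))``; used by the
        population decoder, where the per-subunit factorization keeps the
        evaluation cheap.
        """
        phis = np.asarray(phis, dtype=float)
        speeds = np.asarray(speeds, dtype=float)
        out = np.zeros((phis.size, speeds.size))
        for su in self.subunits:
            out += np.outer(su.tuning(phis), np.exp(su.modulator(speeds)))
        return out


def sample_neuron(
    mode: str,
    n_subunits: int,
    rng: np.random.Generator,
    *,
    kappa: float = DEFAULT_KAPPA,
    weight_sd: float = 0.5,
    weak_offset_range=(0.0, 0.2),
    noise_sd: float = DEFAULT_NOISE_SD,
    antipodal: bool = True,
    tf_gain=None,
) -> SimNeuron:
    """Draw a random neuron from the generative model.

    Basis weights are drawn i.i.d. Normal(0, ``weight_sd``) per subunit.  In
    ``shared`` mode the second subunit reuses the first subunit's weights; in
    ``independent`` mode with two subunits the second subunit is designated
    the weaker one and a single Uniform ``weak_offset_range`` draw is
    subtracted from each of its weights.  ``none`` mode zeroes all weights
    (unit gain at every speed, an unmodulated control).  Preferred directions
    are uniform on the circle; with ``antipodal=True`` (default) the second
    subunit sits opposite the first, instantiating orientation tuning.
    """
    if n_subunits not in (1, 2):
        raise ValueError("n_subunits must be 1 or 2")
    if mode not in ("none", "shared", "independent"):
        raise ValueError(f"unknown modulation mode {mode!r}")

    pref0 = rng.uniform(-math.pi, math.pi)
    if antipodal:
        prefs = [pref0, pref0 + math.pi]
    else:
        prefs = [pref0, rng.uniform(-math.pi, math.pi)]
    prefs = prefs[:n_subunits]

    if mode == "none":
        weight_sets = [np.zeros(N_BASIS) for _ in prefs]
    elif mode == "shared":
        w = rng.normal(0.0, weight_sd, size=N_BASIS)
        weight_sets = [w.copy() for _ in prefs]
    else:  # independent
        weight_sets = [rng.normal(0.0, weight_sd, size=N_BASIS) for _ in prefs]
        if n_subunits == 2:
            offset = rng.uniform(*weak_offset_range)
            weight_sets[1] = weight_sets[1] - offset

    subunits = [
        SimSubunit(preferred_direction=p, kappa=kappa, weights=w)
        for p, w in zip(prefs, weight_sets)
    ]
    if tf_gain is None:
        tf_gain = np.ones(len(TF_HZ))
    return SimNeuron(
        subunits=subunits,
        modulation_mode=mode,
        noise_sd=noise_sd,
        tf_gain=tf_gain,
    )


def simulate_response(neuron: SimNeuron, phi, s, rng: np.random.Generator | None = None):
    """One noisy response of ``neuron`` to direction ``phi`` (rad), speed ``s``.

    Accepts scalars or broadcastable arrays; a single Gaussian noise draw (sd
    ``neuron.noise_sd``) is added per element.  With ``noise_sd == 0`` no rng
    is required and the closed-form noiseless response is returned.
    """
    mean = neuron.mean_response(phi, s)
    if neuron.noise_sd == 0:
        return mean
    if rng is None:
        raise ValueError("rng required when noise_sd > 0")
    return mean + rng.normal(0.0, neuron.noise_sd, size=np.shape(mean))


def uniform_speed_sampler(low: float = 0.0, high: float = SPEED_MAX) -> Callable:
    """Running speeds uniform on [low, high] (the simulation-study condition)."""

    def sampler(rng: np.random.Generator, n: int):
        return rng.uniform(low, high, size=n)

    return sampler


def rest_lognormal_speed_sampler(
    rest_prob: float = 0.4,
    log_mean: float = 1.5,
    log_sd: float = 0.8,
    max_speed: float = SPEED_MAX,
) -> Callable:
    """Mouse-like running-speed distribution for protocol-style trials.

    A mixture of a point mass at 0 cm/s (rest, probability ``rest_prob``) and
    a log-normal truncated to (0, ``max_speed``] for running bouts.  This
    produces the unbalanced speed-bin occupancy that the QC filters are
    designed to catch in real recordings.
    """

    def sampler(rng: np.random.Generator, n: int):
        resting = rng.random(n) < rest_prob
        speeds = np.zeros(n)
        n_run = int((~resting).sum())
        draws = rng.lognormal(log_mean, log_sd, size=n_run)
        # redraw values above the truncation point
        bad = draws > max_speed
        while bad.any():
            draws[bad] = rng.lognormal(log_mean, log_sd, size=int(bad.sum()))
            bad = draws > max_speed
        speeds[~resting] = draws
        return speeds

    return sampler


def generate_trials(
    neurons: Sequence[SimNeuron],
    n_trials: int,
    rng: np.random.Generator,
    *,
    speed_sampler: Callable | None = None,
    mode: str = "discrete_stimuli",
    frame_period_s: float = DEFAULT_FRAME_PERIOD_S,
    s_max: float = SPEED_MAX,
) -> pd.DataFrame:
    """Simulate a trial table for a population of neurons.

    All neurons experience the same stimulus/speed sequence (as in a
    simultaneous population recording) with independent response noise.

    ``discrete_stimuli`` mode draws directions and temporal frequencies
    uniformly from the fixed stimulus sets ({0,45,...,315} deg x
    {1,2,4,8,15} Hz) and speeds from ``speed_sampler`` (default: the
    rest + log-normal mixture).  ``continuous_stimuli`` mode draws directions
    uniformly on the circle and speeds uniformly on [0, 20]; temporal
    frequency is not defined there and the column is NaN.

    Each row represents ``frame_period_s`` seconds of data (one imaging
    frame).  Returns a long-format DataFrame with columns
    :data:`TRIAL_COLUMNS`, reproducible bit-for-bit under a fixed rng.
    """
    neurons = list(neurons)
    if not neurons:
        raise ValueError("neuron list must be non-empty")
    if n_trials <= 0:
        raise ValueError("n_trials must be positive")
    if frame_period_s <= 0:
        raise ValueError("frame_period_s must be positive")

    if mode == "discrete_stimuli":
        if speed_sampler is None:
            speed_sampler = rest_lognormal_speed_sampler()
        dir_deg = rng.choice(DIRECTIONS_DEG, size=n_trials)
        phi = DIRECTIONS_RAD[(dir_deg // 45).astype(int)]
        tf_idx = rng.integers(0, len(TF_HZ), size=n_trials)
        tf = TF_HZ[tf_idx].astype(float)
        speeds = np.asarray(speed_sampler(rng, n_trials), dtype=float)
    elif mode == "continuous_stimuli":
        phi = rng.uniform(-math.pi, math.pi, size=n_trials)
        dir_deg = np.degrees(phi) % 360.0
        tf_idx = None
        tf = np.full(n_trials, np.nan)
        speeds = rng.uniform(0.0, s_max, size=n_trials)
    else:
        raise ValueError(f"unknown trial mode {mode!r}")

    if np.any(speeds < 0) or np.any(speeds > s_max):
        raise ValueError(f"speed sampler produced values outside [0, {s_max}]")

    frames = []
    for j, neuron in enumerate(neurons):
        mean = neuron.mean_response(phi, speeds)
        if tf_idx is not None:
            mean = mean * neuron.tf_gain[tf_idx]
        resp = mean
        if neuron.noise_sd > 0:
            resp = mean + rng.normal(0.0, neuron.noise_sd, size=n_trials)
        frames.append(
            pd.DataFrame(
                {
                    "neuron_id": j,
                    "response": resp,
                    "direction_deg": dir_deg.astype(float),
                    "tf_hz": tf,
                    "speed_cmps": speeds,
                    "duration_s": frame_period_s,
                }
            )
        )
    return pd.concat(frames, ignore_index=True)[TRIAL_COLUMNS]
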