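"""MAP population decoding of stimulus direction and running speed.

Simulated downstream readout: a population of speed-modulated neurons
responds to a (direction, speed) pair with independent Gaussian noise; the
decoder evaluates the joint likelihood on a discretized grid, marginalizes
to per-variable posteriors and reports their maxima.  Priors are uniform,
so MAP coincides with maximum likelihood.

Three neuron architectures are compared: direction-selective (one subunit
with its own random speed modulator), orientation-selective with shared
modulation (two antipodal subunits, one common modulator — direction is
fundamentally ambiguous, pinning the mean angular error near pi/2), and
orientation-selective with independently modulated subunits, which recover
direction information because behavior breaks the symmetry between the two
preferred directions.  A data-matched variant decodes from fitted 8 x 8
tuning curves on the discrete stimulus grid instead of the generative model.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .binning import DIRECTIONS_RAD, SPEED_CENTERS, SPEED_MAX
from .simulate import SimNeuron, sample_neuron

__all__ = [
    "DecodingGrid",
    "DecodingErrorCurve",
    "map_decode",
    "angular_error",
    "speed_error",
    "run_experiment",
    "data_matched_experiment",
    "matched_size_ratio",
    "DEFAULT_SIZES",
]

DEFAULT_SIZES = (2, 4, 8, 16, 32, 64, 128)

NEURON_TYPES = {
    "DS": ("independent", 1),
    "OS_shared": ("shared", 2),
    "OS_independent": ("independent", 2),
}


@dataclass
class DecodingGrid:
    """Discretization of the (direction, speed) plane for the decoder."""

    direction_points: np.ndarray = field(
        default_factory=lambda: np.linspace(-math.pi, math.pi, 120, endpoint=False)
    )
    speed_points: np.ndarray = field(
        default_factory=lambda: np.linspace(0.0, SPEED_MAX, 81)
    )

    def __post_init__(self):
        self.direction_points = np.asarray(self.direction_points, dtype=float)
        self.speed_points = np.asarray(self.speed_points, dtype=float)
        for pts, name in (
            (self.direction_points, "direction"),
            (self.speed_points, "speed"),
        ):
            if pts.size < 8:
                raise ValueError(f"need at least 8 {name} points")
            if np.any(np.diff(pts) <= 0):
                raise ValueError(f"{name} points must be strictly increasing")


@dataclass
class DecodingErrorCurve:
    """Decoding error versus population size (mean and sd across random
    populations; direction error in radians, speed error in (cm/s)^2)."""

    population_sizes: np.ndarray
    direction_error_mean: np.ndarray
    direction_error_sd: np.ndarray
    speed_error_mean: np.ndarray
    speed_error_sd: np.ndarray


def _population_grid_responses(population: Sequence[SimNeuron], grid: DecodingGrid):
    """Noiseless mean responses of each neuron on the grid: (n, D, S)."""
    return np.stack(
        [nrn.response_grid(grid.direction_points, grid.speed_points) for nrn in population]
    )


def _decode_batch(responses: np.ndarray, mu: np.ndarray, noise_sd: float):
    """MAP decode a (T, n) response batch given grid means mu (n, D, S).

    Returns direction and speed grid indices (T,) plus the normalized
    marginal posteriors.  Argmax ties resolve to the lowest grid index.
    """
    T = responses.shape[0]
    n, D, S = mu.shape
    mu2 = mu.reshape(n, D * S)
    # -||r - mu||^2 / (2 sigma^2), expanded for one matmul
    ll = (
        2.0 * responses @ mu2
        - (mu2**2).sum(axis=0)[None, :]
        - (responses**2).sum(axis=1)[:, None]
    ) / (2.0 * noise_sd**2)
    ll -= ll.max(axis=1, keepdims=True)
    post = np.exp(ll).reshape(T, D, S)
    p_dir = post.sum(axis=2)
    p_speed = post.sum(axis=1)
    p_dir /= p_dir.sum(axis=1, keepdims=True)
    p_speed /= p_speed.sum(axis=1, keepdims=True)
    return p_dir.argmax(axis=1), p_speed.argmax(axis=1), p_dir, p_speed


def map_decode(
    responses,
    population: Sequence[SimNeuron],
    grid: DecodingGrid | None = None,
    noise_sd: float = 0.2,
    return_posteriors: bool = False,
):
    """MAP estimates of stimulus direction and speed from population responses.

    ``responses`` is an (n,) vector (one trial) or a (T, n) batch aligned
    with ``population``.  Assumes independent Gaussian response noise of
    known sd and uniform priors; the joint posterior is evaluated on the
    grid and marginalized, and each marginal's argmax is returned (ties at
    the lowest grid index).
    """
    if len(population) == 0:
        raise ValueError("population must be non-empty")
    if grid is None:
        grid = DecodingGrid()
    r = np.atleast_2d(np.asarray(responses, dtype=float))
    if r.shape[1] != len(population):
        raise ValueError("responses must align with the population")
    mu = _population_grid_responses(population, grid)
    ik, il, p_dir, p_speed = _decode_batch(r, mu, noise_sd)
    phi_hat = grid.direction_points[ik]
    s_hat = grid.speed_points[il]
    if np.asarray(responses).ndim == 1:
        phi_hat, s_hat = float(phi_hat[0]), float(s_hat[0])
        p_dir, p_speed = p_dir[0], p_speed[0]
    if return_posteriors:
        return phi_hat, s_hat, p_dir, p_speed
    return phi_hat, s_hat


def angular_error(phi, phi_hat):
    """Circular distance min(|d|, 2 pi - |d|), radians in [0, pi]."""
    d = np.abs(np.asarray(phi, dtype=float) - np.asarray(phi_hat, dtype=float))
    d = np.mod(d, 2 * math.pi)
    out = np.minimum(d, 2 * math.pi - d)
    return out if out.ndim else float(out)


def speed_error(s, s_hat):
    """Squared speed-decoding error, (cm/s)^2."""
    out = (np.asarray(s, dtype=float) - np.asarray(s_hat, dtype=float)) ** 2
    return out if out.ndim else float(out)


def run_experiment(
    neuron_type: str,
    sizes=DEFAULT_SIZES,
    n_pops: int = 500,
    n_trials: int = 500,
    rng: np.random.Generator | None = None,
    grid: DecodingGrid | None = None,
    noise_sd: float = 0.2,
) -> DecodingErrorCurve:
    """Decoding-error curve for random populations of one architecture.

    For each population size, ``n_pops`` random populations are drawn from
    the generative model; each decodes ``n_trials`` random (direction,
    speed) pairs (direction uniform on the circle, speed uniform on
    [0, 20]).  Per-population mean errors are aggregated into mean and sd
    across populations.
    """
    if neuron_type not in NEURON_TYPES:
        raise ValueError(f"unknown neuron type {neuron_type!r}")
    if rng is None:
        raise ValueError("a seeded rng is required")
    if grid is None:
        grid = DecodingGrid()
    mode, n_subunits = NEURON_TYPES[neuron_type]

    sizes = np.asarray(sizes, dtype=int)
    dir_mean, dir_sd, sp_mean, sp_sd = [], [], [], []
    for size in sizes:
        pop_dir = np.empty(n_pops)
        pop_sp = np.empty(n_pops)
        for p in range(n_pops):
            population = [
                sample_neuron(mode, n_subunits, rng, noise_sd=noise_sd)
                for _ in range(size)
            ]
            mu = _population_grid_responses(population, grid)
            phi = rng.uniform(-math.pi, math.pi, size=n_trials)
            s = rng.uniform(0.0, SPEED_MAX, size=n_trials)
            mean_resp = np.stack(
                [nrn.mean_response(phi, s) for nrn in population], axis=1
            )
            r = mean_resp + rng.normal(0.0, noise_sd, size=mean_resp.shape)
            ik, il, _, _ = _decode_batch(r, mu, noise_sd)
            pop_dir[p] = angular_error(phi, grid.direction_points[ik]).mean()
            pop_sp[p] = speed_error(s, grid.speed_points[il]).mean()
        dir_mean.append(pop_dir.mean())
        dir_sd.append(pop_dir.std())
        sp_mean.append(pop_sp.mean())
        sp_sd.append(pop_sp.std())
    return DecodingErrorCurve(
        population_sizes=sizes,
        direction_error_mean=np.array(dir_mean),
        direction_error_sd=np.array(dir_sd),
        speed_error_mean=np.array(sp_mean),
        speed_error_sd=np.array(sp_sd),
    )


def _normalize_curves(curves: np.ndarray) -> np.ndarray:
    peaks = curves.reshape(curves.shape[0], -1).max(axis=1)
    if np.any(peaks <= 0):
        raise ValueError("curves must have a positive maximum")
    return curves / peaks[:, None, None]


def data_matched_experiment(
    curves,
    mode: str = "as_is",
    sizes=DEFAULT_SIZES,
    n_pops: int = 200,
    n_trials: int = 1000,
    rng: np.random.Generator | None = None,
    noise_sd: float = 0.2,
    shared_control_curves=None,
) -> DecodingErrorCurve:
    """Decoding from empirical (fitted) tuning curves on the discrete grid.

    ``curves`` is a collection of 8 x 8 direction-speed curves (or
    decomposition results, from which the model curve is taken); each is
    normalized to maximum 1.  Stimuli are the 8 experimental directions and
    the 8 speed bins; responses are the curve value at the sampled
    (direction, bin) pair plus Gaussian noise.  ``mode="shared_control"``
    instead decodes from curves rebuilt with both subunit modulators
    replaced by their average (pass decomposition results, or provide
    ``shared_control_curves`` directly), restoring the direction ambiguity
    of shared modulation.
    """
    if rng is None:
        raise ValueError("a seeded rng is required")
    if mode not in ("as_is", "shared_control"):
        raise ValueError(f"unknown mode {mode!r}")
    bank = _curve_bank(curves, mode, shared_control_curves)
    if bank.shape[0] == 0:
        raise ValueError("empty curve collection")
    bank = _normalize_curves(bank)

    speed_pts = SPEED_CENTERS
    dir_pts = DIRECTIONS_RAD
    sizes = np.asarray(sizes, dtype=int)
    dir_mean, dir_sd, sp_mean, sp_sd = [], [], [], []
    for size in sizes:
        pop_dir = np.empty(n_pops)
        pop_sp = np.empty(n_pops)
        for p in range(n_pops):
            members = bank[rng.integers(0, bank.shape[0], size=size)]  # (n, 8, 8)
            k = rng.integers(0, 8, size=n_trials)
            l = rng.integers(0, 8, size=n_trials)
            mean_resp = members[:, k, l].T  # (T, n)
            r = mean_resp + rng.normal(0.0, noise_sd, size=mean_resp.shape)
            ik, il, _, _ = _decode_batch(r, members, noise_sd)
            pop_dir[p] = angular_error(dir_pts[k], dir_pts[ik]).mean()
            pop_sp[p] = speed_error(speed_pts[l], speed_pts[il]).mean()
        dir_mean.append(pop_dir.mean())
        dir_sd.append(pop_dir.std())
        sp_mean.append(pop_sp.mean())
        sp_sd.append(pop_sp.std())
    return DecodingErrorCurve(
        population_sizes=sizes,
        direction_error_mean=np.array(dir_mean),
        direction_error_sd=np.array(dir_sd),
        speed_error_mean=np.array(sp_mean),
        speed_error_sd=np.array(sp_sd),
    )


def _curve_bank(curves, mode, shared_control_curves):
    from .decomposition import SubunitDecompositionResults

    if mode == "shared_control" and shared_control_curves is not None:
        return np.stack([np.asarray(c, dtype=float) for c in shared_control_curves])
    out = []
    for c in curves:
        if isinstance(c, SubunitDecompositionResults):
            if mode == "shared_control":
                from .modulators import _top2_significant

                g = c.scaled_modulators.copy()
                i, j = _top2_significant(c)
                g[[i, j]] = 0.5 * (g[i] + g[j])[None, :]
                out.append(g)
            else:
                out.append(c.model.curve)
        else:
            if mode == "shared_control":
                raise ValueError(
                    "shared_control requires decomposition results or "
                    "shared_control_curves"
                )
            out.append(np.asarray(c, dtype=float))
    return np.stack(out) if out else np.empty((0, 8, 8))


def matched_size_ratio(err_a: DecodingErrorCurve, err_b: DecodingErrorCurve) -> float:
    """How many times larger a type-A population must be to match type-B
    speed-decoding error.

    For each type-B point whose error lies inside type-A's error range, the
    type-A population size achieving that error is log-log interpolated
    from A's curve; the geometric mean of the size ratios is returned.
    """
    ea = np.asarray(err_a.speed_error_mean, dtype=float)
    eb = np.asarray(err_b.speed_error_mean, dtype=float)
    na = np.asarray(err_a.population_sizes, dtype=float)
    nb = np.asarray(err_b.population_sizes, dtype=float)
    # interpolate log2(size_a) as a function of log(error): errors decrease
    # with size, so sort by error ascending
    order = np.argsort(ea)
    xe, xs = np.log(ea[order]), np.log2(na[order])
    ratios = []
    for n_i, e_i in zip(nb, eb):
        if not (xe[0] <= np.log(e_i) <= xe[-1]):
            continue
        log2_na = np.interp(np.log(e_i), xe, xs)
        ratios.append(log2_na - np.log2(n_i))
    if not ratios:
        raise ValueError("error curves do not overlap; ratio undefined")
    return float(2.0 ** np.mean(ratios))
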