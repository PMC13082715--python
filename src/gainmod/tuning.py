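"""Trial preprocessing, tuning tensors, QC filters and the speed-modulation test.

The analysis path for one neuron is:

1. :func:`threshold_normalize` — clip negative dF/F-like values to zero and
   divide by the standard deviation of the thresholded trace.
2. :func:`build_tensor` — bin normalized responses by the 8 directions,
   5 temporal frequencies and 8 speed bins into a 3-D tuning tensor.
3. :func:`qc_filters` — reject neurons with empty direction-speed bins,
   under-sampled bins (< 1 s of data) or uneven temporal-frequency coverage.
4. :func:`average_frequency` — collapse the frequency axis into the 8 x 8
   direction-speed tuning curve R.
5. :func:`specificity` — entropy-based sharpness S of the speed-averaged
   direction tuning (0 = untuned, 1 = responds to a single direction).
6. :func:`test_modulation` — bootstrap test of speed modulation: shuffling
   responses across speeds within each (direction, frequency) stratum
   destroys speed structure while preserving sensory tuning and per-bin
   sample counts; the statistic d_mod sums, over speed bins, the Euclidean
   distance between each speed slice of R and the speed-averaged tuning.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .binning import (
    DIRECTIONS_DEG,
    EXCLUDED,
    N_DIRECTIONS,
    N_SPEED_BINS,
    N_TF,
    SPEED_CENTERS,
    SPEED_EDGES,
    assign_speed_bin,
    direction_index,
    tf_index,
)

__all__ = [
    "DegenerateNeuronError",
    "TuningTensor3D",
    "DirectionSpeedCurve",
    "SensoryTuning",
    "QCReport",
    "ModulationTest",
    "threshold_normalize",
    "build_tensor",
    "qc_filters",
    "average_frequency",
    "sensory_tuning",
    "specificity",
    "shuffle_speed",
    "d_mod",
    "test_modulation",
    "bootstrap_speed_shuffled_curves",
]


class DegenerateNeuronError(ValueError):
    """Raised when a neuron's trace is unusable (e.g. zero variance)."""


@dataclass
class TuningTensor3D:
    """Per-bin statistics on the direction x frequency x speed grid.

    ``means`` holds the arithmetic mean response per (direction, tf, speed)
    bin and is NaN where a bin received no samples.  ``tf_coverage[d, v]``
    counts the distinct temporal frequencies contributing to the
    (direction, speed) bin; it drives the frequency-coverage QC filter.
    """

    means: np.ndarray  # (8, 5, 8), NaN where empty
    counts: np.ndarray  # (8, 5, 8) int
    seconds: np.ndarray  # (8, 5, 8)

    @property
    def tf_coverage(self) -> np.ndarray:
        return (self.counts > 0).sum(axis=1)

    @property
    def dirspeed_counts(self) -> np.ndarray:
        return self.counts.sum(axis=1)

    @property
    def dirspeed_seconds(self) -> np.ndarray:
        return self.seconds.sum(axis=1)


@dataclass
class DirectionSpeedCurve:
    """The 8 x 8 direction-speed tuning curve R (directions x speed bins)."""

    values: np.ndarray
    direction_labels: np.ndarray = field(default_factory=lambda: DIRECTIONS_DEG.copy())
    speed_bin_edges: np.ndarray = field(default_factory=lambda: SPEED_EDGES.copy())

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (N_DIRECTIONS, N_SPEED_BINS):
            raise ValueError("curve must be 8 x 8 (direction x speed)")

    @property
    def speed_bin_centers(self) -> np.ndarray:
        return 0.5 * (self.speed_bin_edges[:-1] + self.speed_bin_edges[1:])

    @property
    def complete(self) -> bool:
        return bool(np.all(np.isfinite(self.values)))


@dataclass
class SensoryTuning:
    """Speed-averaged direction tuning and its entropy-based specificity S."""

    values: np.ndarray
    specificity: float


@dataclass
class QCReport:
    passed: bool
    reasons: list


@dataclass
class ModulationTest:
    """Outcome of the bootstrap test of speed modulation for one neuron."""

    d_mod_data: float
    null: np.ndarray
    threshold: float
    significant: bool


def threshold_normalize(responses):
    """Clip negatives to zero, then divide by the sd of the thresholded trace.

    The standard deviation uses the population convention (denominator n).
    A trace whose thresholded version has zero variance cannot be normalized
    and raises :class:`DegenerateNeuronError` — such neurons are excluded.
    """
    r = np.asarray(responses, dtype=float)
    if r.size < 2:
        raise ValueError("need at least 2 samples")
    clipped = np.clip(r, 0.0, None)
    sd = clipped.std()  # ddof=0
    if sd == 0:
        raise DegenerateNeuronError("zero variance after thresholding")
    return clipped / sd


def _prepare(trials: pd.DataFrame):
    """Extract integer bin indices and responses; drop speeds above range."""
    d = direction_index(trials["direction_deg"].to_numpy())
    t = tf_index(trials["tf_hz"].to_numpy())
    v = assign_speed_bin(trials["speed_cmps"].to_numpy())
    r = trials["response"].to_numpy(dtype=float)
    dur = trials["duration_s"].to_numpy(dtype=float)
    keep = v != EXCLUDED
    return d[keep], t[keep], v[keep], r[keep], dur[keep]


def build_tensor(trials: pd.DataFrame) -> TuningTensor3D:
    """Bin one neuron's (already normalized) responses into a 3-D tensor.

    Rows with speeds above 20 cm/s are ignored.  Means are arithmetic means
    per bin and NaN where a bin is empty.
    """
    d, t, v, r, dur = _prepare(trials)
    flat = (d * N_TF + t) * N_SPEED_BINS + v
    n_bins = N_DIRECTIONS * N_TF * N_SPEED_BINS
    counts = np.bincount(flat, minlength=n_bins)
    sums = np.bincount(flat, weights=r, minlength=n_bins)
    secs = np.bincount(flat, weights=dur, minlength=n_bins)
    with np.errstate(invalid="ignore"):
        means = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
    shape = (N_DIRECTIONS, N_TF, N_SPEED_BINS)
    return TuningTensor3D(
        means=means.reshape(shape),
        counts=counts.reshape(shape),
        seconds=secs.reshape(shape),
    )


def qc_filters(
    tensor: TuningTensor3D,
    min_seconds: float = 1.0,
    max_sparse_bins: int = 16,
    min_tf: int = 3,
) -> QCReport:
    """Apply the data-quality filter cascade to one neuron's tensor.

    Fails if any of the 64 direction-speed bins is empty, if any bin holds
    less than ``min_seconds`` of data, or if more than ``max_sparse_bins``
    bins were averaged over fewer than ``min_tf`` distinct temporal
    frequencies.  All violated rules are reported.
    """
    reasons = []
    if np.any(tensor.dirspeed_counts == 0):
        reasons.append("empty bins")
    if np.any(tensor.dirspeed_seconds < min_seconds):
        reasons.append("insufficient seconds")
    if int((tensor.tf_coverage < min_tf).sum()) > max_sparse_bins:
        reasons.append("frequency coverage")
    return QCReport(passed=not reasons, reasons=reasons)


def average_frequency(tensor: TuningTensor3D) -> DirectionSpeedCurve:
    """Collapse the frequency axis: unweighted mean of per-frequency bin
    means over the non-empty frequency cells of each (direction, speed) bin.

    Requires every (direction, speed) bin to be non-empty (QC precondition).
    """
    if np.any(tensor.dirspeed_counts == 0):
        raise ValueError("empty direction-speed bin; QC must pass first")
    with np.errstate(invalid="ignore"):
        values = np.nanmean(tensor.means, axis=1)
    return DirectionSpeedCurve(values=values)


def sensory_tuning(curve: DirectionSpeedCurve) -> SensoryTuning:
    """Speed-averaged direction tuning and its specificity."""
    if not curve.complete:
        raise ValueError("curve must be complete")
    vec = curve.values.mean(axis=1)
    return SensoryTuning(values=vec, specificity=specificity(vec))


def specificity(values) -> float:
    """Tuning specificity S = 1 - H_norm of a non-negative 8-vector.

    The vector is normalized to sum 1 and H_norm is its Shannon entropy in
    bits divided by 3 (= log2 of the 8 direction bins), so S = 0 for uniform
    tuning and S = 1 when a single direction carries all the response.
    """
    v = np.asarray(values, dtype=float)
    if np.any(v < 0):
        raise ValueError("values must be non-negative")
    total = v.sum()
    if total == 0:
        raise ValueError("all-zero tuning vector")
    p = v / total
    nz = p[p > 0]
    h_norm = -(nz * np.log2(nz)).sum() / np.log2(len(v))
    return float(1.0 - h_norm)


def d_mod(curve) -> float:
    """Speed-modulation statistic: sum over the 8 speed bins of the
    Euclidean distance between that bin's direction tuning and the
    speed-averaged direction tuning."""
    values = curve.values if isinstance(curve, DirectionSpeedCurve) else np.asarray(curve)
    mean_dir = values.mean(axis=1)
    return float(np.linalg.norm(values - mean_dir[:, None], axis=0).sum())


def shuffle_speed(
    trials: pd.DataFrame, rng: np.random.Generator, replace: bool = True
) -> pd.DataFrame:
    """Resample responses across speeds within (direction, frequency) strata.

    Every (direction, tf, speed) bin keeps its sample count, but its
    responses are drawn (with replacement by default; ``replace=False``
    permutes instead) from the pooled (direction, tf) stratum.  This removes
    speed structure while preserving direction/frequency tuning exactly.
    """
    if len(trials) == 0:
        raise ValueError("trials must be non-empty")
    out = trials.copy()
    d = direction_index(trials["direction_deg"].to_numpy())
    t = tf_index(trials["tf_hz"].to_numpy())
    r = trials["response"].to_numpy(dtype=float)
    strat = d * N_TF + t
    new_r = r.copy()
    for s in np.unique(strat):
        idx = np.flatnonzero(strat == s)
        if replace:
            new_r[idx] = r[rng.choice(idx, size=idx.size, replace=True)]
        else:
            new_r[idx] = r[rng.permutation(idx)]
    out["response"] = new_r
    return out


def _strata(trials: pd.DataFrame):
    """Group prepared rows by (direction, tf) stratum for fast bootstraps."""
    d, t, v, r, _ = _prepare(trials)
    strat = d * N_TF + t
    order = np.argsort(strat, kind="stable")
    strat, d, v, r = strat[order], d[order], v[order], r[order]
    bounds = np.flatnonzero(np.diff(strat)) + 1
    starts = np.concatenate([[0], bounds])
    stops = np.concatenate([bounds, [strat.size]])
    return [
        (d[a], strat[a] % N_TF, v[a:b], r[a:b]) for a, b in zip(starts, stops)
    ]


def bootstrap_speed_shuffled_curves(
    trials: pd.DataFrame,
    n_boot: int,
    rng: np.random.Generator,
    dir_gain: np.ndarray | None = None,
) -> np.ndarray:
    """Generate ``n_boot`` speed-shuffled direction-speed curves at once.

    Within each (direction, tf) stratum the per-speed-bin responses are
    resampled with replacement from the pooled stratum, preserving every
    bin's sample count.  If ``dir_gain`` (an 8 x 8 direction x speed matrix)
    is given, each resampled response is additionally multiplied by
    ``dir_gain[direction, speed bin]`` — this implements the simulated
    shared-modulator bootstrap of the differential-modulation test.

    Returns an array of shape ``(n_boot, 8, 8)`` of direction-speed curves
    (frequency axis averaged as in :func:`average_frequency`).
    """
    if n_boot <= 0:
        raise ValueError("n_boot must be positive")
    sums = np.zeros((n_boot, N_DIRECTIONS, N_TF, N_SPEED_BINS))
    counts = np.zeros((N_DIRECTIONS, N_TF, N_SPEED_BINS))
    for dir_i, tf_i, v, r in _strata(trials):
        n = r.size
        idx = rng.integers(0, n, size=(n_boot, n))
        res = r[idx]
        if dir_gain is not None:
            res = res * dir_gain[dir_i, v]
        onehot = (v[:, None] == np.arange(N_SPEED_BINS)).astype(float)
        sums[:, dir_i, tf_i, :] += res @ onehot
        counts[dir_i, tf_i, :] += onehot.sum(axis=0)
    with np.errstate(invalid="ignore"):
        means = sums / counts  # NaN where a (d, t, v) bin is empty
        curves = np.nanmean(means, axis=2)
    return curves


def test_modulation(
    trials: pd.DataFrame,
    n_boot: int = 1000,
    alpha_quantile: float = 0.95,
    rng: np.random.Generator | None = None,
) -> ModulationTest:
    """Bootstrap test of speed modulation for one neuron.

    Builds ``n_boot`` speed-shuffled curves, evaluates d_mod on each to form
    the null distribution, and flags the neuron as significantly modulated
    if the observed d_mod exceeds the ``alpha_quantile`` of the null.
    """
    if n_boot <= 0:
        raise ValueError("n_boot must be positive")
    if rng is None:
        raise ValueError("a seeded rng is required")
    curve = average_frequency(build_tensor(trials))
    observed = d_mod(curve)
    null_curves = bootstrap_speed_shuffled_curves(trials, n_boot, rng)
    mean_dir = null_curves.mean(axis=2, keepdims=True)
    null = np.linalg.norm(null_curves - mean_dir, axis=1).sum(axis=1)
    threshold = float(np.quantile(null, alpha_quantile))
    return ModulationTest(
        d_mod_data=observed,
        null=null,
        threshold=threshold,
        significant=bool(observed > threshold),
    )


def speed_bin_centers() -> np.ndarray:
    """The 8 speed-bin centers in cm/s."""
    return SPEED_CENTERS.copy()
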