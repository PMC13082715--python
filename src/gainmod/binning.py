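"""Stimulus and speed binning conventions shared across the package.

The experimental protocol this package models presents drifting gratings at
8 directions (45 degrees apart) and 5 temporal frequencies while the animal
runs freely; running speed is discretized into 8 linearly spaced bins
covering 0-20 cm/s.  All tuning tensors and curves in the package use these
fixed axes.
"""

from __future__ import annotations

import numpy as np

#: Grating drift directions in degrees.
DIRECTIONS_DEG = np.arange(0, 360, 45)

#: Grating drift directions in radians, wrapped to [-pi, pi).
DIRECTIONS_RAD = np.where(
    np.deg2rad(DIRECTIONS_DEG) < np.pi,
    np.deg2rad(DIRECTIONS_DEG),
    np.deg2rad(DIRECTIONS_DEG) - 2 * np.pi,
)

#: Grating temporal frequencies in Hz.
TF_HZ = np.array([1, 2, 4, 8, 15])

N_DIRECTIONS = 8
N_TF = 5
N_SPEED_BINS = 8

#: Upper limit of the analysed running-speed range, cm/s.
SPEED_MAX = 20.0

#: Speed-bin edges: 8 linearly spaced bins on [0, 20] cm/s.
SPEED_EDGES = np.linspace(0.0, SPEED_MAX, N_SPEED_BINS + 1)

#: Speed-bin centers (1.25, 3.75, ..., 18.75 cm/s); used wherever a single
#: speed value must represent a bin (correlations with speed, centers of mass).
SPEED_CENTERS = 0.5 * (SPEED_EDGES[:-1] + SPEED_EDGES[1:])

#: Marker returned for speeds above SPEED_MAX (excluded, not clipped).
EXCLUDED = -1


def direction_index(direction_deg):
    """Map direction values in degrees to axis indices 0..7.

    Raises ``ValueError`` for directions outside the stimulus set.
    """
    d = np.asarray(direction_deg, dtype=float)
    idx = d / 45.0
    out = np.rint(idx).astype(int)
    if np.any(np.abs(idx - out) > 1e-9) or np.any(out < 0) or np.any(out > 7):
        raise ValueError("direction_deg must belong to {0, 45, ..., 315}")
    return out if out.ndim else int(out)


def tf_index(tf_hz):
    """Map temporal-frequency values in Hz to axis indices 0..4."""
    t = np.asarray(tf_hz, dtype=float)
    out = np.searchsorted(TF_HZ, t)
    out = np.clip(out, 0, N_TF - 1)
    if np.any(TF_HZ[out] != t):
        raise ValueError("tf_hz must belong to {1, 2, 4, 8, 15}")
    return out if out.ndim else int(out)


def assign_speed_bin(speed_cmps):
    """Assign running speeds to the 8 linearly spaced bins on [0, 20] cm/s.

    Bins are half-open ``[edge_k, edge_{k+1})``; the last bin is closed at
    20 cm/s.  Speeds above 20 cm/s return :data:`EXCLUDED` (they are dropped
    from tuning curves, not clipped).  Negative speeds are invalid.

    Parameters
    ----------
    speed_cmps : float or array_like
        Running speed(s) in cm/s.

    Returns
    -------
    int or ndarray of int
        Bin index 0..7, or :data:`EXCLUDED` (-1) for speeds above the range.
    """
    s = np.asarray(speed_cmps, dtype=float)
    if np.any(s < 0):
        raise ValueError("running speed must be non-negative")
    bin_width = SPEED_MAX / N_SPEED_BINS
    idx = np.floor(s / bin_width).astype(int)
    idx = np.where(s == SPEED_MAX, N_SPEED_BINS - 1, idx)  # close last bin
    idx = np.where(s > SPEED_MAX, EXCLUDED, idx)
    return idx if idx.ndim else int(idx)
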