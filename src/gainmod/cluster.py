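"""K-means clustering of subunit speed-modulator profiles.

Neurons are summarized by the shapes of their scaled modulators: for
two-subunit neurons the stronger and weaker modulators are concatenated
(stronger leading) into a 16-vector, single-subunit neurons contribute
their 8-vector directly; features are L2-normalized so clustering sees
shape, not amplitude.  The cluster count is a descriptive choice (12 for
two-subunit neurons, 9 for one-subunit neurons); clusters summarize a
continuum of modulation patterns rather than discrete cell types.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans

from .binning import N_SPEED_BINS, SPEED_CENTERS
from .modulators import ModulatorPair

__all__ = [
    "ClusterResult",
    "feature_vector",
    "kmeans_cluster",
    "center_of_mass",
    "sort_within_cluster",
    "membership_table",
]


@dataclass
class ClusterResult:
    labels: np.ndarray
    centroids: np.ndarray
    k: int
    feature_length: int
    inertia: float


def feature_vector(modulators) -> np.ndarray:
    """Unit-norm modulator-shape feature for one neuron.

    ``modulators`` is a sequence of 1 or 2 scaled-modulator 8-vectors; with
    two, the stronger (larger mean) leads regardless of input order.  The
    concatenation is divided by its Euclidean norm.
    """
    mods = [np.asarray(m, dtype=float) for m in modulators]
    if len(mods) not in (1, 2):
        raise ValueError("expected 1 or 2 modulators")
    for m in mods:
        if m.shape != (N_SPEED_BINS,):
            raise ValueError("modulators must be 8-vectors")
    if len(mods) == 2 and mods[1].mean() > mods[0].mean():
        mods = [mods[1], mods[0]]
    feat = np.concatenate(mods)
    norm = np.linalg.norm(feat)
    if norm == 0:
        raise ValueError("zero feature vector")
    return feat / norm


def kmeans_cluster(
    features, k: int, rng: np.random.Generator | None = None, n_restarts: int = 50
) -> ClusterResult:
    """Standard k-means (k-means++ seeding, ``n_restarts`` restarts, best
    objective kept) on an (n, d) feature matrix."""
    X = np.asarray(features, dtype=float)
    if X.ndim != 2:
        raise ValueError("features must be a 2-D array")
    if X.shape[0] < k:
        raise ValueError("fewer feature vectors than clusters")
    if rng is None:
        raise ValueError("a seeded rng is required")
    seed = int(rng.integers(0, 2**31 - 1))
    km = KMeans(
        n_clusters=k, init="k-means++", n_init=n_restarts, tol=1e-6, random_state=seed
    ).fit(X)
    return ClusterResult(
        labels=km.labels_.astype(int),
        centroids=km.cluster_centers_,
        k=k,
        feature_length=X.shape[1],
        inertia=float(km.inertia_),
    )


def center_of_mass(g) -> float:
    """Gain-weighted mean speed of a modulator, using bin centers (cm/s)."""
    g = np.asarray(g, dtype=float)
    if g.shape != (N_SPEED_BINS,):
        raise ValueError("modulator must be an 8-vector")
    total = g.sum()
    if total <= 0:
        raise ValueError("modulator must have positive sum")
    return float((SPEED_CENTERS * g).sum() / total)


def sort_within_cluster(members: Sequence[ModulatorPair]) -> list:
    """Stable sort of cluster members, ascending by the weaker modulator's
    center of mass; ties broken by neuron id."""
    return sorted(
        members, key=lambda p: (center_of_mass(p.weaker), str(p.neuron_id))
    )


def membership_table(labels, groups) -> pd.DataFrame:
    """Per-group cluster-membership proportions (rows: groups, columns:
    clusters; each row sums to 1)."""
    labels = np.asarray(labels)
    groups = np.asarray(groups)
    if labels.shape != groups.shape:
        raise ValueError("labels and groups must align")
    df = pd.DataFrame({"cluster": labels, "group": groups})
    counts = df.groupby(["group", "cluster"]).size().unstack(fill_value=0)
    return counts.div(counts.sum(axis=1), axis=0)
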