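"""Differential speed modulation of two-subunit (orientation-selective) neurons.

A two-subunit neuron carries two effective speed-gain profiles (scaled
modulators), one per subunit.  The question this module answers is whether
running speed modulates the two subunits *differently*.  The test statistic
is rho-bar: the largest achievable average Pearson correlation between a
single non-negative curve and both modulators (the correlation-maximizing
fit).  If one common gain profile can track both modulators, rho-bar is
high; genuinely different modulators force it down.

The null distribution is built from bootstrap tuning curves in which speed
structure is first destroyed by shuffling (as in the speed-modulation test)
and then re-imposed as a *shared* multiplicative modulator — the average of
the neuron's two fitted modulators — applied to the direction rows of the
significant subunits.  Each bootstrap curve is refitted with the
decomposition at the neuron's selected sparsity and its rho-bar recorded.
A neuron is differentially modulated when its observed rho-bar falls below
the alpha-quantile (default 1%) of this shared-modulation null.

Also here: modulator strength ratios, correlations of modulators with
running speed, the permutation band used to delimit "speed-related"
correlations, the four-region classification of the correlation plane, and
the noisy shared-modulator control used to probe the sensitivity of that
classification.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import optimize

from .binning import N_DIRECTIONS, N_SPEED_BINS, SPEED_CENTERS
from .decomposition import SubunitDecompositionResults, fit_curves
from .tuning import bootstrap_speed_shuffled_curves

__all__ = [
    "ModulatorPair",
    "DifferentialTestResult",
    "pearson",
    "strength_ratio",
    "corr_max_fit",
    "shared_modulator",
    "bootstrap_shared",
    "test_differential",
    "speed_correlation",
    "null_speed_band",
    "classify_plane",
    "simulate_shared_with_noise",
]


def pearson(a, b) -> float:
    """Pearson correlation; NaN (an undefined marker, never coerced to 0)
    when either input is constant."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("length mismatch")
    if a.size < 3:
        raise ValueError("need at least 3 points")
    da = a - a.mean()
    db = b - b.mean()
    na = np.linalg.norm(da)
    nb = np.linalg.norm(db)
    if na == 0 or nb == 0:
        return float("nan")
    return float(np.clip(da @ db / (na * nb), -1.0, 1.0))


@dataclass
class ModulatorPair:
    """The two scaled modulators of a two-subunit neuron, stronger first."""

    stronger: np.ndarray
    weaker: np.ndarray
    neuron_id: object = None

    def __post_init__(self):
        self.stronger = np.asarray(self.stronger, dtype=float)
        self.weaker = np.asarray(self.weaker, dtype=float)
        if self.stronger.shape != (N_SPEED_BINS,) or self.weaker.shape != (
            N_SPEED_BINS,
        ):
            raise ValueError("modulators must be 8-vectors")
        if np.any(self.stronger < 0) or np.any(self.weaker < 0):
            raise ValueError("scaled modulators are non-negative")
        if self.stronger.mean() < self.weaker.mean():
            raise ValueError("stronger modulator must have the larger mean")

    @classmethod
    def from_modulators(cls, g_a, g_b, neuron_id=None) -> "ModulatorPair":
        """Build a pair, assigning stronger/weaker by mean gain."""
        g_a = np.asarray(g_a, dtype=float)
        g_b = np.asarray(g_b, dtype=float)
        if g_a.mean() >= g_b.mean():
            return cls(stronger=g_a, weaker=g_b, neuron_id=neuron_id)
        return cls(stronger=g_b, weaker=g_a, neuron_id=neuron_id)

    @classmethod
    def from_fit(cls, fit: SubunitDecompositionResults, neuron_id=None):
        """Extract the pair of the two strongest significant subunits from a
        decomposition fit (at least two required)."""
        i, j = _top2_significant(fit)
        g = fit.scaled_modulators
        return cls.from_modulators(g[i], g[j], neuron_id=neuron_id)

    @property
    def strength_ratio_log2(self) -> float:
        return strength_ratio(self)[1]


def strength_ratio(pair: ModulatorPair):
    """Ratio (and its log2) of mean stronger to mean weaker modulator."""
    num = pair.stronger.mean()
    den = pair.weaker.mean()
    if den == 0:
        return float("nan"), float("nan")
    ratio = num / den
    return float(ratio), float(np.log2(ratio))


def _rho_bar(g, g1, g2) -> float:
    return 0.5 * (pearson(g, g1) + pearson(g, g2))


def corr_max_fit(g1, g2, n_starts: int = 10, rng: np.random.Generator | None = None):
    """Non-negative curve maximizing the average correlation with g1 and g2.

    The curve is parameterized as g = z**2 (non-negative by construction)
    and optimized with BFGS from an analytic warm start — the shifted sum of
    the standardized modulators, which attains the unconstrained optimum
    because correlation is shift-invariant — plus ``n_starts - 1`` random
    restarts.  Returns ``(g_hat, rho_bar)``; both are NaN-marked when either
    input is constant (correlation undefined).
    """
    g1 = np.asarray(g1, dtype=float)
    g2 = np.asarray(g2, dtype=float)
    if g1.std() == 0 or g2.std() == 0:
        return np.full(g1.shape, np.nan), float("nan")
    if n_starts < 1:
        raise ValueError("n_starts must be positive")
    if rng is None:
        rng = np.random.default_rng(0)

    u1 = (g1 - g1.mean()) / np.linalg.norm(g1 - g1.mean())
    u2 = (g2 - g2.mean()) / np.linalg.norm(g2 - g2.mean())

    def neg_obj_grad(z):
        g = z**2
        gc = g - g.mean()
        norm = np.linalg.norm(gc)
        if norm == 0:
            return 1.0, np.zeros_like(z)  # degenerate candidate
        gn = gc / norm
        obj = 0.0
        dg = np.zeros_like(g)
        for u in (u1, u2):
            rho = gn @ u
            obj += 0.5 * rho
            # d rho / d g, using that u is centered and unit-norm
            dg += 0.5 * (u - rho * gn) / norm
        return -obj, -dg * 2.0 * z

    starts = []
    base = u1 + u2
    if base.std() > 1e-12:
        shifted = base - base.min() + 1e-3
        starts.append(np.sqrt(shifted))
    while len(starts) < n_starts:
        starts.append(rng.normal(0.0, 1.0, size=g1.shape))

    best_g, best_rho = None, -np.inf
    for z0 in starts:
        res = optimize.minimize(neg_obj_grad, z0, method="BFGS", jac=True)
        g = res.x**2
        if g.std() == 0:
            continue
        rho = _rho_bar(g, g1, g2)
        if rho > best_rho:
            best_rho, best_g = rho, g
    if best_g is None:  # every start collapsed; fall back to flat marker
        return np.full(g1.shape, np.nan), float("nan")
    return best_g, float(best_rho)


def _top2_significant(fit: SubunitDecompositionResults):
    """The two strongest significant subunits of a fit (>= 2 required)."""
    sig = fit.significant_subunits
    if len(sig) < 2:
        raise ValueError("neuron must have at least 2 significant subunits")
    means = fit.scaled_modulators.mean(axis=1)
    order = sorted(sig, key=lambda i: -means[i])
    return order[0], order[1]


def shared_modulator(fit: SubunitDecompositionResults) -> np.ndarray:
    """Elementwise mean of the two strongest significant subunits' scaled
    modulators — the simulated shared gain of the differential-test null."""
    i, j = _top2_significant(fit)
    g = fit.scaled_modulators
    return 0.5 * (g[i] + g[j])


def bootstrap_shared(
    trials,
    fit: SubunitDecompositionResults,
    n_boot: int = 1000,
    rng: np.random.Generator | None = None,
    refit_inits: int = 3,
    refit_steps: int = 300,
    corr_starts: int = 3,
) -> np.ndarray:
    """Null rho-bar distribution under simulated shared modulation.

    Each replicate: speed-shuffle the trials, multiply the samples falling
    in the significant subunits' direction rows by the shared modulator's
    value at the sample's speed bin, rebuild the direction-speed curve,
    refit the decomposition at the neuron's selected lambda, take the two
    strongest subunits' scaled modulators and record their rho-bar from the
    correlation-maximizing fit.  Per-bin sample counts and sensory tuning
    are preserved by construction.
    """
    if rng is None:
        raise ValueError("a seeded rng is required")
    top2 = list(_top2_significant(fit))
    shared = shared_modulator(fit)
    dir_gain = np.ones((N_DIRECTIONS, N_SPEED_BINS))
    dir_gain[top2, :] = shared[None, :]
    curves = bootstrap_speed_shuffled_curves(trials, n_boot, rng, dir_gain=dir_gain)
    s, M, _ = fit_curves(curves, fit.lambda_, refit_inits, refit_steps, rng)
    scaled = M**2 * (s**2)[:, :, None]  # (n_boot, 8, 8)
    means = scaled.mean(axis=2)
    top2 = np.argsort(-means, axis=1)[:, :2]
    rhos = np.empty(n_boot)
    for b in range(n_boot):
        i, j = top2[b]
        _, rhos[b] = corr_max_fit(scaled[b, i], scaled[b, j], n_starts=corr_starts, rng=rng)
    return rhos


@dataclass
class DifferentialTestResult:
    """Outcome of the differential-modulation test for one neuron."""

    rho_data: float
    null_rhos: np.ndarray
    alpha: float
    threshold: float
    significant: bool


def test_differential(rho_data: float, null, alpha: float = 0.01) -> DifferentialTestResult:
    """Lower-tail test: a neuron is differentially modulated when its
    rho-bar falls below the alpha-quantile of the shared-modulation null
    (a worse-than-null joint fit means one curve cannot track both
    modulators)."""
    null = np.asarray(null, dtype=float)
    if null.size == 0:
        raise ValueError("null distribution must be non-empty")
    threshold = float(np.nanquantile(null, alpha))
    return DifferentialTestResult(
        rho_data=float(rho_data),
        null_rhos=null,
        alpha=alpha,
        threshold=threshold,
        significant=bool(rho_data < threshold),
    )


def speed_correlation(g) -> float:
    """Pearson correlation of a modulator with the speed-bin centers
    (1.25, 3.75, ..., 18.75 cm/s); NaN if the modulator is constant."""
    return pearson(np.asarray(g, dtype=float), SPEED_CENTERS)


def null_speed_band(
    modulators,
    rng: np.random.Generator | None = None,
    q_lo: float = 0.05,
    q_hi: float = 0.95,
    n_perm: int = 100,
):
    """Permutation band for modulator-speed correlations.

    Each modulator's 8 entries are randomly permuted ``n_perm`` times; the
    ``(q_lo, q_hi)`` quantiles of the resulting speed correlations delimit
    the range compatible with no real speed relationship.
    """
    if rng is None:
        raise ValueError("a seeded rng is required")
    mods = np.asarray(modulators, dtype=float)
    if mods.ndim != 2 or mods.shape[1] != N_SPEED_BINS:
        raise ValueError("modulators must be an (n, 8) array")
    if mods.shape[0] < 20:
        raise ValueError("need at least 20 modulators")
    tiled = np.repeat(mods, n_perm, axis=0)
    perm = rng.permuted(tiled, axis=1)
    centered = perm - perm.mean(axis=1, keepdims=True)
    norms = np.linalg.norm(centered, axis=1)
    sc = SPEED_CENTERS - SPEED_CENTERS.mean()
    with np.errstate(invalid="ignore", divide="ignore"):
        corrs = centered @ sc / (norms * np.linalg.norm(sc))
    corrs = corrs[np.isfinite(corrs)]
    if corrs.size == 0:
        raise ValueError("all modulators constant; band undefined")
    return float(np.quantile(corrs, q_lo)), float(np.quantile(corrs, q_hi))


def classify_plane(rho_weaker: float, rho_stronger: float, band) -> str:
    """Region of the correlation plane for one neuron.

    ``both_positive`` / ``both_negative``: both modulators' speed
    correlations beyond the same side of the permutation band; ``neutral``:
    both inside the band; ``asymmetric``: everything else, including pairs
    beyond opposite extremes.
    """
    lo, hi = band
    if not (np.isfinite(rho_weaker) and np.isfinite(rho_stronger)):
        raise ValueError("correlations must be defined")
    above = (rho_weaker > hi, rho_stronger > hi)
    below = (rho_weaker < lo, rho_stronger < lo)
    if all(above):
        return "both_positive"
    if all(below):
        return "both_negative"
    if not any(above) and not any(below):
        return "neutral"
    return "asymmetric"


def simulate_shared_with_noise(
    pair: ModulatorPair,
    noise_sd: float = 0.01,
    rng: np.random.Generator | None = None,
) -> ModulatorPair:
    """Shared-modulation control: replace each modulator by the pair average
    rescaled to the modulator's original Euclidean norm, plus independent
    Gaussian noise of the given sd.  Resulting negative values are clipped
    to zero (scaled modulators are non-negative by definition)."""
    if rng is None and noise_sd > 0:
        raise ValueError("a seeded rng is required when noise_sd > 0")
    avg = 0.5 * (pair.stronger + pair.weaker)
    norm_avg = np.linalg.norm(avg)
    if norm_avg == 0:
        raise ValueError("zero-norm average modulator")
    out = []
    for g in (pair.stronger, pair.weaker):
        norm_g = np.linalg.norm(g)
        if norm_g == 0:
            raise ValueError("zero-norm modulator")
        new = avg * (norm_g / norm_avg)
        if noise_sd > 0:
            new = new + rng.normal(0.0, noise_sd, size=new.shape)
        out.append(np.clip(new, 0.0, None))
    return ModulatorPair.from_modulators(out[0], out[1], neuron_id=pair.neuron_id)
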