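"""Sparse subunit x modulator decomposition of direction-speed tuning curves.

The model represents an 8 x 8 direction-speed tuning curve R as a sum of
direction subunits, each multiplicatively modulated along the speed axis:

    R_hat[k, l] = sum_i phi_i[k, l] * m[i, l]**2 * s[i]**2

where phi_i is the indicator basis matrix with row i set to one (one basis
per stimulus direction), ``m[i, :]`` is the speed modulator of subunit i and
``s[i]`` its coefficient; both are squared so the reconstruction is
non-negative by construction.  Parameters are estimated by minimizing

    cost = MSE(R, R_hat) + lambda * mean(s**2) + lambda * mean(m**2)

with a first-order optimizer (Adam-style adaptive steps on the analytic
gradient, best iterate kept), multiple random initializations, and the fit
with the highest reconstruction SNR retained.  Model selection over the
sparsity path uses a permutation null: curves resampled from a cohort with
their 64 bins globally permuted are fitted at each lambda, and a neuron's
fit is significant at the smallest lambda whose SNR exceeds the null's 95th
percentile.

After fitting, the effective gain of subunit i at speed bin l is the scaled
modulator g[i, l] = m[i, l]**2 * s[i]**2 — exactly the contribution summed
in the reconstruction.  Subunits whose mean scaled modulator reaches at
least 5% of the strongest subunit's are called *significant subunits*; one
significant subunit is direction selectivity, two subunits 180 degrees
apart instantiate orientation selectivity with separately adjustable gains.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .binning import N_DIRECTIONS, N_SPEED_BINS
from .tuning import DirectionSpeedCurve

__all__ = [
    "DecompositionParams",
    "SubunitDecomposition",
    "SubunitDecompositionResults",
    "basis_function",
    "reconstruct",
    "cost",
    "significant_subunits",
    "null_snr_distribution",
    "select_fit",
    "subunit_separation",
    "default_lambda_grid",
]

SIGNIFICANCE_FRACTION = 0.05  # subunit retention threshold, fraction of max


def default_lambda_grid() -> np.ndarray:
    """The 10 sparsity values evenly spaced on [0.01, 0.1]."""
    return np.linspace(0.01, 0.1, 10)


def basis_function(i: int) -> np.ndarray:
    """Direction basis phi_i: an 8 x 8 matrix with row ``i`` set to one."""
    if not 0 <= i < N_DIRECTIONS:
        raise ValueError("basis index out of range")
    out = np.zeros((N_DIRECTIONS, N_SPEED_BINS))
    out[i] = 1.0
    return out


@dataclass
class DecompositionParams:
    """Raw model parameters (squared inside the model).

    ``subunit_coeffs`` is the 8-vector s of subunit coefficients;
    ``modulators`` the 8 x 8 matrix m with ``modulators[i, l]`` the raw
    modulator of subunit i at speed bin l.
    """

    subunit_coeffs: np.ndarray
    modulators: np.ndarray

    def __post_init__(self):
        self.subunit_coeffs = np.asarray(self.subunit_coeffs, dtype=float)
        self.modulators = np.asarray(self.modulators, dtype=float)
        if self.subunit_coeffs.shape != (N_DIRECTIONS,):
            raise ValueError("subunit_coeffs must be an 8-vector")
        if self.modulators.shape != (N_DIRECTIONS, N_SPEED_BINS):
            raise ValueError("modulators must be 8 x 8")
        if not (
            np.all(np.isfinite(self.subunit_coeffs))
            and np.all(np.isfinite(self.modulators))
        ):
            raise ValueError("parameters must be finite")


def reconstruct(params: DecompositionParams) -> np.ndarray:
    """Model reconstruction R_hat[k, l] = m[k, l]^2 * s[k]^2 (non-negative)."""
    s2 = params.subunit_coeffs**2
    return params.modulators**2 * s2[:, None]


def cost(params: DecompositionParams, R: np.ndarray, lambda_: float) -> float:
    """Mean squared reconstruction error plus the two sparsity penalties."""
    if lambda_ < 0:
        raise ValueError("lambda must be non-negative")
    R = np.asarray(R, dtype=float)
    mse = float(np.mean((R - reconstruct(params)) ** 2))
    pen = lambda_ * float(np.mean(params.subunit_coeffs**2)) + lambda_ * float(
        np.mean(params.modulators**2)
    )
    return mse + pen


def _snr_db(R: np.ndarray, mse: np.ndarray) -> np.ndarray:
    """Reconstruction SNR in dB: 10 log10(Var(R) / MSE), per curve."""
    var = R.reshape(R.shape[0], -1).var(axis=1)
    mse = np.maximum(mse, 1e-300)
    with np.errstate(divide="ignore"):
        return 10.0 * np.log10(var / mse)


def _fit_batch(
    R: np.ndarray,
    lambda_: float,
    n_inits: int,
    n_steps: int,
    rng: np.random.Generator,
    learning_rate: float = 0.05,
):
    """Fit the decomposition to a batch of curves, all inits in parallel.

    ``R`` has shape (B, 8, 8).  Returns ``(s, M, mse)`` for the best init of
    each curve, selected by reconstruction MSE (equivalently highest SNR).
    The best iterate encountered along each trajectory is kept, so the final
    cost never exceeds the initial one.
    """
    B = R.shape[0]
    n = B * n_inits
    Rx = np.repeat(R, n_inits, axis=0)  # (n, 8, 8)
    s = np.abs(rng.normal(0.0, 0.1, size=(n, N_DIRECTIONS)))
    M = np.abs(rng.normal(0.0, 0.1, size=(n, N_DIRECTIONS, N_SPEED_BINS)))

    def eval_cost(s, M):
        err = M**2 * (s**2)[:, :, None] - Rx
        mse = (err**2).mean(axis=(1, 2))
        pen = lambda_ * ((s**2).mean(axis=1) + (M**2).mean(axis=(1, 2)))
        return err, mse, mse + pen

    best_s, best_M = s.copy(), M.copy()
    _, best_mse, best_cost = eval_cost(s, M)

    # Adam state
    b1, b2, eps = 0.9, 0.999, 1e-8
    ms = np.zeros_like(s)
    vs = np.zeros_like(s)
    mM = np.zeros_like(M)
    vM = np.zeros_like(M)

    n_cells = N_DIRECTIONS * N_SPEED_BINS
    for step in range(1, n_steps + 1):
        err, mse, c = eval_cost(s, M)
        improved = c < best_cost
        if improved.any():
            best_cost = np.where(improved, c, best_cost)
            best_mse = np.where(improved, mse, best_mse)
            best_s[improved] = s[improved]
            best_M[improved] = M[improved]
        # analytic gradients of the cost
        gM = (4.0 / n_cells) * err * M * (s**2)[:, :, None] + (
            2.0 * lambda_ / n_cells
        ) * M
        gs = (4.0 / n_cells) * (err * M**2).sum(axis=2) * s + (
            2.0 * lambda_ / N_DIRECTIONS
        ) * s
        ms = b1 * ms + (1 - b1) * gs
        vs = b2 * vs + (1 - b2) * gs**2
        mM = b1 * mM + (1 - b1) * gM
        vM = b2 * vM + (1 - b2) * gM**2
        c1 = 1 - b1**step
        c2 = 1 - b2**step
        s = s - learning_rate * (ms / c1) / (np.sqrt(vs / c2) + eps)
        M = M - learning_rate * (mM / c1) / (np.sqrt(vM / c2) + eps)

    err, mse, c = eval_cost(s, M)
    improved = c < best_cost
    best_mse = np.where(improved, mse, best_mse)
    best_s[improved] = s[improved]
    best_M[improved] = M[improved]

    best_mse = best_mse.reshape(B, n_inits)
    pick = best_mse.argmin(axis=1)
    rows = np.arange(B) * n_inits + pick
    return best_s[rows], best_M[rows], best_mse[np.arange(B), pick]


def fit_curves(
    curves: np.ndarray,
    lambda_: float,
    n_inits: int = 5,
    n_steps: int = 300,
    rng: np.random.Generator | None = None,
    learning_rate: float = 0.05,
    chunk: int = 2000,
):
    """Batched decomposition fit for an array of curves (B, 8, 8).

    Returns ``(s, M, snr_db)`` arrays.  This is the fast path used by the
    permutation null and the bootstrap refits; :class:`SubunitDecomposition`
    wraps it for single curves.
    """
    if n_inits <= 0:
        raise ValueError("n_inits must be positive")
    if n_steps <= 0:
        raise ValueError("n_steps must be positive")
    if rng is None:
        raise ValueError("a seeded rng is required")
    curves = np.asarray(curves, dtype=float)
    out_s, out_M, out_mse = [], [], []
    for a in range(0, curves.shape[0], chunk):
        s, M, mse = _fit_batch(
            curves[a : a + chunk], lambda_, n_inits, n_steps, rng, learning_rate
        )
        out_s.append(s)
        out_M.append(M)
        out_mse.append(mse)
    s = np.concatenate(out_s)
    M = np.concatenate(out_M)
    mse = np.concatenate(out_mse)
    return s, M, _snr_db(curves, mse)


def significant_subunits(scaled_modulators: np.ndarray) -> list:
    """Indices of subunits whose mean scaled modulator is at least 5% of the
    strongest subunit's mean scaled modulator."""
    g = np.asarray(scaled_modulators, dtype=float)
    means = g.mean(axis=1)
    top = means.max()
    if top <= 0:
        return []
    return [int(i) for i in np.flatnonzero(means >= SIGNIFICANCE_FRACTION * top)]


class SubunitDecomposition:
    """Sparse subunit-decomposition model for one direction-speed curve.

    Parameters
    ----------
    curve : DirectionSpeedCurve or (8, 8) array_like
        Complete, non-negative direction-speed tuning curve.

    Examples
    --------
    >>> model = SubunitDecomposition(curve)
    >>> res = model.fit(lambda_=0.01, rng=np.random.default_rng(0))
    >>> res.significant_subunits
    [2, 6]
    >>> print(res.summary())
    """

    def __init__(self, curve):
        if isinstance(curve, DirectionSpeedCurve):
            values = curve.values
        else:
            values = np.asarray(curve, dtype=float)
        if values.shape != (N_DIRECTIONS, N_SPEED_BINS):
            raise ValueError("curve must be 8 x 8")
        if not np.all(np.isfinite(values)):
            raise ValueError("curve must be complete (finite everywhere)")
        if np.any(values < 0):
            raise ValueError("curve must be non-negative")
        self.curve = values

    def fit(
        self,
        lambda_: float = 0.01,
        n_inits: int = 5,
        n_steps: int = 300,
        rng: np.random.Generator | None = None,
        learning_rate: float = 0.05,
    ) -> "SubunitDecompositionResults":
        """Fit at a single sparsity value; best of ``n_inits`` random starts."""
        if not np.any(self.curve > 0):
            raise ValueError("degenerate all-zero curve")
        if lambda_ < 0:
            raise ValueError("lambda must be non-negative")
        s, M, snr = fit_curves(
            self.curve[None], lambda_, n_inits, n_steps, rng, learning_rate
        )
        params = DecompositionParams(subunit_coeffs=s[0], modulators=M[0])
        return SubunitDecompositionResults(self, params, float(lambda_), float(snr[0]))

    def fit_path(
        self,
        lambdas=None,
        n_inits: int = 5,
        n_steps: int = 300,
        rng: np.random.Generator | None = None,
        learning_rate: float = 0.05,
    ) -> list:
        """One fit per sparsity value on the lambda grid (default 10 values
        evenly spaced on [0.01, 0.1])."""
        if lambdas is None:
            lambdas = default_lambda_grid()
        lambdas = np.asarray(lambdas, dtype=float)
        if lambdas.size == 0:
            raise ValueError("lambda grid must be non-empty")
        return [
            self.fit(float(lam), n_inits, n_steps, rng, learning_rate)
            for lam in lambdas
        ]


class SubunitDecompositionResults:
    """Fitted decomposition: parameters, effective gains and diagnostics.

    Attributes
    ----------
    params : DecompositionParams
        Raw coefficients and modulators (squared inside the model).
    lambda_ : float
        Sparsity value the fit was obtained at.
    snr_db : float
        Reconstruction SNR, 10 log10(Var(R) / MSE).
    """

    def __init__(self, model, params, lambda_, snr_db):
        self.model = model
        self.params = params
        self.lambda_ = lambda_
        self.snr_db = snr_db

    @property
    def reconstruction(self) -> np.ndarray:
        return reconstruct(self.params)

    @property
    def resid(self) -> np.ndarray:
        return self.model.curve - self.reconstruction

    @property
    def mse(self) -> float:
        return float(np.mean(self.resid**2))

    @property
    def scaled_modulators(self) -> np.ndarray:
        """Effective gains g[i, l] = m[i, l]^2 * s[i]^2 (8 x 8, >= 0)."""
        return reconstruct(self.params)

    @property
    def raw_scaled_modulators(self) -> np.ndarray:
        """The literal |m| * |s| product, for comparison; same support as
        :attr:`scaled_modulators` (its elementwise square root)."""
        return np.abs(self.params.modulators) * np.abs(
            self.params.subunit_coeffs[:, None]
        )

    @property
    def significant_subunits(self) -> list:
        return significant_subunits(self.scaled_modulators)

    @property
    def n_significant(self) -> int:
        return len(self.significant_subunits)

    def subunit_separation(self) -> float | None:
        """Angular separation (degrees) of the two strongest significant
        subunits on the 45-degree direction grid; None if fewer than two."""
        return subunit_separation(self)

    def summary(self) -> str:
        g = self.scaled_modulators
        means = g.mean(axis=1)
        sig = set(self.significant_subunits)
        lines = [
            "Sparse subunit decomposition",
            "=" * 46,
            f"lambda:          {self.lambda_:.4f}",
            f"SNR:             {self.snr_db:.2f} dB",
            f"MSE:             {self.mse:.5f}",
            f"significant:     {sorted(sig)}",
            "-" * 46,
            f"{'dir (deg)':>10} {'mean gain':>12} {'significant':>12}",
        ]
        for i in range(N_DIRECTIONS):
            lines.append(
                f"{i * 45:>10d} {means[i]:>12.4f} {'yes' if i in sig else '':>12}"
            )
        return "\n".join(lines)


def subunit_separation(fit: SubunitDecompositionResults) -> float | None:
    """Circular distance in degrees between the two strongest significant
    subunits (values in {45, 90, 135, 180}); None with fewer than two."""
    sig = fit.significant_subunits
    if len(sig) < 2:
        return None
    means = fit.scaled_modulators.mean(axis=1)
    order = sorted(sig, key=lambda i: -means[i])
    i, j = order[0], order[1]
    d = abs(i - j) * 45
    return float(min(d, 360 - d))


def null_snr_distribution(
    cohort,
    n_null: int = 10000,
    lambdas=None,
    rng: np.random.Generator | None = None,
    n_inits: int = 5,
    n_steps: int = 300,
):
    """Permutation null for the goodness-of-fit test.

    Curves are drawn from ``cohort`` with replacement; each draw's 64 bins
    are globally permuted, destroying the subunit structure while keeping
    the value distribution.  Every null curve is fitted at every lambda on
    the grid and the SNRs recorded.

    Returns ``(lambdas, snr)`` with ``snr`` of shape (n_lambda, n_null).
    """
    if rng is None:
        raise ValueError("a seeded rng is required")
    curves = _cohort_array(cohort)
    if curves.shape[0] == 0:
        raise ValueError("cohort must be non-empty")
    if lambdas is None:
        lambdas = default_lambda_grid()
    lambdas = np.asarray(lambdas, dtype=float)
    picks = rng.integers(0, curves.shape[0], size=n_null)
    flat = curves[picks].reshape(n_null, -1)
    perm = rng.permuted(flat, axis=1)
    null_curves = perm.reshape(n_null, N_DIRECTIONS, N_SPEED_BINS)
    snrs = np.empty((lambdas.size, n_null))
    for j, lam in enumerate(lambdas):
        _, _, snr = fit_curves(null_curves, float(lam), n_inits, n_steps, rng)
        snrs[j] = snr
    return lambdas, snrs


def _cohort_array(cohort) -> np.ndarray:
    if isinstance(cohort, np.ndarray):
        return cohort.reshape(-1, N_DIRECTIONS, N_SPEED_BINS)
    return np.stack(
        [
            c.values if isinstance(c, DirectionSpeedCurve) else np.asarray(c)
            for c in cohort
        ]
    )


def select_fit(fits, null_lambdas, null_snrs, q: float = 0.95):
    """Select the fit at the smallest lambda whose SNR exceeds the
    ``q``-quantile of that lambda's permutation-null SNR distribution.

    Returns the selected :class:`SubunitDecompositionResults`, or None if no
    lambda passes (the neuron's fit is not significant).
    """
    fit_lams = np.array([f.lambda_ for f in fits])
    null_lambdas = np.asarray(null_lambdas, dtype=float)
    if fit_lams.shape != null_lambdas.shape or not np.allclose(
        fit_lams, null_lambdas, atol=1e-12
    ):
        raise ValueError("fit and null lambda grids do not match")
    order = np.argsort(fit_lams)
    thresholds = np.quantile(null_snrs, q, axis=1)
    for j in order:
        if fits[j].snr_db > thresholds[j]:
            return fits[j]
    return None
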