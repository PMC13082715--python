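"""Differential-modulation analysis: rho-bar, bootstraps, correlation plane."""

import numpy as np
import pytest

from gainmod.binning import SPEED_CENTERS
from gainmod.decomposition import (
    DecompositionParams,
    SubunitDecomposition,
    SubunitDecompositionResults,
)
from gainmod.modulators import (
    ModulatorPair,
    classify_plane,
    corr_max_fit,
    null_speed_band,
    pearson,
    shared_modulator,
    simulate_shared_with_noise,
    speed_correlation,
    strength_ratio,
    test_differential as run_differential_test,
)


def make_fit(scaled):
    """A decomposition results object with prescribed scaled modulators."""
    scaled = np.asarray(scaled, dtype=float)
    M = np.sqrt(scaled)
    curve = np.maximum(scaled, 1e-6)
    return SubunitDecompositionResults(
        SubunitDecomposition(curve),
        DecompositionParams(np.ones(8), M),
        0.01,
        10.0,
    )


class TestPearson:
    def test_perfect_and_inverse(self):
        a = np.arange(8.0)
        assert pearson(a, a) == pytest.approx(1.0)
        assert pearson(a, -a) == pytest.approx(-1.0)

    def test_constant_undefined(self):
        assert np.isnan(pearson(np.arange(8.0), np.ones(8)))

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            pearson(np.ones(8), np.ones(7))


class TestStrengthRatio:
    def test_equal_modulators(self):
        p = ModulatorPair(np.ones(8), np.ones(8))
        assert strength_ratio(p) == (pytest.approx(1.0), pytest.approx(0.0))

    def test_four_to_one(self):
        p = ModulatorPair(np.full(8, 4.0), np.ones(8))
        ratio, log2r = strength_ratio(p)
        assert ratio == pytest.approx(4.0)
        assert log2r == pytest.approx(2.0)

    def test_zero_weaker_undefined(self):
        p = ModulatorPair(np.ones(8), np.zeros(8))
        ratio, log2r = strength_ratio(p)
        assert np.isnan(ratio) and np.isnan(log2r)

    def test_ordering_enforced(self):
        with pytest.raises(ValueError):
            ModulatorPair(stronger=np.ones(8), weaker=np.full(8, 2.0))
        p = ModulatorPair.from_modulators(np.ones(8), np.full(8, 2.0))
        assert p.stronger.mean() == 2.0


class TestCorrMaxFit:
    def test_identical_inputs(self, rng):
        g = np.arange(1.0, 9.0)
        ghat, rho = corr_max_fit(g, g, rng=rng)
        assert rho == pytest.approx(1.0, abs=1e-9)
        assert (ghat >= 0).all()

    def test_anticorrelated_affine_pair(self, rng):
        g = np.arange(1.0, 9.0)
        _, rho = corr_max_fit(g, 9 - g, rng=rng)
        assert rho == pytest.approx(0.0, abs=1e-6)

    def test_matches_random_search_oracle(self):
        rng = np.random.default_rng(7)
        oracle_rng = np.random.default_rng(8)
        for _ in range(10):
            g1 = rng.uniform(0, 2, 8)
            g2 = rng.uniform(0, 2, 8)
            _, rho = corr_max_fit(g1, g2, n_starts=3, rng=rng)
            # brute-force search over random non-negative curves
            cand = oracle_rng.uniform(0, 1, size=(20_000, 8))
            cc = cand - cand.mean(axis=1, keepdims=True)
            cc /= np.linalg.norm(cc, axis=1, keepdims=True)
            best = 0.5 * (
                cc @ _unit(g1) + cc @ _unit(g2)
            ).max()
            assert rho >= best - 0.02

    def test_upper_bound_attained(self, rng):
        # the optimum equals sqrt((1 + rho12) / 2): correlation is
        # shift-invariant, so non-negativity never binds
        for _ in range(10):
            g1 = rng.uniform(0, 2, 8)
            g2 = rng.uniform(0, 2, 8)
            bound = np.sqrt((1 + pearson(g1, g2)) / 2)
            _, rho = corr_max_fit(g1, g2, n_starts=3, rng=rng)
            assert rho == pytest.approx(bound, abs=1e-6)

    def test_invariance_to_scaling_and_shift(self, rng):
        g1 = rng.uniform(0, 2, 8)
        g2 = rng.uniform(0, 2, 8)
        _, rho = corr_max_fit(g1, g2, rng=np.random.default_rng(0))
        _, rho2 = corr_max_fit(3 * g1 + 1, 0.5 * g2 + 2, rng=np.random.default_rng(0))
        assert rho2 == pytest.approx(rho, abs=1e-6)

    def test_constant_input_undefined(self, rng):
        _, rho = corr_max_fit(np.ones(8), np.arange(8.0), rng=rng)
        assert np.isnan(rho)


def _unit(g):
    c = g - g.mean()
    return c / np.linalg.norm(c)


class TestSharedModulator:
    def test_identical_modulators(self):
        g = np.linspace(0.5, 2.0, 8)
        scaled = np.zeros((8, 8))
        scaled[0] = scaled[4] = g
        np.testing.assert_allclose(shared_modulator(make_fit(scaled)), g)

    def test_half_of_single(self):
        v = np.linspace(1.0, 2.0, 8)
        scaled = np.zeros((8, 8))
        scaled[1] = v
        scaled[5] = 1e-3  # tiny but significant is required; make it above 5%
        scaled[5] = 0.1 * v
        fit = make_fit(scaled)
        np.testing.assert_allclose(shared_modulator(fit), (v + 0.1 * v) / 2)

    def test_elementwise_mean_oracle(self, rng):
        g1 = rng.uniform(0.5, 2, 8)
        g2 = rng.uniform(0.5, 2, 8)
        scaled = np.zeros((8, 8))
        scaled[2], scaled[6] = g1, g2
        np.testing.assert_allclose(shared_modulator(make_fit(scaled)), (g1 + g2) / 2)

    def test_requires_two_significant(self):
        scaled = np.zeros((8, 8))
        scaled[3] = 1.0
        with pytest.raises(ValueError):
            shared_modulator(make_fit(scaled))


class TestDifferentialDecision:
    def test_above_median_not_significant(self):
        null = np.linspace(0.5, 1.0, 200)
        assert not run_differential_test(0.9, null).significant

    def test_below_minimum_significant(self):
        null = np.linspace(0.5, 1.0, 200)
        res = run_differential_test(0.3, null, alpha=0.01)
        assert res.significant
        assert res.threshold >= 0.5

    def test_empty_null_rejected(self):
        with pytest.raises(ValueError):
            run_differential_test(0.5, [])


class TestSpeedCorrelation:
    def test_linear_profiles(self):
        assert speed_correlation(SPEED_CENTERS * 2 + 1) == pytest.approx(1.0)
        assert speed_correlation(-SPEED_CENTERS) == pytest.approx(-1.0)

    def test_symmetric_bump_uncorrelated(self):
        g = -np.abs(SPEED_CENTERS - 10.0)
        assert speed_correlation(g - g.min() + 0.1) == pytest.approx(0.0, abs=1e-12)

    def test_constant_undefined(self):
        assert np.isnan(speed_correlation(np.ones(8)))


class TestNullSpeedBand:
    def test_roughly_symmetric(self, rng):
        mods = rng.uniform(0, 2, size=(40, 8))
        lo, hi = null_speed_band(mods, rng=rng, n_perm=2000)
        assert lo < 0 < hi
        assert abs(lo + hi) < 0.1

    def test_reproducible(self):
        mods = np.random.default_rng(3).uniform(0, 2, size=(25, 8))
        b1 = null_speed_band(mods, rng=np.random.default_rng(4))
        b2 = null_speed_band(mods, rng=np.random.default_rng(4))
        assert b1 == b2

    def test_constant_modulators_error(self, rng):
        with pytest.raises(ValueError):
            null_speed_band(np.ones((25, 8)), rng=rng)

    def test_too_few_modulators(self, rng):
        with pytest.raises(ValueError):
            null_speed_band(np.ones((10, 8)), rng=rng)


class TestClassifyPlane:
    BAND = (-0.6, 0.6)

    @pytest.mark.parametrize(
        "rw, rs, region",
        [
            (0.99, 0.99, "both_positive"),
            (-0.9, -0.8, "both_negative"),
            (0.0, 0.0, "neutral"),
            (0.99, -0.2, "asymmetric"),
            (-0.9, 0.9, "asymmetric"),  # opposite extremes
        ],
    )
    def test_regions(self, rw, rs, region):
        assert classify_plane(rw, rs, self.BAND) == region

    def test_partition(self, rng):
        regions = {"both_positive", "both_negative", "neutral", "asymmetric"}
        for _ in range(200):
            r = classify_plane(*rng.uniform(-1, 1, 2), self.BAND)
            assert r in regions

    def test_undefined_rejected(self):
        with pytest.raises(ValueError):
            classify_plane(np.nan, 0.0, self.BAND)


class TestSimulateSharedWithNoise:
    def test_identical_modulators_unchanged(self):
        g = np.linspace(0.5, 2, 8)
        p = ModulatorPair(g.copy(), g.copy())
        out = simulate_shared_with_noise(p, noise_sd=0.0)
        np.testing.assert_allclose(out.stronger, g, atol=1e-12)
        np.testing.assert_allclose(out.weaker, g, atol=1e-12)

    def test_norms_preserved_without_noise(self, rng):
        p = ModulatorPair.from_modulators(
            rng.uniform(0.5, 2, 8), rng.uniform(0.5, 2, 8)
        )
        out = simulate_shared_with_noise(p, noise_sd=0.0)
        norms_in = sorted([np.linalg.norm(p.stronger), np.linalg.norm(p.weaker)])
        norms_out = sorted([np.linalg.norm(out.stronger), np.linalg.norm(out.weaker)])
        np.testing.assert_allclose(norms_in, norms_out, rtol=1e-12)

    def test_joint_coherence_erodes_with_noise(self):
        # the noisy shared-modulator control: with little noise both
        # correlations equal the average modulator's, so speed-related
        # neurons land in the jointly-extreme regions of the correlation
        # plane; heavier noise decorrelates the two copies and that joint
        # coherence decays monotonically over the noise grid
        rng = np.random.default_rng(11)
        from gainmod.simulate import modulator_value

        pairs = []
        for _ in range(200):
            g1 = np.exp(modulator_value(rng.normal(0, 0.5, 8), SPEED_CENTERS))
            g2 = np.exp(modulator_value(rng.normal(0, 0.5, 8), SPEED_CENTERS))
            pairs.append(ModulatorPair.from_modulators(g1, g2))
        mods = np.concatenate(
            [[p.stronger for p in pairs], [p.weaker for p in pairs]]
        )
        band = null_speed_band(mods, rng=np.random.default_rng(12), n_perm=200)

        def joint_extreme_fraction(noise):
            n = 0
            rng_n = np.random.default_rng(13)
            for p in pairs:
                out = simulate_shared_with_noise(p, noise_sd=noise, rng=rng_n)
                rw = speed_correlation(out.weaker)
                rs = speed_correlation(out.stronger)
                if np.isnan(rw) or np.isnan(rs):
                    continue
                n += classify_plane(rw, rs, band) in (
                    "both_positive",
                    "both_negative",
                )
            return n / len(pairs)

        fracs = [joint_extreme_fraction(s) for s in (0.01, 0.05, 0.1, 0.2)]
        assert all(a >= b for a, b in zip(fracs, fracs[1:]))
        assert fracs[0] > fracs[-1]

    def test_zero_norm_rejected(self):
        p = ModulatorPair(np.ones(8), np.zeros(8))
        with pytest.raises(ValueError):
            simulate_shared_with_noise(p, noise_sd=0.0)


class TestBootstrapShared:
    def test_null_values_and_count_preservation(self, modulated_trials):
        from gainmod.modulators import bootstrap_shared
        from gainmod.tuning import build_tensor

        _, trials = modulated_trials
        from gainmod.decomposition import SubunitDecomposition
        from gainmod.tuning import average_frequency

        curve = average_frequency(build_tensor(trials))
        fit = SubunitDecomposition(curve).fit(0.02, rng=np.random.default_rng(0))
        if fit.n_significant < 2:
            pytest.skip("fixture neuron fitted with < 2 subunits")
        null = bootstrap_shared(
            trials, fit, n_boot=30, rng=np.random.default_rng(1), refit_steps=150
        )
        assert null.shape == (30,)
        finite = null[np.isfinite(null)]
        assert finite.size >= 25
        assert ((finite >= -1) & (finite <= 1)).all()
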