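"""Preprocessing, tensors, QC, specificity, d_mod and the modulation test."""

import numpy as np
import pandas as pd
import pytest

from gainmod.binning import EXCLUDED, assign_speed_bin
from gainmod.tuning import (
    DegenerateNeuronError,
    DirectionSpeedCurve,
    TuningTensor3D,
    average_frequency,
    bootstrap_speed_shuffled_curves,
    build_tensor,
    d_mod,
    qc_filters,
    sensory_tuning,
    shuffle_speed,
    specificity,
    test_modulation as run_modulation_test,
    threshold_normalize,
)


class TestThresholdNormalize:
    def test_all_negative_is_degenerate(self):
        with pytest.raises(DegenerateNeuronError):
            threshold_normalize([-1.0, -2.0, -3.0])

    def test_unit_sd_example(self):
        # thresholded (0, 0, 2, 2) has population sd exactly 1
        out = threshold_normalize([0.0, 0.0, 2.0, 2.0])
        np.testing.assert_allclose(out, [0.0, 0.0, 2.0, 2.0])

    def test_threshold_before_scaling(self):
        out = threshold_normalize([-5.0, 3.0])
        assert out[0] == 0.0
        assert out.std() == pytest.approx(1.0)

    def test_output_nonnegative(self, rng):
        out = threshold_normalize(rng.normal(size=500))
        assert (out >= 0).all()
        assert out.std() == pytest.approx(1.0)

    def test_too_few_samples(self):
        with pytest.raises(ValueError):
            threshold_normalize([1.0])


class TestSpeedBins:
    @pytest.mark.parametrize(
        "speed, expected",
        [(0.0, 0), (2.49, 0), (2.5, 1), (19.99, 7), (20.0, 7), (25.0, EXCLUDED)],
    )
    def test_edges(self, speed, expected):
        assert assign_speed_bin(speed) == expected

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            assign_speed_bin(-0.1)

    def test_vectorized(self):
        out = assign_speed_bin([0.0, 10.0, 20.0, 21.0])
        np.testing.assert_array_equal(out, [0, 4, 7, EXCLUDED])


def _table(rows):
    return pd.DataFrame(
        rows,
        columns=["neuron_id", "response", "direction_deg", "tf_hz", "speed_cmps", "duration_s"],
    )


class TestBuildTensor:
    def test_singleton_and_mean(self):
        t = _table(
            [
                (0, 1.0, 0, 1, 1.0, 0.1),
                (0, 3.0, 0, 1, 1.0, 0.1),
                (0, 5.0, 45, 2, 6.0, 0.1),
            ]
        )
        tensor = build_tensor(t)
        assert tensor.means[0, 0, 0] == pytest.approx(2.0)
        assert tensor.counts[0, 0, 0] == 2
        assert tensor.seconds[0, 0, 0] == pytest.approx(0.2)
        assert tensor.means[1, 1, 2] == pytest.approx(5.0)
        assert np.isnan(tensor.means[3, 3, 3])

    def test_matches_groupby_oracle(self, rng):
        n = 10_000
        t = _table(
            list(
                zip(
                    np.zeros(n),
                    rng.normal(1, 1, n),
                    rng.choice(np.arange(0, 360, 45), n),
                    rng.choice([1, 2, 4, 8, 15], n),
                    rng.uniform(0, 20, n),
                    np.full(n, 1 / 30),
                )
            )
        )
        tensor = build_tensor(t)
        t2 = t.copy()
        t2["d"] = (t2["direction_deg"] // 45).astype(int)
        t2["f"] = t2["tf_hz"].map({1: 0, 2: 1, 4: 2, 8: 3, 15: 4})
        t2["v"] = assign_speed_bin(t2["speed_cmps"].to_numpy())
        oracle = t2.groupby(["d", "f", "v"])["response"].mean()
        for (d, f, v), m in oracle.items():
            assert tensor.means[d, f, v] == pytest.approx(m, abs=1e-12)

    def test_excluded_speeds_ignored(self):
        t = _table([(0, 1.0, 0, 1, 1.0, 0.1), (0, 99.0, 0, 1, 30.0, 0.1)])
        tensor = build_tensor(t)
        assert tensor.means[0, 0, 0] == pytest.approx(1.0)
        assert tensor.counts.sum() == 1


def _full_tensor(value=1.0, seconds=2.0):
    shape = (8, 5, 8)
    return TuningTensor3D(
        means=np.full(shape, value),
        counts=np.ones(shape, dtype=int),
        seconds=np.full(shape, seconds / 5),
    )


class TestQCFilters:
    def test_clean_tensor_passes(self):
        report = qc_filters(_full_tensor())
        assert report.passed and report.reasons == []

    def test_insufficient_seconds(self):
        tensor = _full_tensor()
        tensor.seconds[3, :, 4] = 0.5 / 5
        report = qc_filters(tensor)
        assert not report.passed
        assert report.reasons == ["insufficient seconds"]

    def test_frequency_coverage_boundary(self):
        # exactly 16 sparse bins still passes; 17 fails
        tensor = _full_tensor()
        flat = [(d, v) for d in range(8) for v in range(8)]
        for d, v in flat[:16]:
            tensor.counts[d, 2:, v] = 0
        assert qc_filters(tensor).passed
        d, v = flat[16]
        tensor.counts[d, 2:, v] = 0
        report = qc_filters(tensor)
        assert report.reasons == ["frequency coverage"]

    def test_empty_bin_and_multiple_reasons(self):
        tensor = _full_tensor()
        tensor.counts[0, :, 0] = 0
        tensor.seconds[0, :, 0] = 0
        report = qc_filters(tensor)
        assert "empty bins" in report.reasons
        assert "insufficient seconds" in report.reasons


class TestAverageFrequency:
    def test_mean_of_bin_means(self):
        tensor = _full_tensor()
        tensor.means[0, :, 0] = [1, 2, 3, 4, 5]
        curve = average_frequency(tensor)
        assert curve.values[0, 0] == pytest.approx(3.0)

    def test_mean_over_nonempty_cells_only(self):
        tensor = _full_tensor()
        tensor.means[0, :, 0] = [2, 2, np.nan, np.nan, np.nan]
        tensor.counts[0, 2:, 0] = 0
        curve = average_frequency(tensor)
        assert curve.values[0, 0] == pytest.approx(2.0)

    def test_matches_masked_mean_oracle(self, rng):
        tensor = _full_tensor()
        tensor.means = rng.uniform(0, 3, size=(8, 5, 8))
        drop = rng.random((8, 5, 8)) < 0.2
        # keep at least one tf per (d, v)
        drop[:, 0, :] = False
        tensor.means[drop] = np.nan
        tensor.counts[drop] = 0
        curve = average_frequency(tensor)
        oracle = np.ma.masked_invalid(tensor.means).mean(axis=1).filled(np.nan)
        np.testing.assert_allclose(curve.values, oracle, atol=1e-12)

    def test_requires_qc(self):
        tensor = _full_tensor()
        tensor.counts[2, :, 2] = 0
        with pytest.raises(ValueError):
            average_frequency(tensor)


class TestSpecificity:
    def test_uniform_is_zero(self):
        assert specificity(np.ones(8)) == pytest.approx(0.0, abs=1e-12)

    def test_single_direction_is_one(self):
        v = np.zeros(8)
        v[3] = 7.0
        assert specificity(v) == pytest.approx(1.0)

    def test_two_equal_bins(self):
        v = np.zeros(8)
        v[0] = v[1] = 0.5
        # entropy = 1 bit, normalized by 3 bits
        assert specificity(v) == pytest.approx(2 / 3, rel=1e-12)

    def test_permutation_and_scale_invariance(self, rng):
        v = rng.uniform(0.1, 2.0, size=8)
        s = specificity(v)
        assert specificity(rng.permutation(v)) == pytest.approx(s, rel=1e-12)
        assert specificity(v * 37.2) == pytest.approx(s, rel=1e-12)

    def test_all_zero_rejected(self):
        with pytest.raises(ValueError):
            specificity(np.zeros(8))

    def test_sensory_tuning_row_means(self, rng):
        values = rng.uniform(0.1, 2.0, size=(8, 8))
        st = sensory_tuning(DirectionSpeedCurve(values=values))
        np.testing.assert_allclose(st.values, values.mean(axis=1), atol=1e-12)


class TestDMod:
    def test_identical_columns_zero(self):
        values = np.tile(np.arange(8.0)[:, None], (1, 8))
        assert d_mod(DirectionSpeedCurve(values=values)) == pytest.approx(0.0)

    def test_one_perturbed_slice(self, rng):
        v = rng.uniform(1, 2, size=8)
        values = np.tile(v[:, None], (1, 8))
        e = np.zeros(8)
        e[2] = 1.0
        values[:, 5] += e
        # mean shifts by e/8: seven slices at 1/8, one at 7/8
        assert d_mod(DirectionSpeedCurve(values=values)) == pytest.approx(1.75)

    def test_matches_bruteforce(self, rng):
        values = rng.uniform(0, 3, size=(8, 8))
        mean_dir = values.mean(axis=1)
        oracle = sum(
            np.sqrt(((values[:, l] - mean_dir) ** 2).sum()) for l in range(8)
        )
        assert d_mod(DirectionSpeedCurve(values=values)) == pytest.approx(oracle, rel=1e-12)

    def test_nonnegative(self, rng):
        for _ in range(20):
            values = rng.uniform(0, 1, size=(8, 8))
            assert d_mod(DirectionSpeedCurve(values=values)) >= 0


class TestShuffleSpeed:
    def test_counts_preserved(self, modulated_trials):
        _, trials = modulated_trials
        shuffled = shuffle_speed(trials, np.random.default_rng(0))
        orig = build_tensor(trials)
        new = build_tensor(shuffled)
        np.testing.assert_array_equal(orig.counts, new.counts)

    def test_constant_stratum_invariant(self):
        rows = []
        for d in range(0, 360, 45):
            for f in [1, 2, 4, 8, 15]:
                for v in range(8):
                    rows.append((0, d + f, d, f, v * 2.5 + 1.0, 0.1))
        trials = _table(rows)
        shuffled = shuffle_speed(trials, np.random.default_rng(1))
        np.testing.assert_array_equal(
            build_tensor(trials).means, build_tensor(shuffled).means
        )

    def test_bootstrap_mean_is_stratum_mean(self):
        # law of total expectation: averaging many shuffled curves recovers
        # the (direction, tf) stratum grand means in every speed bin
        rows = []
        rng = np.random.default_rng(2)
        for d in range(0, 360, 45):
            for f in [1, 2, 4, 8, 15]:
                for v in range(8):
                    for _ in range(3):
                        rows.append((0, rng.uniform(0, 2), d, f, v * 2.5 + 1.0, 0.1))
        trials = _table(rows)
        curves = bootstrap_speed_shuffled_curves(trials, 4000, np.random.default_rng(3))
        grand = build_tensor(trials).means.mean(axis=2)  # (d, f) stratum means
        expected = np.tile(grand.mean(axis=1)[:, None], (1, 8))
        np.testing.assert_allclose(curves.mean(axis=0), expected, atol=0.02)


class TestModulationTest:
    def test_modulated_neuron_significant(self, modulated_trials):
        _, trials = modulated_trials
        res = run_modulation_test(trials, n_boot=200, rng=np.random.default_rng(0))
        assert res.significant
        assert res.d_mod_data > res.threshold
        assert res.null.shape == (200,)

    def test_guard_on_nboot(self, modulated_trials):
        _, trials = modulated_trials
        with pytest.raises(ValueError):
            run_modulation_test(trials, n_boot=0, rng=np.random.default_rng(0))
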