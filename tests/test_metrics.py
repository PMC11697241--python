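"""Reliability metrics: oracle equivalence, invariances, corrections."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from spikerel.metrics import (
    InsufficientRepetitionsError,
    SweepSet,
    corrected_reliability,
    latency_cdf,
    matching_fraction,
    nearest_spike_latencies,
    spiking_reliability,
    subthreshold_reliability,
)


def brute_force_latencies(a, b):
    """O(n*m) oracle: min |t_a - t_b| over all spike pairs."""
    return np.array([min(abs(t - s) for s in b) for t in a])


def brute_force_matching(a, b, window_ms):
    lat = brute_force_latencies(a, b)
    return np.mean(lat <= window_ms * 1e-3)


def make_sweepset(sweeps, window=(0.0, 3.0)):
    return SweepSet("n0", "Noise1", 100, sweeps, stimulus_window_s=window)


class TestNearestSpikeLatencies:
    def test_hand_worked_example(self):
        a = np.array([10.0, 20.0, 30.0]) * 1e-3
        b = np.array([10.5, 25.0, 30.2]) * 1e-3
        np.testing.assert_allclose(
            nearest_spike_latencies(a, b), np.array([0.5, 5.0, 0.2]) * 1e-3
        )

    def test_identical_trains_give_zeros(self):
        a = np.array([0.1, 0.5, 2.9])
        assert np.all(nearest_spike_latencies(a, a) == 0.0)

    def test_empty_reference_raises(self):
        with pytest.raises(ValueError, match="empty"):
            nearest_spike_latencies(np.array([0.1]), np.array([]))

    def test_matches_brute_force_on_random_pairs(self, rng):
        for _ in range(1000):
            a = np.sort(rng.uniform(0, 3, size=rng.integers(1, 30)))
            b = np.sort(rng.uniform(0, 3, size=rng.integers(1, 30)))
            np.testing.assert_allclose(
                nearest_spike_latencies(a, b), brute_force_latencies(a, b)
            )


class TestMatchingFraction:
    def test_hand_worked_example(self):
        a = np.array([10.0, 20.0, 30.0]) * 1e-3
        b = np.array([10.5, 25.0, 30.2]) * 1e-3
        assert matching_fraction(a, b, 1.0) == pytest.approx(2 / 3)

    def test_identical_trains_give_one(self, rng):
        a = np.sort(rng.uniform(0, 3, 17))
        assert matching_fraction(a, a, 0.001) == 1.0

    def test_infinite_window_matches_everything(self, rng):
        a = np.sort(rng.uniform(0, 3, 9))
        b = np.sort(rng.uniform(0, 3, 4))
        assert matching_fraction(a, b, 1e9) == 1.0

    def test_window_boundary_is_inclusive(self):
        assert matching_fraction(np.array([0.010]), np.array([0.011]), 1.0) == 1.0

    def test_empty_train_a_raises(self):
        with pytest.raises(ValueError):
            matching_fraction(np.array([]), np.array([0.1]), 1.0)

    @given(st.integers(0, 2**31 - 1), st.floats(0.1, 5.0), st.floats(1.01, 4.0))
    def test_monotone_in_window(self, seed, w, factor):
        r = np.random.default_rng(seed)
        a = np.sort(r.uniform(0, 3, 10))
        b = np.sort(r.uniform(0, 3, 10))
        assert matching_fraction(a, b, w * factor) >= matching_fraction(a, b, w)

    def test_matches_brute_force_on_random_pairs(self, rng):
        for _ in range(1000):
            a = np.sort(rng.uniform(0, 3, size=rng.integers(1, 25)))
            b = np.sort(rng.uniform(0, 3, size=rng.integers(1, 25)))
            w = rng.uniform(0.1, 5.0)
            assert matching_fraction(a, b, w) == pytest.approx(
                brute_force_matching(a, b, w)
            )


class TestSpikingReliability:
    def test_identical_sweeps_give_one(self, rng):
        s = np.sort(rng.uniform(0, 3, 12))
        assert spiking_reliability(make_sweepset([s, s, s])) == 1.0

    def test_disjoint_sweeps_give_zero(self):
        ss = make_sweepset([np.array([0.1, 0.5]), np.array([1.0, 2.0])])
        assert spiking_reliability(ss) == 0.0

    def test_trial_count_unbiasedness(self, rng):
        """The per-pair average has the same expectation with 2 and with 8
        i.i.d. sweeps; only its variance shrinks with more trials."""
        def draw_sweep():
            base = np.linspace(0.25, 2.75, 12)
            return np.sort(base + rng.normal(0, 2e-3, size=base.size))

        two = [spiking_reliability(make_sweepset([draw_sweep(), draw_sweep()]))
               for _ in range(300)]
        eight = [spiking_reliability(make_sweepset([draw_sweep() for _ in range(8)]))
                 for _ in range(75)]
        assert np.mean(eight) == pytest.approx(np.mean(two), abs=0.02)
        assert np.std(eight) < np.std(two)

    def test_empty_sweeps_are_excluded(self, rng):
        a = np.sort(rng.uniform(0, 3, 8))
        with_empty = make_sweepset([a, np.array([]), a])
        assert spiking_reliability(with_empty) == 1.0

    def test_insufficient_usable_sweeps_raise(self):
        ss = make_sweepset([np.array([0.1]), np.array([])])
        with pytest.raises(InsufficientRepetitionsError):
            spiking_reliability(ss)


class TestCorrectedReliability:
    def test_perfectly_repeated_sparse_trains(self):
        """5 spikes repeated exactly: chance overlap in a 1 ms window of a
        3 s stimulus is tiny, so the corrected value stays near 1."""
        s = np.array([0.2, 0.9, 1.5, 2.1, 2.8])
        res = corrected_reliability(make_sweepset([s, s, s]), rng_seed=0)
        assert res.raw_reliability == 1.0
        assert res.corrected_reliability > 0.99
        assert 0.0 <= res.shuffled_mean <= 1.0

    def test_null_trains_have_near_zero_correction(self, rng):
        """Uniform-random trains are pure chance structure: the permutation
        correction should cancel the raw value on average."""
        vals = []
        for i in range(60):
            sweeps = [
                np.sort(rng.uniform(0, 3, size=rng.integers(10, 40)))
                for _ in range(int(rng.integers(2, 9)))
            ]
            res = corrected_reliability(
                make_sweepset(sweeps), rng_seed=int(rng.integers(2**31))
            )
            vals.append(res.corrected_reliability)
        vals = np.asarray(vals)
        se = vals.std(ddof=1) / np.sqrt(vals.size)
        assert abs(vals.mean()) < 3 * se

    def test_seed_reproducibility(self, rng):
        sweeps = [np.sort(rng.uniform(0, 3, 20)) for _ in range(3)]
        r1 = corrected_reliability(make_sweepset(sweeps), rng_seed=5)
        r2 = corrected_reliability(make_sweepset(sweeps), rng_seed=5)
        assert r1.corrected_reliability == r2.corrected_reliability

    def test_zero_permutations_rejected(self, rng):
        sweeps = [np.sort(rng.uniform(0, 3, 5)) for _ in range(2)]
        with pytest.raises(ValueError):
            corrected_reliability(make_sweepset(sweeps), n_permutations=0)

    def test_result_bookkeeping(self, rng):
        sweeps = [np.sort(rng.uniform(0, 3, 10)) for _ in range(4)]
        res = corrected_reliability(make_sweepset(sweeps), rng_seed=1)
        assert res.n_pairs == 12
        assert res.n_permutations == 100
        assert 0.0 <= res.raw_reliability <= 1.0
        assert -1.0 <= res.corrected_reliability <= 1.0


class TestLatencyCdf:
    def test_all_zero_latencies(self):
        grid = np.array([0.0, 0.5, 1.0])
        np.testing.assert_array_equal(
            latency_cdf(np.zeros(10), grid), np.ones(3)
        )

    def test_uniform_latencies_median(self, rng):
        lat = rng.uniform(0, 1, size=100_000)
        val = latency_cdf(lat, np.array([0.5]))[0]
        assert val == pytest.approx(0.5, abs=0.01)

    @given(st.integers(0, 2**31 - 1), st.sampled_from(["empirical", "gaussian-kernel"]))
    def test_nondecreasing_and_bounded(self, seed, method):
        r = np.random.default_rng(seed)
        lat = r.exponential(1.0, size=50)
        grid = np.linspace(-1, 5, 40)
        cdf = latency_cdf(lat, grid, method=method)
        assert np.all(np.diff(cdf) >= -1e-12)
        assert np.all((cdf >= 0) & (cdf <= 1))

    def test_kernel_tracks_empirical(self, rng):
        lat = rng.exponential(1.0, size=20_000)
        grid = np.linspace(0.1, 4, 10)
        emp = latency_cdf(lat, grid, "empirical")
        ker = latency_cdf(lat, grid, "gaussian-kernel")
        assert np.max(np.abs(emp - ker)) < 0.05

    def test_empty_input_raises(self):
        with pytest.raises(ValueError):
            latency_cdf(np.array([]), np.array([0.5]))


class TestSubthresholdReliability:
    def test_identical_traces(self, rng):
        v = rng.normal(size=500)
        assert subthreshold_reliability([v, v.copy()]) == pytest.approx(1.0)

    def test_monotone_transform_invariance(self, rng):
        v = rng.normal(size=500)
        assert subthreshold_reliability([v, np.exp(v / 2)]) == pytest.approx(1.0)

    def test_independent_noise_is_near_zero(self, rng):
        traces = [rng.normal(size=10_000) for _ in range(4)]
        assert abs(subthreshold_reliability(traces)) < 0.05

    def test_length_mismatch_raises(self, rng):
        with pytest.raises(ValueError, match="length"):
            subthreshold_reliability([rng.normal(size=10), rng.normal(size=11)])

    def test_constant_trace_excluded_with_warning(self, rng):
        v = rng.normal(size=200)
        with pytest.warns(UserWarning, match="constant"):
            rho = subthreshold_reliability([v, v.copy(), np.zeros(200)])
        assert rho == pytest.approx(1.0)

    def test_windowing(self, rng):
        a = rng.normal(size=1000)
        b = np.concatenate([a[:500], rng.normal(size=500)])
        full = subthreshold_reliability([a, b])
        windowed = subthreshold_reliability(
            [a, b], window=(0.0, 0.5), sampling_rate_hz=1000.0
        )
        assert windowed == pytest.approx(1.0)
        assert full < windowed
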