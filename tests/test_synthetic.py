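"""Synthetic population generator: determinism, corruption knobs, layout."""

import numpy as np
import pytest

from spikerel.metrics import corrected_reliability
from spikerel.synthetic_data import (
    EXCITATORY_LIKE,
    PV_LIKE,
    SyntheticCellClass,
    jitter_train,
    make_template_train,
    read_dataset,
    simulate_population,
    write_dataset,
)


class TestMakeTemplateTrain:
    def test_expected_count_matches_rate(self, protocol, rng):
        rate = 12.0
        counts = [
            make_template_train(protocol, rate, rng).size for _ in range(200)
        ]
        expected = rate * 3.0
        # Poisson: SD of the mean of 200 counts
        se = np.sqrt(expected / 200)
        assert abs(np.mean(counts) - expected) < 3 * se

    def test_spikes_confined_to_stimulus_window(self, protocol, rng):
        t = make_template_train(protocol, 20.0, rng)
        assert t.size > 0
        assert t.min() >= 0.0 and t.max() <= 3.0

    def test_same_seed_gives_identical_train(self, protocol):
        a = make_template_train(protocol, 10.0, 42)
        b = make_template_train(protocol, 10.0, 42)
        np.testing.assert_array_equal(a, b)

    def test_invalid_rate_rejected(self, protocol):
        with pytest.raises(ValueError):
            make_template_train(protocol, 0.0, 0)


class TestJitterTrain:
    def test_identity_when_all_knobs_off(self, rng):
        cls = SyntheticCellClass(
            "clean", jitter_sd_ms=0.0, spike_deletion_prob=0.0, extra_spike_rate_hz=0.0
        )
        template = np.sort(rng.uniform(0, 3, 25))
        np.testing.assert_array_equal(jitter_train(template, cls, 0), template)

    def test_full_deletion_leaves_only_extras(self, rng):
        cls = SyntheticCellClass(
            "gone", jitter_sd_ms=0.0, spike_deletion_prob=1.0, extra_spike_rate_hz=5.0
        )
        template = np.sort(rng.uniform(0, 3, 25))
        out = jitter_train(template, cls, 0)
        assert not np.isin(out, template).any()

    def test_mean_absolute_shift_is_half_normal(self):
        """E|shift| = sd * sqrt(2/pi) for Gaussian jitter."""
        sd_ms = 2.0
        cls = SyntheticCellClass(
            "j", jitter_sd_ms=sd_ms, spike_deletion_prob=0.0, extra_spike_rate_hz=0.0
        )
        # spacing (50 ms) >> jitter SD so sorting never reorders spikes
        template = np.linspace(0.25, 2.75, 51)
        shifts = []
        for seed in range(300):
            out = jitter_train(template, cls, seed)
            shifts.append(np.abs(np.sort(out) - template))
        mean_shift_ms = np.mean(np.concatenate(shifts)) * 1e3
        assert mean_shift_ms == pytest.approx(sd_ms * np.sqrt(2 / np.pi), rel=0.05)

    def test_counts_preserved_without_deletion_or_extras(self, rng):
        cls = SyntheticCellClass(
            "k", jitter_sd_ms=50.0, spike_deletion_prob=0.0, extra_spike_rate_hz=0.0
        )
        template = np.sort(rng.uniform(0, 3, 40))
        out = jitter_train(template, cls, 1)
        assert out.size == template.size
        assert out.min() >= 0.0 and out.max() <= 3.0


class TestSimulatePopulation:
    def test_repetition_counts_within_range(self, small_population):
        for rec in small_population:
            for ss in rec.sweep_sets:
                assert 2 <= ss.n_sweeps <= 8

    def test_sweep_layout_covers_conditions(self, small_population):
        for rec in small_population:
            conditions = {(ss.noise_id, ss.intensity_pct) for ss in rec.sweep_sets}
            assert conditions == {
                (n, i) for n in ("Noise1", "Noise2") for i in (75, 100, 150)
            }

    def test_frozen_noise_contract(self, small_population):
        """All sweeps of a neuron at one condition share the stimulus window."""
        for rec in small_population:
            for ss in rec.sweep_sets:
                assert ss.stimulus_window_s == (0.0, 3.0)

    def test_master_seed_reproducibility(self):
        a = simulate_population([PV_LIKE], 2, rng_seed=9)
        b = simulate_population([PV_LIKE], 2, rng_seed=9)
        for ra, rb in zip(a, b):
            for sa, sb in zip(ra.sweep_sets, rb.sweep_sets):
                for wa, wb in zip(sa.sweeps, sb.sweeps):
                    np.testing.assert_array_equal(wa, wb)

    def test_zero_neurons_rejected(self):
        with pytest.raises(ValueError):
            simulate_population([PV_LIKE], 0)

    def test_intrinsic_features_present(self, small_population):
        expected = {
            "membrane_tau_ms",
            "rheobase_pa",
            "upstroke_downstroke_ratio",
            "ramp_time_to_spike_s",
            "capacitance_pf",
            "conductance_ns",
        }
        assert expected <= set(small_population[0].intrinsic_features)

    def test_jitter_separates_corrected_reliability(self, small_population):
        """The low-jitter class must recover higher corrected reliability."""
        by_class = {"PV-like": [], "excitatory-like": []}
        for rec in small_population:
            ss = rec.sweep_set("Noise1", 100)
            res = corrected_reliability(ss, n_permutations=20, rng_seed=0)
            by_class[rec.class_name].append(res.corrected_reliability)
        assert np.mean(by_class["PV-like"]) > np.mean(by_class["excitatory-like"])


class TestDatasetRoundTrip:
    def test_spikes_and_annotations_survive(self, small_population, tmp_path):
        write_dataset(small_population, tmp_path)
        back = read_dataset(tmp_path)
        assert len(back) == len(small_population)
        for orig, rec in zip(small_population, back):
            assert rec.neuron_id == orig.neuron_id
            assert rec.transcriptomic_group == orig.transcriptomic_group
            assert rec.intrinsic_features == pytest.approx(orig.intrinsic_features)
            for so, sr in zip(orig.sweep_sets, rec.sweep_sets):
                assert sr.noise_id == so.noise_id
                assert sr.intensity_pct == so.intensity_pct
                for a, b in zip(so.sweeps, sr.sweeps):
                    np.testing.assert_allclose(b, a, atol=1e-9)

    def test_voltage_traces_survive_hdf5_sidecar(self, tmp_path):
        recs = simulate_population([PV_LIKE], 2, rng_seed=4, with_voltage=True)
        write_dataset(recs, tmp_path, with_voltage=True)
        back = read_dataset(tmp_path)
        for orig, rec in zip(recs, back):
            ss_o = orig.sweep_set("Noise1", 75)
            ss_r = rec.sweep_set("Noise1", 75)
            assert ss_r.sampling_rate_hz == ss_o.sampling_rate_hz
            for a, b in zip(ss_o.voltage, ss_r.voltage):
                np.testing.assert_array_equal(b, a)
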