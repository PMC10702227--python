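"""Spike detection, waveform stability, ISI profiling and rate analyses."""

import numpy as np
import pytest

from somnoephys.spikes import (DiscriminatorSpec, coefficient_of_determination,
                               discriminator_from_template, isi_profile,
                               isi_state_contrast, profile_unit,
                               rate_cross_correlation, smoothed_firing_rate,
                               state_rate_modulation, waveform_stability_test,
                               window_discriminate)
from somnoephys.synthetic import default_waveform_template, render_wideband

RNG = np.random.default_rng(5)
RATE = 20000.0


def planted_trace(n_spikes=100, noise_std=0.0, seed=0, duration_s=60.0,
                  amplitude=1.0):
    rng = np.random.default_rng(seed)
    times = np.sort(rng.uniform(1.0, duration_s - 1.0, n_spikes))
    times = times[np.concatenate(([True], np.diff(times) > 0.01))]
    template = default_waveform_template(RATE, amplitude=amplitude)
    trace = render_wideband(times, duration_s, template=template, rate=RATE,
                            noise_std=noise_std, seed=seed)
    return times, trace, template


class TestWindowDiscriminate:
    def test_noise_free_planted_templates_all_found(self):
        times, trace, template = planted_trace(n_spikes=100, noise_std=0.0)
        spec = discriminator_from_template(template, RATE)
        det, snippets = window_discriminate(trace, spec, RATE)
        assert len(det) == len(times)
        # crossings sit a fixed fraction of a waveform after template onset
        assert np.abs(det - times).max() < 5e-4
        assert snippets.shape[1] == int(3e-3 * RATE)

    def test_windows_off_trajectory_detect_nothing(self):
        _, trace, template = planted_trace(n_spikes=50, noise_std=0.0)
        spec = discriminator_from_template(template, RATE)
        off = DiscriminatorSpec(threshold=spec.threshold,
                                window1=(spec.window1[0], 5.0, 6.0),
                                window2=spec.window2)
        det, _ = window_discriminate(trace, off, RATE)
        assert len(det) == 0

    def test_snr5_sensitivity_and_precision(self):
        # amplitude 1 spikes in noise_std 0.2 -> SNR 5
        times, trace, template = planted_trace(
            n_spikes=200, noise_std=0.2, duration_s=120.0, seed=3)
        spec = discriminator_from_template(template, RATE)
        det, _ = window_discriminate(trace, spec, RATE)
        matched = sum(np.min(np.abs(det - t)) < 5e-4 for t in times)
        sensitivity = matched / len(times)
        false_pos = (len(det) - matched) / max(1, len(det))
        assert sensitivity >= 0.95
        assert false_pos <= 0.05

    def test_low_rate_rejected(self):
        spec = DiscriminatorSpec(-1.0, (0.2, -2, 0), (0.8, 0, 2))
        with pytest.raises(ValueError):
            window_discriminate(np.zeros(1000), spec, rate=5000)


class TestCoD:
    def test_identity_is_one(self):
        w = RNG.standard_normal(60)
        assert coefficient_of_determination(w, w) == 1.0

    def test_flat_at_mean_is_zero(self):
        w = RNG.standard_normal(60)
        b = np.full_like(w, w.mean())
        assert coefficient_of_determination(w, b) == pytest.approx(0.0,
                                                                   abs=1e-12)

    def test_hand_computed_example(self):
        # 1 - 1/5 = 0.8 for [1,2,3,4] vs [1,2,3,5]
        assert coefficient_of_determination(
            [1, 2, 3, 4], [1, 2, 3, 5]) == pytest.approx(0.8)

    def test_flat_reference_rejected(self):
        with pytest.raises(ValueError):
            coefficient_of_determination(np.ones(10), np.zeros(10))


class TestStability:
    def _waveforms(self, template, n=300, noise=0.05, seed=0):
        rng = np.random.default_rng(seed)
        return template + noise * rng.standard_normal((n, len(template)))

    def test_consistent_unit_is_stable(self):
        t = default_waveform_template()
        other = np.roll(t, 8) * 0.7
        res = waveform_stability_test(self._waveforms(t, seed=1),
                                      self._waveforms(t, seed=2),
                                      self._waveforms(other, seed=3))
        assert res.stable

    def test_changed_waveform_is_unstable(self):
        t = default_waveform_template()
        other = np.roll(t, 8) * 0.7
        res = waveform_stability_test(self._waveforms(t, seed=1),
                                      self._waveforms(other, seed=2),
                                      self._waveforms(t, seed=3))
        assert not res.stable

    def test_identical_distributions_not_stable(self):
        t = default_waveform_template()
        res = waveform_stability_test(self._waveforms(t, seed=1),
                                      self._waveforms(t, seed=2),
                                      self._waveforms(t, seed=3))
        assert not res.stable


class TestISIProfile:
    def _train(self, mode_ms, n=3000, seed=0):
        rng = np.random.default_rng(seed)
        # shifted-gamma ISIs with a sharp mode at mode_ms
        shape = 50.0
        scale = mode_ms / (shape - 1)
        isi = rng.gamma(shape, scale, n) / 1000.0
        return np.cumsum(isi)

    def test_fs_and_rs_classes(self):
        _, _, peak_fs, cls_fs = isi_profile(self._train(5.0))
        _, _, peak_rs, cls_rs = isi_profile(self._train(50.0))
        assert cls_fs == "FS" and abs(peak_fs - 5.0) <= 1.0
        assert cls_rs == "RS" and abs(peak_rs - 50.0) <= 2.0

    @pytest.mark.parametrize("mode,expected", [(9.5, "FS"), (10.5, "RS")])
    def test_boundary_is_strict_ten_ms(self, mode, expected):
        rng = np.random.default_rng(1)
        isi = (mode + 0.2 * rng.standard_normal(20000)) / 1000.0
        train = np.cumsum(np.clip(isi, 1e-4, None))
        _, _, peak, cls = isi_profile(train)
        assert cls == expected

    def test_too_few_spikes_rejected(self):
        with pytest.raises(ValueError):
            isi_profile(np.array([0.1]))


class TestISIStateContrast:
    def test_identical_firing_no_contrast(self):
        states = np.array(["Move", "NREM"] * 100)
        train = np.arange(0.05, 1600.0, 0.05)
        c = isi_state_contrast(train, states, "NREM")
        assert not c.missing
        assert np.abs(c.contrast_time).max() < 0.01
        assert np.nansum(c.contrast_time) == pytest.approx(0.0, abs=1e-9)

    def test_planted_rhythm_shows_frequency_peak(self):
        rng = np.random.default_rng(2)
        states = np.array(["Move"] * 100 + ["NREM"] * 100)
        move_t = np.cumsum(rng.exponential(0.05, 12000))
        move_t = move_t[move_t < 800]
        # 8 Hz rhythmic firing in NREM (ISI mode at 125 ms)
        nrem_isi = 0.125 + 0.004 * rng.standard_normal(6000)
        nrem_t = 800 + np.cumsum(np.clip(nrem_isi, 0.01, None))
        nrem_t = nrem_t[nrem_t < 1600]
        train = np.concatenate([move_t, nrem_t])
        c = isi_state_contrast(train, states, "NREM")
        band = (c.freq_hz >= 7) & (c.freq_hz <= 10)
        assert np.nanmax(c.contrast_freq[band]) > 0.5 * np.nanmax(c.contrast_freq)

    def test_missing_state_flagged(self):
        states = np.array(["Move"] * 50)
        c = isi_state_contrast(np.arange(0.1, 300, 0.1), states, "REM")
        assert c.missing


class TestSmoothedRate:
    def test_single_spike_unit_area(self):
        r = smoothed_firing_rate(np.array([0.5]), duration_s=1.0)
        assert r.sum() / 1000.0 == pytest.approx(1.0, abs=1e-6)
        assert r.max() > 0

    def test_homogeneous_train_mean_rate(self):
        rng = np.random.default_rng(0)
        t = np.sort(rng.uniform(0, 100, 2000))
        r = smoothed_firing_rate(t, duration_s=100.0)
        assert r.mean() == pytest.approx(20.0, abs=1.0)

    def test_empty_train_zero_series(self):
        r = smoothed_firing_rate(np.array([]), duration_s=2.0)
        assert np.all(r == 0) and len(r) == 2000

    def test_integral_equals_count_any_train(self):
        rng = np.random.default_rng(4)
        t = np.sort(rng.uniform(0, 10, 137))
        r = smoothed_firing_rate(t, duration_s=10.0)
        assert r.sum() / 1000.0 == pytest.approx(137.0, rel=1e-6)


class TestRateCrossCorrelation:
    def test_self_correlation_peaks_at_zero(self):
        r = smoothed_firing_rate(np.sort(RNG.uniform(0, 50, 1000)), 50.0)
        lags, xc = rate_cross_correlation(r, r)
        assert lags[np.nanargmax(xc)] == 0.0
        assert np.nanmax(xc) == pytest.approx(1.0, abs=1e-9)

    def test_shifted_copy_peaks_at_shift(self):
        r = smoothed_firing_rate(np.sort(RNG.uniform(0, 50, 1000)), 50.0)
        r_shift = np.roll(r, 10)
        lags, xc = rate_cross_correlation(r, r_shift)
        assert lags[np.nanargmax(xc)] == 10.0

    def test_independent_trains_uncorrelated(self):
        a = smoothed_firing_rate(np.sort(RNG.uniform(0, 500, 5000)), 500.0)
        b = smoothed_firing_rate(np.sort(RNG.uniform(0, 500, 5000)), 500.0)
        _, xc = rate_cross_correlation(a, b)
        assert np.nanmax(np.abs(xc)) < 0.05


class TestStateRateModulation:
    def test_uniform_rate_zero_modulation(self):
        states = np.array(["Move", "Rest", "REM", "NREM"] * 50)
        train = np.arange(0.1, 200 * 8.0, 0.1)
        mod = state_rate_modulation(train, states)
        for v in mod.values():
            assert abs(v) < 1.0

    def test_planted_half_rate_hand_value(self):
        # equal occupancy; NREM at half the rate of the others:
        # overall = 0.875x, NREM modulation = (0.5-0.875)/0.875 = -42.86%
        rng = np.random.default_rng(8)
        states = np.repeat(["Move", "Rest", "REM", "NREM"], 250)
        bin_s = 8.0
        t = []
        for i, s in enumerate(states):
            rate = 5.0 if s == "NREM" else 10.0
            n = rng.poisson(rate * bin_s)
            t.append(i * bin_s + np.sort(rng.uniform(0, bin_s, n)))
        train = np.concatenate(t)
        mod = state_rate_modulation(train, states, bin_s)
        assert mod["NREM"] == pytest.approx(-42.86, abs=2.5)
        assert mod["Move"] == pytest.approx(14.29, abs=2.5)

    def test_occupancy_weighted_modulations_sum_to_zero(self):
        rng = np.random.default_rng(9)
        states = np.repeat(["Move", "NREM"], [300, 100])
        t = []
        for i, s in enumerate(states):
            rate = 3.0 if s == "NREM" else 9.0
            n = rng.poisson(rate * 8.0)
            t.append(i * 8.0 + np.sort(rng.uniform(0, 8.0, n)))
        train = np.concatenate(t)
        mod = state_rate_modulation(train, states, 8.0)
        occ = {s: np.mean(states == s) for s in mod}
        weighted = sum(occ[s] * mod[s] for s in mod)
        assert weighted == pytest.approx(0.0, abs=1e-9)

    def test_unit_profile_labels_match_planted_types(self, small_session):
        sess = small_session
        states = sess.truth_states
        for st, meta in zip(sess.spike_times, sess.unit_meta):
            prof = profile_unit(st, states, sess.bin_s)
            assert prof.unit_class == meta["unit_type"]
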