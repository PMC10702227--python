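"""Ground-truth recoverability of the synthetic-session generator."""

import numpy as np
import pytest

import somnoephys as se
from somnoephys.config import ConfigurationError
from somnoephys.spectral import welch_psd_per_bin

from conftest import SHORT_DWELL, short_cfg, two_units


class TestStateSequence:
    def test_night_only_no_awakenings_gives_pure_sleep(self):
        cfg = short_cfg(seed=1, hours=2.0)
        cfg.lights_off = (0.0, 2.0)
        cfg.awakening_prob = 0.0
        states = se.generate_state_sequence(cfg, seed=1)
        assert set(states) <= {"NREM", "REM"}

    def test_default_day_has_all_four_states_nrem_only_at_night(self):
        cfg = se.SimConfig(units=[])
        states = se.generate_state_sequence(cfg, seed=1)
        assert set(states) == {"Move", "Rest", "REM", "NREM"}
        bins_per_hour = 3600 / cfg.bin_s
        idx = np.flatnonzero(states == "NREM")
        max_dwell_bins = cfg.state_dwell["NREM"][1] * 60 / cfg.bin_s
        assert idx.min() >= cfg.lights_off[0] * bins_per_hour - 1
        assert idx.max() <= cfg.lights_off[1] * bins_per_hour + max_dwell_bins

    def test_dwell_time_statistics_match_bounds(self):
        # mean NREM run length must fall inside the configured dwell bounds
        cfg = se.SimConfig(session_hours=24.0, units=[],
                           awakening_prob=0.0, nap_prob=0.0)
        runs = []
        for seed in range(8):
            states = se.generate_state_sequence(cfg, seed=seed)
            is_n = np.concatenate(([0], (states == "NREM").astype(int), [0]))
            edges = np.flatnonzero(np.diff(is_n))
            runs.extend((edges[1::2] - edges[::2]) * cfg.bin_s / 60.0)
        # drop runs truncated by the lights-off boundary
        runs = [r for r in runs if r >= cfg.state_dwell["NREM"][0] / 2]
        lo, hi = cfg.state_dwell["NREM"]
        assert lo <= np.mean(runs) <= hi

    def test_inverted_dwell_bounds_rejected(self):
        cfg = short_cfg(seed=1)
        cfg.state_dwell["NREM"] = (30.0, 10.0)
        with pytest.raises(ConfigurationError):
            se.generate_state_sequence(cfg, seed=1)


class TestLfpSynthesis:
    def test_state_band_power_ordering(self, small_session):
        est = welch_psd_per_bin(small_session.lfp)
        states = small_session.truth_states[:est.psd.shape[1]]
        def band_power(name, st):
            lo, hi = se.band_edges(name)
            m = (est.freqs >= lo) & (est.freqs <= hi)
            return est.psd[:, states == st][:, :, m].mean()
        assert band_power("delta", "NREM") > 2 * band_power("delta", "Move")
        assert band_power("theta", "REM") > 1.5 * band_power("theta", "NREM")
        assert band_power("beta", "Rest") > band_power("beta", "NREM")

    def test_full_shared_fraction_gives_unit_coherence(self):
        cfg = short_cfg(seed=4, hours=1.0, n_channels=3,
                        shared_fraction=1.0)
        states = se.generate_state_sequence(cfg, seed=4)[:40]
        lfp = se.synthesize_lfp(states, cfg, seed=4)
        spec = se.magnitude_squared_coherence(lfp[0], lfp[1], fmax=50.0)
        assert np.median(spec.cxy) > 0.99

    def test_shared_fraction_monotonically_increases_coherence(self):
        meds = []
        for frac in (0.0, 0.5, 1.0):
            cfg = short_cfg(seed=4, hours=1.0, n_channels=2,
                            shared_fraction=frac)
            states = se.generate_state_sequence(cfg, seed=4)[:40]
            lfp = se.synthesize_lfp(states, cfg, seed=4)
            spec = se.magnitude_squared_coherence(lfp[0], lfp[1], fmax=50.0)
            meds.append(np.median(spec.cxy))
        assert meds[0] < meds[1] < meds[2]

    def test_unknown_band_rejected(self):
        cfg = short_cfg(seed=1)
        cfg.band_powers["Move"]["ripple"] = 1.0
        with pytest.raises(ConfigurationError):
            se.synthesize_lfp(np.array(["Move"] * 10), cfg, seed=1)


class TestAccelerometer:
    def test_state_variance_ordering(self, small_session):
        sess = small_session
        rate = sess.accel_rate
        per_bin = int(sess.bin_s * rate)
        n_bins = sess.accel.shape[1] // per_bin
        var = sess.accel[:, :n_bins * per_bin].reshape(3, n_bins, per_bin)
        var = var.var(axis=2).mean(axis=0)
        states = sess.truth_states[:n_bins]
        med = {s: np.median(var[states == s]) for s in set(states)}
        assert med["Move"] > med["REM"] > med["NREM"]

    def test_move_versus_nrem_same_seed(self):
        cfg = short_cfg(seed=9, hours=1.0)
        n_bins = 50
        a_move = se.synthesize_accelerometer(np.full(n_bins, "Move"), cfg, seed=9)
        a_nrem = se.synthesize_accelerometer(np.full(n_bins, "NREM"), cfg, seed=9)
        per_bin = int(cfg.bin_s * cfg.accel_rate)
        v_move = a_move.reshape(3, n_bins, per_bin).var(axis=2)
        v_nrem = a_nrem.reshape(3, n_bins, per_bin).var(axis=2)
        assert np.log(v_move).mean() > np.log(v_nrem).mean()

    def test_zero_burst_length_gives_stationary_noise(self):
        cfg = short_cfg(seed=9, hours=1.0, accel_burst_s=0.0)
        states = np.full(40, "Move")
        a = se.synthesize_accelerometer(states, cfg, seed=9)
        per_bin = int(cfg.bin_s * cfg.accel_rate)
        v = a.reshape(3, 40, per_bin).var(axis=2).mean(axis=0)
        assert v.std() / v.mean() < 0.15


class TestSpikeTrains:
    def test_refractory_respected_and_rates_scale(self, small_session):
        sess = small_session
        states = sess.truth_states
        for st, meta in zip(sess.spike_times, sess.unit_meta):
            isi_ms = np.diff(st) * 1000.0
            assert isi_ms.min() >= meta["refractory_ms"] - 1e-6

    def test_state_rate_ratio_recovered(self):
        cfg = short_cfg(seed=13, hours=1.0, n_channels=1)
        n_bins = 225                      # 30 min
        states = np.where(np.arange(n_bins) % 2 == 0, "Move", "NREM")
        lfp = se.synthesize_lfp(states, cfg, seed=13)
        unit = se.UnitSpec(unit_type="RS", isi_peak_ms=40.0, channel=0,
                           base_rate={"Move": 10.0, "NREM": 5.0})
        spikes = se.synthesize_spike_train(states, lfp, unit, cfg, seed=13)
        which_bin = np.clip((spikes / cfg.bin_s).astype(int), 0, n_bins - 1)
        in_move = np.sum(states[which_bin] == "Move")
        in_nrem = np.sum(states[which_bin] == "NREM")
        t_move = np.sum(states == "Move") * cfg.bin_s
        t_nrem = np.sum(states == "NREM") * cfg.bin_s
        ratio = (in_nrem / t_nrem) / (in_move / t_move)
        assert ratio == pytest.approx(0.5, abs=0.1)

    def test_impossible_rate_rejected(self):
        cfg = short_cfg(seed=13, hours=1.0, n_channels=1)
        states = np.full(10, "Move")
        lfp = se.synthesize_lfp(states, cfg, seed=13)
        unit = se.UnitSpec(unit_type="FS", isi_peak_ms=5.0, refractory_ms=2.0,
                           channel=0, base_rate={"Move": 600.0})
        with pytest.raises(ConfigurationError):
            se.synthesize_spike_train(states, lfp, unit, cfg, seed=13)


class TestDeterminism:
    def test_same_seed_identical_sessions(self):
        cfg = short_cfg(seed=17, hours=1.0, units=two_units())
        a = se.generate_session(cfg)
        b = se.generate_session(cfg)
        assert np.array_equal(a.lfp, b.lfp)
        assert np.array_equal(a.accel, b.accel)
        assert np.array_equal(a.truth_states, b.truth_states)
        for sa, sb in zip(a.spike_times, b.spike_times):
            assert np.array_equal(sa, sb)

    def test_different_seeds_differ(self):
        a = se.generate_session(short_cfg(seed=17, hours=1.0))
        b = se.generate_session(short_cfg(seed=18, hours=1.0))
        assert not np.array_equal(a.lfp, b.lfp)

    def test_requested_duration_honored(self):
        cfg = short_cfg(seed=17, hours=1.0)
        sess = se.generate_session(cfg)
        assert sess.lfp.shape == (cfg.n_channels, int(3600 * cfg.lfp_rate))
        assert sess.accel.shape == (3, int(3600 * cfg.accel_rate))


class TestSessionRoundTrip:
    def test_eog_generated_and_round_trips(self, tmp_path):
        cfg = short_cfg(seed=19, hours=1.0, n_channels=1, with_eog=True)
        sess = se.generate_session(cfg)
        assert sess.eog is not None and sess.eog.shape[0] == 2
        # eye-movement variance ordering: awake >> NREM
        per_bin = int(cfg.bin_s * cfg.lfp_rate)
        n_bins = sess.eog.shape[1] // per_bin
        var = sess.eog[:, :n_bins * per_bin].reshape(2, n_bins, per_bin).var(axis=2).mean(0)
        states = sess.truth_states[:n_bins]
        if "Move" in states and "NREM" in states:
            assert np.median(var[states == "Move"]) > 5 * np.median(var[states == "NREM"])
        p = tmp_path / "eog.h5"
        sess.save(p)
        assert np.array_equal(se.Session.load(p).eog, sess.eog)

    def test_hdf5_save_load(self, small_session, tmp_path):
        p = tmp_path / "s.h5"
        small_session.save(p)
        loaded = se.Session.load(p)
        assert np.array_equal(loaded.lfp, small_session.lfp)
        assert np.array_equal(loaded.truth_states, small_session.truth_states)
        assert loaded.lfp_rate == small_session.lfp_rate
        assert len(loaded.spike_times) == len(small_session.spike_times)
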