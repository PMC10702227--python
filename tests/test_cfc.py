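"""Band filtering, analytic signals, and phase-amplitude coupling (nMVL)."""

import numpy as np
import pytest
from scipy import signal

import somnoephys as se
from somnoephys.cfc import (analytic_signal, bandpass_filter, coupling_estimate,
                            max_possible_mvl, phase_power_map)

RNG = np.random.default_rng(7)
FS = 1000.0


def brute_force_mvl(phase, amplitude):
    """Direct summation of the mean-vector definition."""
    vec = np.sum(amplitude * np.exp(1j * phase)) / len(phase)
    return np.abs(vec), np.mod(np.angle(vec), 2 * np.pi)


class TestBandpass:
    def test_out_of_band_attenuation(self):
        t = np.arange(0, 10, 1 / FS)
        in_band = bandpass_filter(np.sin(2 * np.pi * 6 * t), "theta")
        out_band = bandpass_filter(np.sin(2 * np.pi * 10 * t), "theta")
        r_in = np.sqrt(np.mean(in_band[2000:-2000] ** 2))
        r_out = np.sqrt(np.mean(out_band[2000:-2000] ** 2))
        assert r_out < 0.5 * r_in

    def test_zero_phase(self):
        t = np.arange(0, 10, 1 / FS)
        x = np.sin(2 * np.pi * 6 * t)
        y = bandpass_filter(x, "theta")
        xc = signal.correlate(y[2000:-2000], x[2000:-2000], mode="full")
        lag = np.argmax(xc) - (len(x) - 4001)
        assert lag == 0

    def test_white_noise_mass_in_band(self):
        y = bandpass_filter(RNG.standard_normal(200_000), "beta")
        f, p = signal.welch(y, fs=FS, nperseg=4096)
        in_band = p[(f >= 15) & (f <= 30)].sum()
        assert in_band / p.sum() > 0.8

    def test_band_above_nyquist_rejected(self):
        with pytest.raises(ValueError):
            bandpass_filter(RNG.standard_normal(1000), (400, 600))


class TestAnalyticSignal:
    def test_cosine_amplitude_and_phase_convention(self):
        t = np.arange(0, 10, 1 / FS)
        a = analytic_signal(np.cos(2 * np.pi * 6 * t))
        mid = slice(1000, -1000)
        assert np.allclose(a.amplitude[mid], 1.0, atol=0.01)
        # phase 0 at maxima, pi at minima
        peaks = signal.argrelmax(np.cos(2 * np.pi * 6 * t)[mid])[0]
        troughs = signal.argrelmin(np.cos(2 * np.pi * 6 * t)[mid])[0]
        ph = a.phase[mid]
        assert np.allclose(np.cos(ph[peaks]), 1.0, atol=1e-3)
        assert np.allclose(np.cos(ph[troughs]), -1.0, atol=1e-3)

    def test_amplitude_linearity(self):
        t = np.arange(0, 10, 1 / FS)
        a = analytic_signal(3.7 * np.cos(2 * np.pi * 6 * t))
        assert np.allclose(a.amplitude[1000:-1000], 3.7, atol=0.05)

    def test_chirp_instantaneous_frequency(self):
        t = np.arange(0, 60, 1 / FS)
        x = signal.chirp(t, f0=5, f1=7, t1=60)
        a = analytic_signal(x)
        inst_f = np.diff(np.unwrap(np.mod(a.phase, 2 * np.pi))) * FS / (2 * np.pi)
        expect = 5 + 2 * t[:-1] / 60
        mid = slice(2000, -2000)
        assert np.abs(inst_f[mid] - expect[mid]).max() / 6 < 0.05

    def test_constant_signal_rejected(self):
        with pytest.raises(ValueError):
            analytic_signal(np.ones(1000))


class TestCouplingEstimate:
    def test_uniform_phase_constant_amplitude_cancels(self):
        n = 10_000
        phase = np.mod(np.arange(n) * 2 * np.pi / 100, 2 * np.pi)
        est = coupling_estimate(phase, np.ones(n), edge_exclude_s=0.0)
        assert est.mvl < 1e-10
        assert est.nmvl < 1e-6

    def test_perfect_coupling_analytic_value(self):
        # amplitude = 1 + cos(phi) with uniform phase: MVL = 0.5 exactly
        n = 100_000
        phase = np.mod(np.arange(n) * 2 * np.pi / 360.0, 2 * np.pi)
        amp = 1.0 + np.cos(phase)
        est = coupling_estimate(phase, amp, edge_exclude_s=0.0)
        assert est.mvl == pytest.approx(0.5, abs=0.01)
        assert min(est.mean_phase, 2 * np.pi - est.mean_phase) < 0.05
        assert est.nmvl > 0.5     # near its maximum for this amplitude law

    def test_matches_brute_force_summation(self):
        n = 10_000
        phase = RNG.uniform(0, 2 * np.pi, n)
        amp = RNG.gamma(2.0, 1.0, n)
        est = coupling_estimate(phase, amp, edge_exclude_s=0.0)
        mvl, mean_phase = brute_force_mvl(phase, amp)
        assert est.mvl == pytest.approx(mvl, abs=1e-12)
        assert est.mean_phase == pytest.approx(mean_phase, abs=1e-12)

    def test_phase_rotation_moves_mean_phase_not_mvl(self):
        n = 20_000
        phase = RNG.vonmises(0.5, 1.0, n) % (2 * np.pi)
        amp = 1.0 + 0.5 * np.cos(phase)
        a = coupling_estimate(phase, amp, edge_exclude_s=0.0)
        b = coupling_estimate((phase + 1.0) % (2 * np.pi), amp,
                              edge_exclude_s=0.0)
        assert b.mvl == pytest.approx(a.mvl, rel=1e-9)
        assert (b.mean_phase - a.mean_phase) % (2 * np.pi) == pytest.approx(
            1.0, abs=1e-6)

    def test_gain_invariance_of_nmvl(self):
        n = 20_000
        phase = RNG.uniform(0, 2 * np.pi, n)
        amp = 1.0 + 0.6 * np.cos(phase - 1.0) + 0.05 * RNG.standard_normal(n)
        a = coupling_estimate(phase, amp, edge_exclude_s=0.0)
        b = coupling_estimate(phase, 10.0 * amp, edge_exclude_s=0.0)
        assert b.mvl == pytest.approx(10.0 * a.mvl, rel=1e-9)
        assert b.nmvl == pytest.approx(a.nmvl, rel=1e-9)

    def test_max_mvl_upper_bounds_paired_mvl(self):
        for trial in range(20):
            n = 2000
            phase = RNG.vonmises(0.0, 0.5, n) % (2 * np.pi)
            amp = RNG.gamma(2.0, 1.0, n)
            mvl, _ = brute_force_mvl(phase, amp)
            assert max_possible_mvl(phase, amp) >= mvl - 1e-12

    def test_band_order_enforced(self):
        with pytest.raises(ValueError):
            coupling_estimate(np.zeros(100), np.ones(100),
                              low_band="beta", high_band="delta")

    def test_empty_mask_rejected(self):
        with pytest.raises(ValueError):
            coupling_estimate(np.zeros(100), np.ones(100),
                              state_mask=np.zeros(100, bool))


class TestPlantedCoupling:
    def test_planted_depth_recovered_as_nmvl_ordering(self, nrem_lfp_session):
        states, _, cfg0 = nrem_lfp_session
        results = {}
        for depth in (0.0, 0.8):
            cfg = se.SimConfig(**{**cfg0.__dict__,
                                  "coupling_spec": [("NREM", "delta",
                                                     "high_gamma", depth, np.pi)],
                                  "units": []})
            lfp = se.synthesize_lfp(states, cfg, seed=3)[0]
            low = analytic_signal(bandpass_filter(lfp, "delta"), band="delta")
            high = analytic_signal(bandpass_filter(lfp, "high_gamma"),
                                   band="high_gamma")
            est = coupling_estimate(low.phase, high.amplitude,
                                    low_band="delta", high_band="high_gamma")
            results[depth] = est.nmvl
        assert results[0.8] > 3 * results[0.0]

    def test_uncoupled_phase_amplitude_independent(self, nrem_lfp_session):
        states, _, cfg0 = nrem_lfp_session
        cfg = se.SimConfig(**{**cfg0.__dict__, "coupling_spec": [],
                              "units": []})
        lfp = se.synthesize_lfp(states, cfg, seed=5)[0]
        low = analytic_signal(bandpass_filter(lfp, "delta"))
        high = analytic_signal(bandpass_filter(lfp, "high_gamma"))
        # circular-linear correlation of phase vs amplitude ~ 0
        ph, amp = low.phase[1000:-1000], high.amplitude[1000:-1000]
        rc = np.corrcoef(np.cos(ph), amp)[0, 1]
        rs = np.corrcoef(np.sin(ph), amp)[0, 1]
        assert np.hypot(rc, rs) < 0.02


class TestPhasePowerMap:
    def test_rows_are_zscored(self):
        phase = RNG.uniform(0, 2 * np.pi, 50_000)
        power = RNG.gamma(2.0, 1.0, (3, 50_000))
        _, z = phase_power_map(phase, power)
        assert np.allclose(np.nanmean(z, axis=1), 0.0, atol=1e-9)
        assert np.allclose(np.nanstd(z, axis=1), 1.0, atol=1e-9)

    def test_coupled_power_peaks_at_preferred_phase(self):
        phase = RNG.uniform(0, 2 * np.pi, 100_000)
        power = 1.0 + np.cos(phase)
        centers, z = phase_power_map(phase, power)
        peak = centers[np.argmax(z[0])]
        assert min(peak, 2 * np.pi - peak) < 0.2

    def test_uncoupled_z_small(self):
        phase = RNG.uniform(0, 2 * np.pi, 100_000)
        power = RNG.gamma(2.0, 1.0, 100_000)
        _, z = phase_power_map(phase, power)
        # z-scored across 36 bins; uncoupled rows have no dominant bin
        assert np.nanmax(np.abs(z)) < 3.5
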