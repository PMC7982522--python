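"""Spectral density, SPL, vocal efficiency, CPP, formants and quotients."""

import math

import numpy as np
import pytest
from scipy import signal as sps

import phonosim as ps
import phonosim.metrics as pm


class TestASD:
    def test_sine_peak_at_signal_frequency(self):
        sig = ps.make_fixture("sine", {"freq_hz": 148.0, "duration_s": 1.0})
        asd = pm.compute_asd(sig, f0=148.0)
        df = asd.frequencies[1] - asd.frequencies[0]
        assert abs(asd.dominant_frequency() - 148.0) <= df

    def test_zero_signal_zero_density(self):
        sig = ps.AcousticSignal(np.zeros(8192), 44100.0, 1.0)
        assert pm.compute_asd(sig).total_power() == 0.0

    def test_parseval_consistency_for_sine(self):
        a = 0.7
        sig = ps.make_fixture("sine", {"freq_hz": 200.0, "amplitude": a, "duration_s": 2.0})
        asd = pm.compute_asd(sig, f0=200.0, cycles_per_segment=8)
        assert asd.total_power() == pytest.approx(a**2 / 2, rel=0.05)

    def test_parseval_consistency_for_noise(self, rng):
        sig = ps.AcousticSignal(rng.normal(0, 1.0, 44100), 44100.0, 1.0)
        asd = pm.compute_asd(sig)
        assert asd.total_power() == pytest.approx(np.var(sig.samples), rel=0.05)

    def test_resolution_finer_than_quarter_f0(self):
        sig = ps.make_fixture("sine", {"duration_s": 0.5})
        asd = pm.compute_asd(sig, f0=148.0)
        assert asd.frequencies[1] - asd.frequencies[0] <= 148.0 / 4 + 1e-9

    def test_short_signal_rejected(self):
        sig = ps.AcousticSignal(np.ones(100), 44100.0, 1.0)
        with pytest.raises(ValueError):
            pm.compute_asd(sig)


class TestSPL:
    def test_reference_rms_is_zero_db(self):
        sig = ps.AcousticSignal(np.full(1000, 20e-6), 44100.0, 1.0)
        assert pm.compute_spl(sig) == pytest.approx(0.0)

    def test_unit_sine_level(self):
        sig = ps.make_fixture("sine", {"amplitude": 1.0, "duration_s": 1.0})
        assert pm.compute_spl(sig) == pytest.approx(20 * math.log10(0.70711 / 2e-5), abs=0.01)

    def test_log_law_ten_times_amplitude(self, rng):
        x = rng.normal(0, 0.1, 8192)
        s1 = ps.AcousticSignal(x, 44100.0, 1.0)
        s10 = ps.AcousticSignal(10 * x, 44100.0, 1.0)
        assert pm.compute_spl(s10) - pm.compute_spl(s1) == pytest.approx(20.0)

    def test_zero_signal_undefined(self):
        with pytest.raises(ValueError):
            pm.compute_spl(ps.AcousticSignal(np.zeros(100), 44100.0, 1.0))

    def test_duration_invariance_for_periodic_signal(self):
        levels = [
            pm.compute_spl(ps.make_fixture("sine", {"duration_s": d}))
            for d in (10 / 148.0, 0.5, 2.0)
        ]
        assert max(levels) - min(levels) < 0.1


class TestVocalEfficiency:
    def test_direct_evaluation(self):
        res = pm.vocal_efficiency(spl=120.0, mic_distance=1.0, p_sub=1000.0, q_mean=1e-3)
        assert res.p_radiated == pytest.approx(4 * math.pi)
        assert res.p_aerodynamic == pytest.approx(1.0)
        assert res.ve == pytest.approx(4 * math.pi)

    def test_log_law_in_spl(self):
        base = pm.vocal_efficiency(100.0, 0.2, 775.0, 1e-3).ve
        down = pm.vocal_efficiency(90.0, 0.2, 775.0, 1e-3).ve
        assert down == pytest.approx(0.1 * base)

    def test_quadratic_in_distance(self):
        base = pm.vocal_efficiency(100.0, 0.1, 775.0, 1e-3).ve
        far = pm.vocal_efficiency(100.0, 0.2, 775.0, 1e-3).ve
        assert far == pytest.approx(4 * base)

    def test_invalid_arguments(self):
        with pytest.raises(ValueError):
            pm.vocal_efficiency(100.0, 0.2, 0.0, 1e-3)
        with pytest.raises(ValueError):
            pm.vocal_efficiency(100.0, 0.2, 775.0, 0.0)


def _cepstrum_oracle(x, fs, frame_len, hop, band_hz, reg_s):
    """Brute-force CPP: explicit DFT sums (no FFT), same definition."""
    n_half = frame_len // 2 + 1
    q = np.arange(n_half) / fs
    band = (q >= 1.0 / band_hz[1]) & (q <= 1.0 / band_hz[0])
    reg = (q >= reg_s[0]) & (q <= min(reg_s[1], q[-1]))
    band_idx = np.flatnonzero(band)
    win = sps.get_window("hann", frame_len)
    k = np.arange(n_half)
    n = np.arange(frame_len)
    fwd = np.exp(-2j * np.pi * np.outer(k, n) / frame_len)  # explicit DFT matrix
    kk = np.arange(frame_len)
    inv = np.exp(2j * np.pi * np.outer(n, kk) / frame_len) / frame_len
    cpps = []
    for s in range(0, x.size - frame_len + 1, hop):
        frame = x[s : s + frame_len] * win
        spec = np.abs(fwd @ frame)
        spec_db = 20 * np.log10(spec + 1e-300)
        full = np.concatenate([spec_db, spec_db[-2:0:-1]])  # even symmetry
        ceps = np.real(inv @ full)[:n_half]
        peaks, _ = sps.find_peaks(ceps[band_idx])
        rel = peaks[np.argmax(ceps[band_idx][peaks])] if peaks.size else int(np.argmax(ceps[band_idx]))
        ipk = band_idx[rel]
        slope, intercept = np.polyfit(q[reg], ceps[reg], 1)
        cpps.append(ceps[ipk] - (slope * q[ipk] + intercept))
    return float(np.mean(cpps))


class TestCPP:
    def test_matches_direct_dft_oracle(self):
        sig = ps.make_fixture("pulse_train", {"f0_hz": 148.0, "duration_s": 1.0})
        got = pm.compute_cpp(sig).cpp_db
        fs = sig.sample_rate
        frame_len = int(round(0.040 * fs))
        expected = _cepstrum_oracle(sig.samples, fs, frame_len, frame_len // 2,
                                    (60.0, 300.0), (1e-3, 15e-3))
        assert got == pytest.approx(expected, abs=0.1)

    def test_periodicity_beats_matched_noise(self):
        clean = ps.make_fixture("pulse_train", {"f0_hz": 148.0, "duration_s": 1.0})
        noisy = ps.make_fixture("noisy_harmonic", {"f0_hz": 148.0, "snr_db": 0.0,
                                                   "duration_s": 1.0}, seed=3)
        assert pm.compute_cpp(clean).cpp_db > pm.compute_cpp(noisy).cpp_db

    def test_white_noise_below_harmonic_signal(self):
        noise = ps.make_fixture("white_noise", {"duration_s": 1.0}, seed=5)
        harm = ps.make_fixture("noisy_harmonic", {"snr_db": 30.0, "duration_s": 1.0}, seed=5)
        assert pm.compute_cpp(noise).cpp_db < pm.compute_cpp(harm).cpp_db

    def test_monotone_decrease_with_noise_power(self):
        cpps = [
            pm.compute_cpp(ps.make_fixture("noisy_harmonic", {"snr_db": snr}, seed=7)).cpp_db
            for snr in range(-20, 30, 5)
        ]
        assert all(b > a for a, b in zip(cpps, cpps[1:]))

    def test_peak_found_at_fundamental_quefrency(self):
        sig = ps.make_fixture("pulse_train", {"f0_hz": 148.0, "duration_s": 1.0})
        res = pm.compute_cpp(sig)
        assert res.peak_quefrency_s == pytest.approx(1 / 148.0, rel=0.05)
        assert not res.low_confidence

    def test_too_short_signal_rejected(self):
        sig = ps.AcousticSignal(np.ones(100), 44100.0, 1.0)
        with pytest.raises(ValueError):
            pm.compute_cpp(sig)


class TestFormants:
    def test_single_resonator_peak(self):
        vt = ps.VocalTractFilter(formant_frequencies=(500.0,), formant_bandwidths=(100.0,))
        f, h = vt.frequency_response(2**14)
        peaks = pm.extract_formants((f, h), n_formants=1)
        assert peaks[0] == pytest.approx(500.0, abs=f[1] - f[0])

    def test_flat_spectrum_warns_and_returns_empty(self):
        flat = pm.SpectralDensity(np.linspace(0, 4000, 100), np.ones(100))
        with pytest.warns(UserWarning):
            assert pm.extract_formants(flat) == []


class TestGAWQuotients:
    def test_always_open_sine(self):
        phase = np.arange(512) / 512
        gaw = ps.AreaWaveform(phase, 10.0 + 5.0 * np.sin(2 * np.pi * phase), f0=148.0)
        oq, _ = pm.gaw_quotients(gaw)
        assert oq == 1.0

    def test_baseline_open_quotient_tracks_closure_interval(self, base_gaw):
        oq, sq = pm.gaw_quotients(base_gaw)
        assert oq == pytest.approx(0.80, abs=0.005)
        assert sq < 1.0  # opening faster than closing

    def test_time_reversal_inverts_speed_quotient(self, base_gaw):
        rev = ps.AreaWaveform(base_gaw.phase, base_gaw.area[::-1].copy(), f0=148.0)
        _, sq = pm.gaw_quotients(base_gaw)
        _, sq_rev = pm.gaw_quotients(rev)
        assert sq_rev == pytest.approx(1.0 / sq, rel=0.01)

    def test_constant_waveform_undefined(self):
        gaw = ps.AreaWaveform(np.arange(16) / 16, np.full(16, 3.0), f0=148.0)
        with pytest.raises(ValueError):
            pm.gaw_quotients(gaw)
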