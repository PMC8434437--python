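"""Wall filter, packetization, periodogram, and centroid estimator."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import carodop as cd
from carodop.spectral import CentroidParams, make_packets, packet_starts

PRF = 8000.0


def tone_ensemble(f0, n=4096, amplitude=1.0):
    t = np.arange(n) / PRF
    x = amplitude * np.exp(2j * np.pi * f0 * t)
    return cd.IQEnsemble(x[None, :], PRF, 0.15, 20.0)


def _attenuation_db(f0):
    ens = tone_ensemble(f0)
    out = cd.clutter_filter(ens, 100.0)
    pin = np.mean(np.abs(ens.samples) ** 2)
    pout = np.mean(np.abs(out.samples) ** 2)
    return 10 * np.log10(pout / pin)


class TestClutterFilter:
    def test_dc_removed(self):
        ens = cd.IQEnsemble(np.full((3, 2048), 5.0 + 2.0j), PRF, 0.15, 20.0)
        out = cd.clutter_filter(ens, 100.0)
        res_db = 10 * np.log10(np.mean(np.abs(out.samples) ** 2) / 29.0)
        assert res_db <= -40.0

    def test_passband_tone_preserved(self):
        assert abs(_attenuation_db(2000.0)) <= 1.0

    def test_stopband_tone_suppressed(self):
        assert _attenuation_db(50.0) <= -20.0

    def test_cutoff_above_nyquist_rejected(self):
        with pytest.raises(ValueError):
            cd.clutter_filter(tone_ensemble(1000.0), PRF / 2.0)


class TestPackets:
    def test_two_seconds_at_8khz(self):
        assert len(packet_starts(16000, 128, 0.5)) == 249

    def test_exact_fit_single_packet(self):
        assert len(packet_starts(128, 128, 0.5)) == 1

    def test_too_short_rejected(self):
        with pytest.raises(ValueError):
            packet_starts(127, 128, 0.5)

    def test_packet_layout(self):
        x = np.arange(320.0)
        p = make_packets(x, 128, 0.5)
        assert p.shape == (4, 128)
        assert p[1][0] == 64.0  # hop = 64
        assert p[3][-1] == 319.0


class TestPowerSpectrum:
    def test_tone_at_bin_centre_dominates(self):
        n = 128
        f0 = 10 * PRF / n
        x = np.exp(2j * np.pi * f0 * np.arange(n) / PRF)
        p, f = cd.power_spectrum(x[None, :], PRF)
        assert f[np.argmax(p[0])] == pytest.approx(f0)
        # Hann main lobe: the centre bin carries 2/3 of the power
        assert p[0].max() / p[0].sum() > 0.5

    def test_zero_input_zero_spectrum(self):
        p, _ = cd.power_spectrum(np.zeros((1, 128), complex), PRF)
        assert np.all(p == 0)

    def test_white_noise_roughly_flat(self):
        rng = np.random.default_rng(0)
        x = (rng.standard_normal((500, 128)) + 1j * rng.standard_normal((500, 128)))
        p, f = cd.power_spectrum(x, PRF)
        mean_bins = p.mean(axis=0)
        assert mean_bins.max() / mean_bins.min() < 1.5

    def test_total_power_conserved(self):
        rng = np.random.default_rng(1)
        x = rng.standard_normal(128) + 1j * rng.standard_normal(128)
        p, _ = cd.power_spectrum(x[None, :], PRF)
        assert p.sum() == pytest.approx(np.mean(np.abs(x) ** 2) * 128 / 128, rel=0.35)


class TestCentroid:
    def test_single_bin(self):
        f = np.fft.fftshift(np.fft.fftfreq(128, 1 / PRF))
        spec = np.zeros(128)
        spec[90] = 3.0
        assert cd.centroid_frequency(spec, f) == pytest.approx(f[90])

    def test_symmetric_spectrum_centre_of_mass(self):
        f = np.fft.fftshift(np.fft.fftfreq(128, 1 / PRF))
        spec = np.zeros(128)
        spec[80:85] = [1, 2, 5, 2, 1]
        assert cd.centroid_frequency(spec, f) == pytest.approx(f[82])

    def test_all_zero_undefined(self):
        f = np.fft.fftshift(np.fft.fftfreq(128, 1 / PRF))
        assert np.isnan(cd.centroid_frequency(np.zeros(128), f))

    def test_noise_only_undefined(self):
        rng = np.random.default_rng(4)
        f = np.fft.fftshift(np.fft.fftfreq(128, 1 / PRF))
        n_defined = 0
        for _ in range(200):
            spec = rng.exponential(1.0, 128)
            if not np.isnan(cd.centroid_frequency(spec, f)):
                n_defined += 1
        assert n_defined == 0

    def test_tone_in_noise_within_50hz(self):
        """1 kHz tone at 20 dB SNR, 128-point packets: centroid within 50 Hz."""
        rng = np.random.default_rng(0)
        f0, errs = 1000.0, []
        for _ in range(100):
            x = np.exp(2j * np.pi * f0 * np.arange(128) / PRF)
            x = x + np.sqrt(0.01 / 2) * (rng.standard_normal(128) + 1j * rng.standard_normal(128))
            p, f = cd.power_spectrum(x[None, :], PRF)
            errs.append(cd.centroid_frequency(p[0], f) - f0)
        assert np.max(np.abs(errs)) <= 50.0

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(shift_bins=st.integers(-20, 20))
    def test_shift_linearity(self, shift_bins):
        """Shifting a non-wrapping spectrum by k bins shifts the centroid by
        exactly k bin widths."""
        f = np.fft.fftshift(np.fft.fftfreq(128, 1 / PRF))
        spec = np.zeros(128)
        spec[60:65] = [1, 4, 6, 4, 1]
        base = cd.centroid_frequency(spec, f)
        shifted = np.roll(spec, shift_bins)
        df = PRF / 128
        assert cd.centroid_frequency(shifted, f) - base == pytest.approx(
            shift_bins * df, abs=1e-9)


class TestFrequencyMap:
    def test_map_rows_for_two_seconds(self, geom, cfg):
        flow = cd.steady_flow(0.34, 3.0)
        il, _ = cd.simulate_iq_pair(flow, 23.0, geom, cfg, seed=0, duration_s=2.0)
        fm = cd.frequency_map(il.slice_gates(120, 161), cfg)
        assert fm.n_packets == 249

    def test_clutter_only_all_missing(self, geom, cfg):
        rng = np.random.default_rng(0)
        n = 2048
        t = np.arange(n) / PRF
        clutter = 100.0 * np.exp(2j * np.pi * 3.0 * t)
        noise = np.sqrt(0.005) * (rng.standard_normal((8, n)) + 1j * rng.standard_normal((8, n)))
        ens = cd.IQEnsemble(clutter[None, :] + noise, PRF, 0.15, 20.0)
        fm = cd.frequency_map(ens, cfg)
        assert np.all(np.isnan(fm.fd))

    def test_conjugation_negates_frequencies(self, geom, cfg):
        """Conjugating the IQ data reverses the flow direction: fd -> -fd."""
        flow = cd.steady_flow(0.3, 3.0, duration_s=0.5)
        il, _ = cd.simulate_iq_pair(flow, 23.0, geom, cfg, snr_db=np.inf,
                                    clutter_db=-np.inf, seed=0, duration_s=0.5)
        sl = il.slice_gates(135, 146)
        fm = cd.frequency_map(sl, cfg)
        conj = cd.IQEnsemble(np.conj(sl.samples), sl.prf, sl.gate_spacing_mm,
                             sl.first_gate_depth_mm, sl.side)
        fm_c = cd.frequency_map(conj, cfg)
        both = np.isfinite(fm.fd) & np.isfinite(fm_c.fd)
        assert both.any()
        assert np.allclose(fm_c.fd[both], -fm.fd[both], atol=1.0)
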