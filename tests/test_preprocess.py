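"""Signal-chain oracles: decimation, bipolar referencing, notches, band
bank, Hilbert power, and chain-level properties."""

import numpy as np
import pandas as pd
import pytest
from scipy import signal as sp_signal

from gammamap import (
    BAND_BY_NAME,
    DEFAULT_BANDS,
    ElectrodeTable,
    Recording,
    ValidationError,
    bandpass_bank,
    bipolar_rereference,
    downsample,
    instantaneous_power,
    make_strips,
    notch_filter,
)
from gammamap.preprocess import edge_flag_mask


def tone(freq, fs, dur_s, amp=1.0, phase=0.0):
    t = np.arange(int(dur_s * fs)) / fs
    return amp * np.sin(2 * np.pi * freq * t + phase)


def rms_at(x, fs, freq):
    """Amplitude at one frequency bin via the DFT."""
    n = x.size
    k = int(round(freq * n / fs))
    return 2 * np.abs(np.fft.rfft(x)[k]) / n


class TestDownsample:
    def test_five_fold_decimation_sample_count(self):
        rec = Recording(np.random.default_rng(0).standard_normal((2, 100000)),
                        fs=10000.0, channel_names=["a", "b"])
        out = downsample(rec, 2000.0)
        assert out.fs == 2000.0
        assert out.n_samples == 20000

    def test_identity_passthrough(self):
        rec = Recording(np.ones((1, 100)), fs=2000.0, channel_names=["a"])
        assert downsample(rec, 2000.0) is rec

    def test_upsampling_rejected(self):
        rec = Recording(np.ones((1, 100)), fs=1000.0, channel_names=["a"])
        with pytest.raises(ValidationError):
            downsample(rec, 2000.0)

    def test_inband_tone_survives_with_under_1pct_loss(self):
        fs = 10000.0
        x = tone(100.0, fs, 10.0)
        rec = Recording(x[None, :], fs=fs, channel_names=["a"])
        out = downsample(rec, 2000.0)
        rms_before = np.sqrt(np.mean(x[2000:-2000] ** 2))
        y = out.data[0]
        rms_after = np.sqrt(np.mean(y[400:-400] ** 2))
        assert abs(rms_after - rms_before) / rms_before < 0.01


class TestBipolar:
    def _table(self, n_strips=1, k=4):
        return make_strips(n_strips, k, 10.0, seed=0)

    def test_constant_signals_subtract(self):
        table = self._table()
        data = np.repeat(np.array([[1.0], [2.0], [4.0], [8.0]]), 50, axis=1)
        rec = Recording(data, fs=100.0, channel_names=table.names)
        out, derived = bipolar_rereference(rec, table)
        np.testing.assert_allclose(out.data[:, 0], [-1.0, -2.0, -4.0])
        assert out.reference == "bipolar"
        assert len(derived) == 3

    def test_derived_channel_carries_first_contact_location(self):
        table = self._table()
        rec = Recording(np.zeros((4, 10)), fs=100.0, channel_names=table.names)
        _, derived = bipolar_rereference(rec, table)
        np.testing.assert_array_equal(derived.coords, table.coords[:3])
        assert derived.names == table.names[:3]

    def test_common_mode_rejection_exact(self, rng):
        table = self._table()
        base = rng.standard_normal((4, 1000))
        rec = Recording(base, fs=100.0, channel_names=table.names)
        out0, _ = bipolar_rereference(rec, table)
        common = rng.standard_normal(1000) * 100
        rec2 = Recording(base + common, fs=100.0, channel_names=table.names)
        out1, _ = bipolar_rereference(rec2, table)
        resid = np.abs(out1.data - out0.data).max()
        assert resid <= 1e-6 * np.abs(out0.data).max()

    def test_strip_census_79_to_59(self, rng):
        # 20 strips, 19 fully localized and one with only 3 contacts: the
        # layout of 79 raw contacts reduces to 79 - 20 = 59 channels
        counts = [4] * 19 + [3]
        table = make_strips(20, counts, 10.0, seed=3)
        assert len(table) == 79
        rec = Recording(rng.standard_normal((79, 100)), fs=100.0,
                        channel_names=table.names)
        out, derived = bipolar_rereference(rec, table)
        assert out.n_channels == 59
        assert len(derived) == 59

    def test_single_contact_strip_dropped_with_warning(self, rng):
        table = make_strips(2, [4, 1], 10.0, seed=0)
        rec = Recording(rng.standard_normal((5, 50)), fs=100.0, channel_names=table.names)
        with pytest.warns(UserWarning, match="fewer than 2"):
            out, derived = bipolar_rereference(rec, table)
        assert out.n_channels == 3


class TestNotch:
    def test_50hz_tone_attenuated_at_least_20db(self):
        fs = 1000.0
        x = tone(50.0, fs, 20.0, amp=10.0)
        rec = Recording(x[None, :], fs=fs, channel_names=["a"])
        out = notch_filter(rec, base_freqs=[50.0])
        assert rms_at(out.data[0], fs, 50.0) <= 1.0

    def test_harmonics_of_79_attenuated(self):
        fs = 1000.0
        for harmonic in (79.0, 158.0, 237.0):
            x = tone(harmonic, fs, 20.0, amp=1.0)
            rec = Recording(x[None, :], fs=fs, channel_names=["a"])
            out = notch_filter(rec, base_freqs=[79.0])
            atten_db = 20 * np.log10(rms_at(x, fs, harmonic) / max(rms_at(out.data[0], fs, harmonic), 1e-12))
            assert atten_db >= 20.0, f"{harmonic} Hz attenuated only {atten_db:.1f} dB"

    def test_broadband_power_outside_notches_preserved(self, rng):
        fs = 1000.0
        x = rng.standard_normal(int(fs) * 30)
        rec = Recording(x[None, :], fs=fs, channel_names=["a"])
        out = notch_filter(rec)
        f, p_in = sp_signal.welch(x, fs=fs, nperseg=2048)
        _, p_out = sp_signal.welch(out.data[0], fs=fs, nperseg=2048)
        keep = np.ones_like(f, dtype=bool)
        for base in (50.0, 79.0):
            h = base
            while h < fs / 2:
                keep &= np.abs(f - h) > 3.0
                h += base
        change = abs(p_out[keep].sum() - p_in[keep].sum()) / p_in[keep].sum()
        assert change < 0.05

    def test_base_at_nyquist_rejected(self):
        rec = Recording(np.zeros((1, 100)), fs=100.0, channel_names=["a"])
        with pytest.raises(ValidationError):
            notch_filter(rec, base_freqs=[50.0])


class TestBandBank:
    def test_tone_routed_to_its_band(self):
        fs = 1000.0
        x = tone(100.0, fs, 20.0)
        rec = Recording(x[None, :], fs=fs, channel_names=["a"])
        beta_rec, hg_rec = bandpass_bank(rec, [BAND_BY_NAME["beta"], BAND_BY_NAME["HG"]])
        sl = slice(2000, -2000)
        rms_hg = np.sqrt(np.mean(hg_rec.data[0][sl] ** 2))
        rms_beta = np.sqrt(np.mean(beta_rec.data[0][sl] ** 2))
        assert rms_hg > 0.9 * np.sqrt(0.5)  # tone survives in its band
        assert 20 * np.log10(rms_hg / max(rms_beta, 1e-15)) >= 20.0

    def test_band_above_nyquist_rejected_by_name(self):
        rec = Recording(np.zeros((1, 100)), fs=400.0, channel_names=["a"])
        with pytest.raises(ValidationError, match="HG"):
            bandpass_bank(rec, [BAND_BY_NAME["HG"]])

    def test_white_noise_band_powers_sum_to_broadband(self, rng):
        fs = 2000.0
        x = rng.standard_normal(int(fs) * 30)
        rec = Recording(x[None, :], fs=fs, channel_names=["a"])
        band_recs = bandpass_bank(rec, DEFAULT_BANDS)
        band_sum = sum(float(np.mean(br.data[0] ** 2)) for br in band_recs)
        sos = sp_signal.butter(4, [1.0, 250.0], btype="bandpass", fs=fs, output="sos")
        broad = float(np.mean(sp_signal.sosfiltfilt(sos, x) ** 2))
        assert abs(band_sum - broad) / broad < 0.15

    def test_zero_phase_no_lag(self):
        # an impulse stays centred after forward-backward filtering
        fs = 500.0
        x = np.zeros(2001)
        x[1000] = 1.0
        rec = Recording(x[None, :], fs=fs, channel_names=["a"])
        out = bandpass_bank(rec, [BAND_BY_NAME["beta"]])[0]
        assert abs(int(np.argmax(np.abs(out.data[0]))) - 1000) <= 1


class TestInstantaneousPower:
    def test_sinusoid_amplitude_two_gives_power_four(self):
        fs = 500.0
        band = BAND_BY_NAME["alpha"]
        x = tone(10.0, fs, 30.0, amp=2.0)
        rec = Recording(x[None, :], fs=fs, channel_names=["a"])
        bp = instantaneous_power(rec, band)
        core = bp.power[0][int(fs):-int(fs)]
        assert np.mean(core) == pytest.approx(4.0, rel=0.02)

    def test_zero_signal_zero_power(self):
        rec = Recording(np.zeros((2, 100)), fs=100.0, channel_names=["a", "b"])
        bp = instantaneous_power(rec, BAND_BY_NAME["alpha"])
        np.testing.assert_array_equal(bp.power, 0.0)

    def test_power_tracks_amplitude_modulation(self):
        fs = 1000.0
        t = np.arange(int(fs * 20)) / fs
        a_t = 1.0 + 0.5 * np.sin(2 * np.pi * 0.3 * t)
        x = a_t * np.sin(2 * np.pi * 40.0 * t)
        rec = Recording(x[None, :], fs=fs, channel_names=["a"])
        bp = instantaneous_power(rec, BAND_BY_NAME["LG"])
        sl = slice(int(2 * fs), -int(2 * fs))
        r = np.corrcoef(bp.power[0][sl], a_t[sl] ** 2)[0, 1]
        assert r > 0.99


class TestChainProperties:
    def test_deterministic_and_nan_free(self, rng):
        fs = 500.0
        rec = Recording(rng.standard_normal((2, int(fs) * 10)), fs=fs, channel_names=["a", "b"])

        def chain(r):
            r = notch_filter(r, base_freqs=[50.0])
            br = bandpass_bank(r, [BAND_BY_NAME["beta"]])[0]
            return instantaneous_power(br, BAND_BY_NAME["beta"]).power

        p1, p2 = chain(rec), chain(rec)
        np.testing.assert_array_equal(p1, p2)
        assert np.isfinite(p1).all()

    def test_scaling_equivariance_c_squared(self, rng):
        fs = 500.0
        x = rng.standard_normal((1, int(fs) * 10))
        rec1 = Recording(x, fs=fs, channel_names=["a"])
        rec2 = Recording(3.0 * x, fs=fs, channel_names=["a"])
        band = BAND_BY_NAME["beta"]
        p1 = instantaneous_power(bandpass_bank(rec1, [band])[0], band).power
        p2 = instantaneous_power(bandpass_bank(rec2, [band])[0], band).power
        np.testing.assert_allclose(p2, 9.0 * p1, rtol=1e-10)

    def test_edge_flags_cover_exclusion_zone(self):
        mask = edge_flag_mask(1000, 100.0, edge_s=1.0)
        assert mask[:100].all() and mask[-100:].all() and not mask[100:-100].any()
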