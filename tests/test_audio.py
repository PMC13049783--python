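"""Audio preprocessing: filtering, resampling, denoising, despiking."""

import numpy as np
import pytest
from scipy import signal

import cpet_acoustics as ca
from cpet_acoustics.audio import (
    DenoiseConfig,
    bandpass_filter,
    denoise_ambient,
    load_audio,
    preprocess,
    remove_spikes,
    resample_audio,
    save_audio,
)

from conftest import make_burst_audio


def sine(freq, rate=15277.0, dur=1.0, amp=1.0):
    t = np.arange(int(rate * dur)) / rate
    return ca.AudioRecording(samples=amp * np.sin(2 * np.pi * freq * t), rate=rate)


class TestLoadSave:
    def test_silence_round_trip_preserves_length_and_rate(self, tmp_path):
        rec = ca.AudioRecording(samples=np.zeros(15277), rate=15277.0)
        save_audio(rec, tmp_path / "z.wav")
        back = load_audio(tmp_path / "z.wav")
        assert back.samples.size == 15277
        assert back.rate == 15277.0
        assert np.all(back.samples == 0)

    def test_pcm16_round_trip_is_bit_identical(self, tmp_path):
        rng = np.random.default_rng(0)
        rec = ca.AudioRecording(samples=rng.uniform(-1, 1, 4000), rate=8000.0)
        p1, p2 = tmp_path / "a.wav", tmp_path / "b.wav"
        save_audio(rec, p1)
        first = load_audio(p1)
        save_audio(first, p2)
        second = load_audio(p2)
        np.testing.assert_array_equal(first.samples, second.samples)

    def test_stereo_with_identical_channels_matches_mono(self, tmp_path):
        from scipy.io import wavfile

        rng = np.random.default_rng(1)
        x = (rng.uniform(-0.5, 0.5, 2000) * 32767).astype(np.int16)
        wavfile.write(tmp_path / "mono.wav", 8000, x)
        wavfile.write(tmp_path / "stereo.wav", 8000, np.column_stack([x, x]))
        mono = load_audio(tmp_path / "mono.wav")
        with pytest.warns(UserWarning, match="channel mean"):
            stereo = load_audio(tmp_path / "stereo.wav")
        np.testing.assert_allclose(stereo.samples, mono.samples)

    def test_missing_file_raises(self, tmp_path):
        with pytest.raises(FileNotFoundError):
            load_audio(tmp_path / "absent.wav")


class TestBandpass:
    def test_passband_tone_preserved(self):
        rec = sine(1000.0)
        out = bandpass_filter(rec)
        in_rms = np.sqrt(np.mean(rec.samples**2))
        out_rms = np.sqrt(np.mean(out.samples**2))
        assert abs(out_rms - in_rms) / in_rms < 0.01

    def test_stopband_tone_attenuated_40db(self):
        # evaluate the designed response numerically at 50 Hz
        sos = signal.butter(4, [100, 3000], btype="bandpass", fs=15277, output="sos")
        w, h = signal.sosfreqz(sos, worN=[50.0], fs=15277)
        # forward-backward application squares the magnitude response
        atten_db = -20 * np.log10(np.abs(h[0]) ** 2)
        assert atten_db >= 40
        out = bandpass_filter(sine(50.0, dur=2.0))
        rms_ratio = np.sqrt(np.mean(out.samples[5000:-5000] ** 2) / np.mean(sine(50.0).samples**2))
        assert 20 * np.log10(rms_ratio) <= -40

    def test_white_noise_power_confined_to_band(self):
        rng = np.random.default_rng(3)
        rec = ca.AudioRecording(samples=rng.standard_normal(15277 * 4), rate=15277.0)
        out = bandpass_filter(rec)
        f, pxx = signal.periodogram(out.samples, fs=rec.rate)
        inband = (f >= 100) & (f <= 3000)
        assert pxx[inband].sum() / pxx.sum() >= 0.95

    def test_band_above_nyquist_rejected(self):
        with pytest.raises(ValueError, match="Nyquist"):
            bandpass_filter(sine(100, rate=4000.0), low=100, high=3000)

    def test_preserves_length_and_rate(self):
        rec = sine(500.0)
        out = bandpass_filter(rec)
        assert out.samples.size == rec.samples.size
        assert out.rate == rec.rate


class TestResample:
    def test_length_arithmetic_at_device_rate(self):
        rec = ca.AudioRecording(samples=np.zeros(15277), rate=15277.0)
        out = resample_audio(rec, 6000.0)
        assert out.samples.size == 6000
        assert out.rate == 6000.0

    def test_tone_amplitude_preserved(self):
        rec = sine(1000.0, dur=2.0)
        out = resample_audio(rec, 6000.0)
        # FFT peak amplitude oracle
        spec = np.abs(np.fft.rfft(out.samples * np.hanning(out.samples.size)))
        freqs = np.fft.rfftfreq(out.samples.size, 1 / 6000.0)
        peak_f = freqs[np.argmax(spec)]
        assert abs(peak_f - 1000.0) < 2.0
        rms_mid = np.sqrt(np.mean(out.samples[1000:-1000] ** 2))
        assert abs(rms_mid - 1 / np.sqrt(2)) / (1 / np.sqrt(2)) < 0.01

    def test_zero_signal_stays_zero(self):
        rec = ca.AudioRecording(samples=np.zeros(10000), rate=15277.0)
        out = resample_audio(rec, 6000.0)
        np.testing.assert_allclose(out.samples, 0.0, atol=1e-12)

    def test_upsampling_rejected(self):
        rec = sine(100.0, rate=6000.0)
        with pytest.raises(ValueError, match="upsampling"):
            resample_audio(rec, 12000.0)


class TestDenoise:
    def test_near_identity_on_clean_bursts(self):
        rec = make_burst_audio(n_bursts=20, seed=5)
        out = denoise_ambient(rec)
        rel = np.sqrt(np.mean((out.samples - rec.samples) ** 2) / np.mean(rec.samples**2))
        assert rel <= 0.10

    def test_snr_improves_by_6db_on_stationary_hum(self):
        # stationary multi-line hum (mains harmonics inside the band) at
        # 0 dB segmental SNR; the spectrally sparse floor is subtractable
        clean_rec = make_burst_audio(n_bursts=30, amp=0.2, seed=6)
        clean = clean_rec.samples
        active = np.abs(clean) > 0
        p_clean = np.mean(clean[active] ** 2)
        t = np.arange(clean.size) / clean_rec.rate
        hum = sum(np.sin(2 * np.pi * f * t + 0.7 * k) for k, f in enumerate([150, 450, 750, 1050]))
        hum *= np.sqrt(p_clean / np.mean(hum**2))  # 0 dB segmental SNR
        noisy = ca.AudioRecording(samples=np.clip(clean + hum, -1, 1), rate=clean_rec.rate)
        out = denoise_ambient(noisy)
        snr_in = ca.segmental_snr(clean, noisy.samples - clean, clean_rec.rate)
        snr_out = ca.segmental_snr(clean, out.samples - clean, clean_rec.rate)
        assert snr_out - snr_in >= 6.0

    def test_pure_noise_rms_halved(self):
        rng = np.random.default_rng(8)
        rec = ca.AudioRecording(samples=0.1 * rng.standard_normal(6000 * 20), rate=6000.0)
        out = denoise_ambient(rec)
        assert np.sqrt(np.mean(out.samples**2)) <= 0.5 * np.sqrt(np.mean(rec.samples**2))

    def test_no_frame_gains_energy(self):
        rec = make_burst_audio(n_bursts=10, noise_sigma=0.02, seed=9)
        out = denoise_ambient(rec)
        win = 300
        n = rec.samples.size // win * win
        e_in = np.sum(rec.samples[:n].reshape(-1, win) ** 2, axis=1)
        e_out = np.sum(out.samples[:n].reshape(-1, win) ** 2, axis=1)
        assert np.all(e_out <= e_in * (1 + 1e-3) + 1e-12)

    def test_frame_longer_than_signal_rejected(self):
        rec = ca.AudioRecording(samples=np.zeros(100) + 0.1, rate=6000.0)
        with pytest.raises(ValueError, match="frame"):
            denoise_ambient(rec, DenoiseConfig(frame_s=1.0))


class TestDespike:
    def test_inserted_impulse_removed(self):
        rec = make_burst_audio(n_bursts=20, amp=0.2, burst_s=1.2, gap_s=0.8, seed=10)
        x = rec.samples.copy()
        i0 = int(10.4 * rec.rate)  # inside a silence gap
        width = int(0.03 * rec.rate)
        x[i0 : i0 + width] += 2.0 * signal.windows.tukey(width, 0.5)
        spiked = ca.AudioRecording(samples=np.clip(x, -1, 1), rate=rec.rate)
        out = remove_spikes(spiked)
        n_mod = np.sum(out.samples != spiked.samples)
        assert n_mod <= 0.02 * x.size
        assert np.abs(out.samples[i0 : i0 + width]).max() < 0.5

    def test_spike_free_signal_unchanged(self):
        rec = make_burst_audio(n_bursts=15, burst_s=1.2, gap_s=0.8, seed=11)
        out = remove_spikes(rec)
        np.testing.assert_array_equal(out.samples, rec.samples)

    def test_all_zero_signal_unchanged(self):
        rec = ca.AudioRecording(samples=np.zeros(60000), rate=6000.0)
        out = remove_spikes(rec)
        np.testing.assert_array_equal(out.samples, 0.0)

    def test_window_too_short_rejected(self):
        rec = make_burst_audio(n_bursts=5, seed=12)
        with pytest.raises(ValueError, match="window"):
            remove_spikes(rec, window_s=1e-4)


class TestChain:
    def test_band_content_idempotent(self):
        # content well inside the passband (the filter's -3 dB shoulders are
        # not idempotent by construction, so shape the carrier 300-2000 Hz)
        rng = np.random.default_rng(13)
        rate = 15277.0
        sos = signal.butter(6, [300, 2000], btype="bandpass", fs=rate, output="sos")
        carrier = signal.sosfilt(sos, rng.standard_normal(int(rate * 30)))
        env = np.zeros(carrier.size)
        for k in range(10):
            i0 = int((1 + 3 * k) * rate)
            env[i0 : i0 + int(rate)] = 0.2 * signal.windows.tukey(int(rate), 0.2)
        rec = ca.AudioRecording(samples=np.clip(carrier * env, -1, 1), rate=rate)
        once = preprocess(rec, target_rate=6000.0)
        twice = bandpass_filter(once, 100.0, 2900.0)
        rms1 = np.sqrt(np.mean(once.samples**2))
        rms2 = np.sqrt(np.mean(twice.samples**2))
        assert abs(rms2 - rms1) / rms1 < 1e-3

    def test_denoise_despike_never_reduces_segmental_snr(self, default_record):
        subj = default_record.subject
        rec, parts = ca.synthesize_audio(subj, default_record.protocol, return_parts=True)
        base = preprocess(rec, denoise=False, despike=False)
        out = preprocess(rec)
        clean_ref = resample_audio(
            bandpass_filter(ca.AudioRecording(samples=parts["clean"], rate=rec.rate)), 6000.0
        ).samples
        snr_base = ca.segmental_snr(clean_ref, base.samples - clean_ref, 6000.0)
        snr_out = ca.segmental_snr(clean_ref, out.samples - clean_ref, 6000.0)
        assert snr_out >= snr_base
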