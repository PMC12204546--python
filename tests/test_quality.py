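import dataclasses

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ppgq.beats import BeatSeries, detect_beats_msptd, locate_fiducials
from ppgq.io_formats import Condition, PPGRecording
from ppgq.preprocess import FilterSpec, filter_zero_phase
from ppgq.quality import (
    MetricUnavailable,
    PulseAmplitudes,
    compute_all,
    compute_pi,
    compute_pulse_amplitudes,
    compute_snr,
    compute_tmcc,
    decompose_spectrum,
)
from ppgq.synthetic import WaveformConfig, generate_recording

FS = 100.0
SNR_SPEC = FilterSpec("chebyshev2", 4, (0.5, 12.0), FS, 20.0)
BEAT_SPEC = FilterSpec("butterworth", 4, (0.5, 8.0), FS)


def _rec(x):
    return PPGRecording("s", Condition.SUPINE, FS, np.asarray(x, dtype=float))


def _beats(rec):
    xf = filter_zero_phase(rec.samples, BEAT_SPEC)
    peaks, troughs = detect_beats_msptd(xf, rec.fs)
    return locate_fiducials(rec.samples, xf, peaks, troughs, rec.fs), xf


class TestSNR:
    def test_tone_plus_noise_matches_component_power_oracle(self):
        # oracle: run the generated components through the same retained
        # band and account for their powers directly
        t = np.arange(3000) / FS
        rng = np.random.default_rng(0)
        a, band_fraction = 1.0, (12 - 0.5) / (FS / 2)
        sigma = np.sqrt((a**2 / 2) / 100 / band_fraction)  # ~20 dB target
        tone = a * np.sin(2 * np.pi * 1.5 * t)
        noise = rng.normal(0, sigma, t.size)
        snr, _ = compute_snr(_rec(tone + noise))
        p_tone = np.var(filter_zero_phase(tone, SNR_SPEC))
        p_noise = np.var(filter_zero_phase(noise, SNR_SPEC))
        oracle = 10 * np.log10(p_tone / p_noise)
        assert snr == pytest.approx(oracle, abs=1.5)

    def test_noiseless_in_bin_tone_near_leakage_floor(self):
        t = np.arange(3000) / FS
        snr, _ = compute_snr(_rec(np.sin(2 * np.pi * 2.0 * t)))
        assert snr >= 60.0

    def test_non_harmonic_tone_counts_as_noise(self):
        t = np.arange(3000) / FS
        x = np.sin(2 * np.pi * 1.0 * t) + 0.1 * np.sin(2 * np.pi * 2.5 * t)
        snr, _ = compute_snr(_rec(x))
        assert snr == pytest.approx(20 * np.log10(1 / 0.1), abs=1.0)

    def test_harmonic_tone_is_excluded_from_noise(self):
        t = np.arange(3000) / FS
        base = np.sin(2 * np.pi * 1.0 * t)
        snr_nonharm, _ = compute_snr(_rec(base + 0.1 * np.sin(2 * np.pi * 2.5 * t)))
        snr_harm, _ = compute_snr(_rec(base + 0.1 * np.sin(2 * np.pi * 2.0 * t)))
        assert snr_harm - snr_nonharm >= 20.0

    def test_spectral_power_conservation(self, noisy_recording):
        rec, _, _ = noisy_recording
        _, dec = compute_snr(rec)
        parts = dec.p_dc + dec.p_fundamental + dec.p_harmonics + dec.p_noise
        assert abs(parts - dec.p_total) <= 1e-9 * dec.p_total

    def test_flat_spectrum_unavailable(self):
        with pytest.raises(MetricUnavailable):
            decompose_spectrum(np.zeros(2000), FS)

    def test_scale_offset_invariance(self, noisy_recording):
        rec, _, _ = noisy_recording
        snr1, _ = compute_snr(rec)
        rec2 = dataclasses.replace(rec, samples=2.5 * rec.samples + 40.0)
        snr2, _ = compute_snr(rec2)
        assert snr1 == pytest.approx(snr2, abs=1e-6)


class TestPulseAmplitudes:
    def test_sine_on_offset_baseline(self, sine_recording):
        beats, _ = _beats(sine_recording)
        amps = compute_pulse_amplitudes(sine_recording.samples, beats)
        assert amps.median_ac == pytest.approx(2.0, rel=0.02)
        assert amps.median_dc == pytest.approx(100.0, rel=0.01)

    def test_generated_train_recovers_config(self, clean_recording):
        rec, gt, cfg = clean_recording
        beats, _ = _beats(rec)
        amps = compute_pulse_amplitudes(rec.samples, beats)
        assert amps.median_ac == pytest.approx(cfg.ac_amp, rel=0.05)
        assert amps.median_dc == pytest.approx(cfg.dc_level, rel=0.01)

    def test_negative_baseline_uses_absolute_dc(self):
        t = np.arange(3000) / FS
        x = -100.0 + np.sin(2 * np.pi * 1.2 * t)
        beats, _ = _beats(_rec(x))
        amps = compute_pulse_amplitudes(x, beats)
        assert amps.median_dc == pytest.approx(100.0, rel=0.02)


class TestPI:
    def test_analytic_value(self):
        amps = PulseAmplitudes(ac=np.array([2.0, 2.0, 2.0]), dc=np.array([100.0] * 3))
        assert compute_pi(amps) == pytest.approx(2.0, abs=1e-12)

    def test_zero_ac_gives_zero(self):
        amps = PulseAmplitudes(ac=np.zeros(3), dc=np.array([100.0] * 3))
        assert compute_pi(amps) == 0.0

    def test_zero_dc_undefined(self):
        amps = PulseAmplitudes(ac=np.ones(3), dc=np.zeros(3))
        with pytest.raises(MetricUnavailable):
            compute_pi(amps)

    def test_generated_train_pi(self):
        cfg = WaveformConfig(ac_amp=0.5, dc_level=100.0, noise_sd=0.0, wander_amp=0.0, hr_sd=0.0, seed=1)
        rec, _ = generate_recording(cfg)
        beats, _ = _beats(rec)
        pi = compute_pi(compute_pulse_amplitudes(rec.samples, beats))
        assert pi == pytest.approx(0.5, rel=0.05)


def brute_force_tmcc(x, midpoints, L):
    """Straight-line reimplementation: segment -> mean -> correlate."""
    half = L // 2
    windows = [x[m - half : m + half + 1] for m in midpoints if m - half >= 0 and m + half < len(x)]
    template = sum(windows) / len(windows)
    corrs = []
    for w in windows:
        dw, dt = w - w.mean(), template - template.mean()
        denom = np.sqrt((dw**2).sum() * (dt**2).sum())
        corrs.append((dw * dt).sum() / denom if denom > 0 else 0.0)
    return float(np.mean(corrs))


class TestTMCC:
    def test_identical_pulses_correlate_perfectly(self, clean_recording):
        rec, _, _ = clean_recording
        beats, xf = _beats(rec)
        assert compute_tmcc(xf, beats, rec.fs) >= 0.999

    def test_single_beat_unavailable(self):
        beats = BeatSeries(peaks=[10, 50], onsets=[5, 45], midpoints=[7, 47], fs=FS)
        one = BeatSeries(peaks=[10, 50], onsets=[5, 45], midpoints=[7, 47], fs=FS)
        one.peaks = one.peaks[:1]
        one.onsets = one.onsets[:1]
        one.midpoints = one.midpoints[:1]
        with pytest.raises(MetricUnavailable):
            compute_tmcc(np.random.default_rng(0).normal(size=100), one, FS)

    def test_matches_brute_force_on_noisy_train(self):
        cfg = WaveformConfig(noise_sd=0.0, wander_amp=0.0, hr_sd=0.0, duration=10.0, seed=2)
        rec, _ = generate_recording(cfg)
        rng = np.random.default_rng(0)
        beats, xf = _beats(rec)
        noisy = xf + rng.normal(0, 0.1 * np.std(xf), xf.size)
        got = compute_tmcc(noisy, beats, rec.fs)
        L = int(round(np.median(np.diff(beats.peaks))))
        if L % 2 == 0:
            L -= 1
        ref = brute_force_tmcc(noisy, beats.midpoints, L)
        assert got == pytest.approx(ref, abs=1e-12)
        assert 0.9 < got < 1.0

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(st.integers(min_value=0, max_value=10_000))
    def test_bounded_for_random_signals(self, seed):
        rng = np.random.default_rng(seed)
        x = rng.normal(size=400)
        mids = np.sort(rng.choice(np.arange(30, 370), size=5, replace=False))
        peaks = mids + 3
        onsets = mids - 3
        beats = BeatSeries(peaks=peaks, onsets=onsets, midpoints=mids, fs=FS)
        try:
            tmcc = compute_tmcc(x, beats, FS)
        except MetricUnavailable:
            return
        assert -1.0 - 1e-12 <= tmcc <= 1.0 + 1e-12


class TestComputeAll:
    def test_flat_line_all_missing(self):
        qm = compute_all(_rec(np.full(3000, 100.0)))
        assert qm.qc == "flat_line"
        assert np.isnan(qm.snr_db) and np.isnan(qm.pi_percent) and np.isnan(qm.tmcc)
        assert "snr_db" in qm.reasons

    def test_clean_recording_all_present(self, clean_recording):
        rec, _, _ = clean_recording
        qm = compute_all(rec)
        assert qm.qc == "pass" and not qm.reasons
        assert qm.tmcc > 0.99
        assert np.isfinite(qm.snr_db) and np.isfinite(qm.pi_percent)
        assert qm.n_beats >= 30

    def test_heavy_noise_lowers_snr_of_twin(self):
        base = WaveformConfig(seed=13)
        noisy = dataclasses.replace(base, noise_sd=5 * base.ac_amp)
        s_clean = compute_all(generate_recording(base)[0]).snr_db
        s_noisy = compute_all(generate_recording(noisy)[0]).snr_db
        assert s_noisy < s_clean

    def test_quality_metrics_fall_with_noise(self):
        # monotone probe: mean SNR and TMCC non-increasing over a noise sweep
        levels = [0.0, 0.05, 0.25, 1.0]
        snr_means, tmcc_means = [], []
        for sd in levels:
            snrs, tmccs = [], []
            for seed in range(10):
                cfg = WaveformConfig(noise_sd=sd, seed=seed)
                qm = compute_all(generate_recording(cfg)[0])
                snrs.append(qm.snr_db)
                tmccs.append(qm.tmcc)
            snr_means.append(np.mean(snrs))
            tmcc_means.append(np.nanmean(tmccs))
        assert all(a >= b for a, b in zip(snr_means, snr_means[1:]))
        assert all(a >= b for a, b in zip(tmcc_means, tmcc_means[1:]))

    def test_pi_scale_invariance(self, noisy_recording):
        rec, _, _ = noisy_recording
        pi1 = compute_all(rec).pi_percent
        pi2 = compute_all(dataclasses.replace(rec, samples=3.0 * rec.samples)).pi_percent
        assert pi1 == pytest.approx(pi2, rel=1e-9)

    def test_tmcc_affine_invariance(self, noisy_recording):
        rec, _, _ = noisy_recording
        t1 = compute_all(rec).tmcc
        t2 = compute_all(dataclasses.replace(rec, samples=2.0 * rec.samples + 10.0)).tmcc
        assert t1 == pytest.approx(t2, abs=1e-9)
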