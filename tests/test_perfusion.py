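"""High-pass filter, ventricle signal extraction, and the CCv map."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import signal as sps

from dpdr.perfusion import (
    AnatomyMasks,
    CardiacSignal,
    FrameSequence,
    compute_ccv,
    extract_ventricle_signal,
    highpass_filter,
)
from dpdr.synth import SynthImagingParams, generate_sequence

from conftest import block_scene, naive_ccv_oracle

FS = 15.0


def filtfilt_gain(freq_hz: float, fs: float = FS, cutoff: float = 0.85) -> float:
    """Independent oracle: amplitude gain of the forward-backward 4th-order
    Butterworth high-pass, from its transfer function."""
    sos = sps.butter(4, cutoff, "highpass", fs=fs, output="sos")
    w, h = sps.sosfreqz(sos, worN=8192, fs=fs)
    return float(np.interp(freq_hz, w, np.abs(h) ** 2))


class TestHighpassFilter:
    def test_constant_series_maps_to_zero(self):
        out = highpass_filter(np.full(150, 1234.5), FS)
        assert np.abs(out).max() < 1e-9 * 1234.5

    @pytest.mark.parametrize("freq, stop", [(0.3, True), (1.2, False)])
    def test_magnitude_response(self, freq, stop):
        """Respiratory-band input is blocked; cardiac-band input passes with
        the gain the designed filter actually has at that frequency."""
        t = np.arange(150) / FS
        x = np.sin(2 * np.pi * freq * t)
        y = highpass_filter(x, FS)
        ratio = np.sqrt((y**2).mean() / (x**2).mean())
        if stop:
            assert ratio < 0.1
        assert ratio == pytest.approx(filtfilt_gain(freq), abs=0.01)

    def test_short_series_rejected_with_minimum(self):
        with pytest.raises(ValueError, match="minimum"):
            highpass_filter(np.ones(5), FS)

    @pytest.mark.parametrize("cutoff", [0.0, 7.5, 8.0])
    def test_cutoff_outside_nyquist_rejected(self, cutoff):
        with pytest.raises(ValueError, match="cutoff"):
            highpass_filter(np.ones(50), FS, cutoff_hz=cutoff)

    def test_output_mean_is_negligible(self):
        """The large DC offset is gone; the residual finite-sample mean is a
        small fraction of the fluctuation scale."""
        rng = np.random.default_rng(0)
        x = rng.normal(1000, 10, 200)
        y = highpass_filter(x, FS)
        assert abs(y.mean()) < 0.05 * x.std()


class TestVentricleSignal:
    def test_period_estimate_matches_cardiac_frequency(self, noisy_scene):
        seq, masks, _ = noisy_scene
        card = extract_ventricle_signal(seq, masks)
        assert card.estimated_period_frames == 12  # 15 fps / 1.25 Hz
        assert card.frequency_hz == pytest.approx(1.25, abs=0.05)

    def test_noiseless_signal_matches_stored_waveform(self, clean_scene):
        """pc_lv reproduces the injected ventricle component up to the
        filter's (mild) attenuation at the cardiac frequency."""
        seq, masks, truth = clean_scene
        card = extract_ventricle_signal(seq, masks)
        # linearity oracle: the filtered stored waveform is what pc_lv must be
        filtered_truth = highpass_filter(truth.waveforms["ventricle"], seq.frame_rate_hz)
        assert np.allclose(card.pc_lv, filtered_truth, atol=0.05)  # float32 storage error
        raw = truth.waveforms["ventricle"] - truth.waveforms["ventricle"].mean()
        rel_rms = np.sqrt(((card.pc_lv - raw) ** 2).mean() / (raw**2).mean())
        assert rel_rms < 0.12  # filter transition-band attenuation only
        assert np.corrcoef(card.pc_lv, raw)[0, 1] > 0.995

    def test_constant_roi_raises(self, noisy_scene):
        seq, masks, _ = noisy_scene
        flat = FrameSequence(
            pixels=np.full_like(seq.pixels, 100.0),
            frame_rate_hz=seq.frame_rate_hz,
            pixel_spacing_mm=seq.pixel_spacing_mm,
            saturation_level=seq.saturation_level,
        )
        with pytest.raises(ValueError, match="no cardiac component"):
            extract_ventricle_signal(flat, masks)

    def test_period_within_physiological_band(self, noisy_scene):
        seq, masks, _ = noisy_scene
        card = extract_ventricle_signal(seq, masks)
        assert FS / 3.0 <= card.estimated_period_frames <= FS / 0.85


def _scene_with_copies(c: float = 2.5, T: int = 150):
    """Scene where lung pixels are exact +/- scaled copies of the ventricle."""
    t = np.arange(T) / FS
    vent = 5.0 * np.sin(2 * np.pi * 1.25 * t)
    return block_scene(vent, {"anti": -c * vent, "inphase": c * vent})


class TestComputeCCV:
    def test_perfect_antiphase_scores_one(self):
        seq, masks, idx = _scene_with_copies()
        card = extract_ventricle_signal(seq, masks)
        pm = compute_ccv(seq, card, masks)
        anti = pm.ccv[:, masks.lung][:, idx["anti"]]
        assert np.all(anti > 1 - 1e-9)
        assert np.all(pm.max_ccv[masks.lung][idx["anti"]] == pytest.approx(1.0, abs=1e-9))

    def test_inphase_copy_scores_minus_one(self):
        seq, masks, idx = _scene_with_copies()
        card = extract_ventricle_signal(seq, masks)
        pm = compute_ccv(seq, card, masks)
        inph = pm.ccv[:, masks.lung][:, idx["inphase"]]
        assert np.all(inph < -1 + 1e-9)

    def test_scale_invariance_of_correlation(self):
        """Per-pixel affine rescaling (gain and offset) leaves CCv unchanged."""
        t = np.arange(150) / FS
        rng = np.random.default_rng(4)
        base = np.sin(2 * np.pi * 1.25 * t)[:, None] + 0.5 * rng.standard_normal((150, 8))
        vent = 5.0 * np.sin(2 * np.pi * 1.25 * t)
        seq1, masks, idx = block_scene(vent, {"a": base, "b": 7.0 * base + 123.0})
        card = extract_ventricle_signal(seq1, masks)
        pm = compute_ccv(seq1, card, masks)
        cc = pm.ccv[:, masks.lung]
        assert np.allclose(cc[:, idx["a"]], cc[:, idx["b"]], atol=1e-10)

    def test_zero_variance_pixel_flagged_undefined(self):
        t = np.arange(150) / FS
        vent = 5.0 * np.sin(2 * np.pi * 1.25 * t)
        seq, masks, idx = block_scene(vent, {"dead": np.zeros(150), "live": -vent})
        card = extract_ventricle_signal(seq, masks)
        pm = compute_ccv(seq, card, masks)
        dead = idx["dead"][0]
        assert not pm.defined[:, masks.lung][:, dead].any()
        assert np.all(pm.ccv[:, masks.lung][:, dead] == 0.0)
        assert np.isnan(pm.max_ccv[masks.lung][dead])

    def test_saturated_pixel_flagged_undefined(self):
        t = np.arange(150) / FS
        vent = 5.0 * np.sin(2 * np.pi * 1.25 * t)
        sat_series = -vent.copy()
        sat_series[::3] = 1e7 - 10.0  # pegged at saturation in 1/3 of frames
        seq, masks, idx = block_scene(vent, {"sat": sat_series, "ok": -vent})
        card = extract_ventricle_signal(seq, masks)
        pm = compute_ccv(seq, card, masks)
        assert np.isnan(pm.max_ccv[masks.lung][idx["sat"][0]])
        assert pm.max_ccv[masks.lung][idx["ok"][0]] > 0.99

    def test_window_longer_than_sequence_rejected(self, noisy_scene):
        seq, masks, _ = noisy_scene
        card = extract_ventricle_signal(seq, masks)
        with pytest.raises(ValueError, match="longer than sequence"):
            compute_ccv(seq, card, masks, window_frames=seq.n_frames + 1)

    def test_empty_lung_mask_rejected(self, noisy_scene):
        seq, masks, _ = noisy_scene
        bad = AnatomyMasks(
            right_lung=np.zeros_like(masks.right_lung),
            left_lung=masks.left_lung,
            ventricle_roi=masks.ventricle_roi,
        )
        card = extract_ventricle_signal(seq, masks)
        with pytest.raises(ValueError, match="lung masks"):
            compute_ccv(seq, card, bad)

    def test_matches_bruteforce_oracle(self):
        """Sliding-window implementation equals the naive double loop."""
        rng = np.random.default_rng(99)
        T, n = 60, 40
        t = np.arange(T) / FS
        vent = 3.0 * np.sin(2 * np.pi * 1.3 * t) + 0.1 * rng.standard_normal(T)
        lung_series = rng.normal(0, 1, (T, n)) + np.sin(2 * np.pi * 1.3 * t)[:, None]
        seq, masks, _ = block_scene(vent, {"px": lung_series})
        card = extract_ventricle_signal(seq, masks)
        pm = compute_ccv(seq, card, masks)
        x = highpass_filter(seq.pixels[:, masks.lung].astype(float), FS, axis=0)
        expected = naive_ccv_oracle(x, card.pc_lv, pm.window_frames)
        got = pm.ccv[:, masks.lung]
        assert got.shape == expected.shape
        assert np.nanmax(np.abs(got[pm.defined[:, masks.lung]] - expected[pm.defined[:, masks.lung]])) < 1e-10

    def test_maxccv_is_max_over_valid_frames(self, noisy_scene):
        seq, masks, _ = noisy_scene
        card = extract_ventricle_signal(seq, masks)
        pm = compute_ccv(seq, card, masks)
        cc = pm.ccv[:, masks.lung]
        defined = pm.defined[:, masks.lung]
        recomputed = np.max(np.where(defined, cc, -np.inf), axis=0)
        ok = defined.any(axis=0)
        assert np.allclose(pm.max_ccv[masks.lung][ok], recomputed[ok], atol=1e-6)
        assert len(pm.valid_frames) == seq.n_frames - pm.window_frames + 1

    @settings(max_examples=15, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 2**16))
    def test_ccv_always_within_unit_interval(self, seed):
        """Every defined CCv lies in [-1, 1] for arbitrary random input."""
        rng = np.random.default_rng(seed)
        T = int(rng.integers(30, 80))
        t = np.arange(T) / FS
        vent = rng.uniform(1, 5) * np.sin(2 * np.pi * rng.uniform(1.0, 2.0) * t)
        series = rng.normal(0, rng.uniform(0.1, 3), (T, 12))
        seq, masks, _ = block_scene(vent, {"px": series})
        card = extract_ventricle_signal(seq, masks)
        pm = compute_ccv(seq, card, masks)
        vals = pm.ccv[pm.defined]
        assert np.all(vals >= -1.0) and np.all(vals <= 1.0)
        mx = pm.max_ccv[~np.isnan(pm.max_ccv)]
        assert np.all(mx >= -1.0) and np.all(mx <= 1.0)

    def test_expected_attenuation_by_noise(self):
        """Additive pixel noise attenuates CCv by the closed-form factor
        sqrt(s / (s + n)), with signal and noise powers taken after the
        high-pass filter; checked over 300 replicate pixels."""
        T, a, sigma, fc = 401, 1.0, 1.0, 1.25
        rng = np.random.default_rng(2024)
        t = np.arange(T) / FS
        s = np.sin(2 * np.pi * fc * t)
        noise = sigma * rng.standard_normal((T, 300))
        seq, masks, idx = block_scene(s, {"px": -a * s[:, None] + noise})
        card = extract_ventricle_signal(seq, masks)
        pm = compute_ccv(seq, card, masks, window_frames=T - 2)
        g_sig = filtfilt_gain(fc)
        sos = sps.butter(4, 0.85, "highpass", fs=FS, output="sos")
        w, h = sps.sosfreqz(sos, worN=4096, fs=FS)
        g_noise = float(np.mean(np.abs(h) ** 4))  # white-noise variance factor
        rho = np.sqrt((a * g_sig) ** 2 / 2 / ((a * g_sig) ** 2 / 2 + sigma**2 * g_noise))
        measured = np.nanmean(pm.max_ccv[masks.lung][idx["px"]])
        assert measured == pytest.approx(rho, abs=0.015)
        naive = np.sqrt((a**2 / 2) / (a**2 / 2 + sigma**2))
        assert measured == pytest.approx(naive, abs=0.05)

    def test_monotone_in_cardiac_amplitude(self):
        """With fixed noise, more cardiac amplitude never lowers mean MaxCCv."""
        T, sigma = 150, 1.0
        rng = np.random.default_rng(77)
        t = np.arange(T) / FS
        s = np.sin(2 * np.pi * 1.25 * t)
        amps = [0.3, 0.6, 1.2, 2.4]
        blocks = {
            f"a{k}": -a * s[:, None] + sigma * rng.standard_normal((T, 220))
            for k, a in enumerate(amps)
        }
        seq, masks, idx = block_scene(s, blocks)
        card = extract_ventricle_signal(seq, masks)
        pm = compute_ccv(seq, card, masks)
        means = [np.nanmean(pm.max_ccv[masks.lung][idx[f"a{k}"]]) for k in range(len(amps))]
        assert all(m2 > m1 for m1, m2 in zip(means, means[1:]))

    def test_spatial_binning_raises_snr(self):
        """2x2 binning averages noise down, so mean MaxCCv should not drop."""
        p = SynthImagingParams.test_scale(noise_sd=300.0, rng_seed=3)
        seq, masks, _ = generate_sequence(p)
        card = extract_ventricle_signal(seq, masks)
        m1 = compute_ccv(seq, card, masks, spatial_bin=1)
        m2 = compute_ccv(seq, card, masks, spatial_bin=2)
        assert np.nanmean(m2.max_ccv) > np.nanmean(m1.max_ccv)
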