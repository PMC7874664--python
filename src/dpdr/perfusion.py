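"""Pulmonary perfusion mapping from dynamic chest radiograph sequences.

Cardiac-synchronous pixel-value oscillations in the lung fields track
pulmonary blood flow: with each systole the ventricle brightens (less
attenuation is the opposite — here pixel value *rises* over the ventricle as
blood leaves it toward the lungs, while perfused lung pixels *darken* in
anti-phase as blood fills the capillary bed). The analysis chain is

1. temporal high-pass filtering (cutoff 0.85 Hz) to strip the respiratory
   component and retain the cardiac band,
2. extraction of a reference heartbeat waveform ``pc_lv`` from a ventricle
   region of interest,
3. per-pixel sliding-window Pearson correlation between ``-pc_lv`` and the
   filtered lung-pixel series, giving a cross-correlation value (CCv) map in
   [-1, 1] per frame, and
4. a per-pixel maximum over frames (MaxCCv) — the perfusion image.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal as _signal

__all__ = [
    "FrameSequence",
    "AnatomyMasks",
    "CardiacSignal",
    "PerfusionMap",
    "highpass_filter",
    "extract_ventricle_signal",
    "compute_ccv",
    "DEFAULT_CUTOFF_HZ",
    "CARDIAC_BAND_HZ",
]

DEFAULT_CUTOFF_HZ = 0.85
#: search band for the cardiac spectral peak (0.85 Hz ~ 51 bpm, 3 Hz ~ 180 bpm)
CARDIAC_BAND_HZ = (0.85, 3.0)
MIN_SERIES_LEN = 9
_FILTER_ORDER = 4


@dataclass
class FrameSequence:
    """A dynamic radiograph stack: frames x rows x columns of pixel values."""

    pixels: np.ndarray  # (T, H, W), 16-bit range stored as float
    frame_rate_hz: float
    pixel_spacing_mm: float
    saturation_level: float

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim != 3:
            raise ValueError(f"pixels must be (T, H, W), got shape {self.pixels.shape}")
        if self.frame_rate_hz <= 0:
            raise ValueError("frame_rate_hz must be positive")

    @property
    def n_frames(self) -> int:
        return self.pixels.shape[0]

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.pixels.shape

    def validate(self) -> None:
        """Check the value range and that the cardiac band is observable."""
        if self.pixels.min() < 0 or self.pixels.max() > self.saturation_level:
            raise ValueError("pixel values outside [0, saturation_level]")
        min_frames = int(np.ceil(2 * self.frame_rate_hz / DEFAULT_CUTOFF_HZ))
        if self.n_frames < min_frames:
            raise ValueError(
                f"sequence too short: {self.n_frames} frames; need >= {min_frames} "
                f"(~2 cardiac-band cycles at {self.frame_rate_hz} fps)"
            )


@dataclass
class AnatomyMasks:
    """Right-lung, left-lung and ventricle regions in image coordinates.

    Side labels are the *subject's* anatomy: in a posteroanterior radiograph
    with row 0 superior, the right lung appears on the viewer's left.
    """

    right_lung: np.ndarray
    left_lung: np.ndarray
    ventricle_roi: np.ndarray

    def __post_init__(self) -> None:
        self.right_lung = np.asarray(self.right_lung, bool)
        self.left_lung = np.asarray(self.left_lung, bool)
        self.ventricle_roi = np.asarray(self.ventricle_roi, bool)
        if not (self.right_lung.shape == self.left_lung.shape == self.ventricle_roi.shape):
            raise ValueError("mask shapes differ")
        overlap = (
            (self.right_lung & self.left_lung)
            | (self.right_lung & self.ventricle_roi)
            | (self.left_lung & self.ventricle_roi)
        )
        if overlap.any():
            raise ValueError("masks must be pairwise disjoint")
        if not self.ventricle_roi.any():
            raise ValueError("ventricle ROI is empty")

    @property
    def lung(self) -> np.ndarray:
        """Union of both lung fields."""
        return self.right_lung | self.left_lung

    def to_labels(self) -> np.ndarray:
        """Label image: 0 background, 1 right lung, 2 left lung, 3 ventricle."""
        lab = np.zeros(self.right_lung.shape, np.uint8)
        lab[self.right_lung] = 1
        lab[self.left_lung] = 2
        lab[self.ventricle_roi] = 3
        return lab

    @classmethod
    def from_labels(cls, lab: np.ndarray) -> "AnatomyMasks":
        return cls(right_lung=lab == 1, left_lung=lab == 2, ventricle_roi=lab == 3)


@dataclass
class CardiacSignal:
    """High-pass-filtered mean ventricle-ROI signal and its dominant period."""

    pc_lv: np.ndarray
    estimated_period_frames: int
    frequency_hz: float


@dataclass
class PerfusionMap:
    """Frame-wise CCv stack and its per-pixel MaxCCv reduction.

    ``ccv[i]`` corresponds to the window centred at frame
    ``valid_frames[i]``; values at zero-variance windows are 0 and flagged in
    ``defined``. Pixels outside the lung fields (or saturated) are NaN in
    ``max_ccv`` and carry no defined CCv.
    """

    ccv: np.ndarray  # (T', H, W), NaN outside lung fields
    defined: np.ndarray  # (T', H, W) bool
    max_ccv: np.ndarray  # (H, W), NaN where undefined
    valid_frames: np.ndarray  # frame indices where the full window fits
    window_frames: int
    cardiac_freq_hz: float

    @property
    def n_undefined_pixels(self) -> int:
        lungish = ~np.isnan(self.ccv).all(axis=0)
        return int((lungish & np.isnan(self.max_ccv)).sum())


def _design_sos(frame_rate_hz: float, cutoff_hz: float) -> np.ndarray:
    if not 0 < cutoff_hz < frame_rate_hz / 2:
        raise ValueError(
            f"cutoff_hz must lie in (0, Nyquist={frame_rate_hz / 2} Hz), got {cutoff_hz}"
        )
    return _signal.butter(_FILTER_ORDER, cutoff_hz, "highpass", fs=frame_rate_hz, output="sos")


def highpass_filter(
    series: np.ndarray,
    frame_rate_hz: float,
    cutoff_hz: float = DEFAULT_CUTOFF_HZ,
    axis: int = -1,
) -> np.ndarray:
    """Zero-phase 4th-order Butterworth high-pass along the time axis.

    Applied forward-backward (``sosfiltfilt``) so that the temporal alignment
    the downstream cross-correlation depends on is preserved; the effective
    magnitude response is the squared single-pass response.
    """
    x = np.asarray(series, float)
    n = x.shape[axis]
    if n < MIN_SERIES_LEN:
        raise ValueError(f"series too short for filtering: {n} < minimum {MIN_SERIES_LEN} frames")
    sos = _design_sos(frame_rate_hz, cutoff_hz)
    padlen = min(3 * (2 * sos.shape[0] + 1), n - 1)
    return _signal.sosfiltfilt(sos, x, axis=axis, padlen=padlen)


def _dominant_frequency(x: np.ndarray, fs: float, band: tuple[float, float]) -> float:
    """Frequency of the dominant spectral peak of ``x`` within ``band``.

    Zero-padded periodogram; raises if no peak stands above the in-band noise
    floor (degenerate or non-cardiac input).
    """
    n = len(x)
    nfft = max(4096, 8 * n)
    power = np.abs(np.fft.rfft(x, nfft)) ** 2
    freqs = np.fft.rfftfreq(nfft, 1.0 / fs)
    in_band = (freqs >= band[0]) & (freqs <= band[1])
    pband = power[in_band]
    if pband.size == 0 or pband.max() <= 0:
        raise ValueError("no cardiac component detected in the ventricle signal")
    floor = np.median(pband)
    if floor > 0 and pband.max() < 5.0 * floor:
        raise ValueError("no cardiac component detected in the ventricle signal")
    return float(freqs[in_band][np.argmax(pband)])


def extract_ventricle_signal(
    seq: FrameSequence,
    masks: AnatomyMasks,
    cutoff_hz: float = DEFAULT_CUTOFF_HZ,
    band_hz: tuple[float, float] = CARDIAC_BAND_HZ,
) -> CardiacSignal:
    """Mean ventricle-ROI pixel value per frame, high-pass filtered.

    The dominant spectral peak in the cardiac band gives the heart rate; the
    corresponding period in frames sets the correlation window length.
    """
    roi_mean = seq.pixels[:, masks.ventricle_roi].mean(axis=1)
    pc_lv = highpass_filter(roi_mean, seq.frame_rate_hz, cutoff_hz)
    rms = np.sqrt(np.mean(pc_lv**2))
    if rms < 1e-9 * max(1.0, np.abs(roi_mean).max()):
        raise ValueError("no cardiac component detected in the ventricle signal")
    f0 = _dominant_frequency(pc_lv, seq.frame_rate_hz, band_hz)
    period = int(round(seq.frame_rate_hz / f0))
    return CardiacSignal(pc_lv=pc_lv, estimated_period_frames=period, frequency_hz=f0)


def _window_length(period_frames: int) -> int:
    """One cardiac period, rounded up to odd, never below 5 frames."""
    w = max(5, int(period_frames))
    return w if w % 2 == 1 else w + 1


def _sliding_sums(x: np.ndarray, w: int) -> np.ndarray:
    """Sums over every length-``w`` window along axis 0 (output length T-w+1)."""
    c = np.cumsum(x, axis=0, dtype=np.float64)
    out = np.empty((x.shape[0] - w + 1,) + x.shape[1:], np.float64)
    out[0] = c[w - 1]
    out[1:] = c[w:] - c[: -w]
    return out


def compute_ccv(
    seq: FrameSequence,
    cardiac: CardiacSignal,
    masks: AnatomyMasks,
    window_frames: int | None = None,
    cutoff_hz: float = DEFAULT_CUTOFF_HZ,
    spatial_bin: int = 1,
    saturation_frac: float = 0.10,
) -> PerfusionMap:
    """Frame-by-frame cross-correlation perfusion map.

    For every lung-field pixel and every frame where a full window fits, the
    CCv is the Pearson correlation between ``-pc_lv`` and the high-pass
    filtered pixel series over a centred window of one estimated cardiac
    period (odd length, minimum 5). The sign convention makes perfused pixels
    — which oscillate in anti-phase with the ventricle — score +1.

    Zero-temporal-variance windows give CCv = 0 with the defined flag cleared;
    pixels saturated in more than ``saturation_frac`` of frames are undefined
    throughout. ``spatial_bin`` > 1 averages k x k pixel blocks (snapped to the
    block grid) before correlating, as a noise-robustness option; the map is
    reported on the original grid.
    """
    if not (masks.right_lung.any() and masks.left_lung.any()):
        raise ValueError("both lung masks must be nonempty")
    if masks.right_lung.shape != seq.pixels.shape[1:]:
        raise ValueError("mask geometry does not match the frame geometry")
    w = _window_length(cardiac.estimated_period_frames if window_frames is None else window_frames)
    T = seq.n_frames
    if w > T:
        raise ValueError(f"window of {w} frames longer than sequence of {T} frames")
    if len(cardiac.pc_lv) != T:
        raise ValueError("cardiac signal length does not match the sequence")

    lung = masks.lung
    raw = seq.pixels[:, lung].astype(np.float64)  # (T, Npix)
    if spatial_bin > 1:
        raw = _bin_series(seq.pixels, lung, spatial_bin)
    saturated = (seq.pixels[:, lung] >= seq.saturation_level).mean(axis=0) > saturation_frac

    x = highpass_filter(raw, seq.frame_rate_hz, cutoff_hz, axis=0)
    r = -np.asarray(cardiac.pc_lv, np.float64)

    half = w // 2
    valid = np.arange(half, T - half)
    n_win = len(valid)

    sx = _sliding_sums(x, w)
    sxx = _sliding_sums(x * x, w)
    sr = _sliding_sums(r, w)
    srr = _sliding_sums(r * r, w)
    sxr = _sliding_sums(x * r[:, None], w)

    cov = sxr - sx * sr[:, None] / w
    var_x = sxx - sx**2 / w
    var_r = srr - sr**2 / w

    # zero-variance policy: near-machine-zero window variance is "no signal"
    tol = (1e-9 * max(1.0, float(seq.saturation_level))) ** 2 * w
    bad_x = var_x <= tol
    bad_r = var_r <= tol
    denom = np.sqrt(np.clip(var_x, tol, None) * np.clip(var_r[:, None], tol, None))
    cc = cov / denom
    np.clip(cc, -1.0, 1.0, out=cc)

    defined_flat = ~(bad_x | bad_r[:, None] | saturated[None, :])
    cc[~defined_flat] = 0.0

    ccv = np.full((n_win,) + lung.shape, np.nan)
    ccv[:, lung] = cc
    defined = np.zeros((n_win,) + lung.shape, bool)
    defined[:, lung] = defined_flat

    max_flat = np.where(defined_flat.any(axis=0), np.max(np.where(defined_flat, cc, -np.inf), axis=0), np.nan)
    max_ccv = np.full(lung.shape, np.nan)
    max_ccv[lung] = max_flat

    return PerfusionMap(
        ccv=ccv,
        defined=defined,
        max_ccv=max_ccv,
        valid_frames=valid,
        window_frames=w,
        cardiac_freq_hz=cardiac.frequency_hz,
    )


def _bin_series(pixels: np.ndarray, lung: np.ndarray, k: int) -> np.ndarray:
    """Replace each lung pixel's series with its k x k block average."""
    T, H, W = pixels.shape
    hk, wk = H - H % k, W - W % k
    blocks = pixels[:, :hk, :wk].reshape(T, hk // k, k, wk // k, k).mean(axis=(2, 4))
    out = np.repeat(np.repeat(blocks, k, axis=1), k, axis=2)
    full = np.array(pixels, np.float64)
    full[:, :hk, :wk] = out
    return full[:, lung]
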