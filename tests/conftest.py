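import numpy as np
import pytest

from dpdr.perfusion import AnatomyMasks, FrameSequence
from dpdr.synth import SynthImagingParams, generate_sequence


@pytest.fixture(scope="session")
def default_params() -> SynthImagingParams:
    return SynthImagingParams.test_scale(rng_seed=7)


@pytest.fixture(scope="session")
def noisy_scene(default_params):
    """One generated test-scale sequence shared by read-only tests."""
    return generate_sequence(default_params)


@pytest.fixture(scope="session")
def clean_scene():
    """Noiseless, drift-free sequence: every signal is exactly as injected."""
    params = SynthImagingParams.test_scale(noise_sd=0.0, resp_amplitude=0.0, rng_seed=7)
    return generate_sequence(params)


def block_scene(vent_series, blocks: dict, fs: float = 15.0, baseline: float = 10.0):
    """Hand-built sequence: a ventricle strip plus labelled lung pixel blocks.

    ``blocks`` maps a label to a (T,) series (one pixel) or (T, n) series
    (n pixels). Lung pixels are laid out row-major and split evenly between
    the two lung masks, so the flattened mask order equals block order.
    Returns (seq, masks, index) with ``index[label]`` the block's positions
    in the flattened lung-pixel order.
    """
    vent_series = np.asarray(vent_series, float)
    T = len(vent_series)
    cols = []
    index = {}
    for label, series in blocks.items():
        s = np.asarray(series, float)
        s = s[:, None] if s.ndim == 1 else s
        assert s.shape[0] == T
        index[label] = np.arange(sum(c.shape[1] for c in cols), sum(c.shape[1] for c in cols) + s.shape[1])
        cols.append(s)
    lung_vals = np.concatenate(cols, axis=1)
    n_lung = lung_vals.shape[1]

    W = 64
    H = int(np.ceil(n_lung / W)) + 3
    pix = np.full((T, H, W), baseline)
    vent = np.zeros((H, W), bool)
    vent[0, :4] = True
    pix[:, vent] = baseline + vent_series[:, None]
    right = np.zeros((H, W), bool)
    left = np.zeros((H, W), bool)
    flat = [(r, c) for r in range(2, H) for c in range(W)][:n_lung]
    for k, (r, c) in enumerate(flat):
        (right if k < n_lung // 2 else left)[r, c] = True
    lung = right | left
    pix[:, lung] = baseline + lung_vals
    masks = AnatomyMasks(right_lung=right, left_lung=left, ventricle_roi=vent)
    seq = FrameSequence(pixels=pix, frame_rate_hz=fs, pixel_spacing_mm=3.3, saturation_level=1e7)
    return seq, masks, index


@pytest.fixture
def make_block_scene():
    return block_scene


def naive_ccv_oracle(x_filtered: np.ndarray, pc_lv: np.ndarray, window: int) -> np.ndarray:
    """Brute-force per-pixel, per-window Pearson correlation against -pc_lv.

    ``x_filtered``: (T, Npix) already high-pass filtered lung series.
    Returns (n_windows, Npix) correlations via np.corrcoef per window.
    """
    T, n = x_filtered.shape
    ref = -np.asarray(pc_lv, float)
    out = np.empty((T - window + 1, n))
    for wi in range(T - window + 1):
        seg_r = ref[wi : wi + window]
        for j in range(n):
            out[wi, j] = np.corrcoef(x_filtered[wi : wi + window, j], seg_r)[0, 1]
    return out
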