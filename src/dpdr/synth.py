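"""Synthetic dynamic chest radiographs and patient cohorts with known truth.

No patient imaging is distributed with this package, so every downstream
stage is exercised against simulated data whose ground truth is known:

* ``generate_sequence`` builds a frame stack in which lung-field pixels
  oscillate at the cardiac frequency in anti-phase with a ventricle ROI
  (amplitude proportional to regional perfusion), optionally with a
  low-frequency respiratory drift and additive Gaussian noise, on the
  acquisition grid of a flat-panel dynamic radiography system
  (1024 x 1024 px, 0.417 mm pixels, 15 frames/s, values saturating near
  58,000).
* ``generate_cohort`` builds surgical-cohort tables whose measured
  postoperative FEV1/DLco follow the perfusion-weighted prediction plus
  relative measurement error, and whose respiratory-complication risk falls
  with ppo%DLco through a logistic model.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.special import expit

from .cohort import PatientRecord
from .flow import BFRResult
from .perfusion import AnatomyMasks, FrameSequence
from .ppo import SEGMENTS, SIDE_TOTALS, TOTAL_SEGMENTS, percent_predicted, ppo_perfusion, resolve_resection

__all__ = [
    "SynthImagingParams",
    "GroundTruth",
    "CohortParams",
    "make_masks",
    "cardiac_waveform",
    "generate_sequence",
    "generate_cohort",
    "generate_screening_table",
]


@dataclass
class SynthImagingParams:
    """Acquisition and signal parameters of the simulator.

    Defaults follow the clinical acquisition (1024 x 1024 matrix, 417 um
    pixels, 15 frames/s over ~10 s breath-hold, saturation near 58,000);
    ``test_scale()`` gives a 128 x 128 grid with the same field of view for
    desk-scale runs. Amplitudes are in raw pixel-value units.
    """

    image_height_px: int = 1024
    image_width_px: int = 1024
    n_frames: int = 150
    frame_rate_hz: float = 15.0
    pixel_spacing_mm: float = 0.417
    cardiac_freq_hz: float = 1.25
    resp_freq_hz: float = 0.2
    resp_amplitude: float = 150.0
    perfusion_amplitude_left: float = 300.0
    perfusion_amplitude_right: float = 300.0
    ventricle_amplitude: float = 600.0
    noise_sd: float = 100.0
    baseline_level: float = 30000.0
    saturation_level: float = 58000.0
    cardiac_waveform: str = "sine"  # "sine" | "fast_upstroke"
    allow_clipping: bool = False
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.frame_rate_hz <= 2 * self.cardiac_freq_hz:
            raise ValueError("frame_rate_hz must exceed twice the cardiac frequency")
        if not self.resp_freq_hz < 0.85 < self.cardiac_freq_hz:
            raise ValueError("need resp_freq_hz < 0.85 Hz < cardiac_freq_hz for the filter to separate them")
        amps = (
            self.resp_amplitude,
            self.perfusion_amplitude_left,
            self.perfusion_amplitude_right,
            self.ventricle_amplitude,
            self.noise_sd,
        )
        if any(a < 0 for a in amps):
            raise ValueError("amplitudes and noise SD must be nonnegative")
        headroom = self.baseline_level + max(
            self.resp_amplitude + max(self.perfusion_amplitude_left, self.perfusion_amplitude_right),
            self.ventricle_amplitude,
        )
        if not self.allow_clipping and headroom > self.saturation_level:
            raise ValueError("baseline + amplitudes exceed saturation (set allow_clipping for clipping tests)")

    @classmethod
    def test_scale(cls, **overrides) -> "SynthImagingParams":
        """128 x 128 grid covering the same field of view as the full matrix."""
        scale = 1024 / 128
        p = cls(image_height_px=128, image_width_px=128, pixel_spacing_mm=0.417 * scale)
        return replace(p, **overrides) if overrides else p


@dataclass
class GroundTruth:
    """What the simulator actually injected, for recovery tests."""

    perfusion_amplitude_map: np.ndarray  # (H, W)
    true_left_fraction: float
    cardiac_freq_hz: float
    waveforms: dict[str, np.ndarray]  # "cardiac" (unit), "ventricle", "respiratory"


def cardiac_waveform(phase: np.ndarray, shape: str = "sine") -> np.ndarray:
    """Unit-amplitude zero-mean periodic heartbeat waveform.

    ``"fast_upstroke"`` adds a second harmonic for a systolic-like sharp rise,
    as a robustness variant; the clinical waveform is not specified anywhere,
    so the default is a plain sinusoid.
    """
    if shape == "sine":
        return np.sin(phase)
    if shape == "fast_upstroke":
        w = np.sin(phase) + 0.4 * np.sin(2 * phase)
        return w / 1.2147  # max|w| over one cycle
    raise ValueError(f"unknown cardiac waveform {shape!r}")


def _rounded_rect(h: int, w: int, r0: float, r1: float, c0: float, c1: float, radius: float) -> np.ndarray:
    """Boolean rounded-rectangle mask from fractional bounds (vectorized SDF)."""
    rows = np.arange(h)[:, None]
    cols = np.arange(w)[None, :]
    cy, cx = (r0 + r1) / 2 * h, (c0 + c1) / 2 * w
    hy, hx = (r1 - r0) / 2 * h - radius, (c1 - c0) / 2 * w - radius
    dy = np.maximum(np.abs(rows - cy) - hy, 0.0)
    dx = np.maximum(np.abs(cols - cx) - hx, 0.0)
    return dy**2 + dx**2 <= radius**2


def make_masks(
    height_px: int, width_px: int, pixel_spacing_mm: float, ventricle_side_mm: float = 25.0
) -> AnatomyMasks:
    """Mirror-symmetric rounded-rectangle lung fields and a medial ventricle ROI.

    Subject's right lung sits at low column indices (viewer's left in a
    posteroanterior view). The ventricle ROI is a square of
    ``ventricle_side_mm`` on a side, placed in the inter-lung gap at cardiac
    height.
    """
    h, w = height_px, width_px
    radius = 0.06 * min(h, w)
    right = _rounded_rect(h, w, 0.12, 0.88, 0.08, 0.42, radius)
    left = right[:, ::-1].copy()  # exact mirror: equal areas by construction
    side = int(round(ventricle_side_mm / pixel_spacing_mm))
    side = max(3, min(side, int(0.14 * w)))  # stay inside the inter-lung gap
    r_lo = int(0.55 * h) - side // 2
    c_lo = w // 2 - side // 2
    vent = np.zeros((h, w), bool)
    vent[r_lo : r_lo + side, c_lo : c_lo + side] = True
    vent &= ~(right | left)
    return AnatomyMasks(right_lung=right, left_lung=left, ventricle_roi=vent)


def generate_sequence(
    params: SynthImagingParams, masks: AnatomyMasks | None = None
) -> tuple[FrameSequence, AnatomyMasks, GroundTruth]:
    """Simulate a dynamic radiograph stack with known perfusion asymmetry.

    Inside the lung fields the pixel value is
    ``baseline - amplitude(x, y) * s_card(t) + resp_amplitude * s_resp(t) + noise``;
    the ventricle ROI carries ``baseline + ventricle_amplitude * s_card(t) +
    noise`` — exactly in anti-phase with the lungs. Values are clipped to
    ``[0, saturation_level]``.
    """
    p = params
    if masks is None:
        masks = make_masks(p.image_height_px, p.image_width_px, p.pixel_spacing_mm)
    shape_hw = (p.image_height_px, p.image_width_px)
    if masks.right_lung.shape != shape_hw:
        raise ValueError(f"mask geometry {masks.right_lung.shape} does not match image {shape_hw}")

    rng = np.random.default_rng(p.rng_seed)
    t = np.arange(p.n_frames) / p.frame_rate_hz
    s_card = cardiac_waveform(2 * np.pi * p.cardiac_freq_hz * t, p.cardiac_waveform)
    s_resp = np.sin(2 * np.pi * p.resp_freq_hz * t)

    amp = np.zeros(shape_hw)
    amp[masks.right_lung] = p.perfusion_amplitude_right
    amp[masks.left_lung] = p.perfusion_amplitude_left

    stack = np.full((p.n_frames,) + shape_hw, p.baseline_level, np.float32)
    lung = masks.lung
    stack[:, lung] = (
        p.baseline_level
        - np.outer(s_card, amp[lung])
        + p.resp_amplitude * s_resp[:, None]
    ).astype(np.float32)
    stack[:, masks.ventricle_roi] = (
        p.baseline_level + p.ventricle_amplitude * s_card[:, None]
    ).astype(np.float32)
    if p.noise_sd > 0:
        stack += rng.standard_normal(stack.shape, np.float32) * np.float32(p.noise_sd)
    np.clip(stack, 0.0, p.saturation_level, out=stack)

    total = amp[lung].sum()
    left_frac = float(amp[masks.left_lung].sum() / total) if total > 0 else 0.5
    truth = GroundTruth(
        perfusion_amplitude_map=amp,
        true_left_fraction=left_frac,
        cardiac_freq_hz=p.cardiac_freq_hz,
        waveforms={
            "cardiac": s_card,
            "ventricle": p.ventricle_amplitude * s_card,
            "respiratory": p.resp_amplitude * s_resp,
        },
    )
    seq = FrameSequence(
        pixels=stack,
        frame_rate_hz=p.frame_rate_hz,
        pixel_spacing_mm=p.pixel_spacing_mm,
        saturation_level=p.saturation_level,
    )
    return seq, masks, truth


# ---------------------------------------------------------------------------
# Cohort simulation

#: resection mix of a lung-cancer surgical series (fractions sum to 1)
_DEFAULT_RESECTION_PROBS = {
    "right_upper": 18 / 52,
    "right_middle": 4 / 52,
    "right_lower": 8 / 52,
    "left_upper": 16 / 52,
    "left_lower": 6 / 52,
}


@dataclass
class CohortParams:
    """Distributional parameters of the synthetic surgical cohort.

    Measured postoperative values are the perfusion-weighted prediction times
    ``(1 + N(0, rel_error_sd))``; respiratory complications follow
    ``logit(p) = intercept + slope * ppo%DLco`` with a negative slope so risk
    falls as predicted diffusing capacity rises.
    """

    n_patients: int = 52
    pred_normal_fev1_mean: float = 2.8  # L
    pred_normal_fev1_sd: float = 0.5
    pred_normal_dlco_mean: float = 18.0
    pred_normal_dlco_sd: float = 3.5
    pre_fev1_fraction_mean: float = 0.82  # pre-op value as fraction of predicted normal
    pre_fev1_fraction_sd: float = 0.12
    pre_dlco_fraction_mean: float = 0.75
    pre_dlco_fraction_sd: float = 0.15
    resection_probs: dict = field(default_factory=lambda: dict(_DEFAULT_RESECTION_PROBS))
    bfr_sd: float = 0.07  # spread of the true affected-side BFR around its segment share
    bfr_noise_sd: float = 0.03  # radiographic BFR measurement noise
    pps_bfr_noise_sd: float = 0.03  # scintigraphy-like comparator noise
    fev1_rel_error_sd: float = 0.10  # spirometry relative measurement error
    dlco_rel_error_sd: float = 0.10
    complication_intercept: float = 2.0
    complication_slope: float = -0.055  # per ppo%DLco point
    cardiovascular_rate: float = 0.115
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.n_patients < 2:
            raise ValueError("n_patients must be >= 2")
        for name in ("bfr_sd", "bfr_noise_sd", "pps_bfr_noise_sd", "fev1_rel_error_sd", "dlco_rel_error_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be nonnegative")
        if abs(sum(self.resection_probs.values()) - 1.0) > 1e-9:
            raise ValueError("resection_probs must sum to 1")


def generate_cohort(params: CohortParams) -> list[PatientRecord]:
    """Simulate one surgical cohort; deterministic under a fixed seed."""
    p = params
    rng = np.random.default_rng(p.rng_seed)
    units = list(p.resection_probs)
    probs = np.array([p.resection_probs[u] for u in units])
    records: list[PatientRecord] = []
    for i in range(p.n_patients):
        resected = units[rng.choice(len(units), p=probs)]
        n_res, side = resolve_resection(resected)
        age = float(np.clip(rng.normal(71.7, 7.6), 53, 83))
        sex = "M" if rng.random() < 40 / 52 else "F"
        height = float(rng.normal(168, 8) if sex == "M" else rng.normal(155, 7))

        pn_fev1 = float(np.clip(rng.normal(p.pred_normal_fev1_mean, p.pred_normal_fev1_sd), 1.5, None))
        pn_dlco = float(np.clip(rng.normal(p.pred_normal_dlco_mean, p.pred_normal_dlco_sd), 8.0, None))
        pre_fev1 = pn_fev1 * float(np.clip(rng.normal(p.pre_fev1_fraction_mean, p.pre_fev1_fraction_sd), 0.4, 1.2))
        pre_dlco = pn_dlco * float(np.clip(rng.normal(p.pre_dlco_fraction_mean, p.pre_dlco_fraction_sd), 0.3, 1.2))

        # true affected-side BFR: centred slightly below the side's segment
        # share of 19 (tumour-bearing lungs are hypoperfused on average)
        share = SIDE_TOTALS[side] / TOTAL_SEGMENTS
        true_bfr = float(np.clip(rng.normal(share - 0.05, p.bfr_sd), 0.10, 0.90))
        bfr_true = BFRResult(affected_side=side, bfr_affected=true_bfr, bfr_intact=1 - true_bfr)
        dpdr_bfr = float(np.clip(true_bfr + rng.normal(0, p.bfr_noise_sd), 0.0, 1.0))
        pps_bfr = float(np.clip(true_bfr + rng.normal(0, p.pps_bfr_noise_sd), 0.0, 1.0))

        pred_fev1 = ppo_perfusion(pre_fev1, bfr_true, resected)
        pred_dlco = ppo_perfusion(pre_dlco, bfr_true, resected)

        def measured(pred: float, rel_sd: float) -> float:
            return float(max(pred * (1.0 + rng.normal(0, rel_sd)), 0.0))

        ppo_pct_dlco = percent_predicted(pred_dlco, pn_dlco)
        p_resp = float(expit(p.complication_intercept + p.complication_slope * ppo_pct_dlco))

        records.append(
            PatientRecord(
                id=f"P{i + 1:03d}",
                age=age,
                sex=sex,
                height_cm=height,
                affected_side=side,
                resected_units=resected,
                pre_fev1=pre_fev1,
                pre_dlco=pre_dlco,
                predicted_normal_fev1=pn_fev1,
                predicted_normal_dlco=pn_dlco,
                true_bfr_affected=true_bfr,
                dpdr_bfr_affected=dpdr_bfr,
                pps_bfr_affected=pps_bfr,
                measured_fev1_m1=measured(pred_fev1, p.fev1_rel_error_sd),
                measured_fev1_m3=measured(pred_fev1, p.fev1_rel_error_sd),
                measured_dlco_m1=measured(pred_dlco, p.dlco_rel_error_sd),
                measured_dlco_m3=measured(pred_dlco, p.dlco_rel_error_sd),
                complication_respiratory=bool(rng.random() < p_resp),
                complication_cardiovascular=bool(rng.random() < p.cardiovascular_rate),
            )
        )
    return records


def generate_screening_table(
    n_followed: int = 57, rng_seed: int = 0
) -> "pd.DataFrame":
    """Enrollment fixture: ``n_followed`` screened patients, five excludable.

    Contains two patients with a disease other than primary lung cancer, one
    wedge resection, one lost to follow-up and one consent withdrawal; the
    rest are eligible anatomic resections.
    """
    import pandas as pd

    if n_followed < 6:
        raise ValueError("need at least 6 screened patients for the five exclusion rows")
    rng = np.random.default_rng(rng_seed)
    rows = []
    for i in range(n_followed):
        rows.append(
            {
                "patient_id": f"S{i + 1:03d}",
                "age": float(np.clip(rng.normal(71.7, 7.6), 53, 83)),
                "diagnosis": "primary_lung_cancer",
                "procedure": "lobectomy",
                "prior_thoracic_surgery": False,
                "lost_to_followup": False,
                "consent_withdrawn": False,
            }
        )
    drop = rng.choice(n_followed, size=5, replace=False)
    rows[drop[0]]["diagnosis"] = "metastatic_tumor"
    rows[drop[1]]["diagnosis"] = "benign_nodule"
    rows[drop[2]]["procedure"] = "wedge_resection"
    rows[drop[3]]["lost_to_followup"] = True
    rows[drop[4]]["consent_withdrawn"] = True
    return pd.DataFrame(rows)
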