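"""Left/right blood-flow ratio (BFR) from a MaxCCv perfusion map.

The per-pixel MaxCCv values are summed over each lung field; the BFR of the
surgically affected side is that side's share of the two sums:

    BFR_left  = SumMaxCCv_left  / (SumMaxCCv_right + SumMaxCCv_left)
    BFR_right = SumMaxCCv_right / (SumMaxCCv_right + SumMaxCCv_left)
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .perfusion import AnatomyMasks, PerfusionMap

__all__ = ["LungFieldSums", "BFRResult", "sum_max_ccv", "blood_flow_ratio"]


@dataclass
class LungFieldSums:
    sum_max_ccv_left: float
    sum_max_ccv_right: float
    n_pixels_left: int
    n_pixels_right: int


@dataclass
class BFRResult:
    affected_side: str  # "left" | "right"
    bfr_affected: float
    bfr_intact: float

    def __post_init__(self) -> None:
        if self.affected_side not in ("left", "right"):
            raise ValueError(f"affected_side must be 'left' or 'right', got {self.affected_side!r}")


def sum_max_ccv(
    pmap: PerfusionMap, masks: AnatomyMasks, clip_negative: bool = False
) -> LungFieldSums:
    """Per-side sums of defined MaxCCv values.

    Undefined (NaN) pixels contribute nothing and are excluded from the
    counts. Negative MaxCCv values (possible in pure-noise pixels) are kept
    as-is by default; ``clip_negative`` floors them at zero.
    """
    if not masks.right_lung.any() or not masks.left_lung.any():
        raise ValueError("both lung masks must be nonempty")
    if pmap.max_ccv.shape != masks.right_lung.shape:
        raise ValueError("map geometry does not match the masks")

    def side(mask: np.ndarray) -> tuple[float, int]:
        vals = pmap.max_ccv[mask]
        vals = vals[~np.isnan(vals)]
        if clip_negative:
            vals = np.clip(vals, 0.0, None)
        return float(vals.sum()), int(vals.size)

    s_left, n_left = side(masks.left_lung)
    s_right, n_right = side(masks.right_lung)
    return LungFieldSums(
        sum_max_ccv_left=s_left,
        sum_max_ccv_right=s_right,
        n_pixels_left=n_left,
        n_pixels_right=n_right,
    )


def blood_flow_ratio(sums: LungFieldSums, affected_side: str) -> BFRResult:
    """Affected-side blood-flow ratio; the two ratios share one denominator."""
    total = sums.sum_max_ccv_left + sums.sum_max_ccv_right
    if total <= 0:
        raise ValueError("no perfusion signal: summed MaxCCv is not positive")
    bfr_left = sums.sum_max_ccv_left / total
    if affected_side == "left":
        affected = bfr_left
    elif affected_side == "right":
        affected = 1.0 - bfr_left
    else:
        raise ValueError(f"affected_side must be 'left' or 'right', got {affected_side!r}")
    return BFRResult(affected_side=affected_side, bfr_affected=affected, bfr_intact=1.0 - affected)
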