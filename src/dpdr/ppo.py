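"""Predicted postoperative (ppo) lung function after anatomic lung resection.

Two predictors for a preoperative value (FEV1 in litres, or DLco):

* segment counting —   ppo = pre x (19 - resected segments) / 19
* perfusion-weighted — ppo = pre x (BFR_intact + remaining/total_affected x BFR_affected)

using the conventional 19-segment model of the lung: right upper 3, right
middle 2, right lower 5 (right total 10); left upper division 3, lingula 2,
left lower 4 (left total 9). When the affected side's BFR equals its segment
share of 19, the two predictors coincide.

Percent-predicted values (100 x value / predicted-normal) are banded into the
surgical risk strata used for complication screening: ppo%FEV1 <40 / 40-70 /
>=70 and ppo%DLco <40 / 40-60 / >=60, thresholds belonging to the upper band.
"""

from __future__ import annotations

from dataclasses import dataclass

from .flow import BFRResult

__all__ = [
    "SEGMENTS",
    "SIDE_OF_UNIT",
    "SIDE_TOTALS",
    "TOTAL_SEGMENTS",
    "PpoResult",
    "resolve_resection",
    "ppo_segment_counting",
    "ppo_perfusion",
    "percent_predicted",
    "risk_band",
]

#: bronchopulmonary segments per resection unit
SEGMENTS: dict[str, int] = {
    "right_upper": 3,
    "right_middle": 2,
    "right_lower": 5,
    "left_upper_division": 3,
    "lingula": 2,
    "left_lower": 4,
}
SIDE_OF_UNIT: dict[str, str] = {
    "right_upper": "right",
    "right_middle": "right",
    "right_lower": "right",
    "left_upper_division": "left",
    "lingula": "left",
    "left_lower": "left",
}
#: composite units accepted for convenience (left upper lobectomy = division + lingula)
_COMPOSITE: dict[str, list[str]] = {"left_upper": ["left_upper_division", "lingula"]}
SIDE_TOTALS: dict[str, int] = {"right": 10, "left": 9}
TOTAL_SEGMENTS = 19


@dataclass
class PpoResult:
    ppo_fev1_segment: float
    ppo_fev1_perfusion: float | None
    ppo_dlco_perfusion: float | None
    ppo_pct_fev1: float | None
    ppo_pct_dlco: float | None
    fev1_band: str | None
    dlco_band: str | None


def resolve_resection(
    resected_units: list[str] | str | int, affected_side: str | None = None
) -> tuple[int, str | None]:
    """Number of resected segments and the side they lie on.

    ``resected_units`` may be unit names (``"right_upper"``, the composite
    ``"left_upper"``, a ``+``-joined string), or an explicit segment count for
    segmentectomies — in which case ``affected_side`` says where they were.
    Mixed-side unit lists are rejected (a unilateral resection is assumed).
    """
    if isinstance(resected_units, (int,)):
        n = int(resected_units)
        if n < 0:
            raise ValueError("segment count must be nonnegative")
        return n, affected_side
    if isinstance(resected_units, str):
        resected_units = [u for u in resected_units.split("+") if u]
    units: list[str] = []
    for u in resected_units:
        u = u.strip().lower()
        units.extend(_COMPOSITE.get(u, [u]))
    unknown = [u for u in units if u not in SEGMENTS]
    if unknown:
        valid = sorted(SEGMENTS) + sorted(_COMPOSITE)
        raise ValueError(f"unknown resection unit(s) {unknown}; valid units: {valid}")
    if len(set(units)) != len(units):
        raise ValueError("duplicate resection units")
    sides = {SIDE_OF_UNIT[u] for u in units}
    if len(sides) > 1:
        raise ValueError("resection units span both sides")
    side = sides.pop() if sides else affected_side
    if affected_side is not None and side is not None and side != affected_side:
        raise ValueError(f"resected units lie on the {side} side, not the affected {affected_side}")
    return sum(SEGMENTS[u] for u in units), side


def ppo_segment_counting(
    pre_value: float,
    resected_units: list[str] | str | int,
    affected_side: str | None = None,
    allow_zero: bool = False,
) -> float:
    """Segment-counting prediction: pre x (remaining segments) / 19."""
    n, _ = resolve_resection(resected_units, affected_side)
    if n == 0 and not allow_zero:
        raise ValueError("no segments resected (pass allow_zero=True for the identity case)")
    if not 0 <= n < TOTAL_SEGMENTS:
        raise ValueError(f"resected segment count {n} outside [0, {TOTAL_SEGMENTS})")
    return pre_value * (TOTAL_SEGMENTS - n) / TOTAL_SEGMENTS


def ppo_perfusion(
    pre_value: float,
    bfr: BFRResult,
    resected_units: list[str] | str | int,
    affected_side: str | None = None,
) -> float:
    """Perfusion-weighted prediction using the affected-side blood-flow ratio.

    The intact lung keeps its full perfusion share; the affected lung keeps
    the fraction of its share proportional to its remaining segments.
    """
    side = affected_side or bfr.affected_side
    n, unit_side = resolve_resection(resected_units, side)
    if unit_side is not None and unit_side != bfr.affected_side:
        raise ValueError(
            f"resected units on the {unit_side} side but BFR is for the {bfr.affected_side} side"
        )
    total = SIDE_TOTALS[bfr.affected_side]
    if not 0 <= n <= total:
        raise ValueError(f"resected segment count {n} outside [0, {total}] for the {bfr.affected_side} side")
    remaining = total - n
    return pre_value * (bfr.bfr_intact + (remaining / total) * bfr.bfr_affected)


def percent_predicted(absolute_value: float, predicted_normal_value: float) -> float:
    """Value as a percentage of the patient's predicted-normal value.

    No spirometric reference equation is bundled: the predicted-normal value
    is an input, computed upstream by whichever age/height/sex reference the
    cohort uses.
    """
    if predicted_normal_value <= 0:
        raise ValueError("predicted-normal value must be positive")
    return 100.0 * absolute_value / predicted_normal_value


def risk_band(ppo_pct_fev1: float, ppo_pct_dlco: float) -> tuple[str, str]:
    """Risk strata for ppo%FEV1 and ppo%DLco; thresholds join the upper band."""
    if ppo_pct_fev1 < 0 or ppo_pct_dlco < 0:
        raise ValueError("percent-predicted values must be nonnegative")
    if ppo_pct_fev1 < 40:
        fev1_band = "<40"
    elif ppo_pct_fev1 < 70:
        fev1_band = "40-70"
    else:
        fev1_band = ">=70"
    if ppo_pct_dlco < 40:
        dlco_band = "<40"
    elif ppo_pct_dlco < 60:
        dlco_band = "40-60"
    else:
        dlco_band = ">=60"
    return fev1_band, dlco_band
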