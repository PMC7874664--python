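"""Patient cohort records, CSV schema, and enrollment screening.

One row per patient: preoperative lung function (FEV1 in litres, DLco),
predicted-normal reference values, the resection performed, observed
blood-flow ratios from dynamic radiography and from the scintigraphy-like
comparator, measured postoperative values at months 1 and 3, and
complication flags.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict, fields

import numpy as np
import pandas as pd

__all__ = ["PatientRecord", "COHORT_COLUMNS", "cohort_to_frame", "frame_to_cohort",
           "read_cohort_csv", "write_cohort_csv", "screen_enrollment", "EXCLUSION_REASONS"]


@dataclass
class PatientRecord:
    id: str
    age: float
    sex: str  # "M" | "F"
    height_cm: float
    affected_side: str  # "left" | "right"
    resected_units: str  # unit names joined with '+', or "segments:<n>"
    pre_fev1: float  # L
    pre_dlco: float
    predicted_normal_fev1: float  # L
    predicted_normal_dlco: float
    true_bfr_affected: float | None = None  # simulation ground truth only
    dpdr_bfr_affected: float | None = None
    pps_bfr_affected: float | None = None
    measured_fev1_m1: float | None = None
    measured_fev1_m3: float | None = None
    measured_dlco_m1: float | None = None
    measured_dlco_m3: float | None = None
    complication_respiratory: bool = False
    complication_cardiovascular: bool = False

    def resection(self) -> "list[str] | int":
        """Resected units in the form the ppo operations accept."""
        if self.resected_units.startswith("segments:"):
            return int(self.resected_units.split(":", 1)[1])
        return self.resected_units.split("+")


COHORT_COLUMNS = [f.name for f in fields(PatientRecord)]


def cohort_to_frame(records: list[PatientRecord]) -> pd.DataFrame:
    return pd.DataFrame([asdict(r) for r in records], columns=COHORT_COLUMNS)


def frame_to_cohort(df: pd.DataFrame) -> list[PatientRecord]:
    recs = []
    for row in df.to_dict(orient="records"):
        row = {k: (None if (isinstance(v, float) and np.isnan(v)) else v) for k, v in row.items()}
        row["complication_respiratory"] = bool(row["complication_respiratory"])
        row["complication_cardiovascular"] = bool(row["complication_cardiovascular"])
        recs.append(PatientRecord(**{k: row[k] for k in COHORT_COLUMNS}))
    return recs


def write_cohort_csv(path, records_or_frame) -> None:
    """UTF-8, comma-separated, header row, '.' decimal; byte-stable per seed."""
    df = records_or_frame
    if not isinstance(df, pd.DataFrame):
        df = cohort_to_frame(df)
    df.to_csv(path, index=False, float_format="%.6g", lineterminator="\n")


def read_cohort_csv(path) -> pd.DataFrame:
    return pd.read_csv(path)


# ---------------------------------------------------------------------------
# Enrollment screening

#: exclusion rules applied in order; the first matching rule claims the patient
EXCLUSION_REASONS = [
    ("prior_thoracic_surgery", "history of thoracic surgery"),
    ("under_20", "younger than 20 years"),
    ("other_disease", "disease other than primary lung cancer"),
    ("wedge_resection", "wedge resection (non-anatomic)"),
    ("lost_to_followup", "lost to follow-up"),
    ("consent_withdrawn", "informed consent withdrawn before the postoperative period"),
]


def screen_enrollment(df: pd.DataFrame) -> tuple[pd.DataFrame, dict[str, int]]:
    """Apply the enrollment filters to a screening table.

    Expects columns ``age``, ``diagnosis`` (``"primary_lung_cancer"`` or
    other), ``procedure`` (``"wedge_resection"`` flags a non-anatomic
    resection), and boolean ``prior_thoracic_surgery``, ``lost_to_followup``,
    ``consent_withdrawn``. Returns the analyzed subset and per-reason
    exclusion counts.
    """
    reasons = {
        "prior_thoracic_surgery": df["prior_thoracic_surgery"].astype(bool),
        "under_20": df["age"] < 20,
        "other_disease": df["diagnosis"] != "primary_lung_cancer",
        "wedge_resection": df["procedure"] == "wedge_resection",
        "lost_to_followup": df["lost_to_followup"].astype(bool),
        "consent_withdrawn": df["consent_withdrawn"].astype(bool),
    }
    excluded = pd.Series(False, index=df.index)
    counts: dict[str, int] = {}
    for key, _label in EXCLUSION_REASONS:
        hit = reasons[key] & ~excluded
        counts[key] = int(hit.sum())
        excluded |= hit
    return df[~excluded].reset_index(drop=True), counts
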