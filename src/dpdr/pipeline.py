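"""Pipeline orchestration: configuration, staged execution, cohort analytics.

Ties the stages together: simulate -> perfusion map -> blood-flow ratio ->
postoperative prediction -> agreement statistics, with a validated run
configuration, a manifest recording input hashes, and deterministic outputs
under a fixed seed.
"""

from __future__ import annotations

from dataclasses import asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as dio
from .cohort import write_cohort_csv, cohort_to_frame
from .flow import BFRResult, blood_flow_ratio, sum_max_ccv
from .perfusion import compute_ccv, extract_ventricle_signal
from .ppo import percent_predicted, ppo_perfusion, ppo_segment_counting, risk_band
from .stats import bland_altman, complication_rates, pearson_regression, unpaired_t_test
from .synth import CohortParams, SynthImagingParams, generate_cohort, generate_sequence

__all__ = ["RunConfig", "compute_ppo_table", "cohort_report", "run_pipeline", "PIPELINE_STAGES"]

PIPELINE_STAGES = ["simulate", "perfmap", "bfr", "ppo", "agree"]

#: scale factor applied to blood-flow ratios before agreement statistics, so
#: differences are reported in percentage points
BFR_PERCENT_SCALE = 100.0

try:  # pydantic v2 configuration model
    from pydantic import BaseModel, Field, model_validator

    class RunConfig(BaseModel):
        """Validated run configuration; serialized alongside every run."""

        out_dir: str
        stages: list[str] = Field(default_factory=lambda: list(PIPELINE_STAGES))
        imaging: dict = Field(default_factory=dict)  # SynthImagingParams overrides
        cohort: dict = Field(default_factory=dict)  # CohortParams overrides
        cutoff_hz: float = 0.85
        window_frames: int | None = None
        spatial_bin: int = 1
        clip_negative: bool = False
        affected_side: str = "left"
        seed: int = 0

        @model_validator(mode="after")
        def _check(self):
            unknown = [s for s in self.stages if s not in PIPELINE_STAGES]
            if unknown:
                raise ValueError(f"unknown stages {unknown}; valid: {PIPELINE_STAGES}")
            idx = [PIPELINE_STAGES.index(s) for s in self.stages]
            if idx != sorted(idx) or idx != list(range(idx[0], idx[0] + len(idx))):
                raise ValueError("stages must be a contiguous, ordered subset of the pipeline")
            if self.affected_side not in ("left", "right"):
                raise ValueError("affected_side must be 'left' or 'right'")
            frame_rate = float(self.imaging.get("frame_rate_hz", 15.0))
            if not 0 < self.cutoff_hz < frame_rate / 2:
                raise ValueError(
                    f"cutoff_hz={self.cutoff_hz} outside (0, Nyquist={frame_rate / 2})"
                )
            if self.spatial_bin < 1:
                raise ValueError("spatial_bin must be >= 1")
            return self

except ImportError:  # pragma: no cover - pydantic is a hard dependency
    raise


def compute_ppo_table(df: pd.DataFrame, method: str = "both") -> pd.DataFrame:
    """Add predicted-postoperative columns to a cohort table.

    Segment-counting predictions always use the 19-segment model; perfusion
    predictions are added per available BFR source column
    (``dpdr_bfr_affected``, ``pps_bfr_affected``).
    """
    if method not in ("segment", "perfusion", "both"):
        raise ValueError("method must be 'segment', 'perfusion' or 'both'")
    out = df.copy()

    def resection_of(row) -> "int | str":
        ru = row.resected_units
        if isinstance(ru, str) and ru.startswith("segments:"):
            return int(ru.split(":", 1)[1])
        return ru

    if method in ("segment", "both"):
        out["ppo_fev1_segment"] = [
            ppo_segment_counting(r.pre_fev1, resection_of(r), r.affected_side)
            for r in df.itertuples()
        ]
        out["ppo_dlco_segment"] = [
            ppo_segment_counting(r.pre_dlco, resection_of(r), r.affected_side)
            for r in df.itertuples()
        ]
    if method in ("perfusion", "both"):
        for src in ("dpdr", "pps"):
            col = f"{src}_bfr_affected"
            if col not in df or df[col].isna().all():
                continue
            fev1, dlco, pf, pdl, fb, db = [], [], [], [], [], []
            for r in df.itertuples():
                b = getattr(r, col)
                if b is None or (isinstance(b, float) and np.isnan(b)):
                    fev1.append(np.nan); dlco.append(np.nan); pf.append(np.nan)
                    pdl.append(np.nan); fb.append(None); db.append(None)
                    continue
                bfr = BFRResult(affected_side=r.affected_side, bfr_affected=float(b), bfr_intact=1 - float(b))
                res = resection_of(r)
                v_fev1 = ppo_perfusion(r.pre_fev1, bfr, res, r.affected_side)
                v_dlco = ppo_perfusion(r.pre_dlco, bfr, res, r.affected_side)
                pct_f = percent_predicted(v_fev1, r.predicted_normal_fev1)
                pct_d = percent_predicted(v_dlco, r.predicted_normal_dlco)
                band_f, band_d = risk_band(pct_f, pct_d)
                fev1.append(v_fev1); dlco.append(v_dlco); pf.append(pct_f)
                pdl.append(pct_d); fb.append(band_f); db.append(band_d)
            out[f"ppo_fev1_{src}"] = fev1
            out[f"ppo_dlco_{src}"] = dlco
            out[f"ppo_pct_fev1_{src}"] = pf
            out[f"ppo_pct_dlco_{src}"] = pdl
            out[f"fev1_band_{src}"] = fb
            out[f"dlco_band_{src}"] = db
    return out


def cohort_report(ppo_df: pd.DataFrame) -> dict:
    """Study-style statistics on a PPO-annotated cohort table.

    Blood-flow ratios enter the agreement analysis in percent so that
    Bland-Altman differences read in percentage points.
    """
    report: dict = {"n": int(len(ppo_df))}
    if {"dpdr_bfr_affected", "pps_bfr_affected"} <= set(ppo_df.columns):
        sub = ppo_df.dropna(subset=["dpdr_bfr_affected", "pps_bfr_affected"])
        if len(sub) >= 3:
            report["bfr_agreement"] = bland_altman(
                BFR_PERCENT_SCALE * sub["dpdr_bfr_affected"].to_numpy(),
                BFR_PERCENT_SCALE * sub["pps_bfr_affected"].to_numpy(),
            ).to_dict()

    regs = {}
    for pred, meas in [
        ("ppo_fev1_dpdr", "measured_fev1_m1"),
        ("ppo_fev1_dpdr", "measured_fev1_m3"),
        ("ppo_dlco_dpdr", "measured_dlco_m1"),
        ("ppo_dlco_dpdr", "measured_dlco_m3"),
    ]:
        if pred in ppo_df and meas in ppo_df:
            sub = ppo_df.dropna(subset=[pred, meas])
            if len(sub) >= 3:
                r = pearson_regression(sub[pred].to_numpy(), sub[meas].to_numpy())
                regs[f"{pred}__vs__{meas}"] = asdict(r)
    if regs:
        report["prediction_vs_measured"] = regs

    if "complication_respiratory" in ppo_df:
        ttests = {}
        for col in ("ppo_pct_fev1_dpdr", "ppo_pct_dlco_dpdr"):
            if col not in ppo_df:
                continue
            for flag in ("complication_respiratory", "complication_cardiovascular"):
                if flag not in ppo_df:
                    continue
                g1 = ppo_df.loc[ppo_df[flag].astype(bool), col].dropna().to_numpy()
                g0 = ppo_df.loc[~ppo_df[flag].astype(bool), col].dropna().to_numpy()
                if len(g1) >= 2 and len(g0) >= 2:
                    t, p = unpaired_t_test(g1, g0)
                    ttests[f"{col}__by__{flag}"] = {"t": t, "p": p}
        if ttests:
            report["t_tests"] = ttests

        df = ppo_df.copy()
        any_comp = df["complication_respiratory"].astype(bool)
        if "complication_cardiovascular" in df:
            any_comp = any_comp | df["complication_cardiovascular"].astype(bool)
        df["complication_any"] = any_comp
        rates = {}
        if "dlco_band_dpdr" in df:
            rt = complication_rates(df, "dlco_band_dpdr", "complication_any", ["<40", "40-60", ">=60"])
            rates["by_dlco_band"] = {
                "bands": {k: {"n": v[0], "events": v[1], "rate_pct": v[2]} for k, v in rt.bands.items()},
                "overall": {"n": rt.overall_n, "events": rt.overall_events, "rate_pct": rt.overall_rate_pct},
            }
        if "fev1_band_dpdr" in df:
            rt = complication_rates(df, "fev1_band_dpdr", "complication_any", ["<40", "40-70", ">=70"])
            rates["by_fev1_band"] = {
                "bands": {k: {"n": v[0], "events": v[1], "rate_pct": v[2]} for k, v in rt.bands.items()},
                "overall": {"n": rt.overall_n, "events": rt.overall_events, "rate_pct": rt.overall_rate_pct},
            }
        if rates:
            report["complication_rates"] = rates
    return report


def run_pipeline(config: RunConfig) -> dict:
    """Execute the configured stages, writing artifacts and a manifest.

    Returns the manifest. On failure, partially written artifacts of this run
    are removed before the exception propagates.
    """
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    created: list[Path] = []
    artifacts: dict[str, str] = {}

    def emit(name: str, path: Path, writer) -> None:
        writer(path)
        created.append(path)
        artifacts[name] = path.name

    try:
        imaging = SynthImagingParams.test_scale(**{"rng_seed": config.seed, **config.imaging})
        seq = masks = pmap = bfr = None
        if "simulate" in config.stages:
            seq, masks, truth = generate_sequence(imaging)
            emit("sequence", out_dir / "seq.tif", lambda p: dio.write_sequence(
                p, seq, extra={"rng_seed": imaging.rng_seed,
                               "true_left_fraction": truth.true_left_fraction,
                               "cardiac_freq_hz": truth.cardiac_freq_hz}))
            created.append(out_dir / "seq.tif.json")
            emit("masks", out_dir / "masks.tif", lambda p: dio.write_masks(p, masks))
        if "perfmap" in config.stages:
            if seq is None:
                seq = dio.read_sequence(out_dir / "seq.tif")
                masks = dio.read_masks(out_dir / "masks.tif")
            cardiac = extract_ventricle_signal(seq, masks, cutoff_hz=config.cutoff_hz)
            pmap = compute_ccv(seq, cardiac, masks, window_frames=config.window_frames,
                               cutoff_hz=config.cutoff_hz, spatial_bin=config.spatial_bin)
            emit("max_ccv", out_dir / "max_ccv.tif", lambda p: dio.write_max_ccv(p, pmap))
            emit("perfmap_report", out_dir / "perfmap_report.json", lambda p: dio.write_json(p, {
                "window_frames": int(pmap.window_frames),
                "cardiac_freq_hz": pmap.cardiac_freq_hz,
                "estimated_period_frames": int(cardiac.estimated_period_frames),
                "n_valid_frames": int(len(pmap.valid_frames)),
                "n_undefined_pixels": pmap.n_undefined_pixels,
            }))
        if "bfr" in config.stages:
            if pmap is None:
                masks = dio.read_masks(out_dir / "masks.tif")
                max_ccv = dio.read_max_ccv(out_dir / "max_ccv.tif")
                from .perfusion import PerfusionMap
                pmap = PerfusionMap(ccv=max_ccv[None], defined=~np.isnan(max_ccv)[None],
                                    max_ccv=max_ccv, valid_frames=np.array([0]),
                                    window_frames=0, cardiac_freq_hz=float("nan"))
            sums = sum_max_ccv(pmap, masks, clip_negative=config.clip_negative)
            bfr = blood_flow_ratio(sums, config.affected_side)
            emit("bfr", out_dir / "bfr.json", lambda p: dio.write_json(p, {
                "sum_max_ccv_left": sums.sum_max_ccv_left,
                "sum_max_ccv_right": sums.sum_max_ccv_right,
                "n_pixels_left": sums.n_pixels_left,
                "n_pixels_right": sums.n_pixels_right,
                "affected_side": bfr.affected_side,
                "bfr_affected": bfr.bfr_affected,
                "bfr_intact": bfr.bfr_intact,
            }))
        ppo_df = None
        if "ppo" in config.stages:
            cohort = generate_cohort(CohortParams(**{"rng_seed": config.seed, **config.cohort}))
            df = cohort_to_frame(cohort)
            emit("cohort", out_dir / "cohort.csv", lambda p: write_cohort_csv(p, df))
            ppo_df = compute_ppo_table(df, method="both")
            emit("ppo", out_dir / "ppo.csv", lambda p: write_cohort_csv(p, ppo_df))
        if "agree" in config.stages:
            if ppo_df is None:
                ppo_df = pd.read_csv(out_dir / "ppo.csv")
            emit("agreement", out_dir / "agreement.json",
                 lambda p: dio.write_json(p, cohort_report(ppo_df)))

        manifest = {
            "config": config.model_dump(),
            "artifacts": {
                name: {"path": fname, "sha256": dio.sha256_of(out_dir / fname)}
                for name, fname in artifacts.items()
            },
        }
        dio.write_json(out_dir / "manifest.json", manifest)
        return manifest
    except Exception:
        for p in created:
            p.unlink(missing_ok=True)
        raise
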