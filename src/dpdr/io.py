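"""Readers and writers for the pipeline's on-disk artifacts.

Frame sequences travel as multi-frame 16-bit TIFF with a JSON sidecar
(acquisition metadata, seed, ground-truth summary); masks as an 8-bit label
TIFF (0 background, 1 right lung, 2 left lung, 3 ventricle ROI); MaxCCv maps
as 32-bit float TIFF; tables as UTF-8 comma-separated CSV.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import tifffile

from .perfusion import AnatomyMasks, FrameSequence, PerfusionMap

__all__ = [
    "write_sequence",
    "read_sequence",
    "write_masks",
    "read_masks",
    "write_max_ccv",
    "read_max_ccv",
    "write_ccv_stack",
    "write_json",
    "read_json",
    "sha256_of",
]


def write_json(path, obj) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")


def read_json(path):
    return json.loads(Path(path).read_text())


def sha256_of(path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()


def _sidecar_path(tiff_path) -> Path:
    p = Path(tiff_path)
    return p.with_suffix(p.suffix + ".json")


def write_sequence(path, seq: FrameSequence, extra: dict | None = None) -> None:
    """Write frames as uint16 multi-frame TIFF plus a JSON metadata sidecar."""
    pixels = np.clip(np.rint(seq.pixels), 0, 65535).astype(np.uint16)
    tifffile.imwrite(path, pixels)
    meta = {
        "frame_rate_hz": seq.frame_rate_hz,
        "pixel_spacing_mm": seq.pixel_spacing_mm,
        "saturation_level": seq.saturation_level,
        "n_frames": int(seq.n_frames),
    }
    if extra:
        meta.update(extra)
    write_json(_sidecar_path(path), meta)


def read_sequence(path) -> FrameSequence:
    pixels = tifffile.imread(path).astype(np.float32)
    meta = read_json(_sidecar_path(path))
    return FrameSequence(
        pixels=pixels,
        frame_rate_hz=float(meta["frame_rate_hz"]),
        pixel_spacing_mm=float(meta["pixel_spacing_mm"]),
        saturation_level=float(meta["saturation_level"]),
    )


def write_masks(path, masks: AnatomyMasks) -> None:
    tifffile.imwrite(path, masks.to_labels())


def read_masks(path) -> AnatomyMasks:
    return AnatomyMasks.from_labels(tifffile.imread(path))


def write_max_ccv(path, pmap: PerfusionMap) -> None:
    tifffile.imwrite(path, pmap.max_ccv.astype(np.float32))


def read_max_ccv(path) -> np.ndarray:
    return tifffile.imread(path).astype(np.float32)


def write_ccv_stack(path, pmap: PerfusionMap) -> None:
    """Optional (large) full CCv stack export."""
    tifffile.imwrite(path, pmap.ccv.astype(np.float32))
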