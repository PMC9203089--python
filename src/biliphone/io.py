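"""Dataset layout: patients.csv + per-patient TIFF capture directories.

Layout consumed and produced by the CLI:

    dataset/
      patients.csv            # patient_id, tsb_mg_dl, site, skin_group, ...
      ground_truth.json       # present for synthetic cohorts only
      p000/
        meta.json             # mosaic, exposure_ms, iso
        tissue_on_1.tif ... tissue_off_3.tif
        cal_on_1.tif ... cal_off_3.tif

Calibrated outputs are 32-bit float TIFFs with an 8-bit mask TIFF and a
JSON sidecar (scale, origin, provenance).
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .capture import CalibratedReflectanceImage, CaptureSet, Mosaic, RawFrame
from .exceptions import InsufficientDataError

_LISTS = ("tissue_on", "tissue_off", "cal_on", "cal_off")


def save_capture_set(directory: str | Path, capture: CaptureSet) -> None:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    first = capture.tissue_on[0]
    meta = {
        "mosaic": first.mosaic.value,
        "exposure_ms": first.exposure_ms,
        "iso": first.iso,
    }
    (directory / "meta.json").write_text(json.dumps(meta, indent=2, sort_keys=True))
    for name in _LISTS:
        for i, frame in enumerate(getattr(capture, name), start=1):
            px = frame.pixels
            if np.issubdtype(px.dtype, np.floating) and np.allclose(px, np.round(px)):
                px = px.astype(np.uint16)
            elif np.issubdtype(px.dtype, np.floating):
                px = px.astype(np.float32)
            else:
                px = px.astype(np.uint16)
            kwargs = {"photometric": "rgb"} if px.ndim == 3 else {}
            tifffile.imwrite(directory / f"{name}_{i}.tif", px, **kwargs)


def load_capture_set(directory: str | Path, patient_id: str = "") -> CaptureSet:
    directory = Path(directory)
    meta = json.loads((directory / "meta.json").read_text())
    mosaic = Mosaic(meta["mosaic"])
    lists: dict[str, list[RawFrame]] = {}
    for name in _LISTS:
        frames = []
        for path in sorted(directory.glob(f"{name}_*.tif")):
            frames.append(
                RawFrame(
                    pixels=tifffile.imread(path),
                    mosaic=mosaic,
                    exposure_ms=meta.get("exposure_ms", 400.0),
                    iso=meta.get("iso", 4500),
                    flash=name.endswith("_on"),
                )
            )
        if not frames:
            raise InsufficientDataError(f"no {name} frames in {directory}")
        lists[name] = frames
    return CaptureSet(patient_id=patient_id or directory.name, **lists)


def load_dataset(root: str | Path) -> tuple[pd.DataFrame, dict[str, CaptureSet]]:
    """Load patients.csv and every per-patient capture directory."""
    root = Path(root)
    patients = pd.read_csv(root / "patients.csv")
    captures = {
        pid: load_capture_set(root / pid, pid) for pid in patients["patient_id"]
    }
    return patients, captures


def save_calibrated(directory: str | Path, pid: str, image: CalibratedReflectanceImage) -> None:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    tifffile.imwrite(
        directory / f"{pid}_reflectance.tif",
        image.rgb.astype(np.float32),
        photometric="rgb",
    )
    tifffile.imwrite(
        directory / f"{pid}_mask.tif", image.saturation_mask.astype(np.uint8) * 255
    )
    sidecar = {
        "mm_per_px": image.mm_per_px,
        "origin_mm": list(image.origin),
        "provenance": image.provenance,
    }
    (directory / f"{pid}_meta.json").write_text(
        json.dumps(sidecar, indent=2, sort_keys=True)
    )


def load_calibrated(directory: str | Path, pid: str) -> CalibratedReflectanceImage:
    directory = Path(directory)
    rgb = tifffile.imread(directory / f"{pid}_reflectance.tif").astype(float)
    mask = tifffile.imread(directory / f"{pid}_mask.tif") > 0
    meta = json.loads((directory / f"{pid}_meta.json").read_text())
    return CalibratedReflectanceImage(
        rgb=rgb,
        saturation_mask=mask,
        mm_per_px=float(meta["mm_per_px"]),
        origin=tuple(meta["origin_mm"]),
        provenance=meta.get("provenance", {}),
    )


def load_calibrated_dataset(
    directory: str | Path,
) -> dict[str, CalibratedReflectanceImage]:
    directory = Path(directory)
    out = {}
    for path in sorted(directory.glob("*_reflectance.tif")):
        pid = path.name.removesuffix("_reflectance.tif")
        out[pid] = load_calibrated(directory, pid)
    return out
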