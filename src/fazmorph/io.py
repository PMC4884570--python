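"""Reading and writing the pipeline's on-disk artifacts.

Images are 8-bit grayscale TIFF (or PNG via imageio-compatible tifffile
fallback), ground truth is one JSON per cohort, and tabular artifacts are
plain CSV with headers.  All writers are deterministic: identical inputs
produce byte-identical files.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .types import EnFaceAngiogram, EyeGroundTruth, FazMeasurement


def write_angiogram(image: EnFaceAngiogram, path: str | Path) -> Path:
    """Write a frame as 8-bit grayscale TIFF; pixel scale goes in the name
    of the sidecar-free convention (stored in the cohort CSV as well)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    tifffile.imwrite(
        path,
        np.asarray(image.pixels, dtype=np.uint8),
        resolution=(1e4 / image.um_per_pixel, 1e4 / image.um_per_pixel),
        software=None,
    )
    return path


def read_angiogram(
    path: str | Path, um_per_pixel: float, layer: str, eye_id: str | None = None
) -> EnFaceAngiogram:
    path = Path(path)
    pixels = tifffile.imread(path)
    return EnFaceAngiogram(
        pixels=pixels,
        um_per_pixel=um_per_pixel,
        layer=layer,  # type: ignore[arg-type]
        eye_id=eye_id or path.stem,
    )


def write_ground_truth(eyes: list[EyeGroundTruth], path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    payload = [dataclasses.asdict(e) for e in eyes]
    path.write_text(json.dumps(payload, indent=1, sort_keys=True) + "\n")
    return path


def read_ground_truth(path: str | Path) -> list[EyeGroundTruth]:
    payload = json.loads(Path(path).read_text())
    return [EyeGroundTruth(**rec) for rec in payload]


def cohort_frame(eyes: list[EyeGroundTruth]) -> pd.DataFrame:
    """Tidy per-eye/layer cohort table (one row per eye per layer)."""
    rows = [dataclasses.asdict(e) for e in eyes]
    df = pd.DataFrame(rows).rename(columns={"bcva_letters": "bcva_etdrs"})
    cols = [
        "eye_id", "group", "layer", "bcva_etdrs",
        "faz_semi_major_um", "faz_semi_minor_um", "faz_orientation_deg",
        "n_gaps", "gap_arc_deg", "dropout_fraction", "render_seed",
    ]
    return df[cols]


def write_cohort_csv(eyes: list[EyeGroundTruth], path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    cohort_frame(eyes).to_csv(path, index=False, float_format="%.6g")
    return path


def measurements_frame(measurements: list[FazMeasurement]) -> pd.DataFrame:
    rows = []
    for m in measurements:
        rows.append(
            dict(
                eye_id=m.eye_id,
                layer=m.layer,
                horizontal_um=m.horizontal_um,
                vertical_um=m.vertical_um,
                max_um=m.max_um,
                perp_um=m.perp_um,
                angle_deg=m.angle_deg,
                angle_class=m.angle_class,
            )
        )
    return pd.DataFrame(rows)


def write_measurements_csv(
    measurements: list[FazMeasurement], path: str | Path
) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    measurements_frame(measurements).to_csv(path, index=False, float_format="%.6g")
    return path


def read_measurements_csv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path)
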