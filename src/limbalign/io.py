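"""Reading and writing masks, landmarks and measurement reports.

Masks travel as single-channel PNGs, either one binary mask per bone
(0 = background, 255 = foreground) or one integer label image using the
label map {1: femoral_head, 2: distal_femur, 3: proximal_tibia,
4: distal_tibia, 5: talus}.  Landmarks are JSON ``{name: [x, y]}`` maps in
pixel coordinates (x = column, y = row, origin top-left, y downward).
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Dict, Iterable, Optional

import imageio.v3 as iio
import numpy as np
import pandas as pd

from .landmarks import BONE_NAMES, LandmarkSet, LimbMasks

LABEL_MAP: Dict[str, int] = {name: i for i, name in enumerate(BONE_NAMES, start=1)}


def read_image(path) -> np.ndarray:
    """Grayscale image as a 2-D array (multi-channel inputs averaged)."""
    img = np.asarray(iio.imread(path))
    if img.ndim == 3:
        img = img[..., :3].mean(axis=-1)
    return img


def write_image(path, image: np.ndarray) -> None:
    iio.imwrite(path, np.asarray(image).astype(np.uint8))


def read_mask(path) -> np.ndarray:
    return read_image(path) > 127


def write_mask(path, mask: np.ndarray) -> None:
    iio.imwrite(path, (np.asarray(mask).astype(bool) * 255).astype(np.uint8))


def write_masks(directory, masks: LimbMasks) -> None:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    for name in BONE_NAMES:
        write_mask(directory / f"{name}.png", masks[name])


def read_masks(
    directory, side: str = "right", pixel_spacing: Optional[float] = None
) -> LimbMasks:
    """Load the five per-bone PNGs (``<bone>.png``) from a directory."""
    directory = Path(directory)
    arrays = {name: read_mask(directory / f"{name}.png") for name in BONE_NAMES}
    return LimbMasks(side=side, pixel_spacing=pixel_spacing, **arrays)


def masks_from_label_image(
    label_image: np.ndarray, side: str = "right"
) -> LimbMasks:
    lbl = np.asarray(label_image).astype(int)
    return LimbMasks(
        side=side, **{name: lbl == code for name, code in LABEL_MAP.items()}
    )


def masks_to_label_image(masks: LimbMasks) -> np.ndarray:
    out = np.zeros(masks.shape, dtype=np.uint8)
    for name, code in LABEL_MAP.items():
        out[masks[name]] = code
    return out


def write_landmarks(path, landmarks: LandmarkSet) -> None:
    Path(path).write_text(
        json.dumps({k: list(v) for k, v in landmarks.as_dict().items()}, indent=2)
    )


def read_landmarks(path) -> LandmarkSet:
    return LandmarkSet.from_dict(json.loads(Path(path).read_text()))


def write_report(path, report: Dict) -> None:
    Path(path).write_text(json.dumps(report, indent=2, default=float))


def reports_to_csv(path, reports: Iterable[Dict]) -> pd.DataFrame:
    """One row per leg: side, four angles, classification, flags."""
    rows = []
    for rep in reports:
        row = {"side": rep["side"], **rep["angles"]}
        row["classification"] = rep["classification"]
        row["quality_flags"] = ";".join(rep.get("quality_flags", []))
        rows.append(row)
    frame = pd.DataFrame(rows)
    frame.to_csv(path, index=False)
    return frame
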