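"""Overlap metrics and image/mask readers and writers.

The Jaccard index |A∩B|/|A∪B| and Dice coefficient 2|A∩B|/(|A|+|B|) are the
standard overlap scores for binary segmentations; they are linked by the
identity D = 2J/(1+J).  When both masks are empty the scores are undefined
and reported as NaN with ``defined=False`` rather than as a perfect 1.0, so
sequence averages can skip empty-truth slices instead of being inflated by
them.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "EvalRecord",
    "jaccard",
    "dice",
    "evaluate_masks",
    "eval_table",
    "read_slice",
    "window_to_uint8",
    "write_image_png",
    "write_mask_png",
    "read_mask_png",
    "DEFAULT_WINDOW",
]

logger = logging.getLogger(__name__)

# standard abdominal soft-tissue window (center, width) in Hounsfield units
DEFAULT_WINDOW = (60.0, 400.0)


@dataclass(frozen=True)
class EvalRecord:
    slice_id: str
    jaccard: float
    dice: float
    defined: bool = True


def _as_bool_pair(a, b) -> tuple[np.ndarray, np.ndarray]:
    a = np.asarray(a).astype(bool)
    b = np.asarray(b).astype(bool)
    if a.shape != b.shape:
        raise ValueError(f"mask shapes differ: {a.shape} vs {b.shape}")
    return a, b


def jaccard(a, b) -> float:
    """|A∩B| / |A∪B|; NaN when both masks are empty."""
    a, b = _as_bool_pair(a, b)
    union = np.count_nonzero(a | b)
    if union == 0:
        logger.warning("jaccard undefined: both masks empty")
        return float("nan")
    return np.count_nonzero(a & b) / union


def dice(a, b) -> float:
    """2|A∩B| / (|A|+|B|); NaN when both masks are empty."""
    a, b = _as_bool_pair(a, b)
    denom = np.count_nonzero(a) + np.count_nonzero(b)
    if denom == 0:
        logger.warning("dice undefined: both masks empty")
        return float("nan")
    return 2.0 * np.count_nonzero(a & b) / denom


def evaluate_masks(pred, truth, slice_id: str = "") -> EvalRecord:
    j = jaccard(pred, truth)
    d = dice(pred, truth)
    return EvalRecord(slice_id, j, d, defined=not np.isnan(j))


def eval_table(records) -> pd.DataFrame:
    """Per-slice metric table with an appended mean row (defined slices only)."""
    df = pd.DataFrame(
        [
            {"slice_id": r.slice_id, "jaccard": r.jaccard, "dice": r.dice, "defined": r.defined}
            for r in records
        ]
    )
    defined = df[df["defined"]]
    mean_row = pd.DataFrame(
        [
            {
                "slice_id": "mean",
                "jaccard": defined["jaccard"].mean(),
                "dice": defined["dice"].mean(),
                "defined": bool(len(defined)),
            }
        ]
    )
    return pd.concat([df, mean_row], ignore_index=True)


def window_to_uint8(hu, center: float, width: float) -> np.ndarray:
    """Affine CT windowing: clip HU to [center-width/2, center+width/2] -> 0..255."""
    hu = np.asarray(hu, dtype=float)
    lo = center - width / 2.0
    scaled = np.clip((hu - lo) / width, 0.0, 1.0) * 255.0
    return np.rint(scaled).astype(np.uint8)


def read_slice(path, fmt: str | None = None, window: tuple[float, float] = DEFAULT_WINDOW) -> np.ndarray:
    """Load one slice as an 8-bit gray array.

    PNG files pass through unchanged (and must already be grayscale).
    DICOM files are rescaled to Hounsfield units via the stored
    slope/intercept and windowed to 8 bits with ``window = (center, width)``.
    """
    path = Path(path)
    if fmt is None:
        fmt = "dicom" if path.suffix.lower() in (".dcm", ".dicom", ".ima") else "png"
    if fmt == "png":
        from PIL import Image

        img = Image.open(path)
        if img.mode != "L":
            raise ValueError(f"{path} is not an 8-bit grayscale PNG (mode {img.mode})")
        return np.asarray(img, dtype=np.uint8)
    if fmt == "dicom":
        import pydicom

        ds = pydicom.dcmread(path)
        slope = float(getattr(ds, "RescaleSlope", 1.0))
        intercept = float(getattr(ds, "RescaleIntercept", 0.0))
        hu = ds.pixel_array.astype(float) * slope + intercept
        center, width = window
        logger.info("windowing %s with center=%s width=%s HU", path.name, center, width)
        return window_to_uint8(hu, center, width)
    raise ValueError(f"unknown format {fmt!r}")


def write_image_png(image, path) -> None:
    from PIL import Image

    Image.fromarray(np.asarray(image, dtype=np.uint8), mode="L").save(path)


def write_mask_png(mask, path) -> None:
    """Store a 0/1 mask as a 0/255 grayscale PNG."""
    write_image_png(np.asarray(mask, dtype=np.uint8) * 255, path)


def read_mask_png(path) -> np.ndarray:
    from PIL import Image

    arr = np.asarray(Image.open(path).convert("L"))
    return (arr > 127).astype(np.uint8)
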