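"""End-to-end slice and sequence segmentation.

The per-slice procedure is: estimate (or inherit) LV_A, locate LV_M on the
slice's own histogram, extract the divided-histogram threshold range, keep
pixels inside the closed gray interval [low, high], then clean the binary
mask with mathematical morphology — fill holes, open with a small disk,
keep the largest connected component — and trace the liver contour.

On a sequence, LV_A is computed once on the reference slice (about one third
of the way in, where the liver cross-section is largest) and shared by every
slice; LV_M is still found per slice because the liver gray drifts slightly
along the scan.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage import measure, morphology

from .mixture_models import EMConfig
from .thresholding import (
    BLACK_CUTOFF,
    WHITE_CUTOFF,
    SliceContext,
    ThresholdRange,
    build_histogram,
    estimate_lva,
    find_lvm,
    select_reference_slice,
    tdh_threshold,
    twh_threshold,
)

__all__ = [
    "SegmentationResult",
    "binarize",
    "morphology_clean",
    "segment_slice",
    "segment_sequence",
]

logger = logging.getLogger(__name__)

MORPH_RADIUS = 3


@dataclass
class SegmentationResult:
    """Mask plus every intermediate quantity needed to audit a slice."""

    mask: np.ndarray
    contour: np.ndarray | None
    thresholds: ThresholdRange
    context: SliceContext
    warnings: list[str] = field(default_factory=list)


def binarize(image, trange: ThresholdRange) -> np.ndarray:
    """1 where low <= pixel <= high (closed interval), else 0."""
    image = np.asarray(image)
    return ((image >= trange.low) & (image <= trange.high)).astype(np.uint8)


def morphology_clean(mask, radius: int = MORPH_RADIUS) -> np.ndarray:
    """Fill holes, open with a disk, keep the largest 8-connected component."""
    mask = np.asarray(mask).astype(bool)
    if not mask.any():
        logger.warning("morphology_clean received an empty mask")
        return mask.astype(np.uint8)
    filled = ndimage.binary_fill_holes(mask)
    opened = ndimage.binary_opening(filled, structure=morphology.disk(radius))
    if not opened.any():
        logger.warning("mask vanished under morphological opening")
        return opened.astype(np.uint8)
    labels = measure.label(opened, connectivity=2)
    largest = np.argmax(np.bincount(labels.ravel())[1:]) + 1
    out = ndimage.binary_fill_holes(labels == largest)
    return out.astype(np.uint8)


def _trace_contour(mask: np.ndarray) -> np.ndarray | None:
    contours = measure.find_contours(mask.astype(float), 0.5)
    if not contours:
        return None
    return max(contours, key=len)


def segment_slice(image, lva: int | None = None, config: EMConfig | None = None) -> SegmentationResult:
    """Segment one 8-bit gray slice.

    ``lva`` is the sequence-level approximate liver gray value; if omitted it
    is estimated from this slice alone.  The mixture fit operates on the
    histogram restricted to [BLACK_CUTOFF, WHITE_CUTOFF] so that the air
    background spike and bone saturation cannot capture components.
    """
    config = config or EMConfig()
    image = np.asarray(image)
    warnings: list[str] = []
    if lva is None:
        lva = estimate_lva(image)
    hist = build_histogram(image).restrict(BLACK_CUTOFF, WHITE_CUTOFF)
    lvm = find_lvm(hist, lva)
    context = SliceContext(lva=int(lva), lvm=int(lvm), histogram=hist)
    if config.mode == "twh":
        trange = twh_threshold(context, config)
    else:
        trange = tdh_threshold(context, config)
    if trange.mode != config.mode:
        warnings.append(f"fell back to {trange.mode} thresholding")
    raw = binarize(image, trange)
    if not raw.any():
        warnings.append("no pixels inside the threshold band")
    mask = morphology_clean(raw)
    if raw.any() and not mask.any():
        warnings.append("mask vanished during morphological cleanup")
    logger.info(
        "slice: LV_A=%d LV_M=%d thresholds=[%.1f, %.1f] rules=(%s, %s) mode=%s",
        context.lva,
        context.lvm,
        trange.low,
        trange.high,
        trange.low_rule,
        trange.high_rule,
        trange.mode,
    )
    return SegmentationResult(
        mask=mask,
        contour=_trace_contour(mask),
        thresholds=trange,
        context=context,
        warnings=warnings,
    )


def segment_sequence(slices, config: EMConfig | None = None) -> list[SegmentationResult]:
    """Segment an ordered sequence sharing one reference-slice LV_A."""
    slices = list(slices)
    if not slices:
        raise ValueError("need at least one slice")
    config = config or EMConfig()
    ref = select_reference_slice(len(slices))
    lva = estimate_lva(slices[ref])
    logger.info("reference slice %d of %d: LV_A=%d", ref + 1, len(slices), lva)
    return [segment_slice(s, lva=lva, config=config) for s in slices]
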