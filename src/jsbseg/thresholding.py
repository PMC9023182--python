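"""Liver threshold extraction from gray-level histograms.

The strategy has three stages:

1.  **LV_A** — an approximate liver gray value, read off a reference slice:
    gray statistics are collected in a 10-pixel-tall horizontal band placed
    at one quarter of the body's height, black and white zones are removed,
    and the modal gray value of the band is taken.  Because the liver
    dominates that band on a mid-abdomen slice, the mode is a robust first
    guess at the liver gray level for the whole sequence.

2.  **LV_M** — the liver peak on each individual slice: the smoothed
    gray-level histogram's local maximum nearest LV_A.

3.  **Divided-histogram thresholds (TDH)** — the histogram is split at LV_M
    into a left and a right part (the LV_M bin belongs to both), a Johnson
    S_B mixture is fitted to each part, and the liver threshold band is read
    off the fitted curves: the low threshold is the crossing of the two
    rightmost weighted component curves of the left part, the high threshold
    the crossing of the two leftmost curves of the right part.  If some other
    component's peak lies strictly between a crossing and LV_M, the peak's
    gray value overrides the crossing — a nearby peak signals another tissue
    mode that the threshold must not swallow.

Splitting at LV_M puts the liver mode on the *edge* of each part, which is
exactly the shape a single strongly skewed S_B component fits well; that is
what makes the divided fit stable in the cluster number where a
whole-histogram fit is not.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import optimize, signal

from .errors import EstimationError, SplitError, ThresholdError
from .johnson_sb import JohnsonSBParams, jsb_pdf
from .mixture_models import (
    EMConfig,
    FitResult,
    GaussianParams,
    GrayHistogram,
    fit_em,
    fit_gmm,
)

__all__ = [
    "SliceContext",
    "ThresholdRange",
    "build_histogram",
    "select_reference_slice",
    "estimate_lva",
    "find_lvm",
    "split_histogram",
    "component_intersections",
    "threshold_from_part",
    "tdh_threshold",
    "twh_threshold",
]

logger = logging.getLogger(__name__)

BLACK_CUTOFF = 10
WHITE_CUTOFF = 245
WEIGHT_FLOOR = 5e-3
_GRID_STEP = 0.1


@dataclass(frozen=True)
class SliceContext:
    """Per-slice thresholding inputs: LV_A, LV_M and the fit histogram."""

    lva: int
    lvm: int
    histogram: GrayHistogram


@dataclass(frozen=True)
class ThresholdRange:
    """Closed gray interval classifying liver pixels, with provenance."""

    low: float
    high: float
    low_rule: str = "intersection"
    high_rule: str = "intersection"
    mode: str = "tdh"

    def __post_init__(self):
        if not self.low < self.high:
            raise ValueError(f"need low < high, got ({self.low}, {self.high})")


def build_histogram(image, roi=None, n_levels: int = 256) -> GrayHistogram:
    """Count gray levels over the image (or a boolean region of interest)."""
    image = np.asarray(image)
    values = image[np.asarray(roi, dtype=bool)] if roi is not None else image.ravel()
    if values.size == 0:
        raise ValueError("empty region of interest")
    if values.min() < 0 or values.max() > n_levels - 1:
        raise ValueError(f"gray values must lie in [0, {n_levels - 1}]")
    counts = np.bincount(values.astype(np.int64).ravel(), minlength=n_levels)
    return GrayHistogram(np.arange(n_levels), counts)


def select_reference_slice(sequence_length: int) -> int:
    """0-based index of the slice at about one third of the sequence.

    On abdominal sequences the liver cross-section is largest about a third
    of the way in (a 90-slice scan points at the 30th slice), so that slice
    anchors the LV_A estimate for the whole sequence.
    """
    if sequence_length < 1:
        raise ValueError("sequence_length must be >= 1")
    one_based = int(round(sequence_length / 3))
    one_based = min(max(one_based, 1), sequence_length)
    return one_based - 1


def estimate_lva(
    image,
    band_height: int = 10,
    black_cutoff: int = BLACK_CUTOFF,
    white_cutoff: int = WHITE_CUTOFF,
) -> int:
    """Modal gray value of a thin band across the body at 1/4 body height.

    The band is ``band_height`` rows tall, spans the body bounding box
    horizontally, and sits one quarter of the way down from the top of the
    body.  Gray values below ``black_cutoff`` (air/background) and above
    ``white_cutoff`` (bone/contrast) are excluded before taking the mode.
    """
    image = np.asarray(image)
    body_rows = np.flatnonzero(np.any(image > 0, axis=1))
    body_cols = np.flatnonzero(np.any(image > 0, axis=0))
    if body_rows.size == 0:
        raise EstimationError("image contains no body (all pixels black)")
    top, bottom = int(body_rows[0]), int(body_rows[-1])
    r0 = top + int(round(0.25 * (bottom - top + 1)))
    band = image[r0 : r0 + band_height, body_cols[0] : body_cols[-1] + 1]
    values = band[(band >= black_cutoff) & (band <= white_cutoff)]
    if values.size == 0:
        raise EstimationError(
            f"sampling band at rows [{r0}, {r0 + band_height}) empty after "
            f"black/white removal"
        )
    counts = np.bincount(values.astype(np.int64).ravel(), minlength=256)
    return int(np.argmax(counts))


def _smooth_counts(counts: np.ndarray, window: int = 5) -> np.ndarray:
    # reflect-pad so the moving average creates no artificial edge peaks
    half = window // 2
    padded = np.pad(counts.astype(float), half, mode="reflect")
    return np.convolve(padded, np.ones(window) / window, mode="valid")


def find_lvm(
    hist: GrayHistogram,
    lva: int,
    smooth_window: int = 5,
    prominence_frac: float = 0.01,
) -> int:
    """Gray level of the smoothed-histogram peak nearest LV_A.

    Peaks are strict local maxima of a ``smooth_window``-level moving average
    with prominence at least ``prominence_frac`` of the tallest smoothed
    count.  Ties in distance to LV_A go to the peak with the larger raw
    count, then to the lower gray level.  With no detectable peak the
    function falls back to LV_A itself (logged as a warning).
    """
    smoothed = _smooth_counts(hist.counts, smooth_window)
    peaks, _ = signal.find_peaks(smoothed, prominence=prominence_frac * smoothed.max())
    if peaks.size == 0:
        logger.warning("no histogram peaks found; falling back to LV_A=%d", lva)
        return int(lva)
    levels = hist.levels[peaks]
    counts = hist.counts[peaks]
    order = sorted(
        range(levels.size),
        key=lambda i: (abs(int(levels[i]) - int(lva)), -int(counts[i]), int(levels[i])),
    )
    return int(levels[order[0]])


def split_histogram(hist: GrayHistogram, lvm: int) -> tuple[GrayHistogram, GrayHistogram]:
    """Divide the histogram at LV_M; the LV_M bin belongs to both parts.

    Sharing the boundary bin keeps the liver peak mass on the edge of each
    part, which is the point of the divided fit.
    """
    lo, hi = hist.populated_range
    if not lo < lvm < hi:
        raise SplitError(
            f"LV_M={lvm} must lie strictly inside the populated range [{lo}, {hi}]"
        )
    return hist.restrict(lo, lvm), hist.restrict(lvm, hi)


def _component_pdf(comp, x: np.ndarray) -> np.ndarray:
    if isinstance(comp, JohnsonSBParams):
        return jsb_pdf(x, comp)
    return np.exp(-0.5 * (x - comp.mean) ** 2 / comp.var) / np.sqrt(2 * np.pi * comp.var)


def _model_grid_bounds(model) -> tuple[float, float]:
    if model.support is not None:
        lo, hi = model.support
        return lo + 1e-6, hi - 1e-6
    means = np.array([c.mean for c in model.components])
    sds = np.array([np.sqrt(c.var) for c in model.components])
    return float((means - 4 * sds).min()), float((means + 4 * sds).max())


def _pair_crossings(model, j: int, k: int, a: float, b: float) -> np.ndarray:
    """Gray values where the weighted curves of components j and k cross."""

    def g(x):
        x = np.asarray(x, dtype=float)
        return model.weights[j] * _component_pdf(model.components[j], x) - model.weights[
            k
        ] * _component_pdf(model.components[k], x)

    grid = np.arange(a, b + _GRID_STEP, _GRID_STEP)
    vals = g(grid)
    sign = np.sign(vals)
    flips = np.flatnonzero(sign[:-1] * sign[1:] < 0)
    crossings = [float(optimize.brentq(g, grid[i], grid[i + 1], xtol=1e-3)) for i in flips]
    return np.unique(np.round(np.array(sorted(crossings)), 6))


def component_intersections(model, a: float, b: float) -> np.ndarray:
    """Crossings of all median-adjacent weighted component pairs in [a, b]."""
    if not a < b:
        raise ValueError("need a < b")
    order = np.argsort(model.medians(), kind="stable")
    points: list[float] = []
    for j, k in zip(order[:-1], order[1:]):
        points.extend(_pair_crossings(model, int(j), int(k), a, b).tolist())
    return np.unique(np.asarray(sorted(points)))


def _component_mode(comp, a: float, b: float) -> float:
    """Gray value of a component's density peak within [a, b]."""
    if isinstance(comp, GaussianParams):
        return float(min(max(comp.mean, a), b))
    grid = np.arange(a, b + _GRID_STEP, _GRID_STEP)
    dens = jsb_pdf(grid, comp)
    i = int(np.argmax(dens))
    lo = grid[max(i - 1, 0)]
    hi = grid[min(i + 1, grid.size - 1)]
    res = optimize.minimize_scalar(
        lambda x: -jsb_pdf(x, comp), bounds=(lo, hi), method="bounded"
    )
    return float(res.x)


GROUP_GAP = 4.0
EDGE_MARGIN = 6.0


def _group_components(model, usable: np.ndarray, group_gap: float) -> list[np.ndarray]:
    """Cluster usable components into curves by median proximity.

    A large-K EM fit frequently spends several components on one tissue
    hump (in particular on the spiked boundary bin of a divided
    histogram).  Components whose medians lie within ``group_gap`` gray
    levels of their neighbour belong to the same visible curve and are
    treated as one summed density when locating crossings and peaks.
    """
    medians = model.medians()[usable]
    order = usable[np.argsort(medians, kind="stable")]
    sorted_medians = model.medians()[order]
    groups: list[list[int]] = [[int(order[0])]]
    for idx, med in zip(order[1:], sorted_medians[1:]):
        prev_med = model.medians()[groups[-1][-1]]
        if med - prev_med <= group_gap:
            groups[-1].append(int(idx))
        else:
            groups.append([int(idx)])
    return [np.asarray(g) for g in groups]


def _group_pdf(model, group: np.ndarray, x: np.ndarray) -> np.ndarray:
    out = np.zeros_like(np.asarray(x, dtype=float))
    for idx in group:
        out += model.weights[idx] * _component_pdf(model.components[idx], x)
    return out


def _group_crossings(model, g1: np.ndarray, g2: np.ndarray, a: float, b: float) -> np.ndarray:
    def g(x):
        x = np.asarray(x, dtype=float)
        return _group_pdf(model, g1, x) - _group_pdf(model, g2, x)

    grid = np.arange(a, b + _GRID_STEP, _GRID_STEP)
    vals = g(grid)
    sign = np.sign(vals)
    flips = np.flatnonzero(sign[:-1] * sign[1:] < 0)
    crossings = [float(optimize.brentq(g, grid[i], grid[i + 1], xtol=1e-3)) for i in flips]
    return np.unique(np.round(np.array(sorted(crossings)), 6))


def _group_mode(model, group: np.ndarray, a: float, b: float) -> tuple[float, bool]:
    """Location of the group's density peak and whether it is an interior
    maximum (a curve rising monotonically into the support boundary has its
    argmax at the grid edge and carries no peak in the visible sense)."""
    if group.size == 1 and isinstance(model.components[group[0]], GaussianParams):
        mean = model.components[group[0]].mean
        return float(min(max(mean, a), b)), a < mean < b
    grid = np.arange(a, b + _GRID_STEP, _GRID_STEP)
    dens = _group_pdf(model, group, grid)
    i = int(np.argmax(dens))
    return float(grid[i]), 0 < i < grid.size - 1


def threshold_from_part(
    part_model,
    side: str,
    lvm: float,
    weight_floor: float = WEIGHT_FLOOR,
    group_gap: float = GROUP_GAP,
    edge_margin: float = EDGE_MARGIN,
) -> tuple[float, str]:
    """Segmentation point of one histogram part.

    For the left part the candidate is the crossing of the two fitted
    curves with the *largest* medians (the liver edge curve and its left
    neighbour); for the right part, of the two with the *smallest*
    medians.  Among multiple crossings of the chosen pair the one nearest
    LV_M wins.  If another usable curve peaks strictly between the
    crossing and LV_M, that peak's gray value is returned instead (rule
    ``"peak_override"``).

    Two merging rules decide what counts as one "curve".  Components
    within ``group_gap`` gray levels of each other model a single tissue
    hump (see :func:`_group_components`).  In addition, every component
    whose median lies within ``edge_margin`` of LV_M belongs to the liver
    edge curve: dividing the histogram at LV_M deliberately stacks the
    liver mass against the part boundary, and EM regularly spends two or
    three components (a boundary spike plus broad shoulders) on that one
    edge shape.

    Components with weight below ``weight_floor`` are ignored throughout —
    large-K EM fits routinely park near-empty components in histogram gaps.
    """
    if side not in ("left", "right"):
        raise ValueError(f"side must be 'left' or 'right', got {side!r}")
    usable = np.flatnonzero(part_model.weights > weight_floor)
    if usable.size < 2:
        raise ThresholdError(
            f"{side} part has {usable.size} usable component(s); need >= 2"
        )
    medians = part_model.medians()
    edge = usable[np.abs(medians[usable] - lvm) <= edge_margin]
    rest = usable[np.abs(medians[usable] - lvm) > edge_margin]
    groups: list[np.ndarray]
    if edge.size and rest.size:
        groups = _group_components(part_model, rest, group_gap)
        liver_group = edge
        if side == "left":
            groups = groups + [liver_group]
        else:
            groups = [liver_group] + groups
    else:
        groups = _group_components(part_model, usable, group_gap)
    if len(groups) < 2:
        raise ThresholdError(
            f"{side} part has {len(groups)} distinct fitted curve(s); need >= 2"
        )
    pair = (groups[-2], groups[-1]) if side == "left" else (groups[0], groups[1])
    others = groups[:-2] if side == "left" else groups[2:]

    a, b = _model_grid_bounds(part_model)
    crossings = _group_crossings(part_model, pair[0], pair[1], a, b)
    if crossings.size:
        crossing = float(crossings[np.argmin(np.abs(crossings - lvm))])
    else:
        # nested curves with no sign change: use the valley of the summed
        # pair density between the two curve modes
        m1, _ = _group_mode(part_model, pair[0], a, b)
        m2, _ = _group_mode(part_model, pair[1], a, b)
        m_lo, m_hi = sorted((m1, m2))
        if m_hi - m_lo < _GRID_STEP:
            raise ThresholdError(f"{side} pair produces no usable segmentation point")
        grid = np.arange(m_lo, m_hi, _GRID_STEP)
        dens = _group_pdf(part_model, np.concatenate(pair), grid)
        crossing = float(grid[np.argmin(dens)])

    lo_gap, hi_gap = sorted((crossing, float(lvm)))
    overrides = []
    for group in others:
        mode, interior = _group_mode(part_model, group, a, b)
        if interior and lo_gap < mode < hi_gap:
            overrides.append(mode)
    if overrides:
        # the peak nearest LV_M bounds the liver most conservatively
        peak = min(overrides, key=lambda m: abs(m - lvm))
        return peak, "peak_override"
    return crossing, "intersection"


def _fit_part(part: GrayHistogram, config: EMConfig, family: str) -> FitResult:
    k_eff = min(config.K, part.n_populated - 1)
    cfg = EMConfig(
        K=max(k_eff, 2),
        max_iter=config.max_iter,
        tol=config.tol,
        init_delta=config.init_delta,
        seed=config.seed,
        family=family,
        mode=config.mode,
    )
    return fit_em(part, cfg) if family == "johnson_sb" else fit_gmm(part, cfg)


def twh_threshold(context: SliceContext, config: EMConfig) -> ThresholdRange:
    """Whole-histogram thresholds (the baseline / fallback mode).

    One mixture is fitted to the undivided histogram; the component whose
    median is nearest LV_M is taken as the liver curve, and the thresholds
    are its crossings with the next-lower and next-higher median components
    (nearest LV_M on each side), falling back to the populated range edge
    when a neighbour is missing.
    """
    hist = context.histogram
    fit = _fit_part(hist, config, config.family)
    model = fit.model
    usable = np.flatnonzero(model.weights > WEIGHT_FLOOR)
    if usable.size < 2:
        raise ThresholdError("whole-histogram fit left fewer than 2 usable components")
    medians = model.medians()[usable]
    order = usable[np.argsort(medians, kind="stable")]
    liver_pos = int(np.argmin(np.abs(model.medians()[order] - context.lvm)))
    a, b = _model_grid_bounds(model)
    lo_pop, hi_pop = hist.populated_range

    def _side_threshold(neigh_pos: int, default: float) -> float:
        if neigh_pos < 0 or neigh_pos >= order.size:
            return default
        pts = _pair_crossings(model, int(order[liver_pos]), int(order[neigh_pos]), a, b)
        if pts.size == 0:
            return default
        return float(pts[np.argmin(np.abs(pts - context.lvm))])

    low = _side_threshold(liver_pos - 1, float(lo_pop))
    high = _side_threshold(liver_pos + 1, float(hi_pop))
    low = min(low, float(context.lvm))
    high = max(high, float(context.lvm))
    if not low < high:
        raise ThresholdError("degenerate whole-histogram threshold range")
    return ThresholdRange(low, high, "intersection", "intersection", mode="twh")


def tdh_threshold(context: SliceContext, config: EMConfig) -> ThresholdRange:
    """Divided-histogram liver threshold range for one slice.

    Splits the fit histogram at LV_M, fits a mixture to each part and reads
    the low/high thresholds off the fitted curves.  If either part is too
    small to carry at least two components the whole-histogram fallback is
    used instead (``mode == "twh"``).
    """
    hist = context.histogram
    lvm = context.lvm
    try:
        left, right = split_histogram(hist, lvm)
    except SplitError:
        logger.warning("LV_M=%d on the populated boundary; falling back to TWH", lvm)
        return twh_threshold(context, config)
    if left.n_populated < 4 or right.n_populated < 4:
        logger.warning("histogram part too small for a divided fit; using TWH")
        return twh_threshold(context, config)

    try:
        left_fit = _fit_part(left, config, config.family)
        right_fit = _fit_part(right, config, config.family)
        low, low_rule = threshold_from_part(left_fit.model, "left", lvm)
        high, high_rule = threshold_from_part(right_fit.model, "right", lvm)
        low = min(low, float(lvm))
        high = max(high, float(lvm))
        if not low < high:
            raise ThresholdError(f"degenerate threshold range ({low}, {high})")
    except ThresholdError as err:
        logger.warning("divided fit failed (%s); falling back to TWH", err)
        return twh_threshold(context, config)
    return ThresholdRange(low, high, low_rule, high_rule, mode="tdh")
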