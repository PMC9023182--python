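"""Synthetic abdominal-slice phantoms with known ground truth.

A phantom is a 512x512 8-bit image built from disjoint elliptical regions on
a black background: an elliptical "body" whose outer ring is a bright bone
rim, a soft-tissue interior, one large homogeneous liver blob, and a few
confounder organs whose gray distributions sit only ~15 levels away from the
liver's.  Every region's gray values are drawn from a known Johnson S_B law,
so the generating mixture, the liver mask and the liver gray statistics are
all available as ground truth.

The default gray bands mimic an abdominal CT windowed to 8 bits with a
standard soft-tissue window: air at 0, fat/muscle around 100, liver
parenchyma near 170 with a tight (sd ~ 4-5 gray levels), mildly negatively
skewed distribution, neighbouring organs at 155 and 185, and bone above 240.
The liver skew (gamma > 0) is deliberate: it is the feature an S_B mixture
can represent and a Gaussian mixture cannot.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .errors import RegionOverlapError
from .johnson_sb import JohnsonSBParams, jsb_sample
from .mixture_models import GrayHistogram, MixtureModel

__all__ = [
    "RegionSpec",
    "PhantomSpec",
    "Phantom",
    "default_phantom_spec",
    "make_phantom",
    "make_mixture_histogram",
    "save_phantom",
]


@dataclass(frozen=True)
class RegionSpec:
    """One elliptical organ: centre/axes in pixels plus its gray law."""

    name: str
    center: tuple[float, float]  # (row, col)
    axes: tuple[float, float]  # (semi-row, semi-col)
    dist: JohnsonSBParams


@dataclass(frozen=True)
class PhantomSpec:
    shape: tuple[int, int]
    body_center: tuple[float, float]
    body_axes: tuple[float, float]
    rim_inner_scale: float
    rim_dist: JohnsonSBParams
    tissue_dist: JohnsonSBParams
    regions: tuple[RegionSpec, ...]

    @property
    def liver(self) -> RegionSpec:
        for r in self.regions:
            if r.name == "liver":
                return r
        raise ValueError("phantom spec has no region named 'liver'")

    def to_dict(self) -> dict:
        def dist(d):
            return {"gamma": d.gamma, "delta": d.delta, "xi": d.xi, "lam": d.lam}

        return {
            "shape": list(self.shape),
            "body_center": list(self.body_center),
            "body_axes": list(self.body_axes),
            "rim_inner_scale": self.rim_inner_scale,
            "rim_dist": dist(self.rim_dist),
            "tissue_dist": dist(self.tissue_dist),
            "regions": [
                {
                    "name": r.name,
                    "center": list(r.center),
                    "axes": list(r.axes),
                    "dist": dist(r.dist),
                }
                for r in self.regions
            ],
        }


@dataclass
class Phantom:
    """Synthetic slice plus its ground truth."""

    image: np.ndarray
    liver_mask: np.ndarray
    spec: PhantomSpec
    seed: int

    @property
    def liver_params(self) -> JohnsonSBParams:
        return self.spec.liver.dist


def default_phantom_spec() -> PhantomSpec:
    """The standard test-bed phantom.

    Liver median ~170 (gamma=1.1, delta=6 => sd ~ 4.5 gray levels, negative
    skew), confounders at medians 155 and 185 (15 levels off the liver on
    either side), broad soft tissue near 104, bone rim in 240-255.  One
    confounder sits at the same height as the LV_A sampling band so the
    band statistics are contested, as they are on real slices.
    """
    return PhantomSpec(
        shape=(512, 512),
        body_center=(256.0, 256.0),
        body_axes=(200.0, 225.0),
        rim_inner_scale=0.93,
        rim_dist=JohnsonSBParams(0.0, 1.8, 240.0, 15.0),
        tissue_dist=JohnsonSBParams(0.5, 2.2, 55.0, 110.0),
        regions=(
            RegionSpec("liver", (185.0, 180.0), (78.0, 98.0), JohnsonSBParams(1.1, 6.0, 120.0, 110.0)),
            RegionSpec("organ_low", (340.0, 180.0), (40.0, 50.0), JohnsonSBParams(1.1, 6.0, 105.0, 110.0)),
            RegionSpec("organ_high", (330.0, 345.0), (35.0, 45.0), JohnsonSBParams(1.1, 6.0, 135.0, 110.0)),
            RegionSpec("organ_band", (155.0, 355.0), (28.0, 32.0), JohnsonSBParams(1.1, 6.0, 135.0, 110.0)),
        ),
    )


def _ellipse_mask(shape, center, axes) -> np.ndarray:
    rr, cc = np.ogrid[: shape[0], : shape[1]]
    return ((rr - center[0]) / axes[0]) ** 2 + ((cc - center[1]) / axes[1]) ** 2 <= 1.0


def make_phantom(spec: PhantomSpec | None = None, seed: int = 0) -> Phantom:
    """Render a phantom; identical bytes for identical (spec, seed).

    Raises
    ------
    RegionOverlapError
        If two organ regions overlap or an organ leaves the soft-tissue
        interior (i.e. touches the bone rim or the background).
    """
    spec = spec or default_phantom_spec()
    shape = spec.shape
    body = _ellipse_mask(shape, spec.body_center, spec.body_axes)
    inner = _ellipse_mask(
        shape,
        spec.body_center,
        (spec.body_axes[0] * spec.rim_inner_scale, spec.body_axes[1] * spec.rim_inner_scale),
    )
    rim = body & ~inner

    region_masks = []
    occupied = np.zeros(shape, dtype=bool)
    for region in spec.regions:
        mask = _ellipse_mask(shape, region.center, region.axes)
        if np.any(mask & ~inner):
            raise RegionOverlapError(f"region {region.name!r} leaves the body interior")
        if np.any(mask & occupied):
            raise RegionOverlapError(f"region {region.name!r} overlaps another region")
        occupied |= mask
        region_masks.append(mask)

    tissue = inner & ~occupied
    rng = np.random.default_rng(seed)
    image = np.zeros(shape, dtype=np.uint8)

    def paint(mask, dist):
        n = int(mask.sum())
        if n:
            vals = jsb_sample(dist, n, rng=rng)
            image[mask] = np.clip(np.rint(vals), 0, 255).astype(np.uint8)

    paint(tissue, spec.tissue_dist)
    paint(rim, spec.rim_dist)
    for mask, region in zip(region_masks, spec.regions):
        paint(mask, region.dist)

    liver_mask = region_masks[[r.name for r in spec.regions].index("liver")]
    return Phantom(image=image, liver_mask=liver_mask.astype(np.uint8), spec=spec, seed=seed)


def make_mixture_histogram(model: MixtureModel, n: int, seed: int = 0) -> GrayHistogram:
    """Histogram of ``n`` quantised draws from a fitted (or true) mixture."""
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    per_comp = rng.multinomial(n, model.weights)
    samples = []
    for count, comp in zip(per_comp, model.components):
        if count == 0:
            continue
        if model.family == "johnson_sb":
            samples.append(jsb_sample(comp, int(count), rng=rng))
        else:
            samples.append(comp.mean + np.sqrt(comp.var) * rng.standard_normal(int(count)))
    values = np.clip(np.rint(np.concatenate(samples)), 0, 255).astype(np.int64)
    return GrayHistogram(np.arange(256), np.bincount(values, minlength=256))


def save_phantom(phantom: Phantom, out_dir) -> None:
    """Write image + truth-mask PNGs and the generating spec as JSON."""
    from PIL import Image

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    Image.fromarray(phantom.image, mode="L").save(out / "phantom.png")
    # named to pair with the segmenter's "<stem>_mask.png" outputs
    Image.fromarray(phantom.liver_mask * 255, mode="L").save(out / "phantom_mask.png")
    payload = {"seed": phantom.seed, "spec": phantom.spec.to_dict()}
    with open(out / "phantom.json", "w") as fh:
        json.dump(payload, fh, indent=2)
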