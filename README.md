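# jsbseg

Threshold segmentation of liver CT slices with Johnson S_B mixture models.

Liver parenchyma on an abdominal CT slice occupies a narrow gray band, but
the band drifts between patients and scanners, and its gray-level histogram
peak is visibly *skewed* — which a Gaussian mixture fits poorly. `jsbseg`
fits finite mixtures of bounded Johnson (S_B) distributions to gray-level
histograms by EM and turns the fitted component curves into a liver
threshold band, a binary mask and a contour. It is aimed at medical-image
analysis work where a fast, automatic, statistically interpretable
threshold segmentation is wanted — as a baseline, a pre-segmentation for
atlas/graph methods, or a teaching implementation of histogram mixture
modelling.

## The model

A Johnson S_B variable `x` lives on the open interval `(ξ, ξ+λ)` and

    z = γ + δ · ln((x − ξ) / (ξ + λ − x))

is standard normal (`δ > 0`). Its density is

    p(x) = δ/√(2π) · λ/((x−ξ)(λ+ξ−x)) · exp(−½ (γ + δ f(x))²),
    f(x) = ln((x−ξ)/(λ+ξ−x)).

`γ` shifts the peak and flips the skew; large `δ` tightens the curve; a
single S_B component can hug one edge of a histogram, which Gaussians
cannot. The K-component mixture `p(x|Θ) = Σ_k Φ_k p_k(x|γ_k, δ_k)` (shared
support, `Σ Φ_k = 1`) is fitted to the histogram counts by EM; the M-step
is closed-form: with `f_i` the transform of level `x_i` and `w_ik` the
responsibilities,

    Φ_k = N_k/N,   δ_k = 1/√v_k,   γ_k = −δ_k m_k,

where `m_k, v_k` are the responsibility-weighted mean and variance of `f`.

Segmentation proceeds by locating the approximate liver gray value LV_A on
a reference slice (the mode of a thin band across the body at one quarter
body height), the liver histogram peak LV_M nearest LV_A on each slice,
then *dividing* the histogram at LV_M, fitting a mixture to each part, and
reading the low/high thresholds off the crossings of the fitted component
curves (with a peak-override rule when another curve peaks between a
crossing and LV_M). Binarization in `[low, high]` plus hole filling,
morphological opening and largest-component selection yields the mask. A
Gaussian mixture baseline (`family="gaussian"`) and an undivided
whole-histogram mode (`mode="twh"`) are included for comparison.

## Worked example

Everything is testable offline through the synthetic phantom generator,
which renders a 512×512 abdominal-like slice (black background, bone rim,
soft tissue, a skewed-gray liver and three confounding organs only ~15
gray levels away) with known ground truth:

```python
from jsbseg import EMConfig, make_phantom, segment_slice, jaccard, dice

phantom = make_phantom(seed=0)            # truth: liver gray median 170.0
result = segment_slice(phantom.image, config=EMConfig(K=13))
print(result.context.lva, result.context.lvm)
print(round(result.thresholds.low, 1), round(result.thresholds.high, 1))
print(round(jaccard(result.mask, phantom.liver_mask), 4),
      round(dice(result.mask, phantom.liver_mask), 4))
```

prints

```
170 170
157.3 178.9
0.999 0.9995
```

LV_A/LV_M land on the liver gray median (170); the divided-histogram fit
brackets the liver band with `[157.3, 178.9]` — wide enough to keep ~99 %
of the liver mass, narrow enough to exclude the organs at medians 155 and
185 — and the cleaned mask overlaps the true liver with Jaccard 0.999.

The same run from the shell:

```sh
jsbseg phantom --out ph --seed 0
jsbseg segment --input ph/phantom.png --format png --clusters 13 --out seg
jsbseg eval --pred seg --truth ph --out eval.csv
```

`seg/thresholds.csv` records per-slice LV_A, LV_M, the threshold band and
which rule (curve intersection or peak override) produced each bound.
DICOM input is supported via `--format dicom`, windowed to 8 bits with a
configurable center/width (default 60/400 HU, the standard abdominal
soft-tissue window).

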