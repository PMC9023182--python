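# Methods

## Model and likelihood

The bounded Johnson (S_B) family describes a gray value `x ∈ (ξ, ξ+λ)`
whose logit-type transform `z = γ + δ·f(x)`, `f(x) = ln((x−ξ)/(λ+ξ−x))`,
is standard normal. `δ > 0` and `γ` are shape parameters; `(ξ, λ)` locate
the support. A K-component mixture with weights `Φ_k` and shared support
models a slice's gray-level histogram. Fitting maximises the discrete
log-likelihood `L(Θ) = Σ_i c_i ln Σ_k Φ_k p_k(x_i)` with histogram counts
`c_i` as multiplicities — identical to the per-pixel likelihood but
O(levels·K) per EM sweep instead of O(pixels·K).

Only `(Φ_k, γ_k, δ_k)` are optimised. The support is fixed before EM from
the data: `ξ = min − 0.5`, `λ = range + 1`, the half-gray-level pad keeping
observed boundary levels strictly inside the open support where `f` is
finite. The M-step is the closed-form weighted MLE: the standardised
variable `γ + δ·f` is refitted to a unit normal under the responsibility
weights, giving `δ_k = 1/√v_k`, `γ_k = −δ_k m_k`. These updates were
re-derived from the stationarity conditions of the weighted likelihood;
the test suite verifies them against a direct Nelder–Mead maximiser (max
|difference| ≲ 1e−8 on random histograms), and that cross-check — not the
derivation — is the authority.

Note that `δ` and `γ` are *relative to the support*: the same physical
distribution has different shape values on differently padded supports.
Parameter-recovery comparisons therefore pin the fit to the generator's
support via the optional `support` argument of `fit_em`.

## EM details

* **Initialisation** — equal weights; component medians evenly spaced at
  `c_k = lo + k/(K+1)·(hi−lo)` over the populated range (interior
  placement avoids the boundary divergence of `f`); `δ_k = init_delta = 2`
  (`γ_k = −init_delta·f(c_k)` puts the median exactly at `c_k`). Gaussian
  baseline: means at `c_k`, variance `((hi−lo)/(K+1))²`.
* **Convergence** — relative |ΔL| < 1e−6 or 500 iterations; both fits are
  deterministic given the histogram and configuration.
* **Component collapse** — a component locking onto a single gray level
  drives its transform-space variance to 0 and the likelihood to +∞. The
  M-step raises a collapse error below variance 1e−8; the fitter reseeds
  the offending component once at the most under-fitted populated level.
  If the same component collapses again the data genuinely contain a
  one-bin spike (the shared LV_M bin of a divided histogram is the
  canonical case), and the fitter continues with a per-component variance
  floor equivalent to a ~0.3-gray-level spread rather than aborting. The
  floor is a projection, not an exact M-step, so the monotonicity
  guarantee formally applies only to fits that never hit it; all tracked
  test fits stay on the exact path.
* Zero-count levels contribute nothing and are skipped.

## Threshold extraction

LV_A is the modal gray value of a 10-row band across the body bounding box
at one quarter of body height, after discarding gray values < 10 (air) and
> 245 (bone/saturation); it is computed once per sequence on the reference
slice at ⌈length/3⌉. LV_M is the smoothed-histogram local maximum nearest
LV_A on each slice (5-level moving average with reflect padding; peaks
need prominence ≥ 1 % of the tallest smoothed count; distance ties go to
the larger raw count, then the lower gray level).

The histogram — restricted to [10, 245] so the background spike cannot
capture components — is divided at LV_M with the LV_M bin in both parts,
and a K = 13 mixture is fitted to each part. The low threshold is the
crossing of the two fitted curves with the largest medians in the left
part; the high threshold, of the two smallest-median curves in the right
part; among multiple crossings of a pair the one nearest LV_M is taken,
and each bound is clamped to keep `low ≤ LV_M ≤ high`. If another curve's
density peak (an interior maximum, not a boundary-hugging rise) lies
strictly between a crossing and LV_M, that peak becomes the bound instead
(`peak_override`): an interposed peak marks a tissue mode the threshold
must not swallow.

Two merging rules define what counts as "a curve", because a K = 13 fit
routinely spends several components on one tissue hump:

* components whose medians lie within 4 gray levels of their neighbour are
  summed into one curve;
* components whose medians lie within 6 gray levels of LV_M form the liver
  edge curve — dividing at LV_M deliberately stacks the liver mass against
  the part boundary, and EM regularly represents that edge as a boundary
  spike plus a broad shoulder.

Without these rules the extracted thresholds jumped by 10+ gray levels
between adjacent K; with them the spread over K = 12…15 is below 2 gray
levels on the phantom suite. Components with weight ≤ 0.005 are ignored
throughout (large-K fits park near-empty components in histogram gaps).
When a part is too small for a divided fit (fewer than 4 populated
levels), or the divided rules degenerate, the pipeline falls back to the
whole-histogram (TWH) mode: one fit, liver curve = median nearest LV_M,
thresholds = its crossings with the adjacent-median curves. The Gaussian
baseline uses the same TWH logic.

Curve crossings are located as sign changes of the weighted density
difference on a 0.1-gray-level grid, refined by Brent's method to 1e−3;
an identical dense-grid scan serves as the independent oracle in tests.

## Mask post-processing

Pixels in the closed interval `[low, high]` are kept (threshold ranges
are conventionally quoted inclusively), then: fill holes → binary
opening with a radius-3 disk → keep the largest 8-connected component →
fill again. The radius is small relative to 512² anatomy; hole filling
absorbs the scattered in-liver misses that a finite threshold band leaves
behind. No anatomical-side prior is applied — the largest component stands
in for liver selection, which is correct on mid-liver slices and phantoms.

## Synthetic phantom

The generator renders a 512×512, 8-bit slice: black background, an
elliptical body (axes 200×225 px) with a bone rim (S_B on (240, 255)) and
soft-tissue interior (median ≈ 104, sd ≈ 12), a large elliptical liver
(median 170, `γ = 1.1`, `δ = 6` ⇒ sd ≈ 4.5 gray levels, matching ~6 HU
parenchyma homogeneity under a 400-HU window), and three confounder organs
at gray medians 155 and 185 — 15 levels off the liver on either side, one
of them at the height of the LV_A sampling band so the band statistics are
contested. Regions are disjoint by construction (violations raise), all
randomness flows through one seeded generator, and the truth mask and
generating mixture are returned with the image.

What the phantom does *not* emulate: partial-volume edge blur, streak/beam
artefacts, anatomical shape variability, lesions, and inter-slice
correlation. Passing the phantom suite therefore demonstrates the
correctness and internal stability of the statistical machinery, not
clinical-grade accuracy on real scanner data; per-slice thresholds and
overlap scores on hospital sequences depend on acquisition and windowing
details that no synthetic test bed reproduces.

## Numerical and design choices

* Density evaluation is total: 0 outside the open support, never an error;
  log-space evaluation with log-sum-exp keeps mixtures of tight components
  stable.
* The skew labels follow the field's peak-position convention (`γ > 0` →
  "negative"): note that the *moment* skewness of such a sample is
  positive (peak at low gray, long right tail); tests assert the moment
  sign.
* Gray histograms are dense integer-level count arrays; sub-histograms
  (black/white exclusion, the divided parts) are views selected by level
  range.
* Undefined overlap (both masks empty) reports NaN with a `defined=False`
  flag rather than 1.0, so sequence averages skip empty-truth slices.
* Problem sizes in tests and the acceptance script — 50 000-draw
  distributional checks, 100 000-draw recovery, ten phantom seeds, K
  sweeps of 12…15 — were chosen so the complete suite re-runs in well
  under a minute while keeping Monte-Carlo noise an order of magnitude
  below every asserted tolerance.

## Known limitations

* K is fixed (13 by default); no model-order selection is attempted.
* The divided fit assumes LV_M is findable — a slice whose liver peak is
  absent (little liver in the slice) degrades to the nearest peak to LV_A.
* Components are univariate: no spatial regularisation; morphology is the
  only spatial prior.
* Only the S_B member of the Johnson system is implemented; S_L/S_U are
  out of scope.
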