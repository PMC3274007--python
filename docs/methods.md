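# Methods

This note documents the models and procedures implemented in `forestseg`,
the assumptions behind them, the parameters that matter, and the design
choices made where the design was genuinely open.

## 1. Multiresolution region-growing segmentation

### Model

Image objects begin as single pixels. A merge of objects 1 and 2 into m is
charged the area-weighted increase in heterogeneity

```
f        = w_color · Δh_color + (1 − w_color) · Δh_shape
Δh_color = Σ_b w_b · [ n_m σ_b(m) − ( n_1 σ_b(1) + n_2 σ_b(2) ) ]
Δh_shape = w_compact · Δh_cmpct + (1 − w_compact) · Δh_smooth
h_cmpct  = l / √n          h_smooth = l / b
Δh_x     = n_m h_x(m) − ( n_1 h_x(1) + n_2 h_x(2) )
```

with σ_b the per-band population standard deviation (n-denominator, so a
single pixel has σ = 0 and merge deltas are exact), l the perimeter in
exposed pixel edges, b the bounding-box perimeter, and w_b non-negative
band weights (default 1). A merge is admitted only while `f < s²`; the
scale parameter s therefore bounds the heterogeneity a single merge may
add, and larger scales produce larger objects.

The merge schedule is *local mutual best fitting*: each pass visits the
surviving objects in a seeded pseudo-random order; an object merges with
its cheapest neighbour only if it is reciprocally that neighbour's cheapest
neighbour and the cost clears the threshold; passes repeat until none
merges. All object statistics (count, per-band sum and sum of squares,
perimeter, bounding box) merge in O(1); the merged perimeter uses the
shared-edge count maintained in the adjacency structure, so a final
from-pixels recomputation agrees exactly (tested).

### Numerical and procedural choices

- **Comparison against s², strict inequality.** The published criterion of
  the multiresolution algorithm family compares the fusion cost with the
  squared scale; strict `<` plus smallest-id tie-breaking makes the result
  a deterministic function of (scene, parameters, seed).
- **Visiting order.** The original software's "distributed treatment order"
  is proprietary; a seeded random permutation per pass avoids scanline
  artifacts and makes runs reproducible bit for bit. Consequences of the
  order are distributional, and all properties asserted about segmentation
  are distributional or invariant-based, not bit-exact across seeds.
- **4-connectivity** throughout (segments, adjacency, perimeter
  accounting); nodata pixels carry id 0 and never merge.
- Output ids are relabelled 1..K in row-major order of first occurrence.

## 2. Maximum-likelihood classification

Per-pixel Gaussian quadratic discriminant
`g_i(x) = ln p_i − ½ ln|Σ_i| − ½ (x−μ_i)ᵀ Σ_i⁻¹ (x−μ_i)`; every valid pixel
is assigned (no reject class), ties break to the smallest class id, priors
default to equal. Covariances use the n−1 denominator; a ridge
`Σ + εI, ε = 10⁻⁶·tr(Σ)/B` is applied only when the Cholesky factorization
fails or degenerates.

**Signature trimming.** `extract_signatures(..., trim_outliers=q)` screens
training pixels by per-band median/MAD z-scores and drops those whose
squared norm exceeds the χ²(B) quantile q before taking moments. This is
the numerical analogue of an interpreter excluding shadow and canopy-gap
pixels when delineating homogeneous training areas, and is what the
pipeline uses (q = 0.999); the default (`None`) is the plain sample-moment
estimator. A median/MAD screen is used instead of iterated Mahalanobis
trimming because a 10–15 % shadow fraction at a large spectral offset
inflates the initial covariance enough to hide itself from a
covariance-based screen.

Baselines: a windowed modal ("majority") filter with the centre class kept
on ties, and object-based classification (OBC) applying the same
discriminant to per-segment mean spectra.

## 3. Segment-majority fusion (SBC)

For each segment, the per-pixel classification labels of its pixels are
counted and every pixel is reassigned to the plurality class; ties break to
the smallest class id. "Majority" means plurality — a strict >50 % rule
would leave segments unassigned, which the method's published maps do not
show. Pixels labelled 0 are excluded from the vote; a segment with only
0-labels keeps 0. The operation is idempotent and piecewise-constant on
segments (both tested).

## 4. Accuracy assessment

Test units are 9×9 pixel clusters placed at random, without overlap, so
that the full window lies inside a single reference-class region (and
optionally a single segment); the cluster's reference class is the majority
class of its window. Per-class cluster budgets follow the rule of thumb of
~50 units per class adjusted by class area share with a floor (at desk
scale the budget is scaled down proportionally, default 5 per class,
floor 2 — the study scene is ~360× larger than a 128×128 simulation).

From the K×K error matrix (rows = classified, columns = reference):
overall accuracy `tr/N`, Cohen's kappa
`κ = (p_o − p_e)/(1 − p_e)`, `p_e = Σ row_i·col_i/N²`, and per-class user's
(row) and producer's (column) accuracies.

**Accounting unit.** `build_error_matrix` supports two units. With
`unit="cluster"` (default) each cluster contributes one count at the modal
classified class of its window. With `unit="pixel"` every labelled pixel of
every window contributes one count. The method comparison and the sweep use
the pixel-weighted unit: modal-per-cluster scoring forgives any within-
window error rate below 50 % and therefore hides exactly the scattered and
patchy misclassification the fusion step is designed to remove; the
published per-class accuracies of the original error matrices are likewise
inconsistent with pure modal counting. The shipped case-study matrices are
consumed as printed, so their statistics do not depend on this choice.

The two shipped reference matrices reproduce their printed statistics:
κ = 0.59 and κ = 0.73 (2 d.p.), SBC overall accuracy 76.8 % (1 d.p.), both
totals 409. The per-pixel matrix's printed overall accuracy (63.9 %)
disagrees with its own diagonal (261/409 = 63.8 %) by one rounding unit;
the package reports the computed value.

## 5. Synthetic landscape generator

The generator emulates the statistical structure that makes species-level
classification of metre-resolution forest imagery hard, with known ground
truth. Defaults are the package's study conditions.

- **Stand mosaic.** First-passage percolation: seeds placed on a jittered
  grid grow over an i.i.d. random cost field (Dijkstra), giving connected,
  irregular, Voronoi-like stands of comparable size. Default mean stand
  area 702 px at 1 m resolution (the mean training-segment area of the
  motivating survey); every class is guaranteed at least two stands on
  small scenes, and a draw that leaves a class without a trainable stand is
  redrawn deterministically.
- **Spectral signatures.** Nine 4-band (B/G/R/NIR) Gaussian signatures in
  an 11-bit digital-number range. Visible bands are only modestly
  separated; NIR orders the classes: the two pines nearly identical
  (760/792), larch 1150, then the deciduous group — chestnut lowest (1500,
  early-season foliage), the three oaks 1650/1800/1950 — grass 2040, and a
  dark non-forest pool (560). Within-class spread σ = (28, 32, 28, 80) DN
  with mild visible-band correlation. The absolute numbers are nominal and
  configurable; only the orderings and the separation-to-noise ratios
  matter, and the pines are deliberately confusable at every aggregation
  level.
- **Crown-scale texture.** Within-class variation is split into an i.i.d.
  part and a spatially correlated part (fraction 0.6, Gaussian correlation
  length 3 px): x = μ + Σ^½[√(1−a)·ξ_iid + √a·ξ_corr], with ξ_corr a
  unit-variance Gaussian random field. The *marginal* per-pixel
  distribution is exactly the class signature; the correlation mimics crown
  texture and local illumination, which makes per-pixel errors patchy — the
  regime in which a 3×3 modal filter fails but stand-level plurality
  succeeds.
- **Shadow/gap speckle.** A Bernoulli subset of pixels (expected fraction
  0.10) is replaced by draws from a dark shadow signature; the local
  Bernoulli rate varies as a smooth lognormal field (clump scale 5 px)
  conditioned to a scene-wide mean of exactly p, so shadows arrive both
  isolated and in dense pockets, as gaps and shading do in closed-canopy
  forest. Speckled pixels keep their true class in the ground truth —
  shadows lie on real stands.
- **Training areas.** Up to 6 disjoint 5×5 patches per class, preferring
  distinct stands (≥25 px), mirroring interpreter-delineated training
  segments; classes with too few wide stands fall back to 3×3 patches or
  reuse their largest stands, with warnings.

**What the generator does not emulate:** topographic illumination
gradients, mixed pixels at stand boundaries, sensor noise correlated along
scan lines, phenological within-class gradients, and georeferencing error.
Passing tests therefore demonstrate the pipeline's behaviour under the
assumed error structure (Gaussian classes + patchy texture + clumped
shadows), not performance on any particular real scene; the study's
absolute accuracies are not reproducible without its imagery, and only the
qualitative orderings and curve shapes are asserted.

## 6. The experiment sweep

`run_sweep` crosses the nine color/shape weight cases (`C9S1(M9O1)` …
`C3S7(M5O5)`; subscripts 1, 3, 5, 7, 9 code weights 0.1, 0.25, 0.5, 0.75,
0.9) with a scale list (default 30–280 in steps of 20), scoring each cell's
segment-majority map on one shared cluster sample per scene (paired
comparison), and appends the PBC, 3×3-majority and OBC baselines. OBC is
evaluated on the scale-160 object layer — the operating point at which the
original comparison was published; over-segmentation relative to stands and
the shadow-shifted segment means are what make mean-vector classification
the weakest method. `find_plateau` returns the cells within a kappa
tolerance (default 0.02) of the sweep maximum.

Problem sizes used by the shipped experiments: 128×128 scenes (≈23 stands),
ten seeds, six scales for the plateau curve — sizes chosen so a full
method-comparison experiment runs in minutes on a single CPU while each
stand still contains ≈700 pixels, keeping the stand-to-cluster-to-filter
scale hierarchy (700 ≫ 81 ≫ 9) of the original survey.

## 7. Raster I/O and pan-sharpening

Scenes and label maps are read and written as multi-page TIFF (nodata via
the GDAL tag, NaN-marked) with a whitespace text-matrix fallback for
single-band data; digital numbers are held as float64 internally so
incremental segment statistics are exact. IHS pan-sharpening uses the
linear intensity/chroma transform (I = (R+G+B)/3 and two orthogonal chroma
axes): the coarse RGB is upsampled nearest-neighbour to the pan grid, the
intensity channel replaced by the pan band, and the transform inverted.
This variant has an exact closed-form inverse and preserves hue and
saturation identically under intensity substitution, which is the
property the pipeline relies on; it is applied to the 4-3-2 (NIR-R-G as
RGB) band combination by the preparing workflow, while classification
consumes all four bands on a common grid.

## 8. Known limitations

- Mutual-best-fitting results depend on the visiting seed; segment counts
  and boundaries vary slightly across seeds at fixed parameters.
- Dense shadow pockets can survive as their own segments at plateau scales,
  in which case fusion cannot correct them (their own vote is the shadow
  class); this mirrors a real limitation of segment-majority maps.
- The two pine classes are spectrally near-identical by design; their
  stands merge freely and flip as units, bounding attainable kappa.
- The kappa-vs-scale plateau location depends on the digital-number scale
  of the imagery: the scale parameter has units of (weighted) DN standard
  deviation per merge.
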