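# forestseg

Forest cover mapping from high-resolution multispectral satellite imagery,
at the tree-species level. The package implements the full segment-based
classification (SBC) pipeline used to produce species-level forest cover
maps from metre-resolution imagery such as pan-sharpened IKONOS scenes:

1. **Multiresolution region-growing segmentation.** Image objects start as
   single pixels and merge bottom-up under the homogeneity criterion

   *f* = *w*<sub>color</sub>·Δ*h*<sub>color</sub> + (1 −
   *w*<sub>color</sub>)·Δ*h*<sub>shape</sub>,

   where Δ*h*<sub>color</sub> = Σ<sub>b</sub> *w*<sub>b</sub>[*n*<sub>m</sub>σ<sub>b</sub>(m) −
   (*n*<sub>1</sub>σ<sub>b</sub>(1) + *n*<sub>2</sub>σ<sub>b</sub>(2))] is the
   area-weighted growth in spectral standard deviation, and the shape term
   mixes compactness *l*/√*n* and smoothness *l*/*b* (perimeter *l*,
   bounding-box perimeter *b*). A merge happens only while *f* < *s*², so
   the **scale parameter** *s* bounds object heterogeneity: the larger the
   scale, the larger the objects.
2. **Gaussian maximum-likelihood classification (PBC).** Per-pixel
   assignment by the quadratic discriminant
   *g*<sub>i</sub>(**x**) = ln *p*<sub>i</sub> − ½ln|Σ<sub>i</sub>| −
   ½(**x**−**μ**<sub>i</sub>)ᵀΣ<sub>i</sub>⁻¹(**x**−**μ**<sub>i</sub>), with
   class signatures estimated from training areas.
3. **Segment-majority fusion (SBC).** Every pixel of a segment is
   reassigned to the plurality PBC class of that segment — removing the
   salt-and-pepper scatter of per-pixel classification while keeping its
   per-pixel evidence.
4. **Accuracy assessment.** 9×9-pixel test clusters sampled inside
   homogeneous reference regions, a classified-vs-reference error matrix,
   overall accuracy, Cohen's kappa (K-HAT), and per-class user's/producer's
   accuracies. Comparison baselines: a 3×3 modal (majority) filter on the
   PBC map, and object-based classification (OBC, the same discriminant on
   segment mean spectra).

Because no imagery is distributed with the original study, the package
includes a **synthetic forest landscape generator** with known ground
truth: irregular stand mosaics, 4-band (blue/green/red/NIR) class
signatures separated chiefly in the near infrared, crown-scale correlated
texture, and clumped dark shadow/gap speckle. Every pipeline stage is
validated end-to-end against that truth.

Intended users: remote-sensing and forest-inventory researchers who want a
tested, scriptable reference implementation of segmentation → ML → segment
majority → kappa, or a controlled sandbox for studying how segmentation
scale and color/shape weights affect species-level map accuracy.

## Worked example

```python
import forestseg as fs

# a 128×128 synthetic landscape: truth map, rendered scene, training areas
cfg = fs.SceneConfig(height=128, width=128, rng_seed=1)
scene, truth, training = fs.simulate_scene(cfg)

# signatures -> per-pixel ML -> segmentation -> segment-majority fusion
sigs = fs.extract_signatures(scene, training, trim_outliers=0.999)
pbc = fs.ml_classify(scene, sigs)
segmap = fs.segment(scene, fs.SegmentationParams(scale=90, w_color=0.5), rng_seed=1)
sbc = fs.segment_majority(pbc, segmap)

# accuracy on shared test clusters (pixel-weighted within 9×9 clusters)
from forestseg.accuracy import allocate_test_counts
clusters = fs.sample_test_clusters(truth, allocate_test_counts(truth, 5), rng_seed=1)
for name, m in [("PBC", pbc), ("SBC", sbc)]:
    em = fs.build_error_matrix(m, clusters, truth.class_scheme, unit="pixel")
    print(f"{name}: overall {100*fs.overall_accuracy(em):.1f}%  kappa {fs.kappa(em):.3f}")
```

Output:

```
PBC: overall 75.3%  kappa 0.721
SBC: overall 90.0%  kappa 0.886
```

The per-pixel classifier resolves the nine classes imperfectly — crown
texture, shadow pockets and the two nearly identical pine signatures leave
scattered and patchy errors — while majority fusion over stand-scale
segments recovers most of them; at segmentation scales past the optimum the
gain collapses again as stands of different species merge. The same
pipeline is scriptable from the shell (`forestseg simulate | segment |
classify | sbc | assess | sweep | compare`), where `sweep` reproduces the
kappa-versus-scale curves for the nine color/shape weight cases
(`C9S1(M9O1)` … `C3S7(M5O5)`).

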