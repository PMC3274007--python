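"""Synthetic forest landscapes with known ground truth.

High-resolution imagery of natural forest defeats per-pixel classifiers in a
characteristic way: stands are irregular mosaics, class signatures separate
mainly in the near-infrared, pixel values vary strongly within a stand, and
crown gaps and shadows scatter dark pixels across otherwise homogeneous
stands (the salt-and-pepper effect).  This module generates scenes with
exactly that structure, so every downstream stage can be validated against a
known truth map.

Stands are grown from random seed pixels on a random priority field, which
yields connected, irregular, Voronoi-like regions.  Each pixel's spectral
vector is drawn from its class's multivariate normal signature; an
independent Bernoulli fraction of pixels is replaced by draws from a dark
shadow/gap signature while keeping its true class in the ground-truth
raster — shadows lie on real stands.
"""

from __future__ import annotations

import heapq
import warnings
from dataclasses import dataclass, field, replace

import numpy as np

from .raster_io import ClassScheme, LabelRaster, MultibandScene, default_class_scheme

__all__ = [
    "SpectralSignature",
    "SceneConfig",
    "default_signatures",
    "default_speckle_signature",
    "generate_stand_mosaic",
    "render_scene",
    "sample_training_areas",
    "simulate_scene",
]


@dataclass
class SpectralSignature:
    """Per-class multivariate-normal spectral model in digital numbers."""

    class_id: int
    mean: np.ndarray
    covariance: np.ndarray

    def __post_init__(self) -> None:
        self.mean = np.asarray(self.mean, dtype=np.float64)
        self.covariance = np.asarray(self.covariance, dtype=np.float64)
        b = self.mean.shape[0]
        if self.covariance.shape != (b, b):
            raise ValueError("covariance shape does not match mean length")
        if not np.allclose(self.covariance, self.covariance.T):
            raise ValueError("covariance must be symmetric")
        if np.min(np.linalg.eigvalsh(self.covariance)) < -1e-9:
            raise ValueError("covariance must be positive semi-definite")
        if not np.all(np.isfinite(self.mean)):
            raise ValueError("mean must be finite")


@dataclass
class SceneConfig:
    """Parameters of the synthetic landscape.

    ``mean_stand_area_px`` defaults to 702 px (the mean training-segment area
    of the motivating IKONOS scene at 1 m resolution); ``n_stand_seeds``
    derives from it unless given explicitly.  ``speckle_fraction`` is the
    Bernoulli probability that a pixel is replaced by a shadow/gap draw.
    """

    height: int = 128
    width: int = 128
    n_stand_seeds: int | None = None
    class_proportions: np.ndarray = field(
        default_factory=lambda: np.full(9, 1.0 / 9.0)
    )
    mean_stand_area_px: float = 702.0
    speckle_fraction: float = 0.10
    speckle_signature: SpectralSignature | None = None
    speckle_clump_scale_px: float = 5.0
    texture_fraction: float = 0.6
    texture_scale_px: float = 3.0
    rng_seed: int = 0

    def __post_init__(self) -> None:
        self.class_proportions = np.asarray(self.class_proportions, dtype=np.float64)
        if np.any(self.class_proportions < 0):
            raise ValueError("class proportions must be non-negative")
        if abs(self.class_proportions.sum() - 1.0) > 1e-9:
            raise ValueError("class proportions must sum to 1")
        if self.mean_stand_area_px < 25:
            raise ValueError("mean_stand_area_px must be >= 25")
        if not (0.0 <= self.speckle_fraction < 1.0):
            raise ValueError("speckle_fraction must be in [0, 1)")
        if not (0.0 <= self.texture_fraction <= 1.0):
            raise ValueError("texture_fraction must be in [0, 1]")
        if self.n_stand_seeds is None:
            self.n_stand_seeds = max(1, round(self.height * self.width / self.mean_stand_area_px))
        if self.n_stand_seeds < 1:
            raise ValueError("need at least one stand seed")
        if self.height * self.width < self.n_stand_seeds:
            raise ValueError("more stand seeds than pixels")
        if self.speckle_signature is None:
            self.speckle_signature = default_speckle_signature()


def _default_mean_table() -> dict[int, list[float]]:
    # DN means per class, bands (blue, green, red, nir), 11-bit range as
    # acquired by the emulated sensor.  Chosen to respect the qualitative
    # orderings seen in early-growing-season signatures of central-Korean
    # forest: visible bands only modestly separated; NIR clearly separates
    # deciduous (high) from coniferous (low); chestnut (C.cre, leaves not yet
    # developed in early May) lowest of the deciduous group; the two pines
    # nearly identical.
    # Class structure: two near-identical pines, a mutually-confusable oak
    # trio, and clearly separated larch/chestnut/grass/non-forest groups —
    # per-pixel likelihoods confuse within-group species while segment-level
    # statistics still resolve the groups.
    return {
        1: [416.0, 440.0, 384.0, 760.0],    # P.rig  pitch pine
        2: [424.0, 448.0, 392.0, 792.0],    # P.kor  Korean pine
        3: [440.0, 480.0, 416.0, 1150.0],   # L.lep  Japanese larch
        4: [448.0, 504.0, 424.0, 1800.0],   # Q.mon  Mongolian oak
        5: [464.0, 520.0, 440.0, 1950.0],   # Q.var  cork oak
        6: [456.0, 528.0, 432.0, 1650.0],   # Q.acu  sawtooth oak
        7: [448.0, 496.0, 424.0, 1500.0],   # C.cre  chestnut
        8: [560.0, 680.0, 540.0, 2040.0],   # grass
        9: [656.0, 672.0, 640.0, 560.0],    # non-forest (soil/built/water)
    }


def default_signatures(class_scheme: ClassScheme | None = None) -> list[SpectralSignature]:
    """Nine class signatures emulating the spectral structure of the target
    landscape; absolute digital numbers are nominal and configurable."""
    scheme = class_scheme if class_scheme is not None else default_class_scheme()
    means = _default_mean_table()
    # Within-class spread: modest in the visible, larger in NIR where canopy
    # texture dominates; mild positive correlation between visible bands.
    sds = np.array([28.0, 32.0, 28.0, 80.0])
    corr = np.array(
        [
            [1.0, 0.6, 0.6, 0.1],
            [0.6, 1.0, 0.6, 0.1],
            [0.6, 0.6, 1.0, 0.1],
            [0.1, 0.1, 0.1, 1.0],
        ]
    )
    cov = corr * np.outer(sds, sds)
    return [SpectralSignature(cid, np.array(means[cid]), cov.copy()) for cid in scheme.ids]


def default_speckle_signature() -> SpectralSignature:
    """Dark shadow / canopy-gap signature (class_id 0: not a map class)."""
    mean = np.array([304.0, 304.0, 288.0, 600.0])
    cov = np.diag([576.0, 576.0, 576.0, 1600.0])
    return SpectralSignature(0, mean, cov)


def generate_stand_mosaic(
    config: SceneConfig, class_scheme: ClassScheme | None = None
) -> LabelRaster:
    """Grow an irregular stand mosaic from random seeds.

    Region growth on an i.i.d. random priority field: each seed claims its
    pixel, frontier pixels enter a heap with random priorities, and the
    lowest-priority frontier pixel is claimed next.  Every stand is
    4-connected by construction and every pixel gets a class in 1..K.
    Deterministic for a fixed ``rng_seed``.
    """
    scheme = class_scheme if class_scheme is not None else default_class_scheme()
    h, w = config.height, config.width
    k = len(config.class_proportions)
    if k != len(scheme):
        raise ValueError("class_proportions length must match the class scheme")
    rng = np.random.default_rng(config.rng_seed)
    n = int(config.n_stand_seeds)

    # jittered-grid seed placement: spreads stands over the scene (so each
    # is wide enough to host training patches and test clusters) while the
    # jitter plus the random growth field keeps shapes irregular
    gy = max(1, int(round(np.sqrt(n * h / w))))
    gx = int(np.ceil(n / gy))
    cells = rng.permutation(gy * gx)[:n]
    seeds = np.empty((n, 2), dtype=np.int64)
    for i, cell in enumerate(cells):
        cy, cx = divmod(int(cell), gx)
        r = (cy + 0.15 + 0.7 * rng.random()) * h / gy
        c = (cx + 0.15 + 0.7 * rng.random()) * w / gx
        seeds[i] = (min(int(r), h - 1), min(int(c), w - 1))
    classes = rng.choice(np.arange(1, k + 1), size=n, p=config.class_proportions)
    # guarantee every positive-proportion class appears when seeds allow
    wanted = np.flatnonzero(config.class_proportions > 0) + 1
    if n >= wanted.size:
        missing = [c for c in wanted if c not in classes]
        if missing:
            replace_at = rng.choice(n, size=len(missing), replace=False)
            classes[replace_at] = missing

    # first-passage growth: every pixel carries a random crossing cost and
    # each seed claims pixels in order of cumulative arrival cost, giving
    # connected, irregular, Voronoi-like stands of comparable size
    weight = rng.uniform(0.4, 1.6, size=(h, w))
    stand = np.zeros((h, w), dtype=np.int32)  # stand index, 1-based
    labels = np.zeros((h, w), dtype=np.int32)
    heap: list[tuple[float, int, int]] = []
    for (r, c), sid in zip(seeds, range(1, n + 1)):
        heap.append((0.0, r * w + c, sid))
    heapq.heapify(heap)
    while heap:
        d, pos, sid = heapq.heappop(heap)
        r, c = divmod(pos, w)
        if stand[r, c]:
            continue
        stand[r, c] = sid
        labels[r, c] = classes[sid - 1]
        for rr, cc in ((r - 1, c), (r + 1, c), (r, c - 1), (r, c + 1)):
            if 0 <= rr < h and 0 <= cc < w and stand[rr, cc] == 0:
                heapq.heappush(heap, (d + weight[rr, cc], rr * w + cc, sid))
    out = LabelRaster(labels, scheme)
    out.stand_ids = stand  # stand partition kept for training/cluster sampling
    return out


def _correlated_unit_field(
    rng: np.random.Generator, shape: tuple[int, ...], scale_px: float
) -> np.ndarray:
    """Gaussian random field with unit marginal variance and correlation
    length ``scale_px`` (Gaussian-filtered white noise, exactly renormalized
    by the filter's L2 norm)."""
    from scipy import ndimage

    white = rng.standard_normal(shape)
    axes = (0, 1)
    smooth = ndimage.gaussian_filter(
        white, sigma=scale_px, mode="wrap", axes=axes
    )
    impulse = np.zeros(shape[:2])
    impulse[shape[0] // 2, shape[1] // 2] = 1.0
    kern = ndimage.gaussian_filter(impulse, sigma=scale_px, mode="wrap")
    norm = np.sqrt((kern**2).sum())
    return smooth / norm


def render_scene(
    mosaic: LabelRaster,
    signatures: list[SpectralSignature],
    config: SceneConfig,
) -> MultibandScene:
    """Draw each pixel from its class signature, then overlay speckle.

    Each pixel's value is a draw from its class's multivariate normal; the
    within-class variation is split into an i.i.d. part and a crown-scale
    spatially correlated texture part (fraction ``texture_fraction``,
    correlation length ``texture_scale_px``) so that the marginal per-pixel
    distribution is exactly the class signature while crown texture and
    local illumination are coherent over a few pixels, as in metre-scale
    forest imagery.  An independent Bernoulli(``speckle_fraction``) subset
    of pixels is then replaced by draws from the dark shadow/gap signature.
    The ground-truth raster is untouched.  Bit-for-bit reproducible for a
    fixed ``rng_seed``.
    """
    sig_by_id = {s.class_id: s for s in signatures}
    present = np.unique(mosaic.labels)
    missing = [int(c) for c in present if c != 0 and c not in sig_by_id]
    if missing:
        raise ValueError(f"no signature for mosaic classes {missing}")
    h, w = mosaic.shape
    b = next(iter(sig_by_id.values())).mean.shape[0]
    rng = np.random.default_rng(config.rng_seed)
    a = config.texture_fraction
    xi = np.sqrt(1.0 - a) * rng.standard_normal((h, w, b))
    if a > 0:
        xi += np.sqrt(a) * _correlated_unit_field(rng, (h, w, b), config.texture_scale_px)
    px = np.zeros((h, w, b), dtype=np.float64)
    for cid in present:
        if cid == 0:
            continue
        sig = sig_by_id[int(cid)]
        # Σ^{1/2} via eigendecomposition: valid for any PSD covariance
        evals, evecs = np.linalg.eigh(sig.covariance)
        root = evecs @ np.diag(np.sqrt(np.maximum(evals, 0.0))) @ evecs.T
        sel = mosaic.labels == cid
        px[sel] = sig.mean + xi[sel] @ root.T
    if config.speckle_fraction > 0:
        p = config.speckle_fraction
        if config.speckle_clump_scale_px > 0:
            # shadows and canopy gaps arrive in pockets: the Bernoulli rate
            # varies as a smooth lognormal field with mean p, so some
            # neighbourhoods are shadow-dense while the scene-wide fraction
            # stays p in expectation
            theta = 1.5
            z = _correlated_unit_field(rng, (h, w), config.speckle_clump_scale_px)
            p_local = p * np.exp(theta * z)
            # condition the field on a scene-wide shadow budget of exactly p
            for _ in range(4):
                p_local = np.clip(p_local * (p / p_local.mean()), 0.0, 0.9)
        else:
            p_local = p
        speck = rng.random((h, w)) < p_local
        nspeck = int(speck.sum())
        if nspeck:
            s = config.speckle_signature
            px[speck] = rng.multivariate_normal(s.mean, s.covariance, size=nspeck,
                                                method="cholesky")
    return MultibandScene(px, pixel_size_m=1.0, nodata_mask=mosaic.labels == 0)


def sample_training_areas(
    mosaic: LabelRaster,
    n_per_class: int = 6,
    min_area_px: int = 25,
    rng_seed: int = 0,
    patch_half_width: int = 2,
) -> LabelRaster:
    """Place small square training patches wholly inside single-class stands.

    For each class, up to ``n_per_class`` disjoint ``(2h+1)²`` patches are
    placed, preferring distinct stands of area ≥ ``min_area_px``; when a
    class occupies fewer eligible stands than requested, extra patches go
    into its largest stands (with a warning).  A class with no eligible
    placement raises.  Returns a raster that is 0 outside the patches.
    """
    if n_per_class == 0:
        return LabelRaster(np.zeros(mosaic.shape, dtype=np.int32), mosaic.class_scheme)
    stand = getattr(mosaic, "stand_ids", None)
    if stand is None:
        from scipy import ndimage

        stand = np.zeros(mosaic.shape, dtype=np.int32)
        nxt = 1
        for cid in np.unique(mosaic.labels):
            if cid == 0:
                continue
            lab, nlab = ndimage.label(mosaic.labels == cid)
            stand[lab > 0] = lab[lab > 0] + nxt - 1
            nxt += nlab
    rng = np.random.default_rng(rng_seed)
    h, w = mosaic.shape
    ph = patch_half_width
    side = 2 * ph + 1
    out = np.zeros((h, w), dtype=np.int32)
    taken = np.zeros((h, w), dtype=bool)

    # candidate patch centres: full window inside one stand
    from scipy import ndimage

    smin = ndimage.minimum_filter(stand, size=side, mode="constant", cval=0)
    smax = ndimage.maximum_filter(stand, size=side, mode="constant", cval=0)
    interior = (smin == smax) & (smin > 0)
    interior[:ph] = interior[-ph:] = False
    interior[:, :ph] = interior[:, -ph:] = False

    # fallback candidate grid at 3×3 for classes whose stands are too
    # small/narrow for the full patch size
    if ph > 1:
        smin1 = ndimage.minimum_filter(stand, size=3, mode="constant", cval=0)
        smax1 = ndimage.maximum_filter(stand, size=3, mode="constant", cval=0)
        interior1 = (smin1 == smax1) & (smin1 > 0)
        interior1[:1] = interior1[-1:] = False
        interior1[:, :1] = interior1[:, -1:] = False

    areas = np.bincount(stand.ravel())
    for cid in mosaic.class_scheme.ids:
        ph_c, side_c = ph, side
        cand = np.argwhere(interior & (mosaic.labels == cid))
        if cand.size == 0 and ph > 1:
            warnings.warn(
                f"class {cid}: no stand admits a {side}×{side} patch; "
                "falling back to 3×3",
                stacklevel=2,
            )
            ph_c, side_c = 1, 3
            cand = np.argwhere(interior1 & (mosaic.labels == cid))
        if cand.size == 0:
            raise ValueError(
                f"class {cid}: no stand admits a {side_c}×{side_c} training patch"
            )
        cand_stands = stand[cand[:, 0], cand[:, 1]]
        eligible = np.unique(cand_stands[areas[cand_stands] >= min_area_px])
        if eligible.size == 0:
            eligible = np.unique(cand_stands)
        if eligible.size < n_per_class:
            warnings.warn(
                f"class {cid}: only {eligible.size} eligible stands for "
                f"{n_per_class} patches; reusing the largest stands",
                stacklevel=2,
            )
        placed = 0
        # one pass per requested patch, cycling over stands largest-first
        order = eligible[np.argsort(-areas[eligible], kind="stable")]
        attempts = 0
        while placed < n_per_class and attempts < 10 * n_per_class:
            sid = order[attempts % order.size]
            pts = cand[cand_stands == sid]
            pts = pts[rng.permutation(len(pts))]
            for r, c in pts:
                win = np.s_[r - ph_c : r + ph_c + 1, c - ph_c : c + ph_c + 1]
                if not taken[win].any():
                    out[win] = cid
                    taken[win] = True
                    placed += 1
                    break
            attempts += 1
        if placed == 0:
            raise ValueError(f"class {cid}: could not place any training patch")
        if placed < n_per_class:
            warnings.warn(
                f"class {cid}: placed {placed}/{n_per_class} training patches",
                stacklevel=2,
            )
    return LabelRaster(out, mosaic.class_scheme)


def simulate_scene(
    config: SceneConfig,
    signatures: list[SpectralSignature] | None = None,
    class_scheme: ClassScheme | None = None,
) -> tuple[MultibandScene, LabelRaster, LabelRaster]:
    """Convenience wrapper: mosaic + rendered scene + training areas.

    Returns ``(scene, truth, training)``; training patch placement uses a
    seed derived from ``config.rng_seed``.
    """
    scheme = class_scheme if class_scheme is not None else default_class_scheme()
    sigs = signatures if signatures is not None else default_signatures(scheme)
    # a scene must host at least a couple of stands per class for training
    # and assessment to be possible; only small scenes are affected
    min_seeds = 2 * len(scheme)
    if config.n_stand_seeds < min_seeds:
        config = replace(config, n_stand_seeds=min_seeds)
    # a usable landscape must give every class at least one trainable stand;
    # rare draws that do not are redrawn deterministically
    last_err: Exception | None = None
    for attempt in range(6):
        cfg_a = replace(config, rng_seed=config.rng_seed + 7919 * attempt)
        mosaic = generate_stand_mosaic(cfg_a, scheme)
        try:
            training = sample_training_areas(mosaic, rng_seed=cfg_a.rng_seed + 1)
        except ValueError as e:
            last_err = e
            continue
        scene = render_scene(mosaic, sigs, cfg_a)
        return scene, mosaic, training
    raise ValueError(f"no usable landscape after 6 draws: {last_err}")
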