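"""Gaussian maximum-likelihood classification and the comparison classifiers.

The pixel-based classifier (PBC) assigns each pixel the class maximising the
quadratic discriminant

    g_i(x) = ln p_i − ½ ln|Σ_i| − ½ (x − μ_i)ᵀ Σ_i⁻¹ (x − μ_i)

with class means μ_i and covariances Σ_i estimated from training pixels and
priors p_i.  Two standard baselines are provided: a windowed modal
("majority") filter applied to the PBC map, and object-based classification
(OBC) which applies the same discriminant to per-segment mean spectra.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy import ndimage
from scipy.linalg import solve_triangular
from scipy.stats import chi2

from .raster_io import ClassScheme, LabelRaster, MultibandScene
from .segmentation import SegmentMap, segment_means

__all__ = [
    "ClassSignature",
    "ClassSignatureSet",
    "extract_signatures",
    "ml_classify",
    "majority_filter",
    "obc_classify",
]


@dataclass
class ClassSignature:
    class_id: int
    mean: np.ndarray
    covariance: np.ndarray
    n_training: int
    prior: float


@dataclass
class ClassSignatureSet:
    """Per-class Gaussian signatures with priors."""

    signatures: list[ClassSignature]
    class_scheme: ClassScheme | None = None

    def __post_init__(self) -> None:
        total = sum(s.prior for s in self.signatures)
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"priors must sum to 1, got {total}")
        b = self.signatures[0].mean.shape[0]
        for s in self.signatures:
            if not np.allclose(s.covariance, s.covariance.T):
                raise ValueError(f"class {s.class_id}: covariance not symmetric")
            if s.n_training < b + 1:
                s.flagged = True  # too few pixels for a stable covariance

    @property
    def class_ids(self) -> list[int]:
        return [s.class_id for s in self.signatures]

    @property
    def n_bands(self) -> int:
        return self.signatures[0].mean.shape[0]

    def to_csv(self, path: str | Path) -> None:
        b = self.n_bands
        with open(path, "w", newline="") as fh:
            w = csv.writer(fh)
            w.writerow(
                ["class_id", "n_training", "prior"]
                + [f"mean_{i}" for i in range(b)]
                + [f"cov_{i}_{j}" for i in range(b) for j in range(b)]
            )
            for s in self.signatures:
                w.writerow(
                    [s.class_id, s.n_training, s.prior]
                    + s.mean.tolist()
                    + s.covariance.ravel().tolist()
                )

    @classmethod
    def from_csv(cls, path: str | Path) -> "ClassSignatureSet":
        with open(path, newline="") as fh:
            rows = list(csv.DictReader(fh))
        sigs = []
        b = int(np.sqrt(sum(1 for k in rows[0] if k.startswith("cov_"))))
        for r in rows:
            mean = np.array([float(r[f"mean_{i}"]) for i in range(b)])
            cov = np.array(
                [[float(r[f"cov_{i}_{j}"]) for j in range(b)] for i in range(b)]
            )
            sigs.append(
                ClassSignature(int(r["class_id"]), mean, cov, int(r["n_training"]),
                               float(r["prior"]))
            )
        return cls(sigs)


def extract_signatures(
    scene: MultibandScene,
    training: LabelRaster,
    prior_mode: str = "equal",
    trim_outliers: float | None = None,
) -> ClassSignatureSet:
    """Estimate per-class mean and sample covariance from training pixels.

    ``prior_mode`` is "equal" (default: the study gives no prior
    information) or "proportional" (to training pixel counts).

    ``trim_outliers``: if set (e.g. 0.999), one robust refit pass drops
    training pixels whose squared Mahalanobis distance from the initial
    estimate exceeds the chi-square quantile — the numerical analogue of an
    interpreter excluding shadow and gap pixels when delineating homogeneous
    training areas.  Default None: plain sample moments.
    """
    if prior_mode not in ("equal", "proportional"):
        raise ValueError(f"unknown prior_mode {prior_mode!r}")
    if training.shape != scene.shape:
        raise ValueError("training raster and scene dimensions differ")
    present = [int(c) for c in np.unique(training.labels) if c != 0]
    counts = {c: int((training.labels == c).sum()) for c in present}
    for c, n in counts.items():
        if n < 2:
            raise ValueError(f"class {c}: {n} training pixel(s); need at least 2")
    total = sum(counts.values())
    b = scene.n_bands
    sigs = []
    for c in present:
        x = scene.pixels[training.labels == c]
        mean = x.mean(axis=0)
        cov = np.atleast_2d(np.cov(x, rowvar=False))  # n−1 denominator
        if trim_outliers is not None and x.shape[0] > b + 2:
            # robust initial screen: per-band median/MAD z-scores, so that
            # a heavy shadow fraction cannot inflate the reference scatter
            med = np.median(x, axis=0)
            mad = np.median(np.abs(x - med), axis=0)
            scale = np.maximum(1.4826 * mad, 1e-9)
            z2 = np.sum(((x - med) / scale) ** 2, axis=1)
            keep = z2 <= chi2.ppf(trim_outliers, df=b)
            if keep.sum() > b + 1:
                mean = x[keep].mean(axis=0)
                cov = np.atleast_2d(np.cov(x[keep], rowvar=False))
        prior = 1.0 / len(present) if prior_mode == "equal" else counts[c] / total
        sigs.append(ClassSignature(c, mean, cov, counts[c], prior))
    return ClassSignatureSet(sigs, training.class_scheme)


def _regularized_cholesky(cov: np.ndarray, class_id: int) -> np.ndarray:
    """Cholesky factor of Σ, ridge-regularized if Σ is (near-)singular."""
    b = cov.shape[0]
    try:
        chol = np.linalg.cholesky(cov)
        if np.min(np.diag(chol)) > 1e-12:
            return chol
    except np.linalg.LinAlgError:
        pass
    eps = 1e-6 * max(np.trace(cov) / b, 1e-12)
    try:
        return np.linalg.cholesky(cov + eps * np.eye(b))
    except np.linalg.LinAlgError as e:
        raise np.linalg.LinAlgError(
            f"class {class_id}: covariance singular even after regularization"
        ) from e


def _discriminants(x: np.ndarray, sigs: ClassSignatureSet) -> np.ndarray:
    """Stack of g_i(x) for an N×B matrix of spectral vectors → N×K."""
    n = x.shape[0]
    out = np.empty((n, len(sigs.signatures)))
    for j, s in enumerate(sigs.signatures):
        chol = _regularized_cholesky(s.covariance, s.class_id)
        logdet = 2.0 * np.sum(np.log(np.diag(chol)))
        y = solve_triangular(chol, (x - s.mean).T, lower=True)
        maha = np.sum(y * y, axis=0)
        out[:, j] = np.log(s.prior) - 0.5 * logdet - 0.5 * maha
    return out


def ml_classify(scene: MultibandScene, sigs: ClassSignatureSet) -> LabelRaster:
    """Per-pixel Gaussian maximum-likelihood classification.

    Every valid pixel is assigned to one of the signature classes (no reject
    class); discriminant ties break to the smallest class id; nodata → 0.
    """
    if sigs.n_bands != scene.n_bands:
        raise ValueError(
            f"signatures have {sigs.n_bands} bands, scene has {scene.n_bands}"
        )
    h, w = scene.shape
    x = scene.pixels.reshape(-1, scene.n_bands)
    g = _discriminants(x, sigs)
    # argmax with smallest-class-id tie break: class_ids ascending, so the
    # first maximal column wins as long as signatures are sorted by id.
    order = np.argsort(sigs.class_ids, kind="stable")
    g = g[:, order]
    cid = np.array(sigs.class_ids)[order]
    lab = cid[np.argmax(g, axis=1)].astype(np.int32).reshape(h, w)
    lab[scene.nodata_mask] = 0
    return LabelRaster(lab, sigs.class_scheme)


def majority_filter(classified: LabelRaster, window: int = 3) -> LabelRaster:
    """Windowed modal filter on a classified map.

    Each pixel becomes the modal class of its ``window``×``window``
    neighbourhood (truncated at edges).  If the centre pixel's class ties for
    the maximum count, the centre class is kept; other ties break to the
    smallest class id.  Label 0 pixels are ignored in the counts and stay 0.
    """
    if window % 2 == 0 or window < 3:
        raise ValueError("window must be an odd integer >= 3")
    lab = classified.labels
    classes = [int(c) for c in np.unique(lab) if c != 0]
    if not classes:
        return LabelRaster(lab.copy(), classified.class_scheme)
    kernel = np.ones((window, window))
    counts = np.stack(
        [
            ndimage.correlate((lab == c).astype(np.float64), kernel, mode="constant", cval=0.0)
            for c in classes
        ]
    ).round().astype(np.int64)
    best = counts.max(axis=0)
    # smallest class id among the argmax set
    arg = np.argmax(counts, axis=0)  # classes sorted ascending -> smallest wins
    out = np.array(classes, dtype=np.int32)[arg]
    # centre keeps its class on ties
    centre_idx = {c: i for i, c in enumerate(classes)}
    idx = np.vectorize(lambda c: centre_idx.get(int(c), -1))(lab)
    rows, cols = np.indices(lab.shape)
    valid = idx >= 0
    centre_count = np.zeros_like(best)
    centre_count[valid] = counts[idx[valid], rows[valid], cols[valid]]
    keep = valid & (centre_count == best)
    out[keep] = lab[keep]
    out[lab == 0] = 0
    return LabelRaster(out, classified.class_scheme)


def obc_classify(
    segmap: SegmentMap, scene: MultibandScene, sigs: ClassSignatureSet
) -> LabelRaster:
    """Object-based classification: ML discriminant on segment mean spectra.

    Every pixel of a segment takes the class of the segment's mean vector —
    the same discriminant as :func:`ml_classify` applied to segment means.
    """
    if segmap.segment_ids.shape != scene.shape:
        raise ValueError("segment map and scene dimensions differ")
    means = segment_means(segmap, scene)
    sids = sorted(means)
    x = np.stack([means[s] for s in sids])
    g = _discriminants(x, sigs)
    order = np.argsort(sigs.class_ids, kind="stable")
    cid = np.array(sigs.class_ids)[order]
    seg_class = cid[np.argmax(g[:, order], axis=1)]
    lut = np.zeros(int(segmap.segment_ids.max()) + 1, dtype=np.int32)
    for s, c in zip(sids, seg_class):
        lut[s] = c
    lab = lut[segmap.segment_ids]
    return LabelRaster(lab, sigs.class_scheme)
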