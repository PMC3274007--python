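"""Accuracy assessment: cluster sampling, error matrices, kappa.

Test units are square pixel clusters (default 9×9) placed so that each
cluster lies wholly inside a homogeneous reference region; a cluster's
reference class is the majority class within its window.  Each cluster
contributes one count to a K×K error matrix (rows = classified, columns =
reference) at the modal classified class within its window.  From the matrix
come overall accuracy, Cohen's kappa (K-HAT),

    κ = (p_o − p_e) / (1 − p_e),
    p_o = trace / N,     p_e = Σ_i row_i · col_i / N²,

and per-class user's (row) and producer's (column) accuracies.
"""

from __future__ import annotations

import csv
import warnings
from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import numpy as np
from scipy import ndimage

from .raster_io import ClassScheme, LabelRaster, default_class_scheme
from .segmentation import SegmentMap

__all__ = [
    "TestCluster",
    "ErrorMatrix",
    "sample_test_clusters",
    "allocate_test_counts",
    "build_error_matrix",
    "overall_accuracy",
    "kappa",
    "users_producers",
    "reference_error_matrices",
]


@dataclass
class TestCluster:
    """One square test unit: centre pixel, half-width, and reference class."""

    centre: tuple[int, int]
    half_width: int
    reference_class: int

    def window(self) -> tuple[slice, slice]:
        r, c = self.centre
        h = self.half_width
        return np.s_[r - h : r + h + 1, c - h : c + h + 1]


@dataclass
class ErrorMatrix:
    """K×K contingency counts; rows = classified, columns = reference."""

    counts: np.ndarray
    class_scheme: ClassScheme | None = None

    def __post_init__(self) -> None:
        m = np.asarray(self.counts)
        if m.ndim != 2 or m.shape[0] != m.shape[1]:
            raise ValueError(f"error matrix must be square, got {m.shape}")
        if np.any(m < 0):
            raise ValueError("error matrix entries must be non-negative")
        self.counts = m.astype(np.int64)

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def to_csv(self, path: str | Path) -> None:
        names = (
            self.class_scheme.abbreviations
            if self.class_scheme is not None
            else [str(i + 1) for i in range(self.counts.shape[0])]
        )
        with open(path, "w", newline="") as fh:
            w = csv.writer(fh)
            w.writerow(["classified\\reference", *names])
            for name, row in zip(names, self.counts):
                w.writerow([name, *row.tolist()])

    @classmethod
    def from_csv(cls, path: str | Path, class_scheme: ClassScheme | None = None) -> "ErrorMatrix":
        with open(path, newline="") as fh:
            rows = list(csv.reader(fh))
        data = np.array([[int(v) for v in r[1:]] for r in rows[1:]])
        return cls(data, class_scheme)


def reference_error_matrices() -> dict[str, ErrorMatrix]:
    """The published 9-class IKONOS case-study error matrices over 409 test
    clusters: per-pixel maximum likelihood ("pbc") and segment-majority
    fusion at color weight 0.5, scale 160 ("sbc").  Shipped as package data;
    used as exactness fixtures and by the reproduction script."""
    scheme = default_class_scheme()
    out = {}
    for key, fname in (("pbc", "pbc_error_matrix.csv"), ("sbc", "sbc_error_matrix.csv")):
        ref = resources.files("forestseg.data").joinpath(fname)
        with resources.as_file(ref) as p:
            out[key] = ErrorMatrix.from_csv(p, scheme)
    return out


def allocate_test_counts(
    reference: LabelRaster,
    per_class: int = 50,
    floor: int = 5,
) -> dict[int, int]:
    """Per-class test-cluster allocation following the rule of thumb of
    ``per_class`` units per class, adjusted by class area share (a class
    covering twice its equal share gets twice the budget) and floored at
    ``floor`` clusters per present class."""
    areas = np.bincount(reference.labels.ravel())
    out = {}
    npx = max(int(areas[1:].sum()), 1)
    k = int((areas[1:] > 0).sum())
    for cid in range(1, len(areas)):
        if areas[cid] == 0:
            continue
        out[cid] = max(floor, round(per_class * k * areas[cid] / npx))
    return out


def sample_test_clusters(
    reference: LabelRaster,
    n_per_class: dict[int, int],
    rng_seed: int = 0,
    half_width: int = 4,
    segmap: SegmentMap | None = None,
) -> list[TestCluster]:
    """Place random non-overlapping square clusters in homogeneous regions.

    Each cluster window must lie wholly inside a single reference-class
    region — and, when ``segmap`` is given, inside a single segment.  The
    cluster's reference class is the majority class of its window (here
    equal to the unique class, by construction).  Classes for which fewer
    than the requested number of placements exist are returned partially,
    with a warning; a class with zero candidates raises.
    """
    lab = reference.labels
    h, w = lab.shape
    side = 2 * half_width + 1
    lmin = ndimage.minimum_filter(lab, size=side, mode="constant", cval=-1)
    lmax = ndimage.maximum_filter(lab, size=side, mode="constant", cval=-1)
    homog = (lmin == lmax) & (lmin > 0)
    if segmap is not None:
        sids = segmap.segment_ids
        smin = ndimage.minimum_filter(sids, size=side, mode="constant", cval=-1)
        smax = ndimage.maximum_filter(sids, size=side, mode="constant", cval=-1)
        homog &= (smin == smax) & (smin > 0)
    homog[:half_width] = homog[-half_width:] = False
    homog[:, :half_width] = homog[:, -half_width:] = False

    rng = np.random.default_rng(rng_seed)
    taken = np.zeros((h, w), dtype=bool)
    clusters: list[TestCluster] = []
    for cid in sorted(n_per_class):
        want = n_per_class[cid]
        if want == 0:
            continue
        cand = np.argwhere(homog & (lab == cid))
        if cand.size == 0:
            raise ValueError(
                f"class {cid}: no homogeneous {side}×{side} window available"
            )
        cand = cand[rng.permutation(len(cand))]
        placed = 0
        for r, c in cand:
            if placed == want:
                break
            win = np.s_[r - half_width : r + half_width + 1,
                        c - half_width : c + half_width + 1]
            if taken[win].any():
                continue
            taken[win] = True
            clusters.append(TestCluster((int(r), int(c)), half_width, int(cid)))
            placed += 1
        if placed < want:
            warnings.warn(
                f"class {cid}: placed {placed}/{want} test clusters", stacklevel=2
            )
    return clusters


def _modal_class(window: np.ndarray) -> int:
    """Modal nonzero class of a window; smallest id on ties; 0 if empty."""
    counts = np.bincount(window.ravel())
    if counts.size <= 1 or counts[1:].max() == 0:
        return 0
    return int(np.argmax(counts[1:]) + 1)


def build_error_matrix(
    classified: LabelRaster,
    clusters: list[TestCluster],
    class_scheme: ClassScheme | None = None,
    unit: str = "cluster",
) -> ErrorMatrix:
    """Cross-tabulate classified vs reference class over the test clusters.

    ``unit="cluster"`` (default): each cluster contributes one count at
    (modal classified class within its window, reference class).
    ``unit="pixel"``: every labelled pixel of every cluster window
    contributes one count — the pixel-weighted accounting, which is more
    sensitive to scattered within-window misclassification.
    """
    if not clusters:
        raise ValueError("no test clusters given")
    if unit not in ("cluster", "pixel"):
        raise ValueError(f"unknown accounting unit {unit!r}")
    scheme = class_scheme or classified.class_scheme
    k = (
        len(scheme)
        if scheme is not None
        else max(
            int(classified.labels.max()),
            max(c.reference_class for c in clusters),
        )
    )
    m = np.zeros((k, k), dtype=np.int64)
    for cl in clusters:
        win = classified.labels[cl.window()]
        if unit == "cluster":
            pred = _modal_class(win)
            if pred == 0:
                continue  # window wholly unlabeled: contributes nothing
            m[pred - 1, cl.reference_class - 1] += 1
        else:
            counts = np.bincount(win.ravel(), minlength=k + 1)[1 : k + 1]
            m[:, cl.reference_class - 1] += counts
    return ErrorMatrix(m, scheme)


def overall_accuracy(m: ErrorMatrix) -> float:
    """Fraction of test units on the diagonal: trace / N."""
    n = m.total
    if n == 0:
        raise ValueError("empty error matrix")
    return float(np.trace(m.counts)) / n


def kappa(m: ErrorMatrix) -> float:
    """Cohen's kappa (K-HAT): chance-corrected agreement of the matrix."""
    n = m.total
    if n == 0:
        raise ValueError("empty error matrix")
    p_o = float(np.trace(m.counts)) / n
    rows = m.counts.sum(axis=1)
    cols = m.counts.sum(axis=0)
    p_e = float(rows @ cols) / (n * n)
    if p_e >= 1.0:
        raise ZeroDivisionError("kappa undefined: chance agreement p_e = 1")
    return (p_o - p_e) / (1.0 - p_e)


def users_producers(m: ErrorMatrix) -> dict[int, tuple[float, float]]:
    """Per-class (user's %, producer's %): diagonal over row / column sums.

    Classes with an empty row or column get NaN for the undefined ratio.
    """
    rows = m.counts.sum(axis=1).astype(float)
    cols = m.counts.sum(axis=0).astype(float)
    diag = np.diag(m.counts).astype(float)
    out = {}
    for i in range(m.counts.shape[0]):
        users = 100.0 * diag[i] / rows[i] if rows[i] > 0 else float("nan")
        prod = 100.0 * diag[i] / cols[i] if cols[i] > 0 else float("nan")
        out[i + 1] = (users, prod)
    return out
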