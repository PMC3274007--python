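"""Multiresolution region-growing segmentation.

Image objects start as single pixels and merge pairwise, bottom-up, under
the classic multiresolution homogeneity criterion: the cost of a merge is
the area-weighted increase in heterogeneity it causes, split between a
spectral ("color") term and a geometric ("shape") term,

    cost = w_color * Δh_color + (1 - w_color) * Δh_shape

    Δh_color = Σ_b  w_b * [ n_m σ_b(m) − ( n_a σ_b(a) + n_b σ_b(b) ) ]
    Δh_shape = w_compact * Δh_compact + (1 − w_compact) * Δh_smooth
    h_compact = l / √n          (perimeter over root area)
    h_smooth  = l / b           (perimeter over bounding-box perimeter)
    Δh_x      = n_m h_x(m) − ( n_a h_x(a) + n_b h_x(b) )

with σ the population standard deviation per band and l the perimeter
counted in exposed pixel edges.  A merge is allowed only while
``cost < scale²``: the scale parameter bounds the permitted heterogeneity
growth, so larger scales produce larger objects.

Merging follows local mutual best fitting: objects are visited in a seeded
pseudo-random order and an object merges with its cheapest neighbour only if
it is, reciprocally, that neighbour's cheapest neighbour.  Passes repeat
until a full pass performs no merge.  The visiting order is the only source
of randomness; a fixed seed makes the result bit-reproducible.

Segments are 4-connected; nodata pixels take id 0 and never merge.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from math import inf, sqrt
from pathlib import Path

import numpy as np

from .raster_io import MultibandScene

__all__ = [
    "SegmentationParams",
    "SegmentStats",
    "SegmentMap",
    "init_segments",
    "merge_cost",
    "segment",
    "segment_means",
]


@dataclass
class SegmentationParams:
    """Scale and weight parameters of the homogeneity criterion.

    scale : merge threshold parameter; merges require cost < scale².
    w_color : weight of the spectral term (shape weight is 1 − w_color).
    w_compact : weight of compactness within the shape term
        (smoothness weight is 1 − w_compact).
    band_weights : non-negative per-band weights of the spectral term;
        defaults to 1 for every band.
    """

    scale: float
    w_color: float = 0.5
    w_compact: float = 0.5
    band_weights: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.scale <= 0:
            raise ValueError("scale must be positive")
        if not (0.0 <= self.w_color <= 1.0):
            raise ValueError("w_color must be in [0, 1]")
        if not (0.0 <= self.w_compact <= 1.0):
            raise ValueError("w_compact must be in [0, 1]")
        if self.band_weights is not None:
            bw = np.asarray(self.band_weights, dtype=np.float64)
            if np.any(bw < 0) or not np.any(bw > 0):
                raise ValueError("band_weights must be non-negative, not all zero")
            self.band_weights = bw


@dataclass
class SegmentStats:
    """Incrementally mergeable per-segment statistics.

    Everything the merge cost needs is derivable from pixel count, per-band
    sums and sums of squares, the perimeter (exposed pixel edges) and the
    bounding box — no pixel revisit, except that the merged perimeter needs
    the shared-edge count between the two segments.
    """

    n: int
    band_sum: np.ndarray
    band_sumsq: np.ndarray
    perimeter_l: int
    bbox: tuple[int, int, int, int]  # row_min, row_max, col_min, col_max (inclusive)

    def sigma(self) -> np.ndarray:
        """Population standard deviation per band."""
        mean = self.band_sum / self.n
        var = self.band_sumsq / self.n - mean * mean
        return np.sqrt(np.maximum(var, 0.0))

    def mean(self) -> np.ndarray:
        return self.band_sum / self.n

    @property
    def bbox_perimeter(self) -> int:
        r0, r1, c0, c1 = self.bbox
        return 2 * ((r1 - r0 + 1) + (c1 - c0 + 1))

    def merged_with(self, other: "SegmentStats", shared_edges: int) -> "SegmentStats":
        """Stats of the union, given the number of shared boundary edges."""
        r0 = min(self.bbox[0], other.bbox[0])
        r1 = max(self.bbox[1], other.bbox[1])
        c0 = min(self.bbox[2], other.bbox[2])
        c1 = max(self.bbox[3], other.bbox[3])
        return SegmentStats(
            n=self.n + other.n,
            band_sum=self.band_sum + other.band_sum,
            band_sumsq=self.band_sumsq + other.band_sumsq,
            perimeter_l=self.perimeter_l + other.perimeter_l - 2 * shared_edges,
            bbox=(r0, r1, c0, c1),
        )


@dataclass
class SegmentMap:
    """A labelled partition of the raster into connected segments.

    segment_ids : H×W int array, ids 1..K (0 reserved for nodata).
    stats : id → SegmentStats.
    adjacency : id → set of neighbouring ids (symmetric).
    """

    segment_ids: np.ndarray
    stats: dict[int, SegmentStats]
    adjacency: dict[int, set[int]] = field(default_factory=dict)

    @property
    def n_segments(self) -> int:
        return len(self.stats)

    def ids(self) -> list[int]:
        return sorted(self.stats)

    def to_csv(self, path: str | Path, band_names: list[str] | None = None) -> None:
        """Export per-segment statistics (id, n, per-band mean, perimeter)."""
        import csv

        first = next(iter(self.stats.values()))
        b = first.band_sum.shape[0]
        names = band_names if band_names is not None else [f"band{i+1}" for i in range(b)]
        with open(path, "w", newline="") as fh:
            w = csv.writer(fh)
            w.writerow(["id", "n", *[f"mean_{nm}" for nm in names], "perimeter"])
            for sid in self.ids():
                st = self.stats[sid]
                w.writerow([sid, st.n, *st.mean().tolist(), st.perimeter_l])


def init_segments(scene: MultibandScene) -> SegmentMap:
    """One single-pixel segment per valid pixel; exact stats, 4-adjacency."""
    h, w = scene.shape
    ids = np.arange(1, h * w + 1, dtype=np.int64).reshape(h, w)
    ids[scene.nodata_mask] = 0
    stats: dict[int, SegmentStats] = {}
    adjacency: dict[int, set[int]] = {}
    px = scene.pixels
    for r in range(h):
        for c in range(w):
            sid = int(ids[r, c])
            if sid == 0:
                continue
            v = px[r, c]
            stats[sid] = SegmentStats(
                n=1,
                band_sum=v.copy(),
                band_sumsq=v * v,
                perimeter_l=4,
                bbox=(r, r, c, c),
            )
            nbrs = set()
            for rr, cc in ((r - 1, c), (r + 1, c), (r, c - 1), (r, c + 1)):
                if 0 <= rr < h and 0 <= cc < w and ids[rr, cc] != 0:
                    nbrs.add(int(ids[rr, cc]))
            adjacency[sid] = nbrs
    return SegmentMap(ids, stats, adjacency)


def merge_cost(
    a: SegmentStats,
    b: SegmentStats,
    params: SegmentationParams,
    shared_edges: int = 1,
) -> float:
    """Heterogeneity increase caused by merging segments ``a`` and ``b``.

    ``shared_edges`` is the number of pixel edges on the common boundary
    (needed only for the merged perimeter; spectral cost ignores it).
    """
    m = a.merged_with(b, shared_edges)
    cost = 0.0
    if params.w_color > 0.0:
        bw = params.band_weights
        if bw is None:
            bw = np.ones_like(a.band_sum)
        d_color = float(
            np.dot(bw, m.n * m.sigma() - (a.n * a.sigma() + b.n * b.sigma()))
        )
        cost += params.w_color * d_color
    w_shape = 1.0 - params.w_color
    if w_shape > 0.0:
        d_compact = (
            m.n * m.perimeter_l / sqrt(m.n)
            - a.n * a.perimeter_l / sqrt(a.n)
            - b.n * b.perimeter_l / sqrt(b.n)
        )
        d_smooth = (
            m.n * m.perimeter_l / m.bbox_perimeter
            - a.n * a.perimeter_l / a.bbox_perimeter
            - b.n * b.perimeter_l / b.bbox_perimeter
        )
        cost += w_shape * (
            params.w_compact * d_compact + (1.0 - params.w_compact) * d_smooth
        )
    return cost


# ---------------------------------------------------------------------------
# The merge engine.  Internals use flat python dicts keyed by segment id;
# neighbour maps carry shared-edge counts so merged perimeters are exact.
# ---------------------------------------------------------------------------


class _Engine:
    def __init__(self, scene: MultibandScene, params: SegmentationParams):
        h, w = scene.shape
        self.h, self.w = h, w
        self.params = params
        b = scene.n_bands
        bw = params.band_weights
        self.bw = (np.ones(b) if bw is None else bw).tolist()
        px = scene.pixels
        nod = scene.nodata_mask
        # per-segment state, keyed by id (pixel index + 1 initially)
        self.n: dict[int, int] = {}
        self.s: dict[int, list[float]] = {}
        self.ss: dict[int, list[float]] = {}
        self.per: dict[int, int] = {}
        self.bbox: dict[int, list[int]] = {}
        self.nbr: dict[int, dict[int, int]] = {}  # id -> {nbr id: shared edges}
        self.parent: dict[int, int] = {}
        for r in range(h):
            base = r * w
            for c in range(w):
                if nod[r, c]:
                    continue
                sid = base + c + 1
                v = px[r, c]
                self.n[sid] = 1
                self.s[sid] = v.tolist()
                self.ss[sid] = (v * v).tolist()
                self.per[sid] = 4
                self.bbox[sid] = [r, r, c, c]
                d = {}
                if r > 0 and not nod[r - 1, c]:
                    d[sid - w] = 1
                if r < h - 1 and not nod[r + 1, c]:
                    d[sid + w] = 1
                if c > 0 and not nod[r, c - 1]:
                    d[sid - 1] = 1
                if c < w - 1 and not nod[r, c + 1]:
                    d[sid + 1] = 1
                self.nbr[sid] = d
        self.w_color = params.w_color
        self.w_shape = 1.0 - params.w_color
        self.w_comp = params.w_compact
        self.threshold = params.scale * params.scale
        self.best: dict[int, tuple[float, int]] = {}  # cache: id -> (cost, nbr)

    def cost(self, a: int, b: int, shared: int) -> float:
        na, nb = self.n[a], self.n[b]
        nm = na + nb
        cost = 0.0
        if self.w_color > 0.0:
            sa, sb = self.s[a], self.s[b]
            ssa, ssb = self.ss[a], self.ss[b]
            d_color = 0.0
            for k, wk in enumerate(self.bw):
                if wk == 0.0:
                    continue
                su = sa[k] + sb[k]
                sq = ssa[k] + ssb[k]
                vm = sq / nm - (su / nm) ** 2
                sig_m = sqrt(vm) if vm > 0.0 else 0.0
                term = nm * sig_m
                if na > 1:
                    va = ssa[k] / na - (sa[k] / na) ** 2
                    if va > 0.0:
                        term -= na * sqrt(va)
                if nb > 1:
                    vb = ssb[k] / nb - (sb[k] / nb) ** 2
                    if vb > 0.0:
                        term -= nb * sqrt(vb)
                d_color += wk * term
            cost += self.w_color * d_color
        if self.w_shape > 0.0:
            la, lb = self.per[a], self.per[b]
            lm = la + lb - 2 * shared
            ba, bb = self.bbox[a], self.bbox[b]
            r0 = ba[0] if ba[0] < bb[0] else bb[0]
            r1 = ba[1] if ba[1] > bb[1] else bb[1]
            c0 = ba[2] if ba[2] < bb[2] else bb[2]
            c1 = ba[3] if ba[3] > bb[3] else bb[3]
            pm = 2 * (r1 - r0 + c1 - c0 + 2)
            pa = 2 * (ba[1] - ba[0] + ba[3] - ba[2] + 2)
            pb = 2 * (bb[1] - bb[0] + bb[3] - bb[2] + 2)
            d_comp = nm * lm / sqrt(nm) - na * la / sqrt(na) - nb * lb / sqrt(nb)
            d_smooth = nm * lm / pm - na * la / pa - nb * lb / pb
            cost += self.w_shape * (
                self.w_comp * d_comp + (1.0 - self.w_comp) * d_smooth
            )
        return cost

    def best_of(self, a: int) -> tuple[float, int]:
        cached = self.best.get(a)
        if cached is not None:
            return cached
        bc, bn = inf, 0
        for b, shared in self.nbr[a].items():
            c = self.cost(a, b, shared)
            if c < bc or (c == bc and b < bn):
                bc, bn = c, b
        self.best[a] = (bc, bn)
        return bc, bn

    def merge(self, a: int, b: int) -> int:
        """Merge b into a (a < b assumed); returns surviving id."""
        if b < a:
            a, b = b, a
        shared = self.nbr[a].pop(b)
        self.nbr[b].pop(a)
        self.n[a] += self.n[b]
        sa, sb = self.s[a], self.s[b]
        ssa, ssb = self.ss[a], self.ss[b]
        for k in range(len(sa)):
            sa[k] += sb[k]
            ssa[k] += ssb[k]
        self.per[a] = self.per[a] + self.per[b] - 2 * shared
        ba, bb = self.bbox[a], self.bbox[b]
        if bb[0] < ba[0]:
            ba[0] = bb[0]
        if bb[1] > ba[1]:
            ba[1] = bb[1]
        if bb[2] < ba[2]:
            ba[2] = bb[2]
        if bb[3] > ba[3]:
            ba[3] = bb[3]
        for x, cnt in self.nbr[b].items():
            self.nbr[x].pop(b)
            self.nbr[x][a] = self.nbr[x].get(a, 0) + cnt
            self.nbr[a][x] = self.nbr[a].get(x, 0) + cnt
            self.best.pop(x, None)
        self.best.pop(a, None)
        for x in self.nbr[a]:
            self.best.pop(x, None)
        del self.n[b], self.s[b], self.ss[b], self.per[b], self.bbox[b], self.nbr[b]
        self.parent[b] = a
        return a

    def find(self, sid: int) -> int:
        root = sid
        while root in self.parent:
            root = self.parent[root]
        while sid in self.parent:
            self.parent[sid], sid = root, self.parent[sid]
        return root

    def run(self, rng: np.random.Generator) -> None:
        while True:
            alive = sorted(self.n)
            order = rng.permutation(len(alive))
            merged_any = False
            for idx in order:
                a = alive[idx]
                if a not in self.n:
                    continue
                ca, na_ = self.best_of(a)
                if na_ == 0 or ca >= self.threshold:
                    continue
                cb, nb_ = self.best_of(na_)
                if nb_ != a:
                    continue
                self.merge(a, na_)
                merged_any = True
            if not merged_any:
                break


def segment(
    scene: MultibandScene, params: SegmentationParams, rng_seed: int = 0
) -> SegmentMap:
    """Segment a scene by iterative local mutual-best-fitting merging.

    Deterministic for fixed inputs and seed.  Output ids are 1..K in
    row-major order of each segment's first pixel; nodata pixels carry 0.
    """
    eng = _Engine(scene, params)
    eng.run(np.random.default_rng(rng_seed))

    h, w = scene.shape
    ids = np.zeros((h, w), dtype=np.int64)
    relabel: dict[int, int] = {}
    stats: dict[int, SegmentStats] = {}
    nxt = 1
    nod = scene.nodata_mask
    for r in range(h):
        base = r * w
        for c in range(w):
            if nod[r, c]:
                continue
            root = eng.find(base + c + 1)
            sid = relabel.get(root)
            if sid is None:
                sid = relabel[root] = nxt
                nxt += 1
                stats[sid] = SegmentStats(
                    n=eng.n[root],
                    band_sum=np.array(eng.s[root]),
                    band_sumsq=np.array(eng.ss[root]),
                    perimeter_l=eng.per[root],
                    bbox=tuple(eng.bbox[root]),
                )
            ids[r, c] = sid
    adjacency: dict[int, set[int]] = {sid: set() for sid in stats}
    for root, d in eng.nbr.items():
        sid = relabel[root]
        for x in d:
            adjacency[sid].add(relabel[x])
    return SegmentMap(ids, stats, adjacency)


def segment_means(segmap: SegmentMap, scene: MultibandScene) -> dict[int, np.ndarray]:
    """Exact per-segment per-band mean spectral vectors."""
    if segmap.segment_ids.shape != scene.shape:
        raise ValueError("segment map and scene dimensions differ")
    ids = segmap.segment_ids
    b = scene.n_bands
    k = int(ids.max())
    counts = np.bincount(ids.ravel(), minlength=k + 1).astype(np.float64)
    out: dict[int, np.ndarray] = {}
    sums = np.zeros((k + 1, b))
    flat = ids.ravel()
    for j in range(b):
        sums[:, j] = np.bincount(flat, weights=scene.pixels[:, :, j].ravel(), minlength=k + 1)
    for sid in segmap.stats:
        out[sid] = sums[sid] / counts[sid]
    return out
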