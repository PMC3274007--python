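"""Experiment orchestration: weight-case × scale sweeps and method comparison.

A sweep case names a pair of convex weight splits in the compact notation
``CₓSₓ(MₓOₓ)`` — C = color, S = shape, M = smoothness, O = compactness,
with subscripts coding the weights 1 → 0.1, 3 → 0.25, 5 → 0.5, 7 → 0.75,
9 → 0.9 (C + S = 1 and M + O = 1).  For each (case, scale) cell the sweep
segments the scene, fuses the per-pixel maximum-likelihood map by segment
majority, scores the result on a fixed shared set of test clusters, and
records the kappa; per-pixel (PBC), 3×3 majority-filter, and object-based
(OBC) baselines are scored once on the same clusters for a paired
comparison.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .accuracy import (
    allocate_test_counts,
    build_error_matrix,
    kappa,
    overall_accuracy,
    sample_test_clusters,
)
from .classify import extract_signatures, majority_filter, ml_classify, obc_classify
from .fusion import segment_majority
from .raster_io import LabelRaster, MultibandScene
from .segmentation import SegmentationParams, segment

__all__ = [
    "SweepCase",
    "SweepResult",
    "TABLE_CASES",
    "parse_case_label",
    "run_sweep",
    "find_plateau",
]

log = logging.getLogger(__name__)

_SUBSCRIPT_WEIGHT = {"1": 0.1, "3": 0.25, "5": 0.5, "7": 0.75, "9": 0.9}
_LABEL_RE = re.compile(r"^C([13579])S([13579])\(M([13579])O([13579])\)$")

#: The nine weight cases of the original three-step design.
TABLE_CASES = [
    "C9S1(M9O1)",
    "C9S1(M1O9)",
    "C1S9(M9O1)",
    "C1S9(M1O9)",
    "C5S5(M5O5)",
    "C5S5(M9O1)",
    "C5S5(M1O9)",
    "C7S3(M5O5)",
    "C3S7(M5O5)",
]


@dataclass
class SweepCase:
    """A weight case: everything of SegmentationParams except the scale."""

    label: str
    w_color: float
    w_compact: float
    band_weights: np.ndarray | None = None

    def params(self, scale: float) -> SegmentationParams:
        return SegmentationParams(
            scale=scale,
            w_color=self.w_color,
            w_compact=self.w_compact,
            band_weights=self.band_weights,
        )


def parse_case_label(label: str) -> SweepCase:
    """Decode a ``CxSx(MxOx)`` weight label into a SweepCase.

    The C/S and M/O subscripts must code complementary weights (sum 1).
    """
    m = _LABEL_RE.match(label.strip())
    if m is None:
        raise ValueError(f"malformed case label {label!r}; expected e.g. 'C9S1(M9O1)'")
    c, s, mm, o = (_SUBSCRIPT_WEIGHT[d] for d in m.groups())
    if abs(c + s - 1.0) > 1e-9:
        raise ValueError(f"{label}: color {c} + shape {s} must sum to 1")
    if abs(mm + o - 1.0) > 1e-9:
        raise ValueError(f"{label}: smoothness {mm} + compactness {o} must sum to 1")
    return SweepCase(label=label, w_color=c, w_compact=o)


@dataclass
class SweepResult:
    """Tidy result rows of a sweep plus the shared method-comparison rows.

    ``rows``: one row per (case, scale) with columns method/case/scale/
    n_segments/overall/kappa; the four-method comparison appears as
    method ∈ {pbc, majority, obc, sbc}.
    """

    rows: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(
            columns=["method", "case", "scale", "n_segments", "overall", "kappa"]
        )
    )

    def sbc_rows(self) -> pd.DataFrame:
        return self.rows[self.rows["method"] == "sbc"]

    def to_csv(self, path) -> None:
        self.rows.to_csv(path, index=False)


def run_sweep(
    scene: MultibandScene,
    training: LabelRaster,
    reference: LabelRaster,
    cases: list[SweepCase | str],
    scales: list[float],
    rng_seed: int = 0,
    clusters_per_class: int = 5,
    obc_scale: float | None = 160.0,
    matrix_unit: str = "pixel",
    signature_trim: float | None = 0.999,
) -> SweepResult:
    """Full experiment over cases × scales with shared test clusters.

    One test-cluster sample (drawn from the reference map with ``rng_seed``)
    is reused for every cell and every method, giving a paired comparison.
    PBC and its 3×3 majority filter are scored once; OBC is scored once on
    the first case's segmentation at the scale nearest ``obc_scale``.
    Accuracy uses the pixel-weighted accounting within the shared clusters
    by default (``matrix_unit``); signatures are shadow-trimmed
    (``signature_trim``, see :func:`extract_signatures`).  A failing cell is
    logged and skipped, not fatal.  Deterministic per seed.
    """
    if any(s <= 0 for s in scales):
        raise ValueError("scales must be positive")
    cases = [parse_case_label(c) if isinstance(c, str) else c for c in cases]
    sigs = extract_signatures(scene, training, trim_outliers=signature_trim)
    pbc = ml_classify(scene, sigs)
    counts = allocate_test_counts(reference, per_class=clusters_per_class, floor=2)
    clusters = sample_test_clusters(reference, counts, rng_seed=rng_seed)
    log.info("sampled %d shared test clusters", len(clusters))

    records: list[dict] = []

    def score(labelled: LabelRaster) -> tuple[float, float]:
        m = build_error_matrix(labelled, clusters, reference.class_scheme,
                               unit=matrix_unit)
        return overall_accuracy(m), kappa(m)

    oa, k = score(pbc)
    records.append(dict(method="pbc", case="", scale=np.nan, n_segments=np.nan,
                        overall=oa, kappa=k))
    oa, k = score(majority_filter(pbc))
    records.append(dict(method="majority", case="", scale=np.nan, n_segments=np.nan,
                        overall=oa, kappa=k))

    obc_target = None
    if obc_scale is not None and cases and scales:
        obc_target = (cases[0].label, min(scales, key=lambda s: abs(s - obc_scale)))

    for case in cases:
        for scale in scales:
            try:
                segmap = segment(scene, case.params(scale), rng_seed=rng_seed)
                sbc = segment_majority(pbc, segmap)
                oa, k = score(sbc)
                records.append(
                    dict(method="sbc", case=case.label, scale=scale,
                         n_segments=segmap.n_segments, overall=oa, kappa=k)
                )
                log.info("case %s scale %g: %d segments, kappa %.3f",
                         case.label, scale, segmap.n_segments, k)
                if obc_target == (case.label, scale):
                    oa, k = score(obc_classify(segmap, scene, sigs))
                    records.append(
                        dict(method="obc", case=case.label, scale=scale,
                             n_segments=segmap.n_segments, overall=oa, kappa=k)
                    )
            except Exception:
                log.exception("case %s scale %g failed; skipping cell",
                              case.label, scale)
    return SweepResult(pd.DataFrame.from_records(records))


def find_plateau(result: SweepResult, tolerance: float = 0.02) -> set[tuple[str, float]]:
    """Cells of the sweep whose kappa is within ``tolerance`` of the maximum.

    Returns (case label, scale) pairs over the segment-majority rows (or all
    rows when no sbc rows exist, e.g. a single-method result).
    """
    rows = result.sbc_rows()
    if rows.empty:
        rows = result.rows
    if rows.empty:
        raise ValueError("empty sweep result")
    kmax = rows["kappa"].max()
    sel = rows[rows["kappa"] >= kmax - tolerance]
    return {(str(r["case"]), float(r["scale"])) for _, r in sel.iterrows()}
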