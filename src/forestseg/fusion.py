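"""Segment-based classification (SBC): segment-majority fusion.

The fusion step that defines SBC: for every segment, count the per-pixel
classification labels inside it and reassign all its pixels to the plurality
class.  This removes the salt-and-pepper scatter of per-pixel maximum
likelihood while keeping the per-pixel evidence that object-level mean
spectra discard.
"""

from __future__ import annotations

import numpy as np

from .raster_io import LabelRaster
from .segmentation import SegmentMap

__all__ = ["segment_majority"]


def segment_majority(classified: LabelRaster, segmap: SegmentMap) -> LabelRaster:
    """Reassign every pixel of each segment to the segment's plurality class.

    "Majority" means plurality: the modal class of the per-pixel labels in
    the segment, with ties broken by the smallest class id.  Pixels labelled
    0 are excluded from the counts; a segment containing only 0-labelled
    pixels keeps label 0.
    """
    if classified.shape != segmap.segment_ids.shape:
        raise ValueError("classified map and segment map dimensions differ")
    lab = classified.labels
    ids = segmap.segment_ids
    k = int(lab.max())
    nseg = int(ids.max())
    # joint histogram over (segment, class), including class 0 and segment 0
    joint = np.bincount(
        (ids.astype(np.int64) * (k + 1) + lab).ravel(),
        minlength=(nseg + 1) * (k + 1),
    ).reshape(nseg + 1, k + 1)
    counts = joint[:, 1:]  # drop class 0 from the vote
    winner = np.where(
        counts.sum(axis=1) > 0, np.argmax(counts, axis=1) + 1, 0
    ).astype(np.int32)  # argmax takes the first (smallest id) on ties
    winner[0] = 0
    out = winner[ids]
    out[ids == 0] = 0
    return LabelRaster(out, classified.class_scheme)
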