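"""Internal geometric primitives shared by segmentation and synthesis.

The central primitive is the *nearest-nucleus border distance* field: for
every background pixel within a cutoff of any nucleus, the Euclidean
distance (in pixels, between pixel centres) to the closest pixel of each
nearby nucleus, reduced to the best and second-best owner.  Ring masks,
contested-pixel resolution and perinuclear placement in the synthetic
generator all derive from it.

Ties in ownership (exactly equal distances to two nuclei) go to the lower
label index; this is implemented by iterating labels in ascending order and
updating ownership only on strict improvement.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.ndimage as ndi


@dataclass
class NearestNucleusMaps:
    """Per-pixel nearest-nucleus summary within ``max_dist_px`` of any nucleus.

    ``best_dist``/``best_label`` give the distance to and label of the
    closest nucleus (inf / 0 where no nucleus is within the cutoff or the
    pixel is inside a nucleus).  ``second_dist`` is the distance to the
    closest *other* nucleus.  ``candidates`` maps each label to the flat
    indices and distances of the background pixels within the cutoff of
    that label's border.
    """

    best_dist: np.ndarray
    best_label: np.ndarray
    second_dist: np.ndarray
    candidates: dict[int, tuple[np.ndarray, np.ndarray]]
    max_dist_px: float
    shape: tuple[int, int]


def _expanded_slices(sl: tuple[slice, slice], pad: int, shape: tuple[int, int]) -> tuple[slice, slice]:
    r, c = sl
    return (
        slice(max(r.start - pad, 0), min(r.stop + pad, shape[0])),
        slice(max(c.start - pad, 0), min(c.stop + pad, shape[1])),
    )


def nearest_nucleus_maps(labels: np.ndarray, max_dist_px: float) -> NearestNucleusMaps:
    """Compute nearest- and second-nearest-nucleus border distances.

    Works label-by-label on padded bounding boxes, so cost scales with the
    total dilated nucleus area rather than ``n_labels * image size``.
    """
    shape = labels.shape
    best_dist = np.full(shape, np.inf, dtype=np.float64)
    best_label = np.zeros(shape, dtype=np.int32)
    second_dist = np.full(shape, np.inf, dtype=np.float64)
    candidates: dict[int, tuple[np.ndarray, np.ndarray]] = {}

    present = np.unique(labels)
    present = present[present > 0]
    if present.size == 0:
        return NearestNucleusMaps(best_dist, best_label, second_dist, {}, max_dist_px, shape)

    objects = ndi.find_objects(labels)
    pad = int(np.ceil(max_dist_px)) + 2
    background = labels == 0

    for lab in present.tolist():
        sl = objects[lab - 1]
        if sl is None:  # sparse label id with no pixels
            continue
        sl2 = _expanded_slices(sl, pad, shape)
        crop = labels[sl2]
        # distance from every non-`lab` pixel to the nearest `lab` pixel
        dist = ndi.distance_transform_edt(crop != lab)
        cand = (crop == 0) & (dist > 0) & (dist <= max_dist_px)

        rows, cols = np.nonzero(cand)
        flat = (rows + sl2[0].start) * shape[1] + (cols + sl2[1].start)
        dvals = dist[cand]
        candidates[lab] = (flat, dvals)

        v_best = best_dist[sl2]
        v_blab = best_label[sl2]
        v_second = second_dist[sl2]
        improve = cand & (dist < v_best)
        v_second[improve] = v_best[improve]
        v_blab[improve] = lab
        v_best[improve] = dist[improve]
        runner_up = cand & ~improve & (dist < v_second)
        v_second[runner_up] = dist[runner_up]

    # pixels inside any nucleus never receive ownership
    best_dist[~background] = np.inf
    best_label[~background] = 0
    second_dist[~background] = np.inf
    return NearestNucleusMaps(best_dist, best_label, second_dist, candidates, max_dist_px, shape)
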