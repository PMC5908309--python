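"""Per-cell marker classification.

Four boolean calls are made for every segmented cell:

* **cytoplasmic CC3** — mean CC3 intensity over the cell's ring mask above
  an intensity threshold (the legacy, low-specificity apoptosis readout);
* **CC3(bleb)** — at least ``min_puncta_per_cell`` (default 2) CC3 puncta
  detected in the ring mask, puncta being thresholded 8-connected spots
  with area inside the 0.2-5 um^2 window (the high-specificity readout,
  a proxy for apoptotic membrane blebbing);
* **gammaH2AX** — mean nuclear gammaH2AX intensity above a threshold,
  which can be chosen automatically from the distribution of per-nucleus
  means;
* **colocalization** — gammaH2AX-positive AND CC3(bleb)-positive, the
  assay's apoptosis-associated DNA-damage call.

All positivity rules use strict ``>`` comparisons, and all use *mean*
(not integrated) intensity so calls are independent of nuclear area
within the 50-200 um^2 retention window.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.ndimage as ndi
from skimage.filters import difference_of_gaussians

from .segmentation import CellGeometry, NucleusLabelMap

_S8 = np.ones((3, 3), dtype=bool)


class MarkerCallError(ValueError):
    pass


@dataclass(frozen=True)
class SpotParams:
    """Parameters of the CC3 spot (punctum) detector.

    ``expected_spot_area_um2`` is the nominal punctum footprint (0.9 um^2);
    it sets the scale of the optional band-pass prefilter.  Spots with
    thresholded area outside ``[min_spot_area_um2, max_spot_area_um2]``
    are filtered out.  ``spot_intensity_threshold`` is either an absolute
    intensity or the string ``"auto"`` (background median + k * scaled MAD
    of non-ring pixels).  A cell is CC3(bleb)+ when it owns at least
    ``min_puncta_per_cell`` retained puncta.
    """

    expected_spot_area_um2: float = 0.9
    min_spot_area_um2: float = 0.2
    max_spot_area_um2: float = 5.0
    spot_intensity_threshold: float | str = 4000.0
    min_puncta_per_cell: int = 2
    auto_threshold_k: float = 6.0
    bandpass: bool = False

    def __post_init__(self) -> None:
        if not self.min_spot_area_um2 < self.expected_spot_area_um2 < self.max_spot_area_um2:
            raise MarkerCallError(
                "SpotParams requires min_spot_area_um2 < expected_spot_area_um2 "
                f"< max_spot_area_um2, got ({self.min_spot_area_um2}, "
                f"{self.expected_spot_area_um2}, {self.max_spot_area_um2})"
            )
        if self.min_puncta_per_cell < 1:
            raise MarkerCallError("min_puncta_per_cell must be >= 1")
        if isinstance(self.spot_intensity_threshold, str) and self.spot_intensity_threshold != "auto":
            raise MarkerCallError(
                f"spot_intensity_threshold must be a number or 'auto', got "
                f"{self.spot_intensity_threshold!r}"
            )


@dataclass(frozen=True)
class Punctum:
    """One detected CC3 spot, assigned to the cell whose ring owns it."""

    cell_label: int
    centroid: tuple[float, float]
    area_um2: float
    mean_intensity: float


@dataclass
class CellCall:
    """Per-cell marker calls; ``coloc_pos == gh2ax_pos and cc3_bleb_pos``."""

    cell_label: int
    nuclear_area_um2: float
    cyto_cc3_mean: float
    cyto_cc3_pos: bool
    puncta_count: int
    cc3_bleb_pos: bool
    gh2ax_mean: float
    gh2ax_pos: bool
    coloc_pos: bool = False


def ring_owner_map(cells: list[CellGeometry]) -> np.ndarray:
    if not cells:
        raise MarkerCallError("no cells supplied")
    owner = np.zeros(cells[0].shape, dtype=np.int32)
    for cell in cells:
        owner[cell.ring_rc] = cell.label
    return owner


def classify_cytoplasmic_cc3(
    cells: list[CellGeometry],
    cc3: np.ndarray,
    threshold: float,
) -> tuple[dict[int, float], dict[int, bool], list[int]]:
    """Mean ring CC3 intensity and positivity (mean > threshold) per cell.

    Cells with an empty ring mask cannot be evaluated; their labels are
    returned separately so callers can exclude them from denominators with
    an auditable count.
    """
    if threshold < 0:
        raise MarkerCallError(f"threshold must be nonnegative, got {threshold}")
    means: dict[int, float] = {}
    positive: dict[int, bool] = {}
    unevaluable: list[int] = []
    img = np.asarray(cc3)
    for cell in cells:
        if cell.ring_size == 0:
            unevaluable.append(cell.label)
            continue
        m = float(img[cell.ring_rc].mean())
        means[cell.label] = m
        positive[cell.label] = m > threshold
    return means, positive, unevaluable


def auto_background_threshold(
    image: np.ndarray, foreground_owner: np.ndarray, k: float = 6.0
) -> float:
    """Robust automatic intensity threshold: median + k * (scaled MAD).

    Computed over pixels outside every ring mask, i.e. the local
    background the spots must rise above.
    """
    bg = np.asarray(image, dtype=np.float64)[foreground_owner == 0]
    if bg.size == 0:
        raise MarkerCallError("no background pixels available for auto threshold")
    med = float(np.median(bg))
    mad = float(np.median(np.abs(bg - med)))
    return med + k * 1.4826 * mad


def detect_cc3_puncta(
    cells: list[CellGeometry],
    cc3: np.ndarray,
    params: SpotParams,
    microns_per_pixel: float,
) -> list[Punctum]:
    """Detect CC3 puncta inside the cytoplasmic ring masks.

    The detector thresholds the CC3 raster restricted to the union of ring
    masks, labels 8-connected components, and retains components with area
    in ``[min_spot_area_um2, max_spot_area_um2]``.  Each punctum belongs to
    the cell whose ring contains its centroid (falling back to the
    majority ring owner of its pixels).  Nuclear CC3 spots are ignored by
    construction: only simulated-cytoplasm pixels are searched.
    """
    owner = ring_owner_map(cells)
    img = np.asarray(cc3, dtype=np.float64)
    if params.spot_intensity_threshold == "auto":
        threshold = auto_background_threshold(img, owner, params.auto_threshold_k)
    else:
        threshold = float(params.spot_intensity_threshold)

    work = img
    if params.bandpass:
        # band-pass tuned so the response peaks for disks of the expected area
        r0_px = np.sqrt(params.expected_spot_area_um2 / np.pi) / microns_per_pixel
        work = difference_of_gaussians(img, max(r0_px / 2.0, 0.5), 2.0 * r0_px)
        work = work * (img.max() / max(work.max(), 1e-12))

    masked = np.where(owner > 0, work, 0.0)
    binary = masked > threshold
    lab, n = ndi.label(binary, structure=_S8)
    if n == 0:
        return []

    px_area = microns_per_pixel**2
    puncta: list[Punctum] = []
    slices = ndi.find_objects(lab)
    for i, sl in enumerate(slices, start=1):
        comp = lab[sl] == i
        area = float(comp.sum()) * px_area
        if not params.min_spot_area_um2 <= area <= params.max_spot_area_um2:
            continue
        rows, cols = np.nonzero(comp)
        rows = rows + sl[0].start
        cols = cols + sl[1].start
        cr, cc = float(rows.mean()), float(cols.mean())
        owner_at_centroid = int(owner[int(round(cr)), int(round(cc))])
        if owner_at_centroid > 0:
            cell_label = owner_at_centroid
        else:
            owners = owner[rows, cols]
            vals, counts = np.unique(owners[owners > 0], return_counts=True)
            cell_label = int(vals[np.argmax(counts)])  # ties -> lower label
        puncta.append(
            Punctum(
                cell_label=cell_label,
                centroid=(cr, cc),
                area_um2=area,
                mean_intensity=float(img[rows, cols].mean()),
            )
        )
    return puncta


def count_puncta(puncta: list[Punctum], cells: list[CellGeometry]) -> dict[int, int]:
    counts = {cell.label: 0 for cell in cells}
    for p in puncta:
        counts[p.cell_label] = counts.get(p.cell_label, 0) + 1
    return counts


def classify_cc3_bleb(
    puncta_counts: dict[int, int], min_puncta: int = 2
) -> dict[int, bool]:
    """CC3(bleb)+ iff a cell contains >= ``min_puncta`` puncta (default 2)."""
    if min_puncta < 1:
        raise MarkerCallError("min_puncta must be >= 1")
    for lab, n in puncta_counts.items():
        if n < 0:
            raise MarkerCallError(f"negative punctum count for cell {lab}")
    return {lab: n >= min_puncta for lab, n in puncta_counts.items()}


def auto_threshold_gh2ax(nuclear_means: list[float] | np.ndarray) -> float:
    """Automatic gammaH2AX positivity threshold from per-nucleus means.

    Performs an exhaustive two-class variance-minimising (Otsu-style)
    split of the per-nucleus mean intensities and returns the midpoint of
    the split boundary, which lies strictly between the two class means.
    When the split does not show a credible positive class — the class
    means separated by less than twice the pooled within-class spread, or
    the upper class less than twice as bright as the lower — the input is
    treated as background-only and the maximum observed value is returned,
    so that no cell is called positive under the strict ``>`` rule.
    """
    v = np.sort(np.asarray(nuclear_means, dtype=np.float64))
    n = v.size
    if n < 2:
        raise MarkerCallError("auto_threshold_gh2ax needs at least two values")
    if np.any(v < 0):
        raise MarkerCallError("nuclear means must be nonnegative")
    if v[0] == v[-1]:
        return float(v[-1])

    best_k, best_ssw = 1, np.inf
    for k in range(1, n):
        left, right = v[:k], v[k:]
        ssw = left.var() * k + right.var() * (n - k)
        if ssw < best_ssw:
            best_ssw, best_k = ssw, k
    left, right = v[:best_k], v[best_k:]
    m_lo, m_hi = float(left.mean()), float(right.mean())
    pooled_sd = float(np.sqrt(best_ssw / n))
    separated = (m_hi - m_lo) >= 2.0 * pooled_sd and m_hi >= 2.0 * max(m_lo, 1e-12)
    if not separated:
        return float(v[-1])
    return float((v[best_k - 1] + v[best_k]) / 2.0)


def classify_gh2ax(
    label_map: NucleusLabelMap,
    gh2ax: np.ndarray,
    threshold: float,
) -> tuple[dict[int, float], dict[int, bool]]:
    """Mean nuclear gammaH2AX intensity and positivity (mean > threshold)."""
    if label_map.n_nuclei == 0:
        raise MarkerCallError("label map has no nuclei")
    img = np.asarray(gh2ax, dtype=np.float64)
    ids = np.array(label_map.label_ids)
    sums = ndi.sum_labels(img, label_map.labels, ids)
    counts = ndi.sum_labels(np.ones_like(img), label_map.labels, ids)
    means = {int(lab): float(s / c) for lab, s, c in zip(ids, sums, counts)}
    positive = {lab: m > threshold for lab, m in means.items()}
    return means, positive


def classify_colocalization(calls: list[CellCall]) -> list[CellCall]:
    """Set ``coloc_pos = gh2ax_pos AND cc3_bleb_pos`` on every call (in place)."""
    for call in calls:
        call.coloc_pos = bool(call.gh2ax_pos and call.cc3_bleb_pos)
    return calls


def build_cell_calls(
    cells: list[CellGeometry],
    cyto_means: dict[int, float],
    cyto_pos: dict[int, bool],
    puncta_counts: dict[int, int],
    gh2ax_means: dict[int, float],
    gh2ax_pos: dict[int, bool],
    min_puncta: int = 2,
) -> list[CellCall]:
    """Assemble per-cell calls for every cell present in all inputs."""
    bleb = classify_cc3_bleb(puncta_counts, min_puncta)
    calls = []
    for cell in cells:
        lab = cell.label
        if lab not in cyto_means:  # unevaluable (empty ring)
            continue
        calls.append(
            CellCall(
                cell_label=lab,
                nuclear_area_um2=cell.nuclear_area_um2,
                cyto_cc3_mean=cyto_means[lab],
                cyto_cc3_pos=cyto_pos[lab],
                puncta_count=puncta_counts.get(lab, 0),
                cc3_bleb_pos=bleb.get(lab, False),
                gh2ax_mean=gh2ax_means[lab],
                gh2ax_pos=gh2ax_pos[lab],
            )
        )
    return classify_colocalization(calls)
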