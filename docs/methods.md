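# Methods

This note documents the models, numerical choices and limitations behind
`blebquant`. Everything stated here is computed by the test suite or by
`scripts/acceptance.py`; nothing is quoted from external measurements.

## Assay model

The unit of analysis is one multichannel image field. Per cell, four
boolean marker calls are made, all by strict `mean intensity > threshold`
rules (mean, not integrated, intensity — so calls are independent of
nuclear area across the 50–200 µm² retention window):

| call | region | rule |
|---|---|---|
| cytoplasmic CC3⁺ | ring mask | mean CC3 > threshold |
| CC3(bleb)⁺ | ring mask | ≥ `min_puncta_per_cell` (default 2) puncta |
| γH2AX⁺ | nucleus | mean γH2AX > threshold |
| coloc⁺ | — | γH2AX⁺ ∧ CC3(bleb)⁺ |

A punctum is an 8-connected component of the CC3 raster, restricted to the
union of ring masks, above the spot intensity threshold, with area in
`[0.2, 5] µm²` (inclusive). Components failing the window are discarded —
this is what rejects both diffuse cytoplasmic CC3 (one huge component) and
sub-resolution specks. Each punctum is assigned to the cell whose ring
contains its rounded centroid, falling back to the majority ring owner of
its pixels (ties to the lower label).

Per field, percent-positive values use the number of evaluable cells as
denominator (cells whose ring mask is empty are excluded and counted in the
run log). The conditional quantity "% of γH2AX⁺ cells that are bleb⁺" uses
the γH2AX⁺ count as denominator and is flagged NaN when that count is zero;
it satisfies `pct_conditional × pct_gh2ax / 100 = pct_coloc` exactly on
counts.

## Segmentation recipe

The original analysis used a proprietary tool; the recipe here is a
declared substitute, not a reconstruction: Gaussian smoothing (σ = 1 px) →
global Otsu threshold → hole filling → removal of specks < 10 µm² →
Euclidean distance transform → h-maxima markers (h = 1 px, computed by
grayscale reconstruction so that pixelation wiggles shallower than h never
split one nucleus) → marker-controlled watershed → consecutive relabelling.
A raster whose threshold would call more than 60% of pixels foreground is
treated as having no segmentable nuclei, so noise-only images yield zero
cells rather than artifacts. Everything is deterministic.

## Ring masks and the automatic width

Cytoplasm is simulated by dilating 1–5 µm outward from the nuclear border.
Border distance is the Euclidean distance between pixel centres to the
nearest nucleus pixel. A background pixel joins the ring of the nucleus
with the smallest border distance (≤ width); exact ties go to the lower
label. Rings are therefore pairwise disjoint and disjoint from all nuclei,
and for an isolated nucleus the ring at width w₁ < w₂ is strictly contained
in the ring at w₂.

The per-specimen automatic width selects the **largest** w ∈ {1,…,5} µm for
which the **median per-cell fraction of contested ring pixels** (pixels
within w of at least one other nucleus) is below 20%, falling back to 1 µm
in heavily crowded specimens. This maximises cytoplasmic sampling while
bounding cross-cell contamination, and is monotonically non-increasing as
nuclei pack closer. The rule itself is a design choice: the original
publication states only that the width was set automatically per specimen.

## Thresholds

* **Spot and cytoplasmic CC3 thresholds** are absolute config values by
  default (the synthetic study uses 4,000 and 2,600 on the 16-bit scale,
  placed mid-gap between the rendered background/diffuse levels and the
  puncta level). An automatic mode — background median + k·MAD (scaled,
  k = 6) over non-ring pixels — is available for real material where
  absolute levels are unknown.
* **γH2AX threshold** (automatic mode, the default): an exhaustive
  two-class variance-minimising split of the per-nucleus mean intensities;
  the returned threshold is the midpoint of the split boundary, strictly
  between the class means. The split is accepted only if the class means
  are separated by ≥ 2× the pooled within-class spread **and** the upper
  class is at least 2-fold brighter than the lower; otherwise the input is
  treated as background-only and the maximum observed value is returned, so
  no cell is called positive. The fold condition matters: a variance split
  of unimodal noise routinely passes a pure separation test, and without it
  a marker-free specimen would be assigned ~50% positives.

## Statistics

Two-sided Mann–Whitney U throughout (group contrasts run in both
directions in this assay — cytoplasmic CC3 falls after treatment while
blebbing rises). The exact permutation null is used when `min(n) ≤ 8` and
the pooled values are tie-free; otherwise the normal approximation with tie
and continuity corrections. The exact/approximate boundary is pinned
because typical group sizes (6–13 fields) straddle it. Stars use strict
thresholds (`*` P<0.05, `**` P<0.01, `***` P<0.001, `****` P<0.0001;
P = 0.05 is `ns`). No multiple-testing correction is applied; comparisons
are reported per contrast. Fields are the default unit of comparison; any
grouping key can be supplied instead.

## Synthetic fields

The generator renders what the assay must measure, with exact truth:

* **Nuclei**: non-overlapping ellipses (axis ratio 0.7–1), areas uniform in
  50–200 µm², placed by rejection sampling against an occupancy mask with a
  minimum border gap (default 1.4 µm); larger nuclei first, which raises
  the achievable packing density without biasing class assignment (classes
  are assigned by an independent random permutation).
* **Class counts are exact** (rounded), with the colocalized set a subset
  of both single-marker sets by construction; a binomial mode exists for
  sampling-variance studies.
* **Channels** (16-bit, additive Gaussian noise σ = 60, clipped): DAPI
  nuclei at 12,000 ± 15% over a 300 background; γH2AX positives pan-nuclear
  at `signal_to_background` (default 15) × the 500 background; diffuse CC3
  at 7 × background over the true perinuclear band (≤ 3 µm) of diffuse⁺
  cells — deliberately **below** the spot threshold, since diffuse CC3 is
  the morphology the spot detector must ignore; puncta as steep
  super-Gaussian disks `exp(−ln2·(r/r₀)⁸)` whose half-maximum radius equals
  the nominal spot radius, 2–8 per apoptotic cell in angularly separated
  sectors of the 0.35–0.85 µm perinuclear band (so puncta of one cell do
  not merge and fall inside even a 1 µm ring).
* **Decoys**: spots of 0.1 and 6.0 µm² on a configurable cell fraction.
  At the default 0.4622 µm/px pitch one pixel is 0.214 µm², so a 0.1 µm²
  object is sub-resolution; it is rendered with a PSF-motivated peak
  attenuation (peak scaled by `(area/pixel area)^1.5`), which keeps it
  below the spot threshold — the physically sensible way a sub-pixel spot
  evades detection at this magnification. The 6 µm² decoy is rejected by
  the area filter when it lies fully inside a ring; narrow rings can clip
  it into the window (see limitations).

What the generator does **not** emulate: tissue autofluorescence and
texture, staining gradients, sectioning artifacts, macrophage morphology,
out-of-focus light. Passing recovery tests therefore demonstrates the
correctness of the measurement chain, not robustness to histology-grade
image quality.

## Packaged study and problem sizes

The packaged synthetic study (`blebquant/configs/synthetic_study.yaml`)
uses 2 groups × 6 fields × 1,300 cells (≈15,500 analyzed cells), with a
1% vs 20% colocalization contrast, and 1600 × 1600 px fields: nuclei of
50–200 µm² geometrically cannot pack 1,300 to a 1,000 × 1,000 px field at
this pixel pitch, so the field is enlarged at constant density rather than
shrinking the nuclei. Recovery on these conditions is well within ±2
percentage points per field per marker, and the colocalization contrast is
significant at P < 0.01.

## Known limitations and degenerate cases

* **Punctum-count monotonicity in the spot threshold is not exact.** The
  cytoplasmic-CC3 and γH2AX positive counts are exactly non-increasing in
  their thresholds, and bleb⁺ counts in `min_puncta`. But for a detector
  defined as binarize → connected components → area window, the retained
  spot count can *increase* at isolated threshold values: a merged or
  ring-clipped component with area above 5 µm² at a low threshold shrinks
  into the window as the threshold rises, and spots merged through their
  tails at very low thresholds separate into two retained spots. The
  thresholded support itself is always nested. The corresponding test
  asserts the literal count property and documents its failure mode.
* Narrow (1 µm) rings clip large blobs into the size window; a decoy can
  then register as one punctum. The ≥2-puncta rule makes single leaked
  spots inert for blebbing calls.
* A field with zero retained nuclei is excluded from statistics with a
  logged reason, never scored as 0%.
* Ties or `min(n) > 8` silently switch the U test to the corrected normal
  approximation; the `method` field of every comparison records which null
  was used.
* Calibration is accepted either as linear µm/px or as µm²/px
  (`calibration_unit`), because scanner metadata is ambiguous between the
  two conventions; the default is linear 0.4622 µm/px for 20× scans.
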