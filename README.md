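# blebquant

Per-cell quantitation of the duplex **γH2AX / cleaved-caspase-3 (CC3)
blebbing** immunofluorescence assay for FFPE tissue sections.

## The problem

γH2AX (H2AX phosphorylated at Ser139) marks DNA double-strand breaks, but in
drug-treated tumors the signal is ambiguous: it appears both in cells with
drug-induced, potentially repairable damage and in cells whose DNA is being
fragmented during apoptosis. Diffuse cytoplasmic CC3 staining is likewise a
poor apoptosis readout in tissue. The assay this package implements resolves
both problems at single-cell level: CC3 that has condensed into discrete
perinuclear **puncta** (a morphological proxy for apoptotic membrane
blebbing) is a far more specific death marker, and a cell that is *both*
γH2AX⁺ and CC3(bleb)⁺ can be read as apoptosis-associated DNA fragmentation
rather than damage alone. The per-field percentage of such colocalized cells
is a pharmacodynamic readout of drug-induced tumor cell killing.

## The pipeline

For each image field (1,000 × 1,000 px tiles at 20×, ≈0.46 µm/px, 16-bit;
DAPI + CC3 + γH2AX channels):

1. **Nuclear segmentation** from DAPI: Gaussian smoothing → Otsu threshold →
   hole filling → distance-transform watershed to split touching nuclei.
2. **Area filter**: retain nuclei with area in **[50, 200] µm²**.
3. **Cytoplasm simulation**: exclusive perinuclear **ring masks** built by
   dilating 1–5 µm outward from each nuclear border; contested pixels go to
   the nearer nucleus. The width is chosen automatically per specimen (the
   widest width keeping the median contested-pixel fraction under 20%).
4. **Marker calls** (all strict `mean > threshold` rules):
   * cytoplasmic CC3⁺ — mean ring CC3 intensity above threshold;
   * **CC3(bleb)⁺** — ≥ 2 CC3 puncta in the ring, where puncta are
     thresholded 8-connected spots with area in **[0.2, 5] µm²**
     (nominal spot size 0.9 µm²);
   * γH2AX⁺ — mean nuclear intensity above an automatic two-class
     threshold on the per-nucleus means;
   * coloc⁺ — γH2AX⁺ **and** CC3(bleb)⁺.
5. **Statistics**: per-field percent-positive values; two-sided
   **Mann–Whitney U** tests between treatment groups (exact permutation null
   when `min(n) ≤ 8` without ties), annotated `*P<0.05 **P<0.01 ***P<0.001
   ****P<0.0001` (strict).

Because the original tissue scans are not publicly available, the package
includes a first-class synthetic-field generator
(`blebquant.synthetic_fields`) producing three-channel rasters with exact
per-cell ground truth — elliptical nuclei spanning the retention window,
diffuse cytoplasmic CC3, perinuclear puncta, pan-nuclear γH2AX, decoy spots
outside the size window, and additive noise — so every stage is testable
end to end.

## Worked example

```python
import blebquant as bq

cfg = bq.SyntheticConfig(n_cells=500, frac_gh2ax=0.2, frac_bleb=0.2,
                         frac_coloc=0.2, seed=7)
field, truth = bq.generate_field(cfg)
res = bq.analyze_field(field)
s = res.summary
print(f"ring width {res.diagnostics['ring_width_um']:.0f} um, "
      f"n={s.n_cells} cells")
print(f"gH2AX+ {s.pct_gh2ax:.1f}%  bleb+ {s.pct_bleb:.1f}%  "
      f"coloc+ {s.pct_coloc:.1f}%  (truth 20/20/20)")
```

prints

```
ring width 3 um, n=498 cells
gH2AX+ 20.1%  bleb+ 20.5%  coloc+ 20.1%  (truth 20/20/20)
```

i.e. on a 500-cell field with 20% of cells rendered as apoptotic
(γH2AX⁺ with ≥2 perinuclear CC3 puncta), the pipeline retains 498 nuclei in
the 50–200 µm² window and recovers all three marker percentages within half
a point of the generated truth.

The same workflow runs from the command line over a YAML config (either a
manifest of TIFF fields with group labels, or a synthetic study spec):

```bash
blebquant validate -c config.yaml
blebquant run -c config.yaml -o out/        # cells.csv, fields.csv, comparisons.json
blebquant generate -c config.yaml -o sim/   # synthetic TIFFs + truth.csv
```

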