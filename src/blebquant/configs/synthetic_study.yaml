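# Packaged synthetic study: two treatment groups, six fields per group,
# mirroring the assay's sampling scale (>= 6 fields and >= 15,000 cells
# per specimen).  The "treated" group carries a strong apoptotic
# (gammaH2AX+/CC3-bleb colocalized) response; "control" has a near-zero
# coloc fraction.
seed: 20260901
output_dir: blebquant_out
calibration: 0.4622
calibration_unit: um_per_px
ring_width_um: auto
cyto_cc3_threshold: 2600.0
gh2ax_threshold: auto
min_nucleus_area_um2: 50.0
max_nucleus_area_um2: 200.0
spots:
  expected_spot_area_um2: 0.9
  min_spot_area_um2: 0.2
  max_spot_area_um2: 5.0
  intensity_threshold: 4000.0
  min_puncta_per_cell: 2
synthetic:
  fields_per_group: 6
  n_cells: 1300
  field_px: [1600, 1600]
  frac_diffuse_cc3: 0.3
  groups:
    - {label: control, frac_gh2ax: 0.30, frac_bleb: 0.05, frac_coloc: 0.01}
    - {label: treated, frac_gh2ax: 0.30, frac_bleb: 0.25, frac_coloc: 0.20}
comparisons:
  - {a: control, b: treated, metric: pct_coloc}
  - {a: control, b: treated, metric: pct_bleb}
  - {a: control, b: treated, metric: pct_gh2ax}
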