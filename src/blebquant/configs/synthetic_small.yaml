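# Small, fast synthetic study for smoke tests and examples.
seed: 11
output_dir: blebquant_out
calibration: 0.4622
ring_width_um: auto
cyto_cc3_threshold: 2600.0
gh2ax_threshold: auto
synthetic:
  fields_per_group: 3
  n_cells: 150
  field_px: [640, 640]
  frac_diffuse_cc3: 0.3
  groups:
    - {label: control, frac_gh2ax: 0.30, frac_bleb: 0.05, frac_coloc: 0.01}
    - {label: treated, frac_gh2ax: 0.30, frac_bleb: 0.25, frac_coloc: 0.20}
comparisons:
  - {a: control, b: treated, metric: pct_coloc}
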