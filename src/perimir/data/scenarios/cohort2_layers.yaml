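# 7-day ISH scenario: per-cell intensity over the perilesional sector.
# Planted structure: deep/superficial layer ratio 1.9 in every group,
# TBI at 47% and sham at 71% of the naive per-cell signal; 400 cells per
# subject, 3 subjects per group, in a 1000 x 800 um field at 2 um/px.
name: cohort2_layers
rng_seed: 20318
image_geom:
  width_um: 1000.0
  depth_um: 800.0
  microns_per_pixel: 2.0
  background_gray: 0.9
  noise_gray: 0.002
groups:
  - {group_label: naive, n_subjects: 3}
  - {group_label: sham, n_subjects: 3}
  - {group_label: TBI, n_subjects: 3}
layer_effect: 1.9
group_scale: {naive: 1.0, sham: 0.71, TBI: 0.47}
base_signal: 0.25
signal_cv: 0.15
n_cells_per_subject: 400
cell_radius_um: 8.0
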