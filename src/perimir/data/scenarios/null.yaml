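# Null scenario: no planted effects anywhere (all ratios 1.0).  Used to
# check that the pipeline's contrasts stay non-significant when nothing
# is planted.  Small field and cell counts keep repeated runs cheap.
name: "null"
rng_seed: 60000
image_geom:
  width_um: 600.0
  depth_um: 400.0
  microns_per_pixel: 2.0
  background_gray: 0.9
  noise_gray: 0.002
groups:
  - {group_label: naive, n_subjects: 2}
  - {group_label: sham, n_subjects: 2}
  - {group_label: TBI, n_subjects: 2}
layer_effect: 1.0
group_scale: {naive: 1.0, sham: 1.0, TBI: 1.0}
base_signal: 0.25
signal_cv: 0.15
n_cells_per_subject: 60
cell_radius_um: 8.0
qpcr:
  mir124_vs_mir378:
    n_case: 6
    n_control: 6
    planted_fc: 1.0
    ct_sd: 0.3
    reference_ct_mean: 20.0
    baseline_dct: 5.0
    case_group: TBI
    control_group: sham
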