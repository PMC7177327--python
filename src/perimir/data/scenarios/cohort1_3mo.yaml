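# 3-month post-injury qPCR scenario: chronic miR-124-3p downregulation to
# FC 0.40 and the (non-significant in tissue) Stat3 trend FC 3.11.
name: cohort1_3mo
rng_seed: 10703
qpcr:
  mir124_vs_mir378:
    n_case: 6
    n_control: 6
    planted_fc: 0.40
    ct_sd: 0.3
    reference_ct_mean: 20.0
    baseline_dct: 5.0
    case_group: TBI
    control_group: sham
  stat3_vs_gapdh:
    n_case: 6
    n_control: 6
    planted_fc: 3.11
    ct_sd: 0.3
    reference_ct_mean: 18.0
    baseline_dct: 7.0
    case_group: TBI
    control_group: sham
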