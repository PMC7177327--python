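# 7-day post-injury qPCR scenario: miR-124-3p (vs miR-378) downregulation
# to FC 0.13 and Stat3 (vs Gapdh) upregulation to FC 6.97 in the
# lesion-adjacent perilesional cortex, n = 6 TBI vs 6 sham, plus the
# miR-124-3p / Stat3 anti-correlation (Spearman -0.647).
name: cohort1_7d
rng_seed: 10701
qpcr:
  mir124_vs_mir378:
    n_case: 6
    n_control: 6
    planted_fc: 0.13
    ct_sd: 0.3
    reference_ct_mean: 20.0
    baseline_dct: 5.0
    case_group: TBI
    control_group: sham
  stat3_vs_gapdh:
    n_case: 6
    n_control: 6
    planted_fc: 6.97
    ct_sd: 0.3
    reference_ct_mean: 18.0
    baseline_dct: 7.0
    case_group: TBI
    control_group: sham
correlation:
  rho_spearman: -0.647
  n_pairs: 24
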