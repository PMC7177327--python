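# RNA-seq/in-silico scenario: transcriptome of 12000 genes, of which
# exactly 1547 carry a canonical miR-124-3p seed site in their 3'UTR;
# the DE table has exactly 2583 upregulated and 2381 downregulated
# significant genes (p < 0.05), of which 312 / 311 are planted targets.
# Down-regulated targets carry the strongest evidence so the target set
# is negatively enriched in the preranked list.
name: cohort3
rng_seed: 30025
transcriptome:
  n_genes: 12000
  n_target_genes: 1547
  n_up_sig: 2583
  n_down_sig: 2381
  n_up_targets: 312
  n_down_targets: 311
  utr_len: 300
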