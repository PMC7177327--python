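# Human temporal-lobe scenario: per-cell ISH intensities inside vs outside
# a patchy neuronal-loss area of cortical layer III.  Inside the patch the
# planted per-cell signal has a lower mean (0.6x) and larger dispersion
# (1.5x lognormal sigma); the magnitudes are package choices, the tissue
# analysis reported only the direction of the effect.
name: human_patch
rng_seed: 50002
patch:
  n_inside: 60
  n_outside: 60
  mean_outside: 0.3
  inside_mean_scale: 0.6
  inside_sd_scale: 1.5
  sigma: 0.2
  area_inside_mm2: 0.08
  area_outside_mm2: 0.08
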