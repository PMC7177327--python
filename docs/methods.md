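# Methods

This note records the models, conventions and parameter choices behind each
stage, what the synthetic-data generator does and does not emulate, and the
numerical decisions a maintainer would otherwise have to reverse-engineer.

## Synthetic data: what is emulated

The generators reproduce the *statistical structure* each analysis assumes,
not the biology or optics of real sections.

**ISH scenes.** A section is a flat background of gray `background_gray`
(default 0.9 on a [0, 1] scale) carrying non-overlapping circular cells
(rejection-sampled centers, default radius 8 µm) whose gray is
`background_gray · (1 − s)`. The per-cell signal `s` is lognormal around a
planted mean: `s = base_signal · group_scale[g] · layer_effect^{deep} ·
exp(N(0, signal_cv))`, with `base_signal = 0.25` (a mid-range chromogenic
signal), `signal_cv = 0.15` (per-cell multiplicative noise), and the
deep-layer indicator set by the cell lying below the depth midpoint.
Multiplicative lognormal noise keeps gray in (0, 1] and makes ratio
estimates (layer fold-change, percent-of-control) unbiased, because the
noise factor cancels. Pixel-level Gaussian noise (sd 0.002) is added
globally. Per-(scenario, subject) seeding (`default_rng([rng_seed,
subject_index])`) makes each subject independently reproducible.

Not emulated: RGB color development, nucleus/cytoplasm substructure,
overlapping or partially stained cells, tissue texture, uneven
illumination, the fimbria background region. Passing tests therefore show
that the quantification is correct *given* well-separated darker-than-
background cells; they say nothing about segmentation robustness on real
chromogens.

**qPCR Ct tables.** Control-group ΔCt is centered at `baseline_dct`
(default 5 cycles above the reference assay, whose mean Ct is 20); the case
group at `baseline_dct − log2(planted_fc)`. `ct_sd` is the standard
deviation of the per-sample ΔCt, split as `ct_sd/√2` per assay. The cohort
scenarios use ct_sd = 0.3 — the study did not report per-group Ct variance,
so this is a package choice of a typical well-run assay; at n = 6 vs 6 it
gives a ~12% (1 sd) spread on a single fold-change estimate. No
amplification-efficiency variation or plate effects are simulated.

**Transcriptome.** `n_genes` UTRs (default 300 nt) are rejection-sampled to
contain zero 6mer seed cores; exactly `n_target_genes` of them then receive
one planted canonical site (type drawn 8mer 0.3 / 7mer-m8 0.3 / 7mer-A1 0.2
/ 6mer 0.2), so the scanner's positive set equals the planted set exactly.
The DE table plants exact significant counts at p < 0.05 by drawing p on
disjoint sides of the threshold. Down-regulated targets are given the
strongest evidence (p ∈ 10^[−12, −6], |log2FC| ∈ [1, 4]) — an explicit
repression-release signature that makes the target set negatively enriched
in the preranked list by construction; other significant genes draw
p ∈ 10^[−6, log10 0.05]. Up-regulated targets are *not* given extra
evidence, so no positive enrichment is planted. Real library-size effects,
count noise and correlation between genes are not modeled (the DE table is
generated directly, not from reads).

**Correlated pairs.** Gaussian copula: Pearson ρ = 2·sin(π·ρ_s/6) yields a
population Spearman correlation ρ_s.

**Patch intensities.** Inside the patchy-loss area: mean scaled by 0.6 and
lognormal sigma by 1.5 relative to outside. The tissue analysis reported
only the direction (lower, more variable inside); the magnitudes are
package choices large enough that a 60-vs-60-cell comparison is decisively
significant.

## ISH quantification

Detection is a fixed grayscale threshold plus connected components
(8-connectivity) and an area filter (defaults 20–2000 µm²) — a
deterministic re-specification of an interactively thresholded ImageJ
measurement. The pipeline's automatic threshold sits between the background
and a conservatively dim (≈4 sd below nominal) faintest expected cell:
`bg · (1 − 0.275 · s_min)`. Background is the mean gray of all
above-threshold pixels (or a caller-given rectangle); on flat synthetic
backgrounds this equals the planted background to <1%.

Normalized intensity `(bg − cell)/bg` is kept signed: cells lighter than
background yield negative values and are flagged, not clamped. It is
invariant to global linear rescaling of the image when the background is
measured from the same image.

Sector geometry: the perilesional window is `width_um` (default 1000 µm)
wide starting at the lesion-side edge, split at the x and depth midpoints
into s1 (proximal deep), s2 (proximal superficial), s3 (distal deep), s4
(distal superficial); intervals are half-open [min, split), so every
in-window cell gets exactly one label. The 2×2 midpoint grid is an
interpretation — the original figure does not state the split
coordinates — and both splits are parameters. The human analysis width is
likewise a parameter (the study used narrower sectors there).

## qPCR

ΔΔCt uses group means of ΔCt (the standard Livak formulation; per-sample
relative quantities `2^−(ΔCt_i − mean ΔCt_control)` are also reported, so
the control group's geometric mean is 1). The Grubbs test is two-sided,
single-outlier, non-iterative, with the t-based critical value
`G_crit = ((n−1)/√n)·√(t²/(n−2+t²))`, `t = t_{1−α/(2n), n−2}` — matching
the common online calculator convention. The miR/target correlation is
Spearman's ρ; the correlation method used in the original analysis is
unstated, and the nonparametric choice matches the rest of the framework
(recorded in the result metadata).

## Nonparametric tests

Mann–Whitney U: exact p by full enumeration of the null when the pooled
sample is ≤ 12 with no ties, otherwise the tie-corrected normal
approximation; two-sided exact p is 2·min(tail), capped at 1 (conventions
differ, so this is stated explicitly). Kruskal–Wallis: tie-corrected H,
chi-square p at k − 1 df; all-identical data returns H = 0, p = 1.
Spearman: average ranks for ties; exact permutation p for n ≤ 7 (≤ 5040
permutations), t approximation otherwise. The computational kernels
delegate to scipy.stats; the exact-permutation Spearman p and the Grubbs
test are implemented here. No multiple-testing correction is applied —
mirroring the original per-test α = 0.05 — and every report lists raw
p-values; treat the pairwise p-values accordingly.

## Seed-site scanning

A locus is a distinct 6mer-core start (reverse complement of miRNA nt 2–7
in the target). Flanks classify the locus at its strongest type: complement
of miRNA nt 8 immediately 5′ in the target (m8), adenosine immediately 3′
(t1A); 8mer > 7mer-m8 > 7mer-A1 > 6mer. `start` is the 1-based 5′-most
target nucleotide of the site, so m8-bearing types start one base before
their core. Overlapping cores count as separate loci. Conservation
filtering is deliberately not implemented (no cross-species alignments at
this scale); the planted target set plays that role, and the downstream
counting depends only on set membership. DNA-alphabet FASTA input is
transliterated T→U with a logged notice.

## Preranked enrichment

Ranking metric: sign(log2FC)·(−log10 p), descending, ties broken by gene id
(the original description — "fold-change and p-values" — is ambiguous; this
choice uses both and is monotone in evidence; plain log2FC is available).
Zero p-values are clamped to the smallest positive double and logged.
Running sum: hits add |score|^w / Σ_hits |score|^w (w = 1, configurable),
misses subtract 1/(N − N_hits); ES is the signed maximal |deviation|. If
all hit scores are exactly zero at w > 0, hit weights fall back to counts.
Significance is by gene-set permutation (the only option for preranked
input): p is the same-sign tail fraction with add-one correction,
NES = ES / mean|same-sign null ES|, and FDR is the same-sign null tail
fraction at |NES| — the standard single-set preranked convention.

## Duplex MFE

Dynamic programming over all antiparallel duplexes with Watson–Crick and
G:U pairs: consecutive pairs score a nearest-neighbor stack; interruptions
cost affine penalties (bulge 3.8 + 0.4/nt, internal loop 4.1 + 0.4/nt
beyond the first on each side); duplex initiation +4.09 kcal/mol; dangling
ends free; loops capped at 15 nt per strand; target regions capped at 60 nt
(duplex only — no target folding or accessibility). If no duplex is
negative, the MFE is 0 with an empty pairing. The packaged stack table uses
the Xia-98 Watson–Crick values; wobble-containing stacks are simplified
uniformly negative placeholders (−0.5 to −1.5 kcal/mol), keeping the table
internally consistent and strand-exchange symmetric. Absolute energies are
therefore not comparable to full Turner-model tools; comparative statements
(which duplex is more stable, where binding starts) are the supported use,
and a test checks ordering agreement with an independent thermodynamic
engine. The DP is verified against exhaustive enumeration of all pairings
for short sequences. Default site region: 30 nt centered on the seed site.

## Problem sizes and runtime

The packaged scenarios are sized for desk-scale runs: 3 subjects × 3 groups
× 400 cells for the sector analysis (≈3600 cells, a few seconds), 200
replicate Ct tables per recovery summary, 500 replicate correlation
samples, a 12 000-gene transcriptome with 300-nt UTRs (a few seconds to
generate and scan), and 200–1000 gene-set permutations for enrichment. The
full test suite runs in well under a minute; the acceptance script in
seconds.

## Known limitations

- Detection assumes non-overlapping, uniformly darker cells; no watershed
  splitting or color deconvolution.
- The energy model's wobble entries are placeholders; do not interpret
  absolute MFE values.
- Exact Mann–Whitney is limited to pooled n ≤ 12 without ties.
- The DE generator plants marginal counts and evidence strengths but not
  inter-gene correlation, so permutation nulls are cleaner than in real
  RNA-seq.
- Single-run fold-change estimates at n = 6 vs 6 with Ct sd 0.3 carry ~12%
  noise; headline pass/fail bands in run reports are sized at 2.5 sd.
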