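# perimir

Quantitative pipeline for studying chronic **miR-124-3p downregulation in the
perilesional cortex after traumatic brain injury (TBI)**, written for
researchers who need the analysis arms of such a study — image-based per-cell
expression, relative qPCR, and in-silico target analysis — as tested,
reusable, seedable code. Because the original tissue data are not deposited,
the package ships a first-class synthetic-data module that generates every
input with planted effect sizes, so each analysis can be validated by
parameter recovery.

## What it computes

**Per-cell ISH intensity over perilesional sectors** (`perimir.ish`).
Cells in a chromogenic in situ hybridization section are detected as
connected components darker than a grayscale threshold. Each cell's signal
is the background-normalized intensity

    I = (bg − cell) / bg

where `bg` is the mean gray of a cell-free background region. Cells are
assigned to a 2×2 sector grid over a 1000-µm window at the lesion edge
(s1/s3 deep, s2/s4 superficial; s1/s2 proximal), and groups are compared by
Kruskal–Wallis plus pairwise Mann–Whitney U — including the deep/superficial
fold-change and each group's mean intensity as a percent of the control
group. An inside/outside-patch comparison covers the human cortical
layer-III analysis.

**Relative qPCR quantification** (`perimir.qpcr`). The 2^−ΔΔCt method with
endogenous-control normalization: ΔCt = Ct(target) − Ct(reference) per
sample, ΔΔCt = mean ΔCt(case) − mean ΔCt(control), fold-change = 2^−ΔΔCt;
plus a single-pass two-sided Grubbs outlier test and Spearman correlation of
miRNA and target-mRNA levels.

**Seed-site target scanning** (`perimir.targets`). Canonical miRNA site
types in 3′UTRs — 6mer (match to miRNA nt 2–7), 7mer-A1, 7mer-m8, 8mer —
with each locus reported at its strongest type, and the overlap of the
predicted-target set with a differential-expression table
(p < α, sign of log2FC).

**Preranked gene-set enrichment** (`perimir.gsea`). Weighted
Kolmogorov–Smirnov-style running sum (weight 1) over genes ranked by
sign(log2FC)·(−log10 p), with gene-set-permutation p, NES and FDR.

**miRNA:target duplex MFE** (`perimir.duplex`). Intermolecular
minimum-free-energy duplex by dynamic programming over a packaged
nearest-neighbor stacking table with affine bulge/internal-loop penalties
(no intramolecular structure), reporting the MFE and the 5′-most miRNA
nucleotide of the optimal duplex ("binding start").

The mature miR-124-3p sequence is derived in code from its antisense
detection probe: `perimir.targets.mirna_from_probe("GGCAUUCACCGCGUGCCUUA")`
→ `UAAGGCACGCGGUGAAUGCC`.

## Worked example

Packaged scenarios encode the study's effect sizes. A scenario run
regenerates its inputs, analyzes them, and reports planted vs estimated
values:

```sh
perimir run --config cohort1_7d --out out/
```

Running the numbered drivers in `analysis/` prints, for example
(`python analysis/03_qpcr_ddct.py`):

```
cohort1_7d/mir124_vs_mir378: planted FC 0.13, single run 0.111 (p=0.00216), median of 200 reps 0.13
cohort1_7d/stat3_vs_gapdh: planted FC 6.97, single run 6.37 (p=0.00216), median of 200 reps 6.97
miR/Stat3 correlation: planted r -0.647, single run r -0.816 (p=1.19e-06), median of 500 reps -0.630
```

i.e. a single 6-vs-6 experiment with Ct noise 0.3 estimates the planted
fold-change only roughly, while the median over 200 replicate experiments
recovers it to two decimals. The sector analysis
(`python analysis/02_ish_sectors.py`) recovers the planted layer structure:

```
  naive  deep/superficial FC = 1.93     (planted 1.9)
  TBI    intensity = 47.4% of naive     (planted 47%)
  sham   intensity = 70.7% of naive     (planted 71%)
```

and the in-silico stage (`python analysis/04_target_enrichment.py`) finds
exactly the planted counts — 1547 seed-site-bearing transcripts, of which
312 are among the 2583 upregulated and 311 among the 2381 downregulated
genes — with the target set negatively enriched in the preranked list
(ES ≈ −0.65, p < 0.01, FDR < 0.01).

Subcommands `perimir simulate / ish-quant / qpcr / targets / gsea / duplex`
expose each stage on files (TIFF/PNG images, CSV tables, FASTA, YAML
scenarios).

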