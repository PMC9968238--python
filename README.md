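# circfus

A circRNA analysis pipeline — back-splice junction detection from paired-end
RNA-seq, negative-binomial differential expression of circular vs linear
splicing events, flanking-intron analysis (protein-binding marks from
T-to-C transition events, inverted Alu repeats, the Alu editing index) and
ceRNA sponge-network inference — together with a synthetic-data generator
that plants a fully known ground truth, so the whole pipeline is testable
end-to-end without external datasets.

## Layout

| module | role |
| --- | --- |
| `circfus.simdata` | synthetic genome / GTF / Alu BED / paired-end reads / PAR-CLIP transitions / expression & interaction tables, with planted circRNAs, editing, binding and miRNA sites |
| `circfus.detect` | read preprocessing (adapter clip, duplicate and contaminant removal), anchor-based back-splice calling with GT..AG signal check, junction filters, linear-support counting, host-gene annotation |
| `circfus.annotate` | circRNA localization over 5'UTR/CDS/3'UTR/intron, faux-circRNA null sampling, chi-squared localization-preference test |
| `circfus.diffexp` | circular/linear count matrix, CPM expression calling and set intersections, NB GLM (batch-adjusted additive model) with likelihood-ratio tests, concordance classification |
| `circfus.introns` | 1-kb flanking regions, binding marks, one-sided Fisher enrichment, inverted-Alu detection, hypergeometric overlap, weighted Alu editing index, paired t comparisons |
| `circfus.cerna` | circRNA sequence reconstruction across the BSJ (125-nt search / 25-nt retained extension), seed-weighted miRNA site scanning, sponge calling, target filtering, ORA, network export (GraphML/SIF) |

## CLI

```sh
circfus simulate --outdir sim --seed 1          # synthetic dataset + truth
circfus detect   --genome sim/genome.fa --gtf sim/genes.gtf \
                 --r1 sim/reads_WT_r1_1.fastq --r2 sim/reads_WT_r1_2.fastq \
                 --sample WT_r1 ... --out det
circfus de       --counts det/counts.tsv --design sim/design.tsv --out de
circfus annotate --gtf sim/genes.gtf --junctions det/junctions.bed --out annot
circfus introns  --de de --parclip sim/parclip.bed --alus sim/alus.bed \
                 --genome sim/genome.fa --out intr
circfus cerna    --de de --bsj-reads det/bsj_reads.tsv \
                 --localization sim/localization.tsv --genome sim/genome.fa \
                 --gtf sim/genes.gtf --mirnas sim/mirnas.fa \
                 --mirna-expression sim/mirna_expression.tsv \
                 --interactions sim/interactions.tsv \
                 --mrna-fc sim/mrna_fc.tsv --protein-fc sim/protein_fc.tsv \
                 --categories sim/categories.tsv --out cer
```

`detect` accepts repeated `--r1/--r2/--sample` triples; junctions filtered
per sample (>= 2 unique read pairs, span < 100 kb, unique anchors) are
merged and counted across all samples.

## Conventions

Internal coordinates are 0-based half-open; GTF is 1-based closed; BED6 is
0-based half-open with strand in column 6. Junction ids render as
`chrom:start+1-end_strand` (e.g. `chr1:10917-14564_+`). Library sizes are
raw column sums (no between-sample normalization); DE significance uses raw
p-values (0.05 circular / 0.1 linear) with BH-FDR available as an optional
column downstream.
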