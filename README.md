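# tssenrich

Peak-set enrichment of gene sets: does a group of genes sit unusually close
to a transcription factor's binding sites?

`tssenrich` integrates a TF cistrome (ChIP-seq peaks) with gene sets from
RNA-seq differential-expression analyses. It is written for regulatory
genomicists who have (a) peak calls in BED format, (b) a gene annotation
with strand-aware transcription start sites (TSSs), and (c) gene clusters —
either plain gene lists or DE tables thresholded at FDR < 0.05 — and want
to know whether a cluster is enriched near binding sites, at what genomic
distance the association lives, and which cluster members are plausible
direct targets.

## The statistic

For each extension distance λ on a ladder (default 100 bp → 10 Mbp), every
peak is widened by λ on both sides (or measured from its center), clipped
to chromosome bounds, and the genes with at least one TSS inside an
extended peak are collected. With

- N = genes in the whole-genome background (distinct symbols),
- K = cluster genes present in the background,
- n = genes near a peak at λ,
- k = cluster genes near a peak at λ,

the cluster's over-representation is the upper tail of the hypergeometric
distribution, P(X ≥ k) for X ~ Hypergeom(N, K, n), computed exactly. Fold
enrichment is (k/n)/(K/N), so 1 means "at the background rate". Raw p is
the primary statistic; Benjamini–Hochberg adjusted values across the whole
scan are an extra column. Profiling −log₁₀ p against λ localizes the
association scale: the curve peaks near the characteristic peak-to-TSS
distance and collapses to p = 1 once the extended peaks swallow the genome.

The package also covers the surrounding set algebra: intersecting peak sets
called against different controls into a high-confidence set (half-open
overlap semantics, bedtools-compatible), Venn intersections of up/down DE
gene sets across models, and classification of a putative direct-target
cluster (what fraction is down-regulated in a second contrast; how many
members lie within λ of a peak).

A synthetic-data module generates genomes, peak sets and DE tables with
*planted* structure — a designated target-gene subset with a tunable
fraction of peaks placed within a tunable distance d₀ of target TSSs — so
the whole pipeline can be exercised and validated with a known answer and
no downloads.

## Worked example

Simulate a study-scale dataset (20,000 genes on a 1 Gbp genome, 4,000
200-bp peaks of which half are planted within 10 kbp of 200 target genes,
and a test cluster of 100 targets + 20 random genes), then scan it:

```sh
tssenrich simulate --seed 1 --out sim
# synthetic bundle (seed=1): 20000 genes, 4000 peaks (2000 planted) -> sim

tssenrich scan sim/annotation.refgene.tsv sim/bounds.bed sim/BED_FILES sim/GENE_LISTS --out results
# wrote 11 enrichment rows to results/enrichment.tsv
```

`results/enrichment.tsv` (one row per peak set × cluster × λ):

```
peakset  cluster         lambda_bp  N      K    n      k    fold     p             p_adj
peaks    signal_cluster  100        20000  120  71     22   51.6432  1.69043e-32   3.09911e-32
peaks    signal_cluster  1000       20000  120  287    62   36.0046  2.23604e-83   8.1988e-83
peaks    signal_cluster  5000       20000  120  731    101  23.0278  2.07227e-127  2.27949e-126
peaks    signal_cluster  10000      20000  120  1155   102  14.7186  2.56626e-108  1.41144e-107
peaks    signal_cluster  100000     20000  120  7313   106  2.41579  3.95145e-32   6.20942e-32
peaks    signal_cluster  1000000    20000  120  19750  120  1.01266  0.22003       0.268926
peaks    signal_cluster  10000000   20000  120  20000  120  1        1             1
```

Reading it: of the 120 cluster genes in the 20,000-gene background, 101 lie
within 5 kbp of a peak although only 731 genes genome-wide do — a 23-fold
enrichment with p ≈ 10⁻¹²⁷. Significance is maximal at the planting scale
(λ ≈ d₀ = 10 kbp) and decays to exactly fold = 1, p = 1 by λ = 10 Mbp,
when the extended peaks cover every TSS. The other subcommands:
`tssenrich intersect` (common peaks across calling strategies),
`tssenrich classify` (direct-target report at a single λ, default 100 kbp),
and `--help` on any of them. Every scan writes `run_config.yaml` and
`run.log` beside the results so a run is reproducible from its snapshot.

The same operations are importable as a library (`tssenrich.pegs_scan`,
`tssenrich.genes_near_peaks`, `tssenrich.hypergeom_upper_tail`, ...).

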