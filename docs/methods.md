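# Methods

## Model and procedure

The question answered is whether a gene cluster lies closer to a set of
ChIP-seq peaks than chance would predict. The procedure, per extension
distance λ:

1. **Extend** each peak by λ. Default mode `edges` pads the called interval
   on both sides, `[start−λ, end+λ)`; mode `center` measures from the peak
   center c = ⌊(start+end)/2⌋, giving `[c−λ, c+λ+1)`. Both modes exist
   because a peak's footprint and its summit are both defensible anchors;
   `edges` is the default and results state which was used. Intervals are
   clipped to `[0, chromosome length)` and are never empty after clipping.
2. **Capture**: collect every gene with ≥1 transcript TSS inside ≥1
   extended peak. The TSS is strand-aware: interval start on `+`, last base
   (`end−1`) on `−`, in 0-based half-open coordinates throughout. A gene
   counts once no matter how many peaks or transcripts hit.
3. **Test**: with N background genes, K cluster genes, n captured genes and
   k captured cluster genes, report the inclusive upper tail
   P(X ≥ k), X ~ Hypergeom(N, K, n), and fold enrichment (k/n)/(K/N).

The background N is the number of **distinct gene symbols** in the
annotation, not transcripts: the hypergeometric urn draws genes, so each
gene must appear exactly once. Cluster members absent from the annotation
are removed from both K and k (logged), keeping the urn self-consistent.
Genes on chromosomes missing from the bounds file stay in N but can never
be captured; this preserves the whole-genome background and is logged.

Raw p is the primary statistic. Benjamini–Hochberg step-up adjustment
across all tests of a scan fills the `p_adj` column; it is reported
alongside, never substituted, because the λ-profile of raw p is the object
of interest and its tests are strongly dependent across λ.

### Assumptions

- Gene identity is the symbol (case-sensitive by default; a case-folding
  option exists). Venn intersections of DE sets are symbol-level.
- Under the null, the cluster is an exchangeable draw from the background.
  Clusters defined by expression are not random draws with respect to gene
  density, so p-values quantify proximity enrichment, not causality.
- Overlap is strict ≥1 bp under half-open arithmetic: an interval ending
  where another begins does not overlap it (bedtools convention).

## Set operations around the statistic

- `intersect_peak_sets(primary, others)` keeps the primary peaks (original
  coordinates) overlapping ≥1 peak in *every* other set — the
  "commonly called against both controls" definition of a high-confidence
  cistrome. It is a filter, so its output is a subset of the input and the
  operation is idempotent.
- `select_significant` applies the strict rule FDR < threshold (default
  0.05; an inclusive variant is off by default) with the sign of the
  log-fold-change selecting up/down; log-FC exactly 0 belongs to neither
  direction. NA/empty symbols are dropped on load and duplicate symbols are
  resolved by minimum FDR, both with logged counts.
- `classify_targets` summarizes a putative direct-target cluster: the
  percentage also significantly down-regulated in a second contrast
  (rounded to one decimal) and the number of members with a TSS within λ of
  a peak (default λ = 100 kbp, the distance at which proximity enrichment
  is typically still strong for a nuclear-receptor cistrome).

## Tunable parameters

| parameter | default | meaning |
|---|---|---|
| distance ladder | 100, 500, 1000, 5000, 10⁴, 5·10⁴, 10⁵, 5·10⁵, 10⁶, 5·10⁶, 10⁷ bp | λ values scanned |
| mode | `edges` | extension anchor (`edges`/`center`) |
| fdr_max | 0.05 | strict DE significance threshold |
| classification λ | 100,000 bp | "near a peak" for target reports |
| chrom prefix policy | `keep` | normalize `chr` dialects across inputs |

## Synthetic data generator

The generator emulates the scale of a mammalian TF-cistrome study:
20,000 genes with uniform TSSs and Bernoulli(0.5) strands on 5 chromosomes
of 200 Mbp (≈1 gene / 50 kbp, mammalian-like density); 4,000 peaks of
200 bp, of which round(ρ·n_peaks) are *planted*, centered at a uniform
offset in [−d₀, d₀] from a randomly chosen target-gene TSS (defaults
ρ = 0.5, d₀ = 10 kbp, 200 target genes); two DE tables in which each
target is significant-up (FDR ~ U(0, 0.05), positive log-FC) with
probability `de_effect_fraction` (default 0.9) and every other gene is a
null draw (FDR ~ U(0,1), log-FC ~ N(0,1)), significant at the nominal 5%;
and a test cluster of 100 targets diluted with 20 random non-targets.
One transcript per synthetic gene keeps the truth bookkeeping exact
(multi-TSS behaviour is covered by hand-built fixtures in the tests).

A single integer seed drives independent per-stage substreams
(`SeedSequence` spawn keys per stage), so any stage can be regenerated
alone and all outputs are byte-identical for a fixed seed.

What the generator does **not** emulate: clustered gene density and gene
deserts, peak-width and signal-strength distributions, co-expression
structure among DE genes, chromosome-length heterogeneity, and promoter
biases of real cistromes. Passing tests therefore demonstrate correctness
of the counting and testing machinery and calibration under an
exchangeable null — not that real data meet those assumptions.

### Recovering the planting distance

With ρ·n_peaks = 2,000 planted peaks around 200 targets, capture of the
planted cluster is overwhelming even at λ = 100 bp (≈1% of planted peaks
land within 100 bp of a target TSS), so the *smallest* significant λ says
nothing about d₀. The informative statistic is the λ that maximizes
significance (`recovered_planting_distance`): −log₁₀ p rises while
widening captures targets faster than background and falls once the
cluster saturates, so its maximum sits at the characteristic peak-to-TSS
distance. On defaults it lands within one ladder step of d₀ in 20/20
reseeded replicates.

## Numerical choices

- Hypergeometric tails use the exact survival function; if it underflows
  to 0 the implementation falls back to exp(logsf) and finally to the
  smallest positive float, so 0 < p ≤ 1 always holds.
- TSS capture merges the extended intervals per chromosome and uses binary
  search over sorted TSS positions (O((P+G) log)); membership in the union
  is merge-invariant, which the tests assert against an unmerged all-pairs
  brute-force scan.
- Fold enrichment is defined 0 when n = 0 or k = 0; an empty cluster
  (K = 0) is a contract error.
- BH adjustment enforces step-up monotonicity and caps at 1.
- `recovered_planting_distance` breaks p ties toward the smaller λ.
- All writers are bit-stable (no timestamps; fixed float formatting), so
  identical inputs give byte-identical outputs.

## Problem sizes in the test and acceptance suites

Statistical checks run at the generator's study-scale defaults (20,000
genes, 4,000 peaks): null calibration uses 2,000 random 100-gene clusters
at λ = 10 kbp; planted recovery uses 20 reseeded replicates of the full
pipeline; oracle-equivalence checks use 200 random micro-instances of ≤50
genes and ≤20 peaks against all-pairs brute force and exact rational
enumeration. The whole suite and the acceptance script each complete in
well under a minute on one CPU.

## Known limitations

- No permutation or rotation null (GAT-style) and no regulatory-domain
  weighting (GREAT-style): the null is the exchangeable hypergeometric urn.
- Peak signal strength is ignored; all peaks weigh equally.
- GTF/GFF annotations are out of scope (refGene-style TSV and BED6 only).
- The hypergeometric p-values across λ are strongly dependent; the BH
  column treats them as a flat family and is correspondingly conservative
  as a family-wise summary.
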