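"""Synthetic genomes, peak sets and DE tables with planted ground truth.

The generator emulates the scale of a mammalian TF-cistrome study: a genome
of ~2x10^4 genes with strand-assigned TSSs, ~4x10^3 peaks placed uniformly
except for a planted fraction ρ centered within d₀ of a designated
target-gene subset, and a pair of DE tables in which the targets are
significantly up-regulated.  Because the planted structure is known
exactly, every downstream operation (TSS capture, hypergeometric
enrichment, Venn intersection, target classification) has a recovery
oracle.

One global integer seed drives independent per-stage substreams
(``numpy.random.SeedSequence`` spawn keys), so each stage is reproducible
on its own and stages never share a stream.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .annotation import GeneUniverse, TranscriptRecord, universe_from_transcripts, write_refgene
from .gene_sets import DETable, GeneCluster, build_de_table, write_gene_list
from .intervals import Peak, PeakSet, write_bed, write_chrom_bounds

# fixed spawn keys: one substream per generator stage
_STAGE_ANNOTATION = 0
_STAGE_TARGETS = 1
_STAGE_PEAKS = 2
_STAGE_DE = 3
_STAGE_CLUSTER = 4


@dataclass(frozen=True)
class SyntheticConfig:
    """Study-scale defaults: 20,000 genes and 4,000 peaks on a 1 Gbp genome
    (5 chromosomes of 200 Mbp, one gene per ~50 kbp — mammalian-like
    density), 200-bp peaks, a 200-gene target set with half the peaks
    planted within 10 kbp of target TSSs, and a signal cluster of 100
    targets diluted with 20 non-targets."""

    n_chroms: int = 5
    chrom_length: int = 200_000_000
    n_genes: int = 20_000
    n_peaks: int = 4_000
    peak_width: int = 200
    target_set_size: int = 200
    planting_fraction: float = 0.5
    planting_distance: int = 10_000
    cluster_signal_size: int = 100
    cluster_noise_size: int = 20
    de_effect_fraction: float = 0.9
    seed: int = 1

    def __post_init__(self) -> None:
        if not (
            self.n_chroms > 0
            and self.chrom_length > 0
            and self.n_genes > 0
            and self.n_peaks > 0
            and self.peak_width > 0
        ):
            raise ValueError("all counts and lengths must be positive")
        if self.peak_width >= self.chrom_length:
            raise ValueError("peak_width must be smaller than chrom_length")
        if self.target_set_size > self.n_genes:
            raise ValueError("target_set_size cannot exceed n_genes")
        if not 0.0 <= self.planting_fraction <= 1.0:
            raise ValueError("planting_fraction must be in [0, 1]")
        if not 0.0 <= self.de_effect_fraction <= 1.0:
            raise ValueError("de_effect_fraction must be in [0, 1]")
        if self.planting_distance < 0:
            raise ValueError("planting_distance must be >= 0")
        if self.cluster_signal_size > self.target_set_size:
            raise ValueError("cluster_signal_size cannot exceed target_set_size")
        if self.n_genes > self.n_chroms * self.chrom_length:
            raise ValueError("gene density infeasible for genome size")

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SyntheticConfig":
        with open(path) as fh:
            return cls(**yaml.safe_load(fh))


@dataclass
class SyntheticTruth:
    """The planted structure: who the targets are and which peaks were
    placed near them."""

    target_genes: set[str]
    planted_peak_indices: set[int]
    planting_fraction: float
    planting_distance: int
    transcripts: list[TranscriptRecord] = field(default_factory=list, repr=False)


def _rng(seed: int, stage: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=(stage,)))


def generate_annotation(
    config: SyntheticConfig, seed: int | None = None
) -> tuple[GeneUniverse, dict[str, int], list[TranscriptRecord]]:
    """Uniform TSSs, Bernoulli(0.5) strands, one transcript per gene.

    Returns the universe, the chromosome bounds, and the transcript records
    (for writing the refGene-style file).  Deterministic for a fixed seed.
    """
    seed = config.seed if seed is None else seed
    rng = _rng(seed, _STAGE_ANNOTATION)
    chroms = [f"chr{i + 1}" for i in range(config.n_chroms)]
    bounds = {c: config.chrom_length for c in chroms}
    chrom_idx = rng.integers(0, config.n_chroms, size=config.n_genes)
    tss = rng.integers(0, config.chrom_length, size=config.n_genes)
    minus = rng.random(config.n_genes) < 0.5
    lengths = rng.integers(500, 50_000, size=config.n_genes)
    width = len(str(config.n_genes))
    records: list[TranscriptRecord] = []
    for i in range(config.n_genes):
        chrom = chroms[chrom_idx[i]]
        t = int(tss[i])
        L = int(lengths[i])
        if minus[i]:
            tx_end = t + 1
            tx_start = max(0, tx_end - L)
            strand = "-"
        else:
            tx_start = t
            tx_end = min(config.chrom_length, t + L)
            strand = "+"
        records.append(
            TranscriptRecord(
                gene_symbol=f"G{i:0{width}d}",
                chrom=chrom,
                strand=strand,
                tx_start=tx_start,
                tx_end=tx_end,
            )
        )
    return universe_from_transcripts(records), bounds, records


def select_target_genes(
    config: SyntheticConfig, universe: GeneUniverse, seed: int | None = None
) -> set[str]:
    """Draw the designated target-gene subset uniformly from the universe."""
    seed = config.seed if seed is None else seed
    rng = _rng(seed, _STAGE_TARGETS)
    symbols = sorted(universe.genes)
    chosen = rng.choice(len(symbols), size=config.target_set_size, replace=False)
    return {symbols[i] for i in chosen}


def generate_peaks(
    config: SyntheticConfig,
    universe: GeneUniverse,
    truth_targets: set[str],
    seed: int | None = None,
) -> tuple[PeakSet, SyntheticTruth]:
    """Planted peaks centered uniformly within [-d₀, d₀] of a random target
    TSS; the rest uniform on the genome.  All clipped to bounds."""
    seed = config.seed if seed is None else seed
    rng = _rng(seed, _STAGE_PEAKS)
    w = config.peak_width
    L = config.chrom_length
    chroms = [f"chr{i + 1}" for i in range(config.n_chroms)]
    n_planted = round(config.planting_fraction * config.n_peaks)
    target_sites = sorted(
        (chrom, pos)
        for symbol in sorted(truth_targets)
        for chrom, pos, _strand in universe.genes[symbol]
    )
    peaks: list[Peak] = []
    for i in range(config.n_peaks):
        if i < n_planted:
            chrom, tss = target_sites[rng.integers(0, len(target_sites))]
            d0 = config.planting_distance
            center = int(tss) + int(rng.integers(-d0, d0 + 1))
            start = center - w // 2
        else:
            chrom = chroms[rng.integers(0, config.n_chroms)]
            start = int(rng.integers(0, L - w))
        start = min(max(0, start), L - w)  # keep full width inside bounds
        peaks.append(Peak(chrom=chrom, start=start, end=start + w, label=f"peak{i}"))
    truth = SyntheticTruth(
        target_genes=set(truth_targets),
        planted_peak_indices=set(range(n_planted)),
        planting_fraction=config.planting_fraction,
        planting_distance=config.planting_distance,
    )
    return PeakSet(name="synthetic_peaks", peaks=peaks), truth


def generate_de_tables(
    config: SyntheticConfig,
    truth: SyntheticTruth,
    universe: GeneUniverse,
    seed: int | None = None,
) -> tuple[DETable, DETable]:
    """Two DE contrasts sharing the planted targets as significant-up.

    In each table independently, a target gene is significant-up
    (fdr < 0.05, log_fc > 0) with probability ``de_effect_fraction``;
    every other gene is a null draw, significant at the nominal 5% rate
    (fdr ~ U(0,1)) with a random fold-change sign.
    """
    seed = config.seed if seed is None else seed
    rng = _rng(seed, _STAGE_DE)
    symbols = sorted(universe.genes)
    is_target = np.array([s in truth.target_genes for s in symbols])
    tables = []
    for _contrast in range(2):
        n = len(symbols)
        fdr = rng.random(n)
        log_fc = rng.normal(0.0, 1.0, size=n)
        hit = is_target & (rng.random(n) < config.de_effect_fraction)
        fdr[hit] = rng.random(hit.sum()) * 0.05
        log_fc[hit] = np.abs(rng.normal(2.0, 0.5, size=hit.sum())) + 1e-9
        frame = pd.DataFrame({"gene": symbols, "log_fc": log_fc, "fdr": fdr})
        tables.append(build_de_table(frame, source="synthetic"))
    return tables[0], tables[1]


def make_signal_cluster(
    config: SyntheticConfig,
    truth: SyntheticTruth,
    universe: GeneUniverse,
    seed: int | None = None,
) -> GeneCluster:
    """A test cluster of planted targets diluted with random non-targets."""
    seed = config.seed if seed is None else seed
    rng = _rng(seed, _STAGE_CLUSTER)
    targets = sorted(truth.target_genes)
    non_targets = sorted(set(universe.genes) - truth.target_genes)
    signal = rng.choice(len(targets), size=config.cluster_signal_size, replace=False)
    noise = rng.choice(len(non_targets), size=config.cluster_noise_size, replace=False)
    members = {targets[i] for i in signal} | {non_targets[i] for i in noise}
    return GeneCluster(name="signal_cluster", members=members, direction="up")


def recovered_planting_distance(results) -> int:
    """Estimate the planting distance from one cluster's enrichment profile.

    The profile of -log10(p) against λ rises while widening peaks captures
    planted targets faster than background genes and falls once the cluster
    is saturated and only background accumulates; its maximum therefore sits
    at the characteristic peak-to-TSS distance.  Returns the λ of the most
    significant test (smallest p; ties broken toward the smaller λ).
    """
    if not results:
        raise ValueError("no enrichment results to estimate from")
    best = min(results, key=lambda r: (r.p, r.lam))
    return best.lam


def random_cluster(
    universe: GeneUniverse, size: int, rng: np.random.Generator
) -> GeneCluster:
    symbols = sorted(universe.genes)
    idx = rng.choice(len(symbols), size=size, replace=False)
    return GeneCluster(name="random_cluster", members={symbols[i] for i in idx})


@dataclass
class SyntheticBundle:
    config: SyntheticConfig
    universe: GeneUniverse
    bounds: dict[str, int]
    transcripts: list[TranscriptRecord]
    peaks: PeakSet
    truth: SyntheticTruth
    de_tables: tuple[DETable, DETable]
    signal_cluster: GeneCluster


def simulate_bundle(
    config: SyntheticConfig, seed: int | None = None
) -> SyntheticBundle:
    """Run every generator stage and return the in-memory bundle."""
    seed = config.seed if seed is None else seed
    universe, bounds, transcripts = generate_annotation(config, seed)
    targets = select_target_genes(config, universe, seed)
    peaks, truth = generate_peaks(config, universe, targets, seed)
    truth.transcripts = transcripts
    de_tables = generate_de_tables(config, truth, universe, seed)
    cluster = make_signal_cluster(config, truth, universe, seed)
    return SyntheticBundle(
        config=dataclasses.replace(config, seed=seed),
        universe=universe,
        bounds=bounds,
        transcripts=transcripts,
        peaks=peaks,
        truth=truth,
        de_tables=de_tables,
        signal_cluster=cluster,
    )


def write_bundle(bundle: SyntheticBundle, outdir: str | Path) -> dict[str, Path]:
    """Write the bundle in the exact dialects the pipeline reads.

    Layout: annotation.refgene.tsv, bounds.bed, BED_FILES/peaks.bed,
    GENE_LISTS/signal_cluster.txt, de_table_{1,2}.tsv, truth.yaml,
    config.yaml.  All writers are bit-stable for a fixed seed.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    (outdir / "BED_FILES").mkdir(exist_ok=True)
    (outdir / "GENE_LISTS").mkdir(exist_ok=True)
    paths = {
        "annotation": outdir / "annotation.refgene.tsv",
        "bounds": outdir / "bounds.bed",
        "peaks": outdir / "BED_FILES" / "peaks.bed",
        "cluster": outdir / "GENE_LISTS" / "signal_cluster.txt",
        "de_table_1": outdir / "de_table_1.tsv",
        "de_table_2": outdir / "de_table_2.tsv",
        "truth": outdir / "truth.yaml",
        "config": outdir / "config.yaml",
    }
    write_refgene(bundle.transcripts, paths["annotation"])
    write_chrom_bounds(bundle.bounds, paths["bounds"])
    write_bed(bundle.peaks, paths["peaks"])
    write_gene_list(bundle.signal_cluster, paths["cluster"])
    for key, table in zip(("de_table_1", "de_table_2"), bundle.de_tables):
        table.frame.rename(
            columns={"gene": "gene", "log_fc": "logFC", "fdr": "FDR"}
        ).to_csv(paths[key], sep="\t", index=False, float_format="%.10g")
    with open(paths["truth"], "w") as fh:
        yaml.safe_dump(
            {
                "target_genes": sorted(bundle.truth.target_genes),
                "planted_peak_indices": sorted(bundle.truth.planted_peak_indices),
                "planting_fraction": bundle.truth.planting_fraction,
                "planting_distance": bundle.truth.planting_distance,
            },
            fh,
            sort_keys=True,
        )
    bundle.config.to_yaml(paths["config"])
    return paths
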