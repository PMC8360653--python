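"""Shared fixtures and independent brute-force oracles.

The oracles deliberately avoid the production code paths: gene capture is
an all-pairs loop over (gene, TSS, peak), and the hypergeometric tail is an
exact rational enumeration of the pmf.  Production results are checked
against these on small random instances.
"""

from __future__ import annotations

from fractions import Fraction
from math import comb

import numpy as np
import pytest
from hypothesis import settings

from tssenrich.annotation import GeneUniverse
from tssenrich.intervals import Peak, PeakSet

settings.register_profile("ci", deadline=None, derandomize=True)
settings.load_profile("ci")


def make_universe(genes: dict[str, set[tuple[str, int, str]]]) -> GeneUniverse:
    return GeneUniverse({k: set(v) for k, v in genes.items()})


def brute_genes_near_peaks(peakset, lam, universe, mode="edges", bounds=None):
    """All-pairs TSS-in-extended-peak scan, one extension at a time."""
    near = set()
    for symbol, sites in universe.genes.items():
        for chrom, tss, _strand in sites:
            for peak in peakset:
                if peak.chrom != chrom:
                    continue
                if mode == "edges":
                    start, end = peak.start - lam, peak.end + lam
                else:
                    c = (peak.start + peak.end) // 2
                    start, end = c - lam, c + lam + 1
                start = max(0, start)
                if bounds is not None and chrom in bounds:
                    end = min(end, bounds[chrom])
                if start <= tss < end:
                    near.add(symbol)
    return near


def brute_hypergeom_upper_tail(N: int, K: int, n: int, k: int) -> Fraction:
    """Exact rational P(X >= k) by full enumeration of the pmf."""
    total = comb(N, n)
    tail = sum(comb(K, i) * comb(N - K, n - i) for i in range(k, min(K, n) + 1))
    return Fraction(tail, total)


def brute_intersect(primary: PeakSet, others) -> list[Peak]:
    """All-pairs half-open overlap check against every other set."""
    kept = []
    for p in primary:
        if all(any(p.overlaps(q) for q in other) for other in others):
            kept.append(p)
    return kept


def random_micro_instance(rng: np.random.Generator):
    """A tiny random genome: <=50 genes, <=20 peaks, one or two chromosomes."""
    n_chroms = int(rng.integers(1, 3))
    chrom_len = int(rng.integers(5_000, 50_000))
    bounds = {f"c{i}": chrom_len for i in range(n_chroms)}
    n_genes = int(rng.integers(1, 51))
    genes = {}
    for g in range(n_genes):
        chrom = f"c{rng.integers(0, n_chroms)}"
        pos = int(rng.integers(0, chrom_len))
        strand = "+" if rng.random() < 0.5 else "-"
        genes.setdefault(f"g{g}", set()).add((chrom, pos, strand))
    universe = make_universe(genes)
    n_peaks = int(rng.integers(1, 21))
    peaks = []
    for i in range(n_peaks):
        chrom = f"c{rng.integers(0, n_chroms)}"
        start = int(rng.integers(0, chrom_len - 10))
        width = int(rng.integers(1, 500))
        peaks.append(Peak(chrom=chrom, start=start, end=min(start + width, chrom_len)))
    return universe, PeakSet(name="micro", peaks=peaks), bounds


@pytest.fixture
def tiny_universe() -> GeneUniverse:
    """Three genes on chr1 with TSSs at 1000 / 5000 / 9000."""
    return make_universe(
        {
            "geneA": {("chr1", 1000, "+")},
            "geneB": {("chr1", 5000, "+")},
            "geneC": {("chr1", 9000, "-")},
        }
    )


@pytest.fixture
def tiny_bounds() -> dict[str, int]:
    return {"chr1": 1_000_000, "chr2": 1_000_000}
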