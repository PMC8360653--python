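"""Peak-set enrichment of gene sets.

For each extension distance λ on the ladder, every peak is widened by λ and
the genes with at least one TSS inside an extended peak are collected.  A
gene cluster's overlap with that near-peak set is then tested for
over-representation with an upper-tail hypergeometric test whose background
is the whole gene universe:

    N = background genes, K = cluster genes in the background,
    n = genes near a peak at λ, k = cluster genes near a peak at λ,
    p = P(X >= k),  X ~ Hypergeometric(N, K, n)

Fold enrichment is (k/n)/(K/N): 1 means the cluster hits near-peak genes at
exactly the background rate.  Raw p is the primary statistic; a
Benjamini-Hochberg adjusted value is carried as an extra column.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from typing import TYPE_CHECKING, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import hypergeom

from .annotation import GeneUniverse
from .intervals import ChromBounds, PeakSet, extend_arrays, merge_intervals

if TYPE_CHECKING:  # pragma: no cover
    from .gene_sets import GeneCluster

logger = logging.getLogger(__name__)

#: The default extension-distance ladder, 100 bp to 10 Mbp.
DEFAULT_LADDER = (
    100,
    500,
    1_000,
    5_000,
    10_000,
    50_000,
    100_000,
    500_000,
    1_000_000,
    5_000_000,
    10_000_000,
)


@dataclass(frozen=True)
class DistanceLadder:
    distances: tuple[int, ...] = DEFAULT_LADDER

    def __post_init__(self) -> None:
        d = self.distances
        if not d:
            raise ValueError("distance ladder must be non-empty")
        if any(x < 0 for x in d):
            raise ValueError("distances must be >= 0")
        if any(b <= a for a, b in zip(d, d[1:])):
            raise ValueError("distances must be strictly increasing")

    def __iter__(self):
        return iter(self.distances)

    def __len__(self) -> int:
        return len(self.distances)

    @classmethod
    def parse(cls, text: str) -> "DistanceLadder":
        """Parse a comma- or whitespace-separated distance list."""
        parts = text.replace(",", " ").split()
        return cls(tuple(int(p) for p in parts))


@dataclass
class EnrichmentResult:
    """One (peak set x cluster x distance) hypergeometric test."""

    peakset_name: str
    cluster_name: str
    lam: int
    N: int
    K: int
    n: int
    k: int
    fold: float
    p: float
    p_adj: float | None = None


def genes_near_peaks(
    peakset: PeakSet,
    lam: int,
    universe: GeneUniverse,
    mode: str = "edges",
    bounds: ChromBounds | None = None,
) -> set[str]:
    """Genes with >=1 transcript TSS inside >=1 peak extended by ``lam``.

    Each gene is counted once no matter how many peaks or TSSs hit.  Peaks
    on chromosomes without annotated genes contribute nothing (logged at
    debug level); genes on chromosomes without peaks are simply never
    captured.
    """
    tss_index = universe.tss_index()
    near: set[str] = set()
    for chrom, arr in peakset.by_chrom().items():
        if chrom not in tss_index:
            logger.debug("peaks on %s have no annotated genes", chrom)
            continue
        length = bounds[chrom] if bounds is not None and chrom in bounds else None
        if length is None:
            # no clipping bound: use an effectively unbounded chromosome
            length = np.iinfo(np.int64).max
        extended = extend_arrays(arr, lam, mode, length)
        merged = merge_intervals(extended)
        pos, names = tss_index[chrom]
        lo = np.searchsorted(pos, merged[:, 0], side="left")
        hi = np.searchsorted(pos, merged[:, 1], side="left")
        for a, b in zip(lo, hi):
            if b > a:
                near.update(names[a:b])
    return near


def hypergeom_upper_tail(N: int, K: int, n: int, k: int) -> float:
    """P(X >= k) for X ~ Hypergeometric(N, K, n), inclusive upper tail.

    Computed through the exact survival function (log-space fallback guards
    against underflow so the returned probability is always in (0, 1]).
    """
    _check_counts(N, K, n, k)
    if k == 0:
        return 1.0
    p = float(hypergeom.sf(k - 1, N, K, n))
    if p <= 0.0:
        logp = float(hypergeom.logsf(k - 1, N, K, n))
        p = float(np.exp(logp)) if np.isfinite(logp) else 0.0
    if p <= 0.0:
        p = float(np.nextafter(0, 1))  # smallest positive float
    return min(p, 1.0)


def fold_enrichment(N: int, K: int, n: int, k: int) -> float:
    """(k/n)/(K/N); 0 when the near-peak set or the overlap is empty."""
    _check_counts(N, K, n, k)
    if K == 0:
        raise ValueError("empty cluster has no fold enrichment (K=0)")
    if n == 0 or k == 0:
        return 0.0
    return (k / n) / (K / N)


def _check_counts(N: int, K: int, n: int, k: int) -> None:
    if not (0 <= k <= min(K, n) and K <= N and n <= N):
        raise ValueError(
            f"invalid hypergeometric counts: N={N}, K={K}, n={n}, k={k} "
            "(require 0 <= k <= min(K, n) <= N)"
        )


def adjust_bh(results: list[EnrichmentResult]) -> list[EnrichmentResult]:
    """Fill ``p_adj`` with Benjamini-Hochberg step-up values across all tests.

    Monotonicity is enforced (step-up), and p_adj >= p always holds.
    """
    if not results:
        return results
    p = np.array([r.p for r in results], dtype=float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    adjusted = np.minimum.accumulate(ranked[::-1])[::-1]
    adjusted = np.minimum(adjusted, 1.0)
    p_adj = np.empty(m, dtype=float)
    p_adj[order] = adjusted
    return [replace(r, p_adj=float(q)) for r, q in zip(results, p_adj)]


def pegs_scan(
    peaksets: Sequence[PeakSet],
    clusters: Sequence["GeneCluster"],
    ladder: DistanceLadder,
    universe: GeneUniverse,
    bounds: ChromBounds | None = None,
    mode: str = "edges",
) -> list[EnrichmentResult]:
    """Run the full enrichment grid: one test per (peak set x cluster x λ).

    Cluster members absent from the universe are dropped from both K and k
    (the urn must be self-consistent) with a logged count; a cluster fully
    absent from the universe is reported and skipped while the scan
    continues.  BH adjustment is applied across the whole grid.
    """
    N = universe.N
    usable: list[tuple[str, set[str]]] = []
    for cluster in clusters:
        members = universe.restrict(cluster.members)
        dropped = len(cluster.members) - len(members)
        if dropped:
            logger.info(
                "cluster %s: %d member(s) absent from the gene universe dropped",
                cluster.name,
                dropped,
            )
        if not members:
            logger.error(
                "cluster %s has no members in the gene universe; skipped",
                cluster.name,
            )
            continue
        usable.append((cluster.name, members))
    if not usable:
        raise ValueError("no cluster has any member in the gene universe")

    results: list[EnrichmentResult] = []
    for peakset in peaksets:
        for lam in ladder:
            near = genes_near_peaks(peakset, lam, universe, mode=mode, bounds=bounds)
            n = len(near)
            for name, members in usable:
                K = len(members)
                k = len(members & near)
                results.append(
                    EnrichmentResult(
                        peakset_name=peakset.name,
                        cluster_name=name,
                        lam=lam,
                        N=N,
                        K=K,
                        n=n,
                        k=k,
                        fold=fold_enrichment(N, K, n, k),
                        p=hypergeom_upper_tail(N, K, n, k),
                    )
                )
    return adjust_bh(results)


RESULT_COLUMNS = [
    "peakset",
    "cluster",
    "lambda_bp",
    "N",
    "K",
    "n",
    "k",
    "fold",
    "p",
    "p_adj",
]


def results_to_frame(results: Sequence[EnrichmentResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            (r.peakset_name, r.cluster_name, r.lam, r.N, r.K, r.n, r.k, r.fold, r.p, r.p_adj)
            for r in results
        ],
        columns=RESULT_COLUMNS,
    )


def write_results_tsv(results: Sequence[EnrichmentResult], path) -> None:
    """Long-format TSV; numbers printed with repr-stable formatting."""
    frame = results_to_frame(results)
    frame.to_csv(path, sep="\t", index=False, float_format="%.6g")


def neglog10p_matrix(
    results: Sequence[EnrichmentResult], peakset_name: str
) -> pd.DataFrame:
    """Wide matrix (clusters x distances) of -log10(p) for one peak set."""
    frame = results_to_frame(results)
    frame = frame[frame["peakset"] == peakset_name]
    frame = frame.assign(neglog10_p=-np.log10(frame["p"]))
    return frame.pivot(index="cluster", columns="lambda_bp", values="neglog10_p")


def plot_enrichment(
    results: Sequence[EnrichmentResult],
    path,
    value: str = "fold",
) -> None:
    """Line plot of fold enrichment (or -log10 p) against λ per cluster."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    frame = results_to_frame(results)
    fig, ax = plt.subplots(figsize=(6, 4))
    for (peakset, cluster), sub in frame.groupby(["peakset", "cluster"]):
        y = sub["fold"] if value == "fold" else -np.log10(sub["p"])
        ax.plot(sub["lambda_bp"], y, marker="o", label=f"{peakset}:{cluster}")
    ax.set_xscale("log")
    ax.set_xlabel("extension distance λ (bp)")
    ax.set_ylabel("fold enrichment" if value == "fold" else "-log10 p")
    if value == "fold":
        ax.axhline(1.0, color="grey", lw=0.8, ls="--")
    ax.legend(fontsize=7)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
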