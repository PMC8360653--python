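"""Gene annotation parsing and the strand-aware TSS universe.

The background ("universe") for every enrichment test is the set of distinct
gene symbols in the annotation, each carrying one or more transcription
start sites (TSSs).  The TSS of a transcript is its first transcribed base:
the interval start on the plus strand, the last base (``end - 1``) on the
minus strand.  All coordinates are 0-based, half-open (BED convention);
refGene txStart/txEnd are already in that convention, so no shift is applied
on ingest.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np

logger = logging.getLogger(__name__)

STRANDS = ("+", "-")

#: (chrom, tss_position, strand)
TSS = tuple[str, int, str]


def normalize_chrom(name: str, policy: str = "keep") -> str:
    """Apply a uniform chromosome-prefix policy: keep, strip or add ``chr``."""
    if policy == "keep":
        return name
    if policy == "strip":
        return name[3:] if name.startswith("chr") else name
    if policy == "add":
        return name if name.startswith("chr") else "chr" + name
    raise ValueError(f"unknown chrom-prefix policy: {policy!r}")


def transcript_tss(tx_start: int, tx_end: int, strand: str) -> int:
    """0-based TSS of a transcript: start on ``+``, ``end - 1`` on ``-``."""
    if tx_start >= tx_end:
        raise ValueError(f"tx_start must be < tx_end, got [{tx_start}, {tx_end})")
    if strand == "+":
        return tx_start
    if strand == "-":
        return tx_end - 1
    raise ValueError(f"unknown strand: {strand!r}")


@dataclass(frozen=True)
class TranscriptRecord:
    """One transcript row of a gene annotation."""

    gene_symbol: str
    chrom: str
    strand: str
    tx_start: int
    tx_end: int

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("chrom must be non-empty")
        if self.strand not in STRANDS:
            raise ValueError(f"unknown strand: {self.strand!r}")
        if not 0 <= self.tx_start < self.tx_end:
            raise ValueError(
                f"require 0 <= tx_start < tx_end, got [{self.tx_start}, {self.tx_end})"
            )

    @property
    def tss(self) -> int:
        return transcript_tss(self.tx_start, self.tx_end, self.strand)


@dataclass
class GeneUniverse:
    """Background gene set: symbol -> set of (chrom, tss, strand).

    ``N`` (the hypergeometric background size) is the number of distinct
    gene symbols, not transcripts; a gene with several annotated transcripts
    still counts once.
    """

    genes: dict[str, set[TSS]]
    _chrom_index: dict[str, tuple[np.ndarray, np.ndarray]] | None = field(
        default=None, repr=False, compare=False
    )

    @property
    def N(self) -> int:
        return len(self.genes)

    def __len__(self) -> int:
        return self.N

    def __contains__(self, symbol: str) -> bool:
        return symbol in self.genes

    def symbols(self) -> set[str]:
        return set(self.genes)

    def restrict(self, symbols: Iterable[str]) -> set[str]:
        """Subset of ``symbols`` present in the universe."""
        return {s for s in symbols if s in self.genes}

    def tss_index(self) -> Mapping[str, tuple[np.ndarray, np.ndarray]]:
        """Per-chromosome sorted TSS positions with parallel gene-symbol array.

        Built lazily and cached; the universe is treated as immutable once
        queried.
        """
        if self._chrom_index is None:
            by_chrom: dict[str, list[tuple[int, str]]] = {}
            for symbol, sites in self.genes.items():
                for chrom, pos, _strand in sites:
                    by_chrom.setdefault(chrom, []).append((pos, symbol))
            index: dict[str, tuple[np.ndarray, np.ndarray]] = {}
            for chrom, entries in by_chrom.items():
                entries.sort()
                pos = np.array([p for p, _ in entries], dtype=np.int64)
                names = np.array([s for _, s in entries], dtype=object)
                index[chrom] = (pos, names)
            self._chrom_index = index
        return self._chrom_index

    def check_bounds(self, bounds: Mapping[str, int]) -> list[str]:
        """Validate TSSs against chromosome lengths; return chroms missing
        from the bounds (their genes stay in N but can never be near a peak).
        """
        missing: set[str] = set()
        for symbol, sites in self.genes.items():
            for chrom, pos, _ in sites:
                if chrom not in bounds:
                    missing.add(chrom)
                elif not 0 <= pos < bounds[chrom]:
                    raise ValueError(
                        f"TSS of {symbol} at {chrom}:{pos} outside chromosome "
                        f"bounds [0, {bounds[chrom]})"
                    )
        if missing:
            logger.warning(
                "%d chromosome(s) in annotation absent from bounds: %s "
                "(their genes remain in the background but can never be near "
                "a peak)",
                len(missing),
                ", ".join(sorted(missing)),
            )
        return sorted(missing)


def universe_from_transcripts(
    records: Iterable[TranscriptRecord], case_insensitive: bool = False
) -> GeneUniverse:
    genes: dict[str, set[TSS]] = {}
    for rec in records:
        symbol = rec.gene_symbol.upper() if case_insensitive else rec.gene_symbol
        genes.setdefault(symbol, set()).add((rec.chrom, rec.tss, rec.strand))
    return GeneUniverse(genes)


# Default column indices for the refGene-style TSV layout.
REFGENE_COLUMNS = {"symbol": 0, "chrom": 1, "strand": 2, "start": 3, "end": 4}


def load_gene_annotation(
    path: str | Path,
    format: str = "refgene",
    columns: Mapping[str, int] | None = None,
    case_insensitive: bool = False,
    chrom_prefix: str = "keep",
) -> GeneUniverse:
    """Load a gene annotation and build the TSS universe.

    Parameters
    ----------
    path
        refGene-style TSV or BED6 file.
    format
        ``"refgene"``: tab-separated with configurable column indices
        (defaults: symbol, chrom, strand, txStart, txEnd).
        ``"bed"``: BED6, the name field is the gene symbol.
    columns
        Column-index overrides for the refgene layout.
    case_insensitive
        Fold gene symbols to upper case before deduplication.
    chrom_prefix
        ``keep`` / ``strip`` / ``add`` a ``chr`` prefix uniformly.

    Rows with malformed coordinates are rejected and counted in the log;
    an unknown strand character raises immediately, naming the line.
    """
    path = Path(path)
    if format not in ("refgene", "bed"):
        raise ValueError(f"unknown annotation format: {format!r}")
    if not path.exists():
        raise FileNotFoundError(f"annotation file not found: {path}")
    cols = dict(REFGENE_COLUMNS)
    if columns:
        cols.update(columns)
    records: list[TranscriptRecord] = []
    n_malformed = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            try:
                if format == "refgene":
                    symbol = fields[cols["symbol"]]
                    chrom = fields[cols["chrom"]]
                    strand = fields[cols["strand"]]
                    start = fields[cols["start"]]
                    end = fields[cols["end"]]
                else:  # bed6: chrom start end name score strand
                    chrom, start, end, symbol, _score, strand = fields[:6]
            except IndexError:
                n_malformed += 1
                continue
            if strand not in STRANDS:
                raise ValueError(
                    f"{path}:{lineno}: unknown strand character {strand!r}"
                )
            try:
                rec = TranscriptRecord(
                    gene_symbol=symbol,
                    chrom=normalize_chrom(chrom, chrom_prefix),
                    strand=strand,
                    tx_start=int(start),
                    tx_end=int(end),
                )
            except ValueError:
                n_malformed += 1
                continue
            records.append(rec)
    if n_malformed:
        logger.info("%s: rejected %d malformed row(s)", path, n_malformed)
    if not records:
        raise ValueError(f"{path}: no valid annotation rows (empty universe)")
    return universe_from_transcripts(records, case_insensitive=case_insensitive)


def write_refgene(records: Iterable[TranscriptRecord], path: str | Path) -> None:
    """Write transcripts in the refGene-style TSV layout (bit-stable)."""
    with open(path, "w") as fh:
        for rec in records:
            fh.write(
                f"{rec.gene_symbol}\t{rec.chrom}\t{rec.strand}"
                f"\t{rec.tx_start}\t{rec.tx_end}\n"
            )
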