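"""Peak I/O, peak-set intersection and distance extension with clipping.

All intervals are 0-based half-open.  Two intervals overlap iff they share
at least one base under half-open arithmetic: ``a.start < b.end and
b.start < a.end`` — an interval ending exactly where another begins does
not overlap it (bedtools-compatible).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Mapping, Sequence

import numpy as np

from .annotation import normalize_chrom

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class Peak:
    chrom: str
    start: int
    end: int
    label: str | None = None

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("chrom must be non-empty")
        if not 0 <= self.start < self.end:
            raise ValueError(
                f"require 0 <= start < end, got {self.chrom}:{self.start}-{self.end}"
            )

    def overlaps(self, other: "Peak") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )

    @property
    def center(self) -> int:
        return (self.start + self.end) // 2


@dataclass
class PeakSet:
    """An ordered, possibly overlapping collection of peaks under one label.

    No merging happens on load; overlap structure of the input is preserved.
    """

    name: str
    peaks: list[Peak] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.peaks)

    def __iter__(self) -> Iterator[Peak]:
        return iter(self.peaks)

    def by_chrom(self) -> dict[str, np.ndarray]:
        """chrom -> (n, 2) array of [start, end), in input order."""
        out: dict[str, list[list[int]]] = {}
        for p in self.peaks:
            out.setdefault(p.chrom, []).append([p.start, p.end])
        return {c: np.array(v, dtype=np.int64) for c, v in out.items()}


ChromBounds = Mapping[str, int]  # chrom -> length


def read_bed(
    path: str | Path, name: str | None = None, chrom_prefix: str = "keep"
) -> PeakSet:
    """Read a BED3+ file into a PeakSet (track/browser/# lines skipped)."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"BED file not found: {path}")
    if name is None:
        name = path.stem
    peaks: list[Peak] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"{path}:{lineno}: expected >=3 tab-separated columns")
            try:
                peak = Peak(
                    chrom=normalize_chrom(fields[0], chrom_prefix),
                    start=int(fields[1]),
                    end=int(fields[2]),
                    label=fields[3] if len(fields) > 3 else None,
                )
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: {exc}") from exc
            peaks.append(peak)
    if not peaks:
        logger.warning("%s: empty BED file", path)
    return PeakSet(name=name, peaks=peaks)


def write_bed(peakset: PeakSet, path: str | Path) -> None:
    """Write peaks as BED (bit-stable; label column only when present)."""
    with open(path, "w") as fh:
        for p in peakset:
            if p.label is not None:
                fh.write(f"{p.chrom}\t{p.start}\t{p.end}\t{p.label}\n")
            else:
                fh.write(f"{p.chrom}\t{p.start}\t{p.end}\n")


def read_chrom_bounds(path: str | Path, chrom_prefix: str = "keep") -> dict[str, int]:
    """Chromosome lengths from BED3 (end column) or two-column chrom-sizes."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"bounds file not found: {path}")
    bounds: dict[str, int] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            chrom = normalize_chrom(fields[0], chrom_prefix)
            length = int(fields[2]) if len(fields) >= 3 else int(fields[1])
            if length <= 0:
                raise ValueError(f"{path}:{lineno}: non-positive chromosome length")
            bounds[chrom] = max(bounds.get(chrom, 0), length)
    if not bounds:
        raise ValueError(f"{path}: no chromosome bounds found")
    return bounds


def write_chrom_bounds(bounds: ChromBounds, path: str | Path) -> None:
    with open(path, "w") as fh:
        for chrom in sorted(bounds):
            fh.write(f"{chrom}\t0\t{bounds[chrom]}\n")


def _overlap_lookup(peakset: PeakSet):
    """Build a fast any-overlap query over one peak set.

    Per chromosome, peaks are sorted by start and a running maximum of ends
    is kept: an interval [s, e) overlaps some peak iff among peaks with
    start < e there is one with end > s.
    """
    index: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for chrom, arr in peakset.by_chrom().items():
        order = np.argsort(arr[:, 0], kind="stable")
        starts = arr[order, 0]
        ends_cummax = np.maximum.accumulate(arr[order, 1])
        index[chrom] = (starts, ends_cummax)

    def query(chrom: str, start: int, end: int) -> bool:
        if chrom not in index:
            return False
        starts, ends_cummax = index[chrom]
        i = int(np.searchsorted(starts, end, side="left"))
        return i > 0 and ends_cummax[i - 1] > start

    return query


def intersect_peak_sets(primary: PeakSet, others: Sequence[PeakSet]) -> PeakSet:
    """Peaks of ``primary`` overlapping (>=1 bp) at least one peak in every
    set of ``others``; primary coordinates are preserved.

    This is the "peaks commonly called by both strategies" operation: a
    high-confidence region is a primary peak supported by every comparison
    set.
    """
    if not others:
        raise ValueError("intersect_peak_sets requires at least one other set")
    queries = [_overlap_lookup(o) for o in others]
    kept = [
        p
        for p in primary
        if all(q(p.chrom, p.start, p.end) for q in queries)
    ]
    return PeakSet(name=primary.name, peaks=kept)


def extend_interval(
    peak: Peak, lam: int, mode: str = "edges", bounds: ChromBounds | None = None
) -> Peak:
    """Extend a peak by ``lam`` bp and clip to chromosome bounds.

    ``edges`` mode pads the interval on both sides: [start-lam, end+lam).
    ``center`` mode measures from the peak center c = floor((start+end)/2):
    [c-lam, c+lam+1).  The result is clipped to [0, chrom length) and is
    always non-empty.
    """
    if lam < 0:
        raise ValueError("extension distance must be >= 0")
    if mode == "edges":
        start, end = peak.start - lam, peak.end + lam
    elif mode == "center":
        c = peak.center
        start, end = c - lam, c + lam + 1
    else:
        raise ValueError(f"unknown extension mode: {mode!r}")
    start = max(0, start)
    if bounds is not None:
        if peak.chrom not in bounds:
            raise KeyError(f"chromosome {peak.chrom!r} missing from bounds")
        end = min(end, bounds[peak.chrom])
    return Peak(chrom=peak.chrom, start=start, end=end, label=peak.label)


def extend_arrays(
    arr: np.ndarray, lam: int, mode: str, chrom_length: int
) -> np.ndarray:
    """Vectorized :func:`extend_interval` over an (n, 2) interval array."""
    if mode == "edges":
        starts = arr[:, 0] - lam
        ends = arr[:, 1] + lam
    elif mode == "center":
        c = (arr[:, 0] + arr[:, 1]) // 2
        starts = c - lam
        ends = c + lam + 1
    else:
        raise ValueError(f"unknown extension mode: {mode!r}")
    return np.column_stack(
        (np.clip(starts, 0, None), np.clip(ends, None, chrom_length))
    )


def merge_intervals(arr: np.ndarray) -> np.ndarray:
    """Merge an (n, 2) array of half-open intervals into disjoint ones.

    Used internally for TSS lookup; membership of a point in the union is
    invariant under merging, which the test suite asserts against an
    unmerged brute-force scan.
    """
    if len(arr) == 0:
        return arr.reshape(0, 2)
    order = np.argsort(arr[:, 0], kind="stable")
    starts, ends = arr[order, 0], arr[order, 1]
    merged: list[list[int]] = [[int(starts[0]), int(ends[0])]]
    for s, e in zip(starts[1:], ends[1:]):
        if s <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], int(e))
        else:
            merged.append([int(s), int(e)])
    return np.array(merged, dtype=np.int64)
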