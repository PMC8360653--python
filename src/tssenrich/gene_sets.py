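"""Gene clusters from differential-expression tables, Venn intersections,
and classification of state-dependent direct targets.

A cluster is a named set of gene symbols with an optional regulation
direction.  Clusters are built from DE tables by the strict rule
``FDR < fdr_max`` (with sign of the log-fold-change selecting up/down;
log_fc exactly 0 belongs to neither direction), intersected across models
to define "common" DE genes, and classified against a second contrast and a
near-peak gene set to quantify direct, state-unmasked targets.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import pandas as pd

logger = logging.getLogger(__name__)


@dataclass
class GeneCluster:
    name: str
    members: set[str] = field(default_factory=set)
    direction: str = "none"  # {"up", "down", "none"}

    def __post_init__(self) -> None:
        if self.direction not in ("up", "down", "none"):
            raise ValueError(f"unknown direction: {self.direction!r}")
        self.members = set(self.members)

    def __len__(self) -> int:
        return len(self.members)


@dataclass
class DETable:
    """A differential-expression table: (gene_symbol, log_fc, fdr) rows.

    Symbols are unique (duplicates resolved by minimum FDR); NA/empty
    symbols are dropped on load, both with logged counts.
    """

    frame: pd.DataFrame  # columns: gene, log_fc, fdr

    def __post_init__(self) -> None:
        required = {"gene", "log_fc", "fdr"}
        if not required.issubset(self.frame.columns):
            raise ValueError(f"DE table needs columns {sorted(required)}")
        bad = ~self.frame["fdr"].between(0.0, 1.0)
        if bad.any():
            raise ValueError(f"{int(bad.sum())} FDR value(s) outside [0, 1]")
        if self.frame["gene"].duplicated().any():
            raise ValueError("duplicate gene symbols in DE table")

    def __len__(self) -> int:
        return len(self.frame)


def read_de_table(
    path: str | Path,
    gene_col: str = "gene",
    lfc_col: str = "logFC",
    fdr_col: str = "FDR",
) -> DETable:
    """Read a TSV/CSV DE table with a header (separator sniffed)."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"DE table not found: {path}")
    frame = pd.read_csv(path, sep=None, engine="python")
    missing = [c for c in (gene_col, lfc_col, fdr_col) if c not in frame.columns]
    if missing:
        raise ValueError(f"{path}: missing column(s) {missing}")
    frame = frame[[gene_col, lfc_col, fdr_col]].copy()
    frame.columns = ["gene", "log_fc", "fdr"]
    return build_de_table(frame, source=str(path))


def build_de_table(frame: pd.DataFrame, source: str = "<memory>") -> DETable:
    """Normalize a raw (gene, log_fc, fdr) frame into a valid DETable."""
    frame = frame.copy()
    na_mask = frame["gene"].isna() | (frame["gene"].astype(str).str.strip() == "") | (
        frame["gene"].astype(str) == "NA"
    )
    if na_mask.any():
        logger.info("%s: dropped %d row(s) with NA/empty gene symbol", source, int(na_mask.sum()))
        frame = frame[~na_mask]
    frame["gene"] = frame["gene"].astype(str)
    n_dup = int(frame["gene"].duplicated().sum())
    if n_dup:
        logger.info("%s: %d duplicate symbol(s) resolved by minimum FDR", source, n_dup)
        frame = frame.sort_values(["gene", "fdr"], kind="stable").drop_duplicates(
            "gene", keep="first"
        )
    frame = frame.reset_index(drop=True)
    return DETable(frame)


def select_significant(
    table: DETable,
    fdr_max: float = 0.05,
    direction: str = "both",
    name: str | None = None,
    inclusive: bool = False,
) -> GeneCluster:
    """Genes passing the FDR threshold with the requested fold-change sign.

    The threshold is strict (``fdr < fdr_max``) by default; ``inclusive``
    switches to ``<=``.  ``direction`` is ``up`` (log_fc > 0), ``down``
    (log_fc < 0) or ``both``; log_fc exactly 0 is excluded from up and down
    alike.
    """
    if not 0.0 < fdr_max <= 1.0:
        raise ValueError("fdr_max must be in (0, 1]")
    if direction not in ("up", "down", "both"):
        raise ValueError(f"unknown direction: {direction!r}")
    frame = table.frame
    sig = frame["fdr"] <= fdr_max if inclusive else frame["fdr"] < fdr_max
    if direction == "up":
        sig &= frame["log_fc"] > 0
    elif direction == "down":
        sig &= frame["log_fc"] < 0
    else:
        sig &= frame["log_fc"] != 0
    members = set(frame.loc[sig, "gene"])
    if not members:
        logger.warning("significance selection (%s, fdr<%g) is empty", direction, fdr_max)
    return GeneCluster(
        name=name or f"{direction}_fdr{fdr_max:g}",
        members=members,
        direction=direction if direction != "both" else "none",
    )


@dataclass(frozen=True)
class VennCounts:
    a_only: int
    common: int
    b_only: int


def intersect_clusters(a: GeneCluster, b: GeneCluster) -> tuple[GeneCluster, VennCounts]:
    """Common members of two clusters plus the two-set Venn counts."""
    if (
        a.direction != "none"
        and b.direction != "none"
        and a.direction != b.direction
    ):
        logger.warning(
            "intersecting clusters of opposite direction (%s vs %s)",
            a.direction,
            b.direction,
        )
    common = a.members & b.members
    counts = VennCounts(
        a_only=len(a.members - b.members),
        common=len(common),
        b_only=len(b.members - a.members),
    )
    direction = a.direction if a.direction == b.direction else "none"
    return (
        GeneCluster(name=f"{a.name}&{b.name}", members=common, direction=direction),
        counts,
    )


@dataclass
class TargetClassification:
    """Summary of a putative direct-target cluster.

    ``pct_down`` is the percentage of the cluster also significantly
    down-regulated in the second contrast, to one decimal; ``n_within_lambda``
    counts members with >=1 TSS within λ of a peak.
    """

    cluster_name: str
    total: int
    n_down_in_second_contrast: int
    pct_down: float
    n_within_lambda: int
    lambda_used: int

    def to_dict(self) -> dict:
        return {
            "cluster": self.cluster_name,
            "total": self.total,
            "n_down_in_second_contrast": self.n_down_in_second_contrast,
            "pct_down": self.pct_down,
            "n_within_lambda": self.n_within_lambda,
            "lambda_used": self.lambda_used,
        }

    def write_tsv(self, path) -> None:
        pd.DataFrame([self.to_dict()]).to_csv(path, sep="\t", index=False)

    def write_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)
            fh.write("\n")


def classify_targets(
    cluster: GeneCluster,
    second_contrast_down: GeneCluster,
    near_peak_genes: set[str],
    lam: int,
) -> TargetClassification:
    """Classify a cluster of putative direct targets.

    Counts members also in the down-regulated set of a second contrast
    (e.g. the diet response of intact animals) and members whose TSS lies
    within λ of a peak (``near_peak_genes`` computed by the enrichment
    module at that λ).
    """
    if not cluster.members:
        raise ValueError("cannot classify an empty cluster")
    total = len(cluster.members)
    n_down = len(cluster.members & second_contrast_down.members)
    return TargetClassification(
        cluster_name=cluster.name,
        total=total,
        n_down_in_second_contrast=n_down,
        pct_down=round(100.0 * n_down / total, 1),
        n_within_lambda=len(cluster.members & near_peak_genes),
        lambda_used=lam,
    )


def read_gene_list(path: str | Path, name: str | None = None) -> GeneCluster:
    """One gene symbol per line; blank lines and # comments skipped."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"gene list not found: {path}")
    members: set[str] = set()
    with open(path) as fh:
        for line in fh:
            symbol = line.strip()
            if symbol and not symbol.startswith("#"):
                members.add(symbol)
    direction = "none"
    stem = path.stem.lower()
    if stem.endswith("_up") or stem.startswith("up"):
        direction = "up"
    elif stem.endswith("_down") or stem.startswith("down"):
        direction = "down"
    return GeneCluster(name=name or path.stem, members=members, direction=direction)


def write_gene_list(cluster: GeneCluster, path: str | Path) -> None:
    with open(path, "w") as fh:
        for symbol in sorted(cluster.members):
            fh.write(symbol + "\n")
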