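"""Grouping reads with identical methylation patterns into clusters.

Two reads belong to the same cluster iff their binary patterns are identical
— exact grouping, equivalent to density clustering with a zero neighborhood
radius under Hamming distance, with the minimum-size drop playing the role of
the noise rule.  Groups with fewer than ``min_cluster_size`` reads (default 4)
are dropped; surviving clusters are a proxy for cell subpopulations.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from .ingest import Window
from .matrix import DEFAULT_CONDITIONS, ReadMethylationMatrix

CLUSTER_COLUMNS = ("chrom", "start", "end", "pattern", "size", "level", "count_A", "count_B")


@dataclass(frozen=True)
class PatternCluster:
    """A group of reads sharing one identical methylation pattern.

    ``level`` is the fraction of methylated CpGs in the pattern — the mean of
    its 0/1 entries.  ``count_a``/``count_b`` split the reads by condition;
    ``size = count_a + count_b``.
    """

    window: Window
    pattern: tuple[int, ...]
    size: int
    count_a: int
    count_b: int

    @property
    def level(self) -> float:
        return sum(self.pattern) / len(self.pattern)

    @property
    def pattern_string(self) -> str:
        return "".join(str(v) for v in self.pattern)


@dataclass(frozen=True)
class ClusterConfig:
    min_cluster_size: int = 4

    def __post_init__(self) -> None:
        if self.min_cluster_size < 1:
            raise ValueError("min_cluster_size must be >= 1")


def cluster_patterns(
    matrix: ReadMethylationMatrix,
    config: ClusterConfig = ClusterConfig(),
    conditions: Sequence[str] = DEFAULT_CONDITIONS,
) -> list[PatternCluster]:
    """Group the matrix's reads by exact pattern identity.

    Returns one cluster per distinct pattern occurring at least
    ``config.min_cluster_size`` times; reads with rarer patterns belong to no
    cluster.  Output is ordered by (level, pattern) so downstream results are
    byte-reproducible regardless of read input order.
    """
    cond_a, cond_b = conditions
    totals: Counter[tuple[int, ...]] = Counter()
    per_a: Counter[tuple[int, ...]] = Counter()
    for row, cond in zip(matrix.values, matrix.row_conditions):
        pat = tuple(int(v) for v in row)
        totals[pat] += 1
        if cond == cond_a:
            per_a[pat] += 1
    clusters = [
        PatternCluster(matrix.window, pat, size, per_a[pat], size - per_a[pat])
        for pat, size in totals.items()
        if size >= config.min_cluster_size
    ]
    clusters.sort(key=lambda c: (c.level, c.pattern))
    return clusters


def cluster_summary(clusters: Iterable[PatternCluster]) -> pd.DataFrame:
    """Per-cluster table: location, pattern, size, level, per-condition counts."""
    rows = [
        (
            c.window.chrom,
            c.window.start,
            c.window.end,
            c.pattern_string,
            c.size,
            c.level,
            c.count_a,
            c.count_b,
        )
        for c in clusters
    ]
    return pd.DataFrame(rows, columns=CLUSTER_COLUMNS)


def write_cluster_summary(clusters: Iterable[PatternCluster], path: str | Path) -> None:
    cluster_summary(clusters).to_csv(path, sep="\t", index=False)


def read_cluster_summary(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(
        path,
        sep="\t",
        dtype={"chrom": str, "pattern": str},
    )


def tanghulu(matrix: ReadMethylationMatrix, methylated: str = "●", unmethylated: str = "○") -> str:
    """Plain-text per-read rendering of a window's CpG states, one row per read.

    Mirrors the "tanghulu" plots used to display read-level methylation:
    filled circles for methylated CpGs, open for unmethylated.
    """
    w = matrix.window
    lines = [f"{w.chrom}:{w.start}-{w.end}  CpGs at {','.join(map(str, w.cpg_positions))}"]
    for rid, cond, row in zip(matrix.row_ids, matrix.row_conditions, matrix.values):
        dots = "".join(methylated if v else unmethylated for v in row)
        lines.append(f"{dots}  {cond}  {rid}")
    return "\n".join(lines)
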