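"""Condition-unique cluster detection, sector classification, permutation FPR.

A read cluster is *unique* to a condition when every one of its reads comes
from that condition; such clusters are the signal that a cell subpopulation
changed its methylation pattern between conditions.  For each window carrying
at least one cluster unique to condition A (control) and one unique to
condition B (knockout), every (unique-B level, unique-A level) pair is placed
in the plane whose x axis is the B-unique level and y axis the A-unique
level.  Quadrants of that plane, cut at a high threshold (default 0.55) and a
low threshold (default 0.45), define the sectors:

* sector 1 — both levels high;
* sector 2 — A-unique level >= high and B-unique level <= low: a
  substantially methylated cluster present only in the control, replaced in
  the knockout by a unique hypomethylated cluster (methylation lost in the
  affected cell type);
* sector 3 — both levels low;
* sector 4 — the converse of sector 2 (methylation gained).

Levels strictly between the thresholds (the dead band) disqualify a pair.  A
window is counted in every sector some pair of its unique clusters reaches,
so a window can in principle sit in both sectors 2 and 4.

The false-positive rate of each sector is estimated by permutation: within
each gated window, condition labels are shuffled across reads (preserving
per-condition read counts), the full clustering/uniqueness/sector pipeline is
re-run, and the mean permuted sector count over iterations is divided by the
observed count.  Under the null the labels are exchangeable and the ratio is
near 1; genuine condition-pattern linkage drives it toward 0.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .clustering import ClusterConfig, PatternCluster, cluster_patterns
from .ingest import SequencedFragment, Window
from .matrix import (
    DEFAULT_CONDITIONS,
    DepthGate,
    ReadMethylationMatrix,
    apply_depth_gate,
    iter_window_matrices,
)

SECTORS = (1, 2, 3, 4)


@dataclass(frozen=True)
class SectorConfig:
    """Thresholds and permutation settings for sector classification."""

    high_threshold: float = 0.55
    low_threshold: float = 0.45
    permutation_iterations: int = 10
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 <= self.low_threshold < self.high_threshold <= 1.0):
            raise ValueError(
                f"need 0 <= low ({self.low_threshold}) < high ({self.high_threshold}) <= 1"
            )
        if self.permutation_iterations < 1:
            raise ValueError("permutation_iterations must be >= 1")


@dataclass(frozen=True)
class UniqueClusterPair:
    """Levels of one A-unique and one B-unique cluster in the same window."""

    window: Window
    level_unique_b: float
    level_unique_a: float


@dataclass
class SectorAssignment:
    """A window's sector membership and the cluster pairs that earned it."""

    window: Window
    sectors: frozenset[int]
    qualifying_pairs: list[tuple[UniqueClusterPair, frozenset[int]]]

    @property
    def best_pair(self) -> UniqueClusterPair | None:
        """The qualifying pair with the widest level separation (for reports)."""
        if not self.qualifying_pairs:
            return None
        return max(
            self.qualifying_pairs,
            key=lambda pq: abs(pq[0].level_unique_a - pq[0].level_unique_b),
        )[0]


def find_unique_clusters(
    clusters: Iterable[PatternCluster],
    *,
    contamination_tolerance: float = 0.0,
) -> tuple[list[PatternCluster], list[PatternCluster], list[PatternCluster]]:
    """Split one window's clusters into (unique_to_A, unique_to_B, shared).

    By default uniqueness is strict: zero reads from the other condition.  A
    nonzero ``contamination_tolerance`` allows up to that fraction of a
    cluster's reads to come from the other condition.
    """
    unique_a: list[PatternCluster] = []
    unique_b: list[PatternCluster] = []
    shared: list[PatternCluster] = []
    for c in clusters:
        allowed = int(contamination_tolerance * c.size)
        if c.count_b <= allowed and c.count_a > 0:
            unique_a.append(c)
        elif c.count_a <= allowed and c.count_b > 0:
            unique_b.append(c)
        else:
            shared.append(c)
    return unique_a, unique_b, shared


def _pair_sectors(level_a: float, level_b: float, config: SectorConfig) -> frozenset[int]:
    hi, lo = config.high_threshold, config.low_threshold
    s = set()
    if level_a >= hi and level_b >= hi:
        s.add(1)
    if level_a >= hi and level_b <= lo:
        s.add(2)
    if level_a <= lo and level_b <= lo:
        s.add(3)
    if level_b >= hi and level_a <= lo:
        s.add(4)
    return frozenset(s)


def assign_sectors(
    unique_to_a: Sequence[PatternCluster],
    unique_to_b: Sequence[PatternCluster],
    config: SectorConfig = SectorConfig(),
) -> SectorAssignment | None:
    """Classify a window from the levels of its condition-unique clusters.

    Returns ``None`` when the window lacks a unique cluster on either side
    (not assignable).  Otherwise every (A-unique, B-unique) level pair is
    evaluated; the window carries the union of the sectors its pairs reach,
    possibly empty when every pair has a level in the dead band.
    """
    if not unique_to_a or not unique_to_b:
        return None
    window = unique_to_a[0].window
    pairs: list[tuple[UniqueClusterPair, frozenset[int]]] = []
    sectors: set[int] = set()
    for ca in unique_to_a:
        for cb in unique_to_b:
            sec = _pair_sectors(ca.level, cb.level, config)
            if sec:
                pairs.append((UniqueClusterPair(window, cb.level, ca.level), sec))
                sectors |= sec
    return SectorAssignment(window, frozenset(sectors), pairs)


# ---------------------------------------------------------------------------
# genome-wide scan


@dataclass
class WindowResult:
    """Everything computed for one depth-gated window."""

    window: Window
    matrix: ReadMethylationMatrix
    clusters: list[PatternCluster]
    unique_a: list[PatternCluster]
    unique_b: list[PatternCluster]
    assignment: SectorAssignment | None


@dataclass
class SectorScanResult:
    """Genome-wide scan output: per-window results plus attrition counters."""

    results: list[WindowResult]
    n_windows: int
    n_windows_with_cpgs: int
    n_gated: int
    conditions: tuple[str, str] = DEFAULT_CONDITIONS

    def sector_windows(self, sector: int) -> list[WindowResult]:
        return [
            r
            for r in self.results
            if r.assignment is not None and sector in r.assignment.sectors
        ]

    @property
    def sector_counts(self) -> dict[int, int]:
        return {s: len(self.sector_windows(s)) for s in SECTORS}

    @property
    def assignable(self) -> list[WindowResult]:
        return [r for r in self.results if r.assignment is not None]

    def dual_sector_fraction(self) -> float:
        """|S2 and S4| / |S2 or S4| over windows; NaN when the union is empty."""
        s2 = {id(r) for r in self.sector_windows(2)}
        s4 = {id(r) for r in self.sector_windows(4)}
        union = s2 | s4
        if not union:
            return math.nan
        return len(s2 & s4) / len(union)

    def to_frame(self) -> pd.DataFrame:
        """Master per-gated-window table (one row per window)."""
        rows = []
        for r in self.results:
            a = r.assignment
            best = a.best_pair if a else None
            rows.append(
                (
                    r.window.chrom,
                    r.window.start,
                    r.window.end,
                    r.window.n_cpgs,
                    r.matrix.m,
                    len(r.clusters),
                    len(r.unique_a),
                    len(r.unique_b),
                    ",".join(str(s) for s in sorted(a.sectors)) if a else "",
                    best.level_unique_a if best else math.nan,
                    best.level_unique_b if best else math.nan,
                )
            )
        return pd.DataFrame(
            rows,
            columns=(
                "chrom",
                "start",
                "end",
                "n_cpgs",
                "n_reads",
                "n_clusters",
                "n_unique_A",
                "n_unique_B",
                "sectors",
                "best_level_unique_A",
                "best_level_unique_B",
            ),
        )

    def sector_bed(self, sector: int) -> pd.DataFrame:
        """BED (0-based half-open) of the sector's windows; score = qualifying pairs."""
        rows = []
        for r in self.sector_windows(sector):
            a = r.assignment
            n_pairs = sum(1 for _, sec in a.qualifying_pairs if sector in sec)
            rows.append(
                (r.window.chrom, r.window.start, r.window.end, f"sector{sector}", n_pairs)
            )
        return pd.DataFrame(rows, columns=("chrom", "start", "end", "name", "score"))

    def write_outputs(self, out_dir: str | Path) -> dict[str, Path]:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        paths: dict[str, Path] = {}
        master = out / "sector_scan.tsv"
        self.to_frame().to_csv(master, sep="\t", index=False, float_format="%.6g")
        paths["sector_scan"] = master
        for s in SECTORS:
            p = out / f"sector{s}.bed"
            self.sector_bed(s).to_csv(p, sep="\t", index=False, header=False)
            paths[f"sector{s}_bed"] = p
        return paths


def scan_windows(
    windows: Sequence[Window],
    fragments: Iterable[SequencedFragment],
    *,
    depth_gate: DepthGate = DepthGate(),
    cluster_config: ClusterConfig = ClusterConfig(),
    sector_config: SectorConfig = SectorConfig(),
    conditions: Sequence[str] = DEFAULT_CONDITIONS,
    contamination_tolerance: float = 0.0,
) -> SectorScanResult:
    """Run the full per-window pipeline over already-labelled fragments.

    Pipeline per window: build matrix (full-coverage rule) -> depth gate ->
    exact-pattern clustering -> condition-unique cluster detection -> sector
    assignment.  Windows failing the gate are excluded from all downstream
    analysis, including the permutation test.
    """
    results: list[WindowResult] = []
    n_with_cpgs = 0
    n_gated = 0
    for window, mat in iter_window_matrices(windows, fragments):
        n_with_cpgs += 1
        if not apply_depth_gate(mat, depth_gate, conditions):
            continue
        n_gated += 1
        clusters = cluster_patterns(mat, cluster_config, conditions)
        ua, ub, _ = find_unique_clusters(
            clusters, contamination_tolerance=contamination_tolerance
        )
        assignment = assign_sectors(ua, ub, sector_config)
        results.append(WindowResult(window, mat, clusters, ua, ub, assignment))
    return SectorScanResult(
        results=results,
        n_windows=len(windows),
        n_windows_with_cpgs=n_with_cpgs,
        n_gated=n_gated,
        conditions=tuple(conditions),
    )


def run_sector_scan(
    fragments_a: Iterable[SequencedFragment],
    fragments_b: Iterable[SequencedFragment],
    windows: Sequence[Window],
    *,
    depth_gate: DepthGate = DepthGate(),
    cluster_config: ClusterConfig = ClusterConfig(),
    sector_config: SectorConfig = SectorConfig(),
    conditions: Sequence[str] = DEFAULT_CONDITIONS,
    contamination_tolerance: float = 0.0,
) -> SectorScanResult:
    """Label the two read sets with their conditions and scan all windows."""
    cond_a, cond_b = conditions
    labelled: list[SequencedFragment] = []
    for frag in fragments_a:
        labelled.append(replace_condition(frag, cond_a))
    for frag in fragments_b:
        labelled.append(replace_condition(frag, cond_b))
    return scan_windows(
        windows,
        labelled,
        depth_gate=depth_gate,
        cluster_config=cluster_config,
        sector_config=sector_config,
        conditions=conditions,
        contamination_tolerance=contamination_tolerance,
    )


def replace_condition(frag: SequencedFragment, condition: str) -> SequencedFragment:
    if frag.condition == condition:
        return frag
    return SequencedFragment(frag.fragment_id, condition, frag.chrom, frag.calls)


# ---------------------------------------------------------------------------
# permutation false-positive rate


@dataclass
class PermutationResult:
    """Observed vs permuted window counts for one sector."""

    sector: int
    observed_count: int
    permuted_counts: list[int]

    @property
    def fpr(self) -> float:
        """Mean permuted count / observed count; NaN when nothing was observed."""
        if self.observed_count == 0:
            return math.nan
        return float(np.mean(self.permuted_counts)) / self.observed_count


def permutation_fpr(
    scan: SectorScanResult,
    *,
    cluster_config: ClusterConfig = ClusterConfig(),
    sector_config: SectorConfig = SectorConfig(),
    contamination_tolerance: float = 0.0,
    rng: np.random.Generator | None = None,
) -> dict[int, PermutationResult]:
    """Estimate per-sector FPRs by within-window condition-label permutation.

    Each iteration shuffles the condition labels across the rows of every
    gated matrix — a permutation, so per-window per-condition read counts are
    preserved — and re-runs clustering, uniqueness, and sector assignment.
    Seeded via ``sector_config.rng_seed`` unless an explicit ``rng`` is given;
    results are bit-reproducible for a fixed seed.
    """
    if rng is None:
        rng = np.random.default_rng(sector_config.rng_seed)
    observed = scan.sector_counts
    permuted: dict[int, list[int]] = {s: [] for s in SECTORS}
    for _ in range(sector_config.permutation_iterations):
        iter_counts = dict.fromkeys(SECTORS, 0)
        for r in scan.results:
            mat = r.matrix
            shuffled = ReadMethylationMatrix(
                mat.window,
                mat.row_ids,
                rng.permutation(mat.row_conditions),
                mat.values,
            )
            clusters = cluster_patterns(shuffled, cluster_config, scan.conditions)
            ua, ub, _ = find_unique_clusters(
                clusters, contamination_tolerance=contamination_tolerance
            )
            assignment = assign_sectors(ua, ub, sector_config)
            if assignment is not None:
                for s in assignment.sectors:
                    iter_counts[s] += 1
        for s in SECTORS:
            permuted[s].append(iter_counts[s])
    return {
        s: PermutationResult(s, observed[s], permuted[s]) for s in SECTORS
    }


def permutation_report(results: dict[int, PermutationResult]) -> pd.DataFrame:
    rows = [
        (
            r.sector,
            r.observed_count,
            ",".join(str(c) for c in r.permuted_counts),
            r.fpr,
        )
        for r in results.values()
    ]
    return pd.DataFrame(rows, columns=("sector", "observed", "permuted_counts", "fpr"))
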