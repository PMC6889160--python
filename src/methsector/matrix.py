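"""Per-window read-methylation matrices and the per-condition depth gate.

For each window the reads fully covering all of its CpGs form an m x n binary
matrix (m reads, n CpG sites, 0 = unmethylated, 1 = methylated).  Reads not
covering every CpG in the window are excluded rather than imputed, so the
matrix never contains a missing value.  A window enters downstream analysis
only if each condition contributes at least ``min_reads_per_condition``
(default 10) fully covering reads; the two per-condition matrices are then
combined, keeping per-row condition labels.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Iterator, Sequence

import numpy as np

from .ingest import SequencedFragment, Window

DEFAULT_CONDITIONS = ("A", "B")


@dataclass
class ReadMethylationMatrix:
    """Binary m x n matrix of read-level CpG calls for one window.

    Column *j* holds each read's call at ``window.cpg_positions[j]``; rows
    carry fragment ids and condition labels.
    """

    window: Window
    row_ids: list[str]
    row_conditions: np.ndarray  # dtype=object/str, shape (m,)
    values: np.ndarray  # dtype=uint8, shape (m, n)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.uint8)
        self.row_conditions = np.asarray(self.row_conditions, dtype=object)
        m, n = self.values.shape if self.values.ndim == 2 else (0, 0)
        if n != self.window.n_cpgs:
            raise ValueError(
                f"matrix has {n} columns but window has {self.window.n_cpgs} CpGs"
            )
        if len(self.row_ids) != m or len(self.row_conditions) != m:
            raise ValueError("row metadata length mismatch")

    @property
    def m(self) -> int:
        return self.values.shape[0]

    @property
    def n(self) -> int:
        return self.values.shape[1]

    def condition_count(self, condition: str) -> int:
        return int(np.sum(self.row_conditions == condition))


@dataclass(frozen=True)
class DepthGate:
    """Minimum fully-covering reads per condition before clustering."""

    min_reads_per_condition: int = 10

    def __post_init__(self) -> None:
        if self.min_reads_per_condition < 1:
            raise ValueError("min_reads_per_condition must be >= 1")


def build_matrix(
    window: Window,
    fragments: Iterable[SequencedFragment],
) -> ReadMethylationMatrix | None:
    """Assemble the window's matrix from fragments fully covering its CpGs.

    A fragment contributes a row iff it has a call at *every* CpG of the
    window (full-coverage rule; no imputation).  Windows with no CpGs yield
    ``None``.  Row order follows input order, but downstream clustering is
    order-independent.
    """
    if window.n_cpgs == 0:
        return None
    positions = window.cpg_positions
    row_ids: list[str] = []
    row_conditions: list[str] = []
    rows: list[list[int]] = []
    for frag in fragments:
        if frag.chrom != window.chrom:
            continue
        calls = frag.calls
        try:
            row = [calls[p] for p in positions]
        except KeyError:
            continue
        row_ids.append(frag.fragment_id)
        row_conditions.append(frag.condition)
        rows.append(row)
    values = (
        np.array(rows, dtype=np.uint8)
        if rows
        else np.empty((0, len(positions)), dtype=np.uint8)
    )
    return ReadMethylationMatrix(window, row_ids, np.array(row_conditions, dtype=object), values)


def apply_depth_gate(
    matrix: ReadMethylationMatrix,
    gate: DepthGate = DepthGate(),
    conditions: Sequence[str] = DEFAULT_CONDITIONS,
) -> bool:
    """True iff every condition has at least the gate's read count."""
    need = gate.min_reads_per_condition
    return all(matrix.condition_count(c) >= need for c in conditions)


def iter_window_matrices(
    windows: Sequence[Window],
    fragments: Iterable[SequencedFragment],
) -> Iterator[tuple[Window, ReadMethylationMatrix]]:
    """Yield (window, matrix) for every CpG-bearing window, efficiently.

    Fragments are bucketed by chromosome and matched to candidate windows via
    a sorted-start binary search over the span of their calls, so each
    fragment is tested only against the handful of windows it can touch.  A
    fragment may fully cover, and thus contribute to, several windows.
    """
    by_chrom: dict[str, list[SequencedFragment]] = {}
    for frag in fragments:
        by_chrom.setdefault(frag.chrom, []).append(frag)

    win_by_chrom: dict[str, list[Window]] = {}
    for w in windows:
        win_by_chrom.setdefault(w.chrom, []).append(w)

    for chrom, wins in win_by_chrom.items():
        wins = sorted(wins, key=lambda w: w.start)
        starts = np.array([w.start for w in wins])
        candidates: list[list[SequencedFragment]] = [[] for _ in wins]
        for frag in by_chrom.get(chrom, []):
            lo = int(np.searchsorted(starts, frag.min_pos(), side="right")) - 1
            hi = int(np.searchsorted(starts, frag.max_pos(), side="right"))
            for i in range(max(lo, 0), hi):
                candidates[i].append(frag)
        for w, frags in zip(wins, candidates):
            mat = build_matrix(w, frags)
            if mat is not None:
                yield w, mat


def matrix_to_rows(matrix: ReadMethylationMatrix) -> list[tuple]:
    """Flatten a matrix for a per-window TSV dump: one row per read."""
    w = matrix.window
    out = []
    for rid, cond, vals in zip(matrix.row_ids, matrix.row_conditions, matrix.values):
        pattern = "".join(str(int(v)) for v in vals)
        out.append((w.chrom, w.start, w.end, rid, cond, pattern))
    return out
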