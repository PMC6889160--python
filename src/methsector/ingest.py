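"""Read ingest: per-fragment CpG methylation calls on forward-strand coordinates.

Each sequenced fragment (a stitched read pair) is the clonal derivative of a
single DNA molecule, so its ordered CpG calls carry single-cell information.
This module parses aligned bisulfite reads (SAM/BAM with Bismark-style ``XM``
methylation strings) or a plain tabular read-call exchange format into
:class:`SequencedFragment` objects, and tiles reference chromosomes into
fixed-size windows annotated with their CpG positions.

Coordinates are 0-based, half-open throughout.  Both strands of a CpG report
to the forward-strand C coordinate, the standard bisulfite convention, so that
patterns are comparable across reads regardless of which strand was sequenced.
"""

from __future__ import annotations

import csv
import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping, NamedTuple, Sequence

logger = logging.getLogger(__name__)

DEFAULT_WINDOW_SIZE = 100

_CPG_RE = re.compile("CG")

READCALLS_HEADER = ("fragment_id", "condition", "chrom", "calls")


class MethCall(NamedTuple):
    """A single CpG methylation call.

    ``pos`` is the 0-based forward-strand coordinate of the CpG's cytosine;
    ``state`` is 1 (methylated) or 0 (unmethylated).  Ambiguous calls are
    never stored — they are dropped at parse time.
    """

    chrom: str
    pos: int
    state: int


@dataclass
class SequencedFragment:
    """One clonally derived molecule with its per-CpG binary calls.

    ``calls`` maps forward-strand C coordinates to 0/1 states; at most one
    call per position (mate overlaps are resolved before construction).
    """

    fragment_id: str
    condition: str
    chrom: str
    calls: dict[int, int]

    def positions(self) -> list[int]:
        return sorted(self.calls)

    def min_pos(self) -> int:
        return min(self.calls)

    def max_pos(self) -> int:
        return max(self.calls)


@dataclass(frozen=True)
class Window:
    """A genomic tile with the CpG coordinates it contains.

    ``[start, end)`` half-open; ``cpg_positions`` are the forward-strand C
    coordinates of CpGs whose C lies inside the window (a CpG straddling the
    right boundary belongs to the window containing its C).
    """

    chrom: str
    start: int
    end: int
    cpg_positions: tuple[int, ...]

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError(f"empty window [{self.start}, {self.end})")
        for p in self.cpg_positions:
            if not (self.start <= p < self.end):
                raise ValueError(f"CpG at {p} outside window [{self.start}, {self.end})")

    @property
    def n_cpgs(self) -> int:
        return len(self.cpg_positions)


def find_cpg_positions(sequence: str) -> list[int]:
    """Forward-strand C coordinates of every CG dinucleotide in *sequence*."""
    seq = sequence.upper()
    return [m.start() for m in _CPG_RE.finditer(seq)]


def enumerate_windows(
    reference_sequences: Mapping[str, str] | None = None,
    window_size: int = DEFAULT_WINDOW_SIZE,
    *,
    cpg_positions: Mapping[str, Sequence[int]] | None = None,
    chrom_lengths: Mapping[str, int] | None = None,
) -> list[Window]:
    """Tile chromosomes into non-overlapping windows of ``window_size`` bp.

    Either ``reference_sequences`` (chrom -> sequence string, or a pyfaidx/
    dict-like of str-able records) or an explicit ``cpg_positions`` map with
    ``chrom_lengths`` must be given.  The trailing partial window at each
    chromosome end is retained.  A CpG belongs to the window containing its
    C coordinate, including a CG straddling a window boundary.
    """
    if window_size < 2:
        raise ValueError("window_size must be >= 2 (a CpG spans two bases)")
    per_chrom: dict[str, tuple[int, list[int]]] = {}
    if reference_sequences is not None:
        for chrom, seq in reference_sequences.items():
            s = str(seq)
            per_chrom[chrom] = (len(s), find_cpg_positions(s))
    elif cpg_positions is not None:
        if chrom_lengths is None:
            raise ValueError("chrom_lengths required when passing explicit CpG positions")
        for chrom, length in chrom_lengths.items():
            per_chrom[chrom] = (length, sorted(cpg_positions.get(chrom, [])))
    else:
        raise ValueError("supply reference_sequences or cpg_positions + chrom_lengths")

    windows: list[Window] = []
    for chrom, (length, positions) in per_chrom.items():
        i = 0
        for start in range(0, length, window_size):
            end = min(start + window_size, length)
            cpgs: list[int] = []
            while i < len(positions) and positions[i] < end:
                cpgs.append(positions[i])
                i += 1
            windows.append(Window(chrom, start, end, tuple(cpgs)))
    return windows


# ---------------------------------------------------------------------------
# mate stitching


def stitch_mates(
    mate1_calls: dict[int, int] | None,
    mate2_calls: dict[int, int] | None,
) -> tuple[dict[int, int], int]:
    """Merge mate call sets, discarding mate-2 calls at overlapping positions.

    Overlapping bases originate from the same molecule and must not be
    counted twice; where the mates disagree, mate 1 wins and the disagreement
    is counted (returned as the second element, a QC metric).  Single-end
    input passes through unchanged.
    """
    if mate1_calls is None:
        return dict(mate2_calls or {}), 0
    if mate2_calls is None:
        return dict(mate1_calls), 0
    merged = dict(mate1_calls)
    conflicts = 0
    for pos, state in mate2_calls.items():
        if pos in merged:
            if merged[pos] != state:
                conflicts += 1
        else:
            merged[pos] = state
    return merged, conflicts


# ---------------------------------------------------------------------------
# SAM/BAM parsing (Bismark XM dialect)


@dataclass
class ParseStats:
    """Counters accumulated while parsing an alignment file."""

    records: int = 0
    skipped_flag: int = 0
    skipped_no_tag: int = 0
    overlap_conflicts: int = 0
    fragments: int = 0


def _mate_calls_from_record(rec, chrom: str) -> dict[int, int]:
    """Extract CpG calls from one alignment record's XM string.

    Only ``Z``/``z`` symbols (CpG context) are kept.  Reads informative on
    the reverse strand (Bismark ``XG:GA``) see the G of the CpG; their calls
    are shifted by -1 onto the forward-strand C.
    """
    xm = rec.get_tag("XM")
    try:
        xg = rec.get_tag("XG")
        reverse = xg == "GA"
    except KeyError:
        reverse = rec.is_reverse
    shift = -1 if reverse else 0
    calls: dict[int, int] = {}
    for qpos, rpos in rec.get_aligned_pairs(matches_only=True):
        sym = xm[qpos]
        if sym == "Z":
            calls[rpos + shift] = 1
        elif sym == "z":
            calls[rpos + shift] = 0
    return calls


def parse_alignment_file(
    path: str | Path,
    condition: str,
    *,
    stats: ParseStats | None = None,
) -> Iterator[SequencedFragment]:
    """Stream stitched fragments from a coordinate- or name-ordered SAM/BAM.

    Records that are unmapped, secondary, supplementary, or duplicate-flagged
    are skipped, as are records lacking the XM tag (counted in ``stats``).
    Mates sharing a query name are stitched with mate-1 precedence.  Pairs
    are buffered by query name, so mates need not be adjacent.
    """
    import pysam

    st = stats if stats is not None else ParseStats()
    pending: dict[str, tuple[str, dict[int, int], bool]] = {}
    with pysam.AlignmentFile(str(path), check_sq=False) as af:
        for rec in af:
            st.records += 1
            if rec.is_unmapped or rec.is_secondary or rec.is_supplementary or rec.is_duplicate:
                st.skipped_flag += 1
                continue
            if not rec.has_tag("XM"):
                st.skipped_no_tag += 1
                continue
            chrom = rec.reference_name
            calls = _mate_calls_from_record(rec, chrom)
            name = rec.query_name
            is_read2 = rec.is_paired and rec.is_read2
            if rec.is_paired and name in pending:
                o_chrom, o_calls, o_is_read2 = pending.pop(name)
                if o_is_read2 and not is_read2:
                    first, second = calls, o_calls
                else:
                    first, second = o_calls, calls
                merged, conflicts = stitch_mates(first, second)
                st.overlap_conflicts += conflicts
                st.fragments += 1
                if merged:
                    yield SequencedFragment(name, condition, o_chrom, merged)
            elif rec.is_paired and rec.mate_is_mapped:
                pending[name] = (chrom, calls, is_read2)
            else:
                st.fragments += 1
                if calls:
                    yield SequencedFragment(name, condition, chrom, calls)
    # unpaired leftovers (mate missing from file) are emitted as-is
    for name, (chrom, calls, _) in pending.items():
        st.fragments += 1
        if calls:
            yield SequencedFragment(name, condition, chrom, calls)
    if st.skipped_no_tag:
        logger.info("skipped %d records lacking XM tag in %s", st.skipped_no_tag, path)


def restrict_to_reference_cpgs(
    fragments: Iterable[SequencedFragment],
    cpg_positions: Mapping[str, Sequence[int]],
) -> Iterator[SequencedFragment]:
    """Drop calls whose position is not a known CpG C-coordinate."""
    sets = {chrom: set(pos) for chrom, pos in cpg_positions.items()}
    for frag in fragments:
        keep = sets.get(frag.chrom)
        if keep is None:
            continue
        calls = {p: s for p, s in frag.calls.items() if p in keep}
        if calls:
            yield SequencedFragment(frag.fragment_id, frag.condition, frag.chrom, calls)


# ---------------------------------------------------------------------------
# tabular read-call exchange format


class ReadCallsFormatError(ValueError):
    """Malformed row in the read-call TSV exchange format."""


def _parse_calls_field(text: str, lineno: int) -> dict[int, int]:
    calls: dict[int, int] = {}
    for item in text.split(","):
        try:
            pos_s, state_s = item.split(":")
            pos, state = int(pos_s), int(state_s)
        except ValueError as exc:
            raise ReadCallsFormatError(f"line {lineno}: bad call field {item!r}") from exc
        if state not in (0, 1):
            raise ReadCallsFormatError(f"line {lineno}: state {state} not in {{0,1}}")
        if pos in calls:
            raise ReadCallsFormatError(f"line {lineno}: duplicate position {pos}")
        calls[pos] = state
    return calls


def parse_readcalls_tsv(path: str | Path) -> Iterator[SequencedFragment]:
    """Stream fragments from the tab-delimited read-call exchange format.

    Columns: fragment_id, condition, chrom, comma-separated ``pos:state``
    pairs.  A header line is required.  Malformed rows raise
    :class:`ReadCallsFormatError` with the offending line number.
    """
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.reader(fh, delimiter="\t")
        header = next(reader, None)
        if header is None:
            return
        if tuple(header) != READCALLS_HEADER:
            raise ReadCallsFormatError(f"bad header {header!r}, expected {READCALLS_HEADER}")
        for lineno, row in enumerate(reader, start=2):
            if not row:
                continue
            if len(row) != 4:
                raise ReadCallsFormatError(f"line {lineno}: expected 4 columns, got {len(row)}")
            frag_id, condition, chrom, calls_field = row
            yield SequencedFragment(frag_id, condition, chrom, _parse_calls_field(calls_field, lineno))


def write_readcalls_tsv(fragments: Iterable[SequencedFragment], path: str | Path) -> int:
    """Write fragments to the exchange format; returns the row count."""
    n = 0
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(READCALLS_HEADER)
        for frag in fragments:
            calls = ",".join(f"{p}:{frag.calls[p]}" for p in sorted(frag.calls))
            writer.writerow([frag.fragment_id, frag.condition, frag.chrom, calls])
            n += 1
    return n
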