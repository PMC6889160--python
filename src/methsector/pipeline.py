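"""End-to-end workflow: ingest -> scan -> permutation -> outputs -> manifest."""

from __future__ import annotations

import hashlib
import json
import math
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Any, Mapping, Sequence

import pandas as pd

from . import __version__
from .clustering import ClusterConfig, cluster_summary
from .ingest import (
    SequencedFragment,
    Window,
    enumerate_windows,
    parse_alignment_file,
    parse_readcalls_tsv,
)
from .matrix import DepthGate
from .sectors import (
    SECTORS,
    SectorConfig,
    SectorScanResult,
    permutation_fpr,
    permutation_report,
    run_sector_scan,
)


@dataclass
class PipelineConfig:
    """Validated configuration for a full run."""

    reads_a: str
    reads_b: str
    fasta: str | None = None
    window_size: int = 100
    min_reads: int = 10
    min_cluster: int = 4
    hi: float = 0.55
    lo: float = 0.45
    iterations: int = 10
    seed: int = 0
    contamination_tolerance: float = 0.0

    def __post_init__(self) -> None:
        if not (0.0 <= self.lo < self.hi <= 1.0):
            raise ValueError(f"need 0 <= lo ({self.lo}) < hi ({self.hi}) <= 1")
        if self.window_size < 2:
            raise ValueError("window_size must be >= 2")

    @property
    def depth_gate(self) -> DepthGate:
        return DepthGate(self.min_reads)

    @property
    def cluster_config(self) -> ClusterConfig:
        return ClusterConfig(self.min_cluster)

    @property
    def sector_config(self) -> SectorConfig:
        return SectorConfig(self.hi, self.lo, self.iterations, self.seed)


def load_config(path: str | Path, overrides: Mapping[str, Any] | None = None) -> PipelineConfig:
    """Key-value YAML config; explicit overrides (CLI flags) win."""
    import yaml

    data = yaml.safe_load(Path(path).read_text(encoding="utf-8")) or {}
    if overrides:
        data.update({k: v for k, v in overrides.items() if v is not None})
    return PipelineConfig(**data)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def load_fragments(path: str | Path, condition: str) -> list[SequencedFragment]:
    """Read fragments from a read-call TSV or a SAM/BAM alignment file."""
    p = Path(path)
    if p.suffix.lower() in (".sam", ".bam", ".cram"):
        return list(parse_alignment_file(p, condition))
    return list(parse_readcalls_tsv(p))


def windows_for_inputs(
    config: PipelineConfig,
    fragments: Sequence[SequencedFragment],
) -> list[Window]:
    """Windows from the reference FASTA, or inferred from observed call sites.

    Without a reference, every called position is taken as a CpG C-coordinate
    (true for simulator output and for CpG-context-filtered parsers).
    """
    if config.fasta:
        import pysam

        with pysam.FastaFile(config.fasta) as fa:
            ref = {name: fa.fetch(name) for name in fa.references}
        return enumerate_windows(ref, config.window_size)
    positions: dict[str, set[int]] = {}
    lengths: dict[str, int] = {}
    for frag in fragments:
        ps = positions.setdefault(frag.chrom, set())
        ps.update(frag.calls)
        lengths[frag.chrom] = max(lengths.get(frag.chrom, 0), frag.max_pos() + 2)
    return enumerate_windows(
        None,
        config.window_size,
        cpg_positions={c: sorted(s) for c, s in positions.items()},
        chrom_lengths=lengths,
    )


@dataclass
class RunOutputs:
    scan: SectorScanResult
    permutation: dict[int, Any]
    paths: dict[str, Path]
    manifest_path: Path


def run_full(config: PipelineConfig, out_dir: str | Path) -> RunOutputs:
    """Execute every stage and write all outputs plus a run manifest."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for label, p in (("reads_a", config.reads_a), ("reads_b", config.reads_b)):
        if not Path(p).exists():
            raise FileNotFoundError(f"{label}: {p}")

    frags_a = load_fragments(config.reads_a, "A")
    frags_b = load_fragments(config.reads_b, "B")
    windows = windows_for_inputs(config, frags_a + frags_b)

    scan = run_sector_scan(
        frags_a,
        frags_b,
        windows,
        depth_gate=config.depth_gate,
        cluster_config=config.cluster_config,
        sector_config=config.sector_config,
        contamination_tolerance=config.contamination_tolerance,
    )
    paths = scan.write_outputs(out)

    clusters = [c for r in scan.results for c in r.clusters]
    cluster_path = out / "clusters.tsv"
    cluster_summary(clusters).to_csv(cluster_path, sep="\t", index=False, float_format="%.6g")
    paths["clusters"] = cluster_path

    perm = permutation_fpr(
        scan,
        cluster_config=config.cluster_config,
        sector_config=config.sector_config,
        contamination_tolerance=config.contamination_tolerance,
    )
    perm_path = out / "permutation.tsv"
    permutation_report(perm).to_csv(perm_path, sep="\t", index=False, float_format="%.6g")
    paths["permutation"] = perm_path

    manifest = {
        "tool": "methsector",
        "version": __version__,
        "seed": config.seed,
        "config": asdict(config),
        "inputs": {
            "reads_a": _sha256(Path(config.reads_a)),
            "reads_b": _sha256(Path(config.reads_b)),
        },
        "counts": {
            "fragments_a": len(frags_a),
            "fragments_b": len(frags_b),
            "windows": scan.n_windows,
            "windows_with_cpgs": scan.n_windows_with_cpgs,
            "windows_gated": scan.n_gated,
            "clusters": len(clusters),
            "sector_counts": {str(s): c for s, c in scan.sector_counts.items()},
        },
        "outputs": {name: {"path": p.name, "sha256": _sha256(p)} for name, p in paths.items()},
    }
    manifest_path = out / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2) + "\n", encoding="utf-8")
    return RunOutputs(scan, perm, paths, manifest_path)


def verify_manifest(out_dir: str | Path) -> list[str]:
    """Return the names of declared outputs that are missing or altered."""
    out = Path(out_dir)
    manifest = json.loads((out / "manifest.json").read_text(encoding="utf-8"))
    bad = []
    for name, entry in manifest["outputs"].items():
        p = out / entry["path"]
        if not p.exists() or _sha256(p) != entry["sha256"]:
            bad.append(name)
    return bad


def summarize_run(out_dir: str | Path) -> str:
    """Human-readable summary of a completed (or partial) run directory."""
    out = Path(out_dir)
    lines = []
    scan_path = out / "sector_scan.tsv"
    if scan_path.exists():
        df = pd.read_csv(scan_path, sep="\t", dtype={"sectors": str})
        df["sectors"] = df["sectors"].fillna("")
        n = len(df)
        lines.append(f"gated windows: {n}")
        assignable = df[(df["n_unique_A"] > 0) & (df["n_unique_B"] > 0)]
        lines.append(f"assignable windows (unique clusters on both sides): {len(assignable)}")
        in_sector = {
            s: df["sectors"].str.split(",").apply(lambda xs, s=s: str(s) in xs).sum()
            for s in SECTORS
        }
        for s in SECTORS:
            lines.append(f"sector {s} windows: {in_sector[s]}")
        if len(assignable):
            dead = (assignable["sectors"] == "").sum()
            lines.append(f"dead-band fraction (assignable, no sector): {dead / len(assignable):.3f}")
        union = df["sectors"].str.split(",").apply(lambda xs: "2" in xs or "4" in xs)
        both = df["sectors"].str.split(",").apply(lambda xs: "2" in xs and "4" in xs)
        if union.sum():
            lines.append(f"dual-sector fraction (S2&S4 / S2|S4): {both.sum() / union.sum():.3f}")
        if in_sector[2] + in_sector[4] == 0:
            lines.append("no windows assigned to sector 2 or 4")
    else:
        lines.append("sector_scan.tsv missing — scan stage incomplete")
    perm_path = out / "permutation.tsv"
    if perm_path.exists():
        perm = pd.read_csv(perm_path, sep="\t")
        for _, row in perm.iterrows():
            fpr = row["fpr"]
            fpr_s = "NA" if pd.isna(fpr) else f"{fpr:.3f}"
            lines.append(
                f"sector {int(row['sector'])} permutation FPR: {fpr_s} "
                f"(observed {int(row['observed'])})"
            )
    else:
        lines.append("permutation.tsv missing — permutation stage incomplete")
    return "\n".join(lines)
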