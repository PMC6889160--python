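"""Genomic-feature annotation of sector windows and chi-square enrichment.

Sector windows are annotated to genomic features (promoters, CpG islands,
enhancers, gene bodies, custom BED intervals) by an any-overlap rule on
half-open intervals.  Enrichment of a gene set's sector-2 vs sector-4 bin
counts against a background list — and of per-cell-type up- vs downregulated
differentially expressed gene counts against the overall DE background — is
tested with a Pearson chi-square on the 2x2 contingency table (1 df, no
continuity correction), Bonferroni-adjusted over the number of sets tested.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

DEFAULT_PROMOTER_HALFWIDTH = 2500  # +/- 2.5 kb around the TSS


@dataclass
class FeatureSet:
    """Named collection of half-open genomic intervals."""

    name: str
    intervals: pd.DataFrame  # columns: chrom, start, end (0-based half-open)

    def __post_init__(self) -> None:
        df = self.intervals
        missing = {"chrom", "start", "end"} - set(df.columns)
        if missing:
            raise ValueError(f"feature set {self.name!r} missing columns {missing}")
        if (df["end"] <= df["start"]).any():
            raise ValueError(f"feature set {self.name!r} has empty/inverted intervals")


def read_bed(path: str | Path, name: str | None = None) -> FeatureSet:
    """Load a BED3+ file into a FeatureSet (extra columns ignored)."""
    df = pd.read_csv(
        path,
        sep="\t",
        comment="#",
        header=None,
        usecols=[0, 1, 2],
        names=["chrom", "start", "end"],
        dtype={"chrom": str, "start": np.int64, "end": np.int64},
    )
    return FeatureSet(name or Path(path).stem, df)


def _gff_attr(attrs: str, keys: Sequence[str]) -> str:
    found: dict[str, str] = {}
    for part in attrs.replace("; ", ";").split(";"):
        part = part.strip()
        if not part:
            continue
        if "=" in part:  # GFF3
            k, v = part.split("=", 1)
        elif " " in part:  # GTF
            k, v = part.split(" ", 1)
            v = v.strip('"')
        else:
            continue
        found[k] = v
    for k in keys:  # keys are in priority order
        if k in found:
            return found[k]
    return ""


def extract_tss(path: str | Path, feature_types: Sequence[str] = ("gene",)) -> pd.DataFrame:
    """TSS table (chrom, tss, strand, gene) from a GFF3/GTF file.

    The TSS is the start coordinate of the feature on + strands and the end
    coordinate on - strands (converted to 0-based).
    """
    rows = []
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            if line.startswith("#") or not line.strip():
                continue
            f = line.rstrip("\n").split("\t")
            if len(f) < 9 or f[2] not in feature_types:
                continue
            chrom, start, end, strand = f[0], int(f[3]) - 1, int(f[4]), f[6]
            tss = start if strand != "-" else end - 1
            gene = _gff_attr(f[8], ("gene_name", "Name", "gene_id", "ID"))
            rows.append((chrom, tss, strand, gene))
    return pd.DataFrame(rows, columns=("chrom", "tss", "strand", "gene"))


def promoters_from_tss(
    tss: pd.DataFrame, halfwidth: int = DEFAULT_PROMOTER_HALFWIDTH
) -> FeatureSet:
    """Promoter intervals: TSS +/- halfwidth, clipped at 0, half-open."""
    df = pd.DataFrame(
        {
            "chrom": tss["chrom"].astype(str),
            "start": (tss["tss"] - halfwidth).clip(lower=0).astype(np.int64),
            "end": (tss["tss"] + halfwidth).astype(np.int64),
            "gene": tss.get("gene", ""),
        }
    )
    return FeatureSet("promoter", df)


def _overlaps_any(
    chrom: np.ndarray,
    start: np.ndarray,
    end: np.ndarray,
    features: pd.DataFrame,
) -> np.ndarray:
    """Boolean any-overlap of query intervals with a feature table (half-open)."""
    hit = np.zeros(len(chrom), dtype=bool)
    for c, grp in features.groupby("chrom"):
        mask = chrom == c
        if not mask.any():
            continue
        fs = grp["start"].to_numpy()
        fe = grp["end"].to_numpy()
        order = np.argsort(fs)
        fs, fe = fs[order], fe[order]
        # running max of ends lets a single sweep answer "any f with
        # f.start < q.end and f.end > q.start"
        fe_cummax = np.maximum.accumulate(fe)
        qs, qe = start[mask], end[mask]
        idx = np.searchsorted(fs, qe, side="left")  # features with start < q.end
        ok = idx > 0
        ok[ok] = fe_cummax[idx[ok] - 1] > qs[ok]
        hit[mask] = ok
    return hit


def annotate_windows(
    assignments: pd.DataFrame,
    feature_sets: Iterable[FeatureSet],
) -> pd.DataFrame:
    """Label each window row with every feature set it overlaps (>=1 bp).

    ``assignments`` needs chrom/start/end columns (e.g. the sector-scan
    master table); one boolean column per feature set is appended.  Windows
    on chromosomes absent from an annotation simply do not overlap it.
    """
    out = assignments.copy()
    if out.empty:
        for fs in feature_sets:
            out[fs.name] = pd.Series(dtype=bool)
        return out
    chrom = out["chrom"].to_numpy(dtype=object)
    start = out["start"].to_numpy()
    end = out["end"].to_numpy()
    for fs in feature_sets:
        out[fs.name] = _overlaps_any(chrom, start, end, fs.intervals)
    return out


# ---------------------------------------------------------------------------
# chi-square enrichment


@dataclass
class EnrichmentResult:
    """2x2 chi-square outcome for one gene set / cell type label."""

    label: str
    count_s2: int
    count_s4: int
    bg_s2: int
    bg_s4: int
    chi2: float
    p: float
    p_adj: float
    testable: bool

    @property
    def ratio_text(self) -> str:
        return f"{self.count_s2}:{self.count_s4}"


def _chi2_2x2(a: int, b: int, c: int, d: int) -> tuple[float, float, bool]:
    """Pearson chi-square, 1 df, no continuity correction; (chi2, p, testable)."""
    table = np.array([[a, b], [c, d]], dtype=float)
    if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
        return math.nan, math.nan, False
    chi2, p, _, _ = stats.chi2_contingency(table, correction=False)
    return float(chi2), float(p), True


def enrichment_chi2(
    set_counts: tuple[int, int],
    background_counts: tuple[int, int],
    n_tests: int = 1,
    label: str = "",
) -> EnrichmentResult:
    """Test a set's sector-2:sector-4 split against the background split.

    ``set_counts`` and ``background_counts`` are (sector2, sector4) bin
    counts.  Returns NaN p-values, flagged untestable, on a zero margin.
    The Bonferroni-adjusted p is ``min(1, p * n_tests)``.
    """
    s2, s4 = set_counts
    b2, b4 = background_counts
    chi2, p, testable = _chi2_2x2(s2, s4, b2, b4)
    p_adj = min(1.0, p * n_tests) if testable else math.nan
    return EnrichmentResult(label, s2, s4, b2, b4, chi2, p, p_adj, testable)


def de_ratio_chi2(
    per_set_up_down: Mapping[str, tuple[int, int]],
    background_up_down: tuple[int, int],
    n_tests: int | None = None,
) -> list[EnrichmentResult]:
    """Per-gene-set up:down DE-ratio tests against the overall DE background.

    Same 2x2 machinery as :func:`enrichment_chi2`; the (up, down) counts are
    stored in the s2/s4 slots of the result.  ``n_tests`` defaults to the
    number of sets.
    """
    if n_tests is None:
        n_tests = len(per_set_up_down)
    results = []
    for label, (up, down) in per_set_up_down.items():
        results.append(enrichment_chi2((up, down), background_up_down, n_tests, label))
    return results


def count_gene_set_windows(
    annotated: pd.DataFrame,
    promoter_sets: Mapping[str, FeatureSet],
) -> dict[str, tuple[int, int]]:
    """Per gene set: (sector-2, sector-4) counts of windows overlapping the
    set's promoter intervals.  ``annotated`` needs a ``sectors`` column (the
    comma-joined sector string from the scan master table)."""
    sectors = annotated["sectors"].fillna("").astype(str)
    in_s2 = sectors.str.split(",").apply(lambda xs: "2" in xs).to_numpy()
    in_s4 = sectors.str.split(",").apply(lambda xs: "4" in xs).to_numpy()
    chrom = annotated["chrom"].to_numpy(dtype=object)
    start = annotated["start"].to_numpy()
    end = annotated["end"].to_numpy()
    out: dict[str, tuple[int, int]] = {}
    for label, fs in promoter_sets.items():
        hit = _overlaps_any(chrom, start, end, fs.intervals)
        out[label] = (int((hit & in_s2).sum()), int((hit & in_s4).sum()))
    return out


def read_gene_list(path: str | Path) -> list[str]:
    """Plain-text gene list, one symbol per line; blanks and '#' lines skipped."""
    genes = []
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            g = line.strip()
            if g and not g.startswith("#"):
                genes.append(g)
    return genes


def enrichment_table(results: Iterable[EnrichmentResult]) -> pd.DataFrame:
    rows = [
        (
            r.label,
            r.count_s2,
            r.count_s4,
            r.bg_s2,
            r.bg_s4,
            r.chi2,
            r.p,
            r.p_adj,
            r.ratio_text,
            r.testable,
        )
        for r in results
    ]
    return pd.DataFrame(
        rows,
        columns=(
            "label",
            "count_s2",
            "count_s4",
            "bg_s2",
            "bg_s4",
            "chi2",
            "p",
            "p_adj",
            "ratio",
            "testable",
        ),
    )
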