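"""Synthetic mixed-cell-type bisulfite read-call generator with ground truth.

Every read in a WGBS library is the clonal derivative of a DNA molecule from
a single cell, so a bulk library over a heterogeneous tissue is a mixture of
cell-type-specific methylation haplotypes.  The generator emulates exactly
that: latent cell types with fixed genome proportions each carry one binary
methylation haplotype per window (per condition); each simulated read picks a
cell type by proportion, copies its haplotype, and flips each CpG call
independently with a small conversion-error probability.  Condition effects
are planted as haplotype switches in a chosen cell type at chosen windows,
and the truth table records which windows should land in which sector.

Reads cover the whole window by default, which isolates downstream logic
from fragment-span modelling; an optional span mode emits reads covering
only a sub-interval so the full-coverage filter is also exercised.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .ingest import SequencedFragment, Window

CONDITIONS = ("A", "B")


@dataclass
class CellTypeProfile:
    """A latent cell type: mixture proportion plus per-window haplotypes.

    ``haplotypes[condition]`` is one binary pattern per window (pattern
    length = that window's CpG count).  Conditions without an entry fall
    back to condition "A"'s haplotypes (no condition effect).
    """

    name: str
    proportion: float
    haplotypes: dict[str, list[tuple[int, ...]]]

    def pattern(self, condition: str, window_index: int) -> tuple[int, ...]:
        per_cond = self.haplotypes.get(condition) or self.haplotypes["A"]
        return per_cond[window_index]


@dataclass(frozen=True)
class PlantedSwitch:
    """A condition-specific haplotype replacement — the simulated effect."""

    window_index: int
    cell_type: str
    condition: str
    replacement: tuple[int, ...]
    expected_sector: int


@dataclass
class MixtureSpec:
    """Full ground-truth description of a two-condition simulation."""

    windows: list[Window]
    cell_types: list[CellTypeProfile]
    planted_switches: list[PlantedSwitch] = field(default_factory=list)
    coverage: float = 40.0
    error_rate: float = 0.01
    # optional asymmetric conversion failure: P(0->1), P(1->0); when None the
    # symmetric error_rate is used for both directions
    flip_probs: tuple[float, float] | None = None

    def __post_init__(self) -> None:
        total = sum(ct.proportion for ct in self.cell_types)
        if not math.isclose(total, 1.0, abs_tol=1e-9):
            raise ValueError(f"cell_types: proportions sum to {total}, expected 1")
        if not (0.0 <= self.error_rate < 0.5):
            raise ValueError(f"error_rate: {self.error_rate} outside [0, 0.5)")
        if self.coverage <= 0:
            raise ValueError(f"coverage: {self.coverage} must be > 0")
        names = {ct.name for ct in self.cell_types}
        for i, sw in enumerate(self.planted_switches):
            if sw.cell_type not in names:
                raise ValueError(f"planted_switches[{i}].cell_type: unknown {sw.cell_type!r}")
            if not (0 <= sw.window_index < len(self.windows)):
                raise ValueError(f"planted_switches[{i}].window_index: out of range")
            n = self.windows[sw.window_index].n_cpgs
            if len(sw.replacement) != n:
                raise ValueError(
                    f"planted_switches[{i}].replacement: length {len(sw.replacement)} != {n} CpGs"
                )
        for ct in self.cell_types:
            for cond, pats in ct.haplotypes.items():
                if len(pats) != len(self.windows):
                    raise ValueError(
                        f"cell type {ct.name!r}, condition {cond}: "
                        f"{len(pats)} haplotypes for {len(self.windows)} windows"
                    )

    def effective_pattern(self, ct: CellTypeProfile, condition: str, window_index: int) -> tuple[int, ...]:
        for sw in self.planted_switches:
            if (
                sw.window_index == window_index
                and sw.cell_type == ct.name
                and sw.condition == condition
            ):
                return sw.replacement
        return ct.pattern(condition, window_index)

    def truth_frame(self) -> pd.DataFrame:
        planted = {sw.window_index: sw.expected_sector for sw in self.planted_switches}
        rows = [
            (
                w.chrom,
                w.start,
                w.end,
                i,
                i in planted,
                planted.get(i, 0),
            )
            for i, w in enumerate(self.windows)
        ]
        return pd.DataFrame(
            rows,
            columns=("chrom", "start", "end", "window_index", "planted", "expected_sector"),
        )


# ---------------------------------------------------------------------------
# window scaffolding


def make_windows(
    n_windows: int,
    n_cpgs: int = 4,
    window_size: int = 100,
    chrom: str = "chrS",
) -> list[Window]:
    """Evenly spaced CpGs inside each of ``n_windows`` consecutive tiles."""
    spacing = window_size // (n_cpgs + 1)
    offsets = [spacing * (k + 1) for k in range(n_cpgs)]
    return [
        Window(
            chrom,
            i * window_size,
            (i + 1) * window_size,
            tuple(i * window_size + o for o in offsets),
        )
        for i in range(n_windows)
    ]


def _random_pattern(rng: np.random.Generator, n: int, n_meth: int) -> tuple[int, ...]:
    pat = np.zeros(n, dtype=int)
    pat[rng.choice(n, size=n_meth, replace=False)] = 1
    return tuple(int(v) for v in pat)


# ---------------------------------------------------------------------------
# canned study mixtures


def null_mixture(
    n_windows: int = 500,
    n_cpgs: int = 8,
    coverage: float = 40.0,
    error_rate: float = 0.01,
    seed: int = 0,
) -> MixtureSpec:
    """Null tissue: no condition effect anywhere.

    One dominant cell type (10% of cells) plus twenty rare subpopulations at
    4.5% each — ten carrying substantially methylated haplotypes (3/4 of the
    window's CpGs methylated) and ten hypomethylated ones (1/4 methylated).
    Within each class the per-window haplotypes are sampled without
    replacement, so every subpopulation is distinguishable.  At ~1.8 expected
    reads per rare type per condition, sampling alone occasionally leaves a
    pattern with >= 4 reads in one condition and none in the other, so
    chance condition-unique clusters (and hence a nonzero sector-call null
    rate for the permutation FPR to calibrate against) occur at a low rate,
    as in real heterogeneous tissue.  Haplotypes are identical between
    conditions — every sector call is a false positive by construction.
    """
    import itertools

    rng = np.random.default_rng(seed)
    windows = make_windows(n_windows, n_cpgs)

    def pool(n_meth_choices: Sequence[int]) -> list[tuple[int, ...]]:
        pats = []
        for k in n_meth_choices:
            for combo in itertools.combinations(range(n_cpgs), k):
                pat = [0] * n_cpgs
                for i in combo:
                    pat[i] = 1
                pats.append(tuple(pat))
        return pats

    hi_k = [k for k in range(n_cpgs + 1) if 0.55 <= k / n_cpgs <= 0.9]
    lo_k = [k for k in range(n_cpgs + 1) if 0.1 <= k / n_cpgs <= 0.45]
    hi_pool, lo_pool = pool(hi_k), pool(lo_k)
    n_rare = 10
    hi_haps: list[list[tuple[int, ...]]] = [[] for _ in range(n_rare)]
    lo_haps: list[list[tuple[int, ...]]] = [[] for _ in range(n_rare)]
    dom_haps: list[tuple[int, ...]] = []
    mid_k = max(1, n_cpgs // 2)
    for _ in range(n_windows):
        for haps, src in ((hi_haps, hi_pool), (lo_haps, lo_pool)):
            idx = rng.choice(len(src), size=n_rare, replace=False)
            for j in range(n_rare):
                haps[j].append(src[idx[j]])
        dom_haps.append(_random_pattern(rng, n_cpgs, mid_k))

    cell_types = [CellTypeProfile("dominant", 0.10, {"A": dom_haps})]
    for j in range(n_rare):
        cell_types.append(CellTypeProfile(f"rare_meth_{j}", 0.045, {"A": hi_haps[j]}))
    for j in range(n_rare):
        cell_types.append(CellTypeProfile(f"rare_hypo_{j}", 0.045, {"A": lo_haps[j]}))
    return MixtureSpec(windows, cell_types, [], coverage, error_rate)


def planted_mixture(
    n_planted: int = 200,
    n_null: int = 100,
    n_cpgs: int = 4,
    focal_proportion: float = 0.3,
    coverage: float = 40.0,
    error_rate: float = 0.01,
    seed: int = 0,
) -> MixtureSpec:
    """A focal cell type loses methylation in condition B at planted windows.

    The focal type (default 30% of cells) is fully methylated everywhere in
    condition A; at the first ``n_planted`` windows its condition-B haplotype
    is switched to fully unmethylated, the expected sector-2 signature (a
    methylated cluster unique to A replaced by a hypomethylated cluster
    unique to B).  Two background types share the remaining proportion and
    carry mixed haplotypes (neither all-0 nor all-1) identical in both
    conditions, so they can never mask the focal clusters.  Background
    haplotypes keep 2..n-2 methylated CpGs — at least two Hamming steps from
    either focal pattern — so a single conversion-error flip cannot place a
    background read inside a focal cluster and silently break uniqueness;
    this needs pattern length >= 4.
    """
    if n_cpgs < 4:
        raise ValueError("planted_mixture needs n_cpgs >= 4 for distinguishable haplotypes")
    rng = np.random.default_rng(seed)
    n_windows = n_planted + n_null
    windows = make_windows(n_windows, n_cpgs)
    full = tuple([1] * n_cpgs)
    empty = tuple([0] * n_cpgs)
    focal = CellTypeProfile("focal", focal_proportion, {"A": [full] * n_windows})
    rest = 1.0 - focal_proportion
    mixed_choices = list(range(2, n_cpgs - 1))
    bg1 = CellTypeProfile(
        "bg1",
        rest / 2,
        {"A": [_random_pattern(rng, n_cpgs, int(rng.choice(mixed_choices))) for _ in range(n_windows)]},
    )
    bg2 = CellTypeProfile(
        "bg2",
        rest / 2,
        {"A": [_random_pattern(rng, n_cpgs, int(rng.choice(mixed_choices))) for _ in range(n_windows)]},
    )
    switches = [
        PlantedSwitch(i, "focal", "B", empty, expected_sector=2) for i in range(n_planted)
    ]
    return MixtureSpec(windows, [focal, bg1, bg2], switches, coverage, error_rate)


# ---------------------------------------------------------------------------
# read generation


def simulate_reads(
    spec: MixtureSpec,
    seed: int = 0,
    *,
    read_span: int | None = None,
) -> tuple[list[SequencedFragment], list[SequencedFragment], pd.DataFrame]:
    """Draw the two condition read sets and return them with the truth table.

    Per window and condition the read count is Poisson(coverage); each read
    samples a cell type by proportion, copies its (condition-specific,
    planted-switch-aware) haplotype, and flips each call with the conversion
    error probability.  With ``read_span`` set (bp), reads start uniformly
    across the window and carry only the CpGs inside their span, producing
    partial-coverage reads for the full-coverage filter to reject.
    Bit-reproducible for a fixed seed.
    """
    rng = np.random.default_rng(seed)
    p01, p10 = spec.flip_probs if spec.flip_probs is not None else (spec.error_rate, spec.error_rate)
    proportions = np.array([ct.proportion for ct in spec.cell_types])
    proportions = proportions / proportions.sum()
    out: dict[str, list[SequencedFragment]] = {c: [] for c in CONDITIONS}
    for cond in CONDITIONS:
        for w_idx, window in enumerate(spec.windows):
            n = window.n_cpgs
            if n == 0:
                continue
            patterns = [
                np.array(spec.effective_pattern(ct, cond, w_idx), dtype=np.uint8)
                for ct in spec.cell_types
            ]
            m = int(rng.poisson(spec.coverage))
            if m == 0:
                continue
            picks = rng.choice(len(spec.cell_types), size=m, p=proportions)
            u = rng.random((m, n))
            for r in range(m):
                state = patterns[picks[r]].copy()
                flip = np.where(state == 1, u[r] < p10, u[r] < p01)
                state = state ^ flip
                positions = window.cpg_positions
                if read_span is not None:
                    rs = int(rng.integers(window.start, window.end))
                    keep = [k for k, p in enumerate(positions) if rs <= p < rs + read_span]
                    if not keep:
                        continue
                    calls = {positions[k]: int(state[k]) for k in keep}
                else:
                    calls = {p: int(s) for p, s in zip(positions, state)}
                out[cond].append(
                    SequencedFragment(f"{cond}_w{w_idx:05d}_r{r:04d}", cond, window.chrom, calls)
                )
    return out["A"], out["B"], spec.truth_frame()


def make_null_pair(
    spec: MixtureSpec, seed: int = 0
) -> tuple[list[SequencedFragment], list[SequencedFragment], pd.DataFrame]:
    """Two condition datasets from the identical generating process.

    Requires a spec without planted switches; the two conditions are
    independent draws (distinct sub-streams of the seeded generator) and the
    truth table marks every window null.
    """
    if spec.planted_switches:
        raise ValueError("make_null_pair requires a spec without planted switches")
    return simulate_reads(spec, seed)


def write_simulation(
    fragments_a: Sequence[SequencedFragment],
    fragments_b: Sequence[SequencedFragment],
    truth: pd.DataFrame,
    out_dir: str | Path,
) -> dict[str, Path]:
    """Write read-call TSVs per condition, the truth BED, and a count summary."""
    from .ingest import write_readcalls_tsv

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "reads_A": out / "reads_A.tsv",
        "reads_B": out / "reads_B.tsv",
        "truth_bed": out / "truth.bed",
        "summary": out / "simulation_summary.json",
    }
    n_a = write_readcalls_tsv(fragments_a, paths["reads_A"])
    n_b = write_readcalls_tsv(fragments_b, paths["reads_B"])
    planted = truth[truth["planted"]]
    bed = planted[["chrom", "start", "end"]].copy()
    bed["name"] = "sector" + planted["expected_sector"].astype(str)
    bed.to_csv(paths["truth_bed"], sep="\t", index=False, header=False)
    summary = {
        "n_fragments_A": n_a,
        "n_fragments_B": n_b,
        "n_windows": int(len(truth)),
        "n_planted": int(truth["planted"].sum()),
    }
    paths["summary"].write_text(json.dumps(summary, indent=2) + "\n", encoding="utf-8")
    return paths
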