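# Methods

## Model and rationale

A bulk WGBS library over a mixed tissue is modelled as a finite mixture of
latent cell types. Within a fixed genomic window, each cell type carries one
binary methylation haplotype over the window's CpGs; every read is a clonal
copy of one molecule from one cell, so its observed pattern is that cell
type's haplotype corrupted by independent per-CpG bisulfite conversion
errors. Grouping reads by *exact* pattern identity therefore recovers, at
sufficient coverage, one read cluster per sufficiently abundant cell type
(plus small error-derived satellite groups, which the minimum-cluster-size
rule removes).

A methylation change confined to one cell type between two conditions then
has a precise read-level signature: the old pattern's cluster disappears
from the changed condition and a new cluster appears there, while shared
cell types keep contributing identical clusters to both conditions. A
cluster whose reads all come from one condition ("condition-unique") is the
unit of evidence; a window with a unique cluster on *both* sides is
classified by where the pair of unique-cluster levels falls in the
(knockout-unique, control-unique) plane.

## Pipeline parameters

| parameter | default | meaning |
|---|---|---|
| window size | 100 bp | tiling unit; windows are disjoint, trailing partial window kept |
| depth gate | 10 reads | minimum fully-covering reads *per condition* per window |
| min cluster size | 4 reads | groups below this are dropped (noise rule) |
| high threshold | 0.55 | "substantially methylated" cluster level (inclusive ≥) |
| low threshold | 0.45 | "hypomethylated" cluster level (inclusive ≤) |
| permutation iterations | 10 | label shuffles for the FPR estimate |
| contamination tolerance | 0 | fraction of other-condition reads a "unique" cluster may contain |
| promoter halfwidth | 2500 bp | promoter = TSS ± halfwidth |

All are configurable per run (CLI flags / YAML config / dataclass
arguments); levels exactly at a threshold qualify.

## Design choices

- **Exact grouping, not density clustering.** Identical-pattern grouping is
  implemented as a hash count over row patterns. It is equivalent to DBSCAN
  with a sub-1 Hamming neighborhood and `min_samples` equal to the cluster
  floor (the test suite cross-checks this against scikit-learn's DBSCAN),
  but is deterministic, order-independent, and directly oracle-checkable.
  Approximate merging of near-identical patterns is deliberately not done:
  with a 1-mismatch radius, error-derived satellites would chain clusters
  from distinct cell types together.
- **Sector orientation.** Sector 2 means: a methylated (≥ 0.55) cluster
  unique to the control paired with a hypomethylated (≤ 0.45) cluster
  unique to the knockout — methylation *lost* in the affected cell type.
  Sector 4 is the mirror image. Axes: x = knockout-unique level,
  y = control-unique level; sectors 1/3 are both-high/both-low.
- **Any-pair rule.** A window with several unique clusters per side is
  evaluated over every cross pair and carries the union of the sectors the
  pairs reach, so a window can belong to sectors 2 and 4 simultaneously;
  dual-sector windows are counted in both totals and reported as a rate.
- **Uniqueness is strict** (zero reads from the other condition). A single
  stray read — error-derived or contaminating — voids uniqueness. The
  `contamination_tolerance` knob relaxes this, but the default follows the
  strictest reading and all shipped results use it.
- **Permutation preserves counts.** Labels are permuted within each gated
  window across its rows, so per-window per-condition read depths are
  invariant; only the label–pattern linkage is destroyed. The FPR is pooled
  genome-wide: mean permuted sector count over iterations divided by the
  observed count, reported as NA when nothing was observed.
- **Mate overlap.** Overlapping mate bases are counted once, mate 1 taking
  precedence even on disagreement; the disagreement count is kept as a QC
  metric. Both strands report to the forward-strand C coordinate.
- **χ² without continuity correction**, 1 df, on 2×2 tables; Bonferroni
  over the number of sets tested. Zero-margin tables are flagged
  untestable rather than patched.

## The simulator

`simulate.MixtureSpec` draws, per window and condition, a Poisson(coverage)
number of reads; each read samples a cell type by proportion, copies its
(condition-specific, planted-switch-aware) haplotype and flips each call
with probability `error_rate` (symmetric by default; an asymmetric
`(p01, p10)` pair is available, since real conversion failure is
asymmetric). Two canned study mixtures define the conditions used by the
tests and the acceptance script:

- **Planted cohort** (`planted_mixture`): 200 affected + 100 unaffected
  windows, 4 CpGs each; a focal cell type at 30% of cells is fully
  methylated in condition A and switched to fully unmethylated in B at the
  affected windows; two background types (35% each) carry mixed haplotypes
  with 2..n−2 methylated CpGs — at least two Hamming steps from either
  focal pattern, so a single conversion-error flip cannot drop a background
  read into a focal cluster and void its uniqueness. Coverage 40× per
  condition, error 1%.
- **Null cohort** (`null_mixture`): 500 windows, 8 CpGs each, identical
  mixtures in both conditions: a dominant type (10%) plus twenty rare
  subpopulations at 4.5% — ten substantially methylated, ten
  hypomethylated, with per-window haplotypes sampled without replacement
  within each class so subpopulations stay distinguishable. At ≈1.8
  expected reads per rare type per condition, sampling alone occasionally
  yields a condition-unique cluster pair, giving a small nonzero null
  sector rate (≈2–3% of windows) — necessary for the permutation-FPR ratio
  to be defined, and representative of real tissues, where rare
  subpopulations make spurious unique clusters possible.

Sizes were chosen so the full test suite runs in well under a minute and
the acceptance script in seconds, while leaving Monte-Carlo error small
relative to the effects measured.

What the simulator does *not* model: fragment-length and GC biases,
correlated (read-level) conversion failure, copy-number variation,
non-CpG methylation, mapping errors, and genuine continuous intra-cell-type
heterogeneity. Passing tests therefore demonstrate the pipeline's logic and
calibration under the mixture model, not robustness to alignment artifacts;
the optional `read_span` mode exercises the full-coverage filter but not
realistic span distributions.

## Numerical and degenerate-input conventions

- Coordinates 0-based half-open everywhere; BED output likewise. Window ↔
  feature overlap is any-overlap (≥1 bp) under half-open semantics: a
  window ending exactly at a feature start does not overlap it.
- Cluster output is sorted by (level, pattern); all downstream outputs are
  byte-reproducible under a fixed seed and config.
- A CpG whose C is the last base of a window belongs to that window (the C
  coordinate decides).
- Windows with no CpGs produce no matrix; windows with a single CpG are
  retained (pattern space {0, 1}); no minimum CpG count is imposed.
- Empty inputs yield empty outputs (header-only tables), never errors;
  malformed exchange-format rows fail loudly with line numbers.
- FPR with zero observed windows is NA, not 0 or ∞.

## Known limitations

- Strict uniqueness makes sensitivity degrade when distinct cell-type
  haplotypes sit within one Hamming step of each other relative to the
  error rate; the contamination tolerance mitigates this at the cost of
  specificity, and no automatic choice is attempted.
- The permutation FPR is pooled genome-wide, as a ratio of counts; it is
  not a per-window p-value and windows are not ranked by significance.
- Promoter association uses interval overlap only; gene assignment beyond
  nearest-promoter intervals (e.g. regulatory-domain models) is out of
  scope.
- The scan holds per-window matrices for the permutation stage in memory;
  genome-scale inputs should be processed per chromosome (results are
  identical, as windows are independent).
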