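# Methods

## Scope and shape

`mirfish` implements a staged prioritization funnel: ligand-based target
fishing → protein–protein interaction (PPI) network construction and
scale-free selection → Maximal Clique Centrality (MCC) hub ranking with
annotation intersection → four-tool miRNA-prediction consensus → 3′UTR
accessibility filtering → final candidate ranking. Every stage consumes an
export format of an external service and never queries the service itself;
the package is deterministic end to end given its inputs and a seed.

## Target fishing

The similarity principle: structurally similar compounds tend to share
targets. A library record contributes its target when

* Tanimoto similarity to the query is **strictly greater than 0.7**,
* potency is present and **strictly below 150 µM**,
* the organism matches (default `Homo sapiens`).

Both inequalities are strict because the selection rules are worded as
"more than" and "less than"; records with unknown potency are excluded — a
filter that cannot be verified is treated as failed, the conservative
choice. The Tanimoto of two empty fingerprints is defined as 0.0 (0/0 is
indeterminate, and a structureless compound should never match anything).

The built-in fingerprint hashes every contiguous substring (length 1–7 by
default) of the raw structure string onto a 2048-bit set with CRC-32. It is
deliberately simple and dependency-free: similarity thresholds in public
compound databases are backend-specific and unspecified here, so no
fingerprint choice could reproduce an external search bit-for-bit.
`fish_targets` therefore accepts precomputed fingerprints, so an ECFP/Morgan
backend (e.g. RDKit) can be swapped in without touching the filter logic.

## Network construction and scale-free selection

Edge lists are STRING-style three-column TSVs. Scores on the 0–1000 integer
scale are auto-detected (any value > 1) and divided by 1000; edges at or
below the confidence floor (default **0.4, strict**) are dropped; duplicate
undirected edges keep the maximum score; self-loops are discarded.

Sphere expansion adds, first, the `first_sphere` non-seed neighbours with
the highest **summed edge score to the seed set**, then the `second_sphere`
best neighbours of the enlarged set. The ranking heuristic of the original
database's expansion is not published, so summed score with lexicographic
tie-breaks was chosen for determinism. Seeds absent from the interactome
are retained as isolated nodes (they are real query proteins; dropping them
would silently change the funnel's counts).

The degree distribution is fitted as `log P(k) = c − γ log k` by ordinary
least squares over the **distinct observed degrees k ≥ 1, without
binning**; `P(k)` is the fraction of all nodes (degree-0 nodes count in the
denominator but contribute no point, since log 0 is undefined). This is the
simplest faithful rendering of an R²-based scale-free criterion on small
networks; maximum-likelihood (Clauset-style) estimation is intentionally
out of scope because the selection statistic is the regression R², not the
exponent. Fewer than two distinct positive degrees is a degenerate fit and
an error. Among candidate networks the highest R² wins; ties break by
smaller node count, then lexicographically smallest settings (parsimony,
and permutation invariance of the selection).

## MCC hub ranking

`MCC(v) = Σ (|C|−1)!` over the maximal cliques `C` containing `v`. Cliques
come from Bron–Kerbosch with pivoting (networkx `find_cliques`); the test
suite checks the enumeration and the scores against an independent
brute-force subset oracle on hundreds of random graphs. Factorials are
exact integers — `(|C|−1)!` leaves float range around clique size 20.
Edge scores are ignored: cliques are topological. An isolated node scores 1
(its singleton is its maximal clique, `0! = 1`), which keeps the ranking a
total order; ranking ties break by higher degree, then symbol. The top-k
hubs are intersected with an annotation set (default GO term label
"apoptotic process" in a two-column symbol/term table), reported in hub
order.

## miRNA consensus

Per-tool pass rules, honouring strict vs inclusive wording exactly:
RNA22 `p < 0.05`; miRDB `score > 80`; DIANA `miTG ≥ 0.7`; TargetScan
`context+ ≤ −0.1` **or** `P_CT ≥ 0.5`. Each miRNA is judged on its
best-scoring record per tool (max score/miTG/PCT, min p/context+), because
tools emit several sites per miRNA while the unit of selection is the
miRNA. Ids are matched case-insensitively with the `hsa-` prefix
normalized on. A miRNA is kept when ≥ `min_tools` (default 3) of the four
pass sets contain it. The full 15-cell Venn decomposition is always
reported with each miRNA counted once, in its exact membership cell, so any
bookkeeping discrepancy in a published count is directly diagnosable.
Records missing their tool's score fields are skipped and counted, never
fatal. Column names per tool dialect live in a packaged YAML mapping.

## Accessibility and final ranking

Accessible regions are maximal runs of positions whose single-strandedness
probability is **strictly above 0.5** (a partition-function profile is an
input, never recomputed). A candidate site passes when it overlaps any
region by at least `min_overlap` nucleotides (default **1 nt**; the
published rule says only that candidates "hybridize with" accessible
regions, so the weakest overlap notion is the default and stricter ones are
a parameter). Coordinates are 1-based inclusive throughout, matching how
site positions are printed.

Candidates are ranked by **rank-sum** of (descending) LogitProb and
(ascending) ∆G hybrid, with rank-sum ties broken by LogitProb then id. On
the packaged candidate table the two criteria agree — the winner is the
double optimum — but they can conflict in general, and the rank-sum makes
the trade-off policy explicit, deterministic, and order-invariant.
LogitProb and ∆G are always consumed as inputs; units are assumed kcal/mol.

The nearest-neighbor duplex energy (`duplex_dG`) exists to generate
plausible synthetic ∆G values and for property tests: initiation penalty
plus Watson–Crick stack terms from the packaged Turner-set table
(Xia et al. 1998; 16 WC steps, values at 37 °C). GU wobbles are accepted as
pairs but their stacks contribute 0; loops, bulges and dangling ends are
out of scope. Published ∆G values are never recomputed.

## Synthetic data: what it emulates, and what it does not

The generators produce inputs with exactly the property each stage detects:

* **Interactomes** — preferential attachment (seeded with the complete
  graph `K_{m+1}`, so `m = n−1` degenerates to `K_n`) as the heavy-tailed
  positive control, Erdős–Rényi as the negative control whose binomial
  degree law should fail the log–log fit. Edge scores are drawn uniformly
  in (0.4, 1.0] so generated graphs pass the read filter unchanged.
  Defaults (200 nodes, m = 2) give a small interactome whose fitted
  exponent lands in the 1.5–3.5 band typical of biological networks.
* **Prediction tables** — planted miRNAs appear in ≥ 3 tools with passing
  scores; decoys either fail a threshold by a margin of at least 0.01 of
  its scale (avoiding float-boundary flakiness) or appear in ≤ 2 tools.
  Decoys can therefore never reach consensus, which makes planted-set
  recovery exact at every noise level — `noise_rate` only controls how many
  decoys look individually convincing. Defaults: 100 miRNAs, 10 planted,
  noise 0.2.
* **Profiles** — probabilities in [0.55, 0.95] inside planted windows and
  [0.05, 0.45] outside: a 0.05 guard band on both sides of the 0.5
  threshold. Default length 3600 nt, the scale implied by the largest
  printed site coordinate (3531).

None of this reproduces real marginal distributions: bioactivity values,
tool score correlations, and folding profiles of real transcripts are all
richer than these controls. Passing tests therefore demonstrate that the
*logic* of each filter and ranking is correct and deterministic, not that
the pipeline would reach the same biology from today's live databases.

## Packaged fixtures

The published intermediate tables are transcribed as golden inputs: the
25-target table, the 14-candidate table (site positions 1-based inclusive,
signed ∆G), the top-10 hub list, and the 14-gene apoptosis set. Their
checksums are asserted in tests. The interactome fixture is synthetic (no
edge list was published, only "110 interactions involving 35 proteins"):
it is constructed so that expansion from the 25 seeds with first sphere 10
and no second sphere yields exactly 35 nodes and 110 edges, and so that the
MCC ranking of that network reproduces the printed top-10 order — a
10-clique of hubs plus "prefix" attachments (a seed adjacent to the first
j hubs adds `j!` to each, making scores strictly decreasing along the
intended order), weakly attached decoys excluded by the first-sphere
cut-off. One published inconsistency is noted: the reported Venn total
(73 = 12 + 51) does not sum; the Venn reporting here keeps all 15 cells
explicit so such discrepancies are visible.

## Problem sizes and determinism

Tests and the acceptance script run on desk-scale inputs: fixture networks
of ≤ 40 nodes, oracle comparisons on ≤ 12-node random graphs (exhaustive
subset enumeration), synthetic tables of ≤ 100 miRNAs, profiles of ≤ 3.6 kb
— sizes at which every oracle is exact and the full suite completes in
seconds. All randomness flows through a single spec/seed; re-running any
generator or the whole pipeline with the same configuration is
byte-identical (reports contain no timestamps).

## Known limitations

* The fingerprint is not a cheminformatics-grade descriptor; exact
  reproduction of an external similarity search is explicitly not
  attempted (the target table is a fixture).
* OLS on log–log degree points is a selection statistic, not a rigorous
  power-law test.
* The duplex model has no loop/bulge/dangle terms and no GU stacks.
* GO annotation is a supplied table; no enrichment statistics are
  computed beyond set intersection.
* Other hub centralities (MNC, DMNC, EPC) are not implemented.
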