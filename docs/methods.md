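# Methods

## Scope and data model

`phagenet` analyses the structure of a binary bipartite infection matrix
`A` (rows `i` = bacterial phage types, PTs; columns `j` = typing phages,
TPs; `A_ij = 1` when phage `j` lyses type `i`).  Orientation is fixed —
rows are always bacteria — so every formula below can use the shared
symbols `r`, `c` (matrix dimensions), `k_i`, `d_j` (row/column degrees),
`F` (total interactions) and `M = r·c` without ambiguity.  Input is
already-binary delimited text; how graded lysis reactions are thresholded
into presence/absence is upstream of this package and deliberately out of
scope.

## Nestedness

All three scores are reported so that lower = more nested, 0 = perfect.

**NODF.**  For each unordered pair of rows with strictly decreasing fill
(`k_rich > k_poor > 0`) the contribution is `100·|overlap|/k_poor`,
otherwise 0; the same over column pairs; the raw score is the mean over
all `r(r−1)/2 + c(c−1)/2` pairs.  Equal-fill pairs contribute 0 by the
canonical definition (this also avoids 0/0 for empty vectors).  The
reported score is `100 − raw`.  The implementation is verified against an
exhaustive pair-enumeration oracle (exact equality).

**Temperature (NTC).**  Published temperature calculators differ in
packing refinement, isocline family and boundary handling, so temperature
is only reproducible *within* one fully specified variant.  Ours: degree
packing (stable ties); cell centres mapped to the unit square; the
isocline of perfect nestedness is the superellipse `u^p + v^p = 1`, with
`p` found by root finding so the presence-region area `Γ(1+1/p)²/Γ(1+2/p)`
equals the fill (to 1e−9); a presence in the absence region or absence in
the presence region scores the square of its normalised distance to the
isocline along the 45° line through the cell; `T = 100·U/0.04145` with `U`
the mean per-cell unexpectedness.  Completely full or empty matrices have
no unexpected cells; they return `T = 0` with a degeneracy flag rather
than erroring, so null-ensemble replicates remain scoreable.
Cross-implementation agreement is approximate by nature (a few
temperature points); within-package reproducibility is exact.

**BR (discrepancy).**  Columns ordered by descending degree (stable
ties); the packed reference left-justifies each row's `k_i` presences in
that order; BR counts packed presences missing from the observed row.
This is deterministic and auditable via the returned permutations.

## Bipartite modularity

Barber's modularity for a partition assigning labels `g_i` to rows and
`h_j` to columns:

    Q_B = (1/F) Σ_ij (A_ij − k_i d_j/F) δ(g_i, h_j)

Maximisation follows the LPAb+ scheme: (1) unique initial labels on the
column side; (2) label-propagation sweeps in which every row node adopts
the column-side label with the largest modularity gain, then columns
symmetrically; (3) greedy agglomeration — merge the module pair with the
largest strictly positive ΔQ_B, re-propagate, repeat until no merge
helps; (4) keep the best partition over many trials.  Because a node's
contribution to Q_B depends only on opposite-side labels, each adoption
and each merge is non-decreasing in Q_B, and only strict improvements
change labels, so every trial terminates at a local maximum and the
single-module score 0 is a global floor.

Tie-breaking is where the stochasticity lives: a node keeps its current
label when it ties the maximum, otherwise it picks uniformly at random
among maximisers.  A fully deterministic tie rule (e.g. lowest label id)
would make every trial identical and best-of-N pointless; random ties are
what let repeated trials escape different local maxima, which is the
reason the best-of-1000 protocol exists.  Runs are bit-reproducible given
a seed (per-trial RNG streams are spawned from the master seed).  Default
trials: 1000 on an observed matrix, configurable down (nulls use 20 by
default, 5 in the acceptance script) because null ensembles multiply the
cost by N.

## Null models and significance

Model 1: `p_ij = F/M` (uniform, fill-preserving in expectation).  Model
2: `p_ij = 0.5(d_j/r + k_i/c)` (degree-informed; preserves row/column
gradients in expectation).  Each replicate draws every cell independently
Bernoulli(`p_ij`).  Replicate `i` always receives RNG stream `i` derived
from the master seed (counter scheme), so an adaptive ensemble extends
rather than re-draws a fixed one.

Significance is one-sided in the structured direction — larger for Q_B,
smaller for the three nestedness scores — giving the familiar sign
semantics: a structured matrix has z > 0 for modularity and z < 0 for
nestedness.  `p = (b+1)/(N+1)` (add-one rule, never 0) with a flag marking
`b = 0`, the case a study would print as "< 1/N".  `z = (x − mean)/sd`
over the null scores; zero null variance raises rather than returning an
infinite z.  Degenerate null draws (empty rows/columns, even empty
matrices) are *retained* by default — every measure has a defined
degenerate convention — because rejection would silently change the null
process; an opt-in flag resamples them.  Adaptive mode starts at N = 100
and grows in steps of 100 until 5 extreme null scores are seen or N_max
(5000) is reached: clearly significant results stop early only in the
sense of a bounded p, borderline ones get resolution.

## Two-way clustering

Rows and columns are clustered independently: Euclidean distance on the
raw 0/1 profiles (no standardisation — profiles are already commensurate),
Ward linkage via the Lance–Williams recurrence on squared distances,
heights reported on the distance scale.  The implementation is written
out rather than delegated so tie-breaks are pinned (lowest cluster index
first), making leaf orders identical across runs; scipy's Ward is used as
an independent cross-check in tests, and each merge height `h` is checked
against the direct identity ΔESS = `h²/2`.

Dendrogram levels are also expressed as Wishart's objective function —
`100·(1 − ESS_level/ESS_total)` percent of information remaining — which
is 100 before any merge and 0 at one cluster; all-identical items (ESS
total 0) report 100 throughout with a degeneracy flag.

Group number is screened with MRPP: `delta` is the size-weighted
(`n_g/Σn_g`) mean within-group distance on raw (unsquared) distances; `A
= 1 − delta/mean(permuted deltas)` with sampled label permutations; `p`
is the add-one permutation p-value.  `select_groups` scans cuts k =
2..k_max and applies the fewest-groups-greatest-gain rule: the smallest k
whose A-gain over k−1 exceeds ε (default 0.01) while the further gain to
k+1 falls below ε.  Cuts with singleton groups (within-group mean
undefined) are recorded as NaN and skipped; if gains are still above
threshold at k_max the selection is flagged truncated; if nothing
qualifies, no k is selected and the full table is returned for the caller
to judge — the package deliberately reports the table rather than forcing
a cut.

## Synthetic data

The generators define the conditions every stage is tested under.

* `gen_random` — independent Bernoulli(fill) cells: exactly the model-1
  null process.
* `gen_nested` — staircase: row `i` left-justifies `k_i = round(c·(1 −
  i/r)·s)` presences, `s` chosen so realised fill is closest to target.
  By construction it equals its own packed form (BR = 0) and is isocline-
  consistent (T = 0).  Rescaled NODF is exactly 0 only when all row and
  column degrees are distinct, which a square staircase at the triangular
  fill `(c+1)/2c` achieves; with r ≫ c distinct row degrees are
  impossible (only c+1 values exist), so equal-fill pairs keep raw NODF
  below 100 — a property of the measure, not a generator defect.  The
  zero-score controls therefore use square staircases.
* `gen_modular` — planted-partition matrix: q row/column groups
  (near-equal, or explicit column sizes), Bernoulli(p_in) within,
  Bernoulli(p_out) between; the planted partition is returned.  Note that
  at nonzero p_out the planted partition is not always the Q_B argmax of
  the realised matrix: a row whose noise edges outweigh its within-module
  edges genuinely belongs elsewhere, and a correct maximiser will (and
  should) return that better partition.  Tests therefore distinguish
  "found ≥ planted" (always) from exact recovery (guaranteed only as
  p_out → 0).
* `gen_typing_like` — the 66 × 16 typing-scheme analogue: four planted
  typing-phage groups of sizes 6, 4, 4, 2 (the three T4-like groups and
  the T7-like pair), rows assigned proportionally.  Row degrees follow a
  geometric-like gradient (a few near-universal types down to narrow
  specialists) scaled to the target fill (default 0.5 — the real scheme's
  fill is not published, so this is a documented knob); each row places
  presences own-module-first with spill-over in a fixed module rotation,
  plus a 2% Bernoulli flip.  This makes the matrix simultaneously modular
  (specialists stay within modules) and nested (generalists' ranges
  contain specialists'), the coexistence the real scheme exhibits.

What the generators do **not** emulate: graded lysis phenotypes,
phylogenetic correlation between typing phages within a group, or
host-range constraints beyond degree structure.  Passing tests show the
measures and inference behave correctly under known structure and
calibrated noise; they do not validate biological conclusions about any
particular laboratory matrix.

## Numerical choices

* NODF/Q_B are exact rational arithmetic in floating point; equivalence
  oracles are asserted at 1e−12.
* Isocline area matching: Brent root finding to 1e−9 on the area;
  unexpectedness roots to 1e−12 along the cell diagonal.
* LPAb+ gain ties use a 1e−12 tolerance; merges require gain > 1e−12.
* Ward tie-break: minimum distance, then lowest active cluster index.
* Degenerate inputs: empty matrix → pack/Q_B error; full/empty → T = 0
  flagged; all-identical items → information remaining 100 flagged.

## Problem sizes

Unit and property tests run at ≤ 12 × 12 (oracle scale) plus 66 × 16 for
recovery and sign checks.  The acceptance script analyses one 66 × 16
matrix with 200 LPAb+ trials, 200-replicate ensembles per model (5 trials
per null for Q_B) and 499 MRPP permutations — sizes chosen so z-scores are
stable to a few percent while the whole run completes in minutes.

## Known limitations

* Temperature values are variant-specific; comparing them across software
  carries a few points of slack.
* MRPP's chance correction uses the sampled permutation mean rather than
  the exact expectation (they agree to O(1/√n_perm); the exact form is
  cross-checked in tests).
* The group-selection ε rule is a screen, not a test; the A/p table is
  the primary output.
* Row-cluster counts on strongly gradient-dominated matrices (like the
  typing analogue) are sensitive to ε: the nested gradient produces many
  small gains rather than one sharp elbow.
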