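# Methods

## The classifier contract

Every algorithm interacts with the classifier through one call:
genes × cells matrix + per-cell cluster labeling + target cluster label in;
cluster prediction, cluster score, a cells × cell-types score matrix and
per-cell predictions out.  Adapters must be pure (never mutate the matrix)
and deterministic unless declared stochastic.  Per-cell predictions are the
row-wise argmax of the score matrix with a first-column tie-break, so runs
are reproducible bit-for-bit.

The cluster-level *score vector* counts, over the target cluster, how many
cells have each type as their argmax.  Its top two entries (ctype1/ctype2)
define the gradient-descent target.  For a unanimous cluster the runner-up
is degenerate (all other counts are zero); ties are broken by the
column-wise sum of cell scores over the cluster, then by column order, so
ctype2 is always well defined.  The adapter's own cluster prediction remains
authoritative for attack success; during CGD the ctype1 used in the slope is
aligned with that prediction whenever it appears in the vocabulary, which
prevents a count tie from inverting the attack direction mid-run.

## Modifications

All operators rewrite only the (selected genes) × (target-cluster cells)
block and return a new matrix; inputs are never mutated.  Percentile,
extremum and decile statistics are computed **per gene over all cells of the
pristine matrix**, once per attack run, with linear interpolation between
closest ranks.  Two reasons: the aberrant magnitude is defined against the
*dataset* maximum, which is global; and cluster-local statistics would turn
`perc99` into a no-op for genes silent in the target cluster.  Whether
statistics should instead be cluster-local is genuinely open; the global
convention is recorded here and applied consistently.

`decile±N` maps each value to the quantile at its empirical CDF position
shifted by ±N/10, clamped to [0, 1]; N = 10 therefore saturates at the gene
minimum/maximum, and the shift is monotone in N.  `random` draws i.i.d.
uniform values between the gene's min and max from the spec's seed;
`aberrant±` writes ±1e5 × dataset maximum (with a warning when the maximum
is 0, in which case entries become 0).  `custom` applies a caller transform
to the dense submatrix; the bundled `dropout_custom(p, seed)` zeroes entries
with probability p and re-seeds per application, so a spec applied twice
yields identical matrices.

## Single-gene attack

Default 100 contiguous bins (numpy `array_split`: sizes differ by at most
one).  Each bin is modified wholesale and classified once (so an
unattackable dataset costs exactly `n_bins` evaluations).  Flipping bins are
resolved by a dichotomy designed around three rules:

1. a directly tested non-flipping half certifies all its genes clean and the
   parent's flip is attributed to the sibling half without testing it;
2. when a half *does* flip, the sibling must still be checked for additional
   hits; those sibling checks are deferred, merged, and resolved in one
   pooled classification, recursively split only if the pool itself flips;
3. every reported hit comes from a classification of that gene alone
   (soundness by construction); a tested flipping set whose descendants all
   certify clean is a combination effect and is reported in
   `discarded_combination_bins`, never silently dropped.

Rules 1–2 assume flips are attributable to single genes; when that fails the
leaf verification of rule 3 catches it and the combination set is reported.
With one attackable gene in a 200-gene bin the worst case is
`n_bins + ⌈log₂ 200⌉ + 2 = 110` evaluations (path tests + at most one leaf
verification + one pooled cleanliness check).  Reported `classifier_calls`
count evaluations of modified matrices; the single baseline classification
of the pristine cluster is excluded, a convention applied across all
attacks.

`block_size > 1` halts the dichotomy early and reports flipping gene
*blocks* — the overview quick mode; an optional `genes` argument restricts
the search to a subset (used when refining flagged blocks).

## Max-change attack

Greedy keep-set growth: the candidate set (initially all genes) is always
tested *in combination with* the keep-set accumulated so far; unchanged
classifications absorb the candidate, changed ones split it in half and
recurse (first half first, for determinism).  Candidates at or below
`max_split_size` that still flip are surrendered to the signature without
per-gene resolution — the documented precision/cost trade-off (default 1 =
full recursion).  The final keep-set is re-verified in one classification;
for non-monotone classifiers the verification can fail, which is surfaced as
a warning and a `verified=False` flag rather than hidden.  For monotone
classifiers the result is maximal: adding any signature gene flips.

## Cluster-based gradient descent

Probe: `f(x) = (1 + α·sign(x))·x + ε` with `sign(0) = 0` — a probe at a
zero-valued entry is driven by ε alone, and a pure-α attack cannot move
zeros.  One classification per probed gene serves every cell of the cluster
simultaneously (the contract returns per-cell scores in one call), cutting
calls by a factor of the cluster size versus per-cell probing; this assumes
each cell's scores depend only on its own expression vector, which holds for
the bundled fixtures and for per-cell classifiers generally.  Per cell,
`slope = Δscore(ctype2) − Δscore(ctype1)`; cells whose own top prediction
already equals the cluster's ctype2, or whose slope is zero, are skipped.
Accepted updates move each remaining cell one step along the sign of its
slope; the cluster is then reclassified and ctype1/ctype2 refreshed
(`freeze_target=True` pins them at their step-0 values; with more than two
cell types the refreshed runner-up is attacked).  Success is the cluster
prediction leaving the baseline label; the non-augmented mode stops there,
the augmented mode iterates through all provided genes and records the
fraction of cells still predicted as baseline per step
(`prediction_dynamics`).  Updates may produce negative expression (log-scale
data can be negative); `clip_at_zero=True` floors them.  Default gene order
is the pairwise t-statistic ranking; explicit lists support random or
variance orderings.

Exhausting `max_genes` without a flip returns `success=False` with the full
step log — not an exception — since a resistant classifier is a result, not
an error.

## Gene ranking

For every unordered cluster pair with at least two cells per side, genes are
scored by |Welch t| (scipy `ttest_ind`, `equal_var=False`); zero-variance
pairs give t = 0, and |t| ties break lexicographically on gene id.  The
output interleaves per-pair rankings round-robin, so with k clusters the
first C(k, 2) genes come from C(k, 2) distinct pairs whenever each pair has
an unused gene.  Pooled-variance t and other interleavings would be
defensible; Welch plus round-robin is the package's recorded choice.

## Random walk and grid

The walk draws a full random gene → modification assignment (seeded); once
one flips, single entries are removed in a re-shuffled order each sweep,
keeping removals that preserve the flip, until a fixpoint (1-minimal by
construction: the last sweep verified every single-entry removal) or until
the `max_walk` classifier-call budget — shared between initial resampling
and reduction — runs out.  The grid enumerates every per-gene choice among
the modifications plus "untouched" ((|mods|+1)^n − 1 non-empty assignments,
n ≤ 9 enforced) and returns the full table sorted by assignment size then
lexicographically; the enumeration is its own oracle.

## Overview survey

Quick settings: 20 initial bins, dichotomy halted at 100-gene blocks,
`max_split_size = 100`.  Summaries are vulnerable-unit counts (single-gene)
and signature lengths (max-change); per-cell attack errors are recorded in
the grid row and the sweep continues.  `refine=True` reruns the precise
single-gene search restricted to each flagged block.  Blocks can only
over-approximate: on classifiers without combination effects every gene the
precise attack finds lies inside some reported block.

## Synthetic data generator

`make_synthetic_dataset` emulates a log-normalized, cluster-structured
matrix: Gaussian baseline (mean 1.0, sd 0.5 by default), per-cluster
exclusive marker genes at seeded-random positions shifted up by the marker
effect (2.0), values floored at zero, and entries zeroed at the dropout rate
(0.3).  Defaults were chosen once as a realistic small-scale sketch of
log-normalized scRNA-seq data.  What it does *not* emulate: count noise and
library-size variation, correlated gene programs, doublets, batch effects,
or continuous differentiation trajectories.  Tests passing on these fixtures
therefore demonstrate algorithmic correctness (completeness, call budgets,
gradient signs) — not robustness claims about real classifiers on real data,
which depend on the wrapped model.

`make_balanced_subset` equalizes cluster sizes (default 100 cells),
bootstrapping small clusters by resampling each gene independently within
the cluster (marginal bootstrap — the joint alternative is defensible; the
marginal choice is recorded here).  The reference classifiers (marker
voting, linear scorer with exposed weights, single-gene threshold, constant)
exist to give the attacks analytically checkable targets; the linear scorer
in particular makes the finite-difference estimate exactly
`w_kj · (α|x| + ε)`.

## Sizes and budgets

Unit and property tests run on 10–300-gene fixtures; the call-budget checks
use a 20 000-gene, 50-cell instance (sub-second per attack thanks to the
cheap fixture classifiers).  The acceptance script uses the same 20 000 × 50
instance.  These sizes were chosen so the full suite completes in well under
a minute while still exercising the default 100-bin configuration at
realistic gene counts.

## Known limitations

- Single-gene completeness and max-change maximality are guaranteed only for
  classifiers whose flips are monotone/attributable; for adversarial
  non-monotone models the results are heuristic (flagged via combination
  bins and the `verified` flag).
- The cluster-wide CGD probe assumes per-cell score independence; classifiers
  with cross-cell normalization would need per-cell probing (at |cluster|
  times the call cost).
- `cluster_score` semantics are adapter-defined; the toolkit never compares
  scores across different adapters.
- Stochastic classifiers (declared via `stochastic=True`) are accepted but
  all call-count guarantees assume determinism.
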