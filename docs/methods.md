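# Methods

## Problem and model

Single-cell DNA sequencing of a tumor yields a binary matrix `B` (rows =
cells, columns = somatic SNVs) with entries 1 (mutation observed), 0
(absent) or missing (no usable reads).  Under the infinite sites
assumption the error-free matrix admits a perfect phylogeny; the tumor
evolved *linearly* when the clonal tree is a path, equivalently when the
per-mutation cell sets (one-states `O_j = {i : b_ij = 1}`) can be totally
ordered by set inclusion.

Dropout (false negatives, rates up to ~0.4) destroys this structure, so
the package solves a minimum-flip repair problem: given a budget `z` of
allowed 1→0 corrections (expected false positives, typically
`z = ⌈α · #ones⌉` for a platform false-positive rate α around 1e-4–1e-3),
find the minimum number `y` of 0→1 flips after which the matrix is a
linear perfect phylogeny.  The problem is NP-hard — a binary matrix is a
linear perfect phylogeny exactly when its bipartite cell–mutation graph
is a chain graph, and minimum chain-graph edge insertion is NP-complete —
so an exact integer-programming solver is used.

`y/N` (with `N` the number of ones in the repaired matrix) estimates the
dropout fraction `β̂` implied by forcing linearity.  Two beta-binomial
hypotheses are compared: under linear evolution `y` should look like
genuine dropout (`p ~ Beta(μ_linear, s_linear)`, `y ~ Bin(N, p)`), under
branched evolution the flips also have to erase real branching, giving a
stochastically larger `β̂`.  The Bayes factor

    K = P(y | H_linear) / P(y | H_branched)

computed from the two beta-binomial marginals (all in log-gamma space)
supports linearity when K > 1.  A simpler hard threshold declares
"branched" when `β̂ > β*`; it can never positively support linearity, so
its non-rejection outcome is reported as `NOT_REJECTED` rather than
`LINEAR`.

## Exact solver

The solver is a mixed-integer program over binaries `x_ij` (the repaired
matrix) plus one boolean `w_ab` per unordered column pair: `w_ab = 1`
forces column `a`'s one-state inside column `b`'s (`x_ia ≤ x_ib` for all
rows), `w_ab = 0` the reverse.  Pairwise nestedness of a set family is
equivalent to being a chain, so no explicit permutation variables are
needed; the column order is read off the solved matrix by sorting
one-states by size.  The objective charges observed zeros that end as
ones; one knapsack row caps observed ones ending as zeros at `z`;
missing entries are free variables with zero cost, excluded from the
flip sets, from `N` (by default) and from the ones-count behind
`z = ⌈α·#ones⌉`, and reported separately as imputations.  The engine is
HiGHS (via `scipy.optimize.milp`), single-threaded and deterministic;
it proves optimality (`OPTIMAL`) or returns the best incumbent at the
time limit (`FEASIBLE_TIMEOUT`), which downstream classification
surfaces via `solver_status`.  A feasible solution always exists (the
all-ones matrix is a one-clone linear phylogeny), so valid input never
returns infeasible.

Exactness safeguards, all independent of the primary encoding:

* a brute-force oracle enumerating all `m!` column orders, with a
  per-row cut-cost table and a dynamic program over the shared `z`
  budget (`permutation_cost`), checked against the solver on hundreds of
  random small instances;
* an alternative encoding that forbids the 2×2 `[[1,0],[0,1]]` submatrix
  directly (the forbidden-submatrix characterization of chain graphs),
  required to give identical objectives;
* a post-hoc validity check (`is_linear` on the returned matrix, flip
  bookkeeping, budget respected) on every returned solution.

Two performance details are exact reductions: duplicate rows are merged
with multiplicities only when `z = 0` (with a shared 1→0 budget an
optimum may treat identical rows asymmetrically, so merging is disabled
for `z > 0`), and a greedy upper bound (columns ordered by observed
one-state size, then the per-row cut dynamic program) is added as an
objective cut to prune search.  An already-linear complete matrix
returns immediately with zero flips.

Numerical/tie conventions: column orders are reported most-derived first
(smallest one-state first); equal one-states — mutations that cannot be
ordered — keep their column order (stable sort) and are treated as one
pseudo-edge by the tree-distance code; a Bayes factor of exactly 1 is
classified BRANCHED with a warning (ties are measure-zero and should not
silently claim linearity); `β̂ = 0/0` is defined as 0 with a warning.

## Default priors

`H_linear`: μ = 0.05, s = 10 — the dropout profile of current
high-throughput single-cell DNA platforms.  `H_branched`: μ = 0.15,
s = 10 as a theoretical "implausibly high dropout" default; the
recommended practice, and what the robustness experiment does, is to fit
(μ_branched, s_branched) by method of moments (mean, and
`s = μ(1−μ)/Var − 1`, clamped to [0.5, 1000]) to `β̂` values from
branched-evolution simulations matched to the data's size and error
profile, separately per mutation count `m`.  All four parameters are
overridable.

## Synthetic data

The generator emulates the structure the classifier must detect, not any
specific cohort.  A clone tree over `m+1` clones (clone 0 = mutation-free
founder, one new mutation per edge) is either a path (LINEAR) or a
random-attachment tree rejection-sampled to contain a multifurcation
(BRANCHED).  Clonal prevalences are a symmetric Dirichlet(1) draw; cells
are sampled i.i.d. by prevalence, so rare clones may go unsampled — in
that case mutations private to unsampled clones share a one-state and
their relative order is unidentifiable, which is why the "error-free
linear data is recovered exactly (AD distance 0)" law is asserted only
when every clone contributed a cell.  Errors follow the standard
single-cell model: per-entry dropout β (1→0), false positives α (0→1),
and doublets δ (a row OR-merged with the true genotype of a second,
uniformly chosen cell).  Doublets are applied before read errors — a
doublet is co-captured material that is then sequenced once.  The
generator does not emulate: read-depth variation and missing data (the
solver and I/O handle missing entries, but the error model leaves them
out), copy-number events violating infinite sites, or cohort-specific
clone prevalences (user-suppliable).  Passing tests therefore show
correctness of the method under its own model assumptions, not
robustness to every artifact of real data.

## Robustness experiment

The sweep crosses pattern ∈ {LINEAR, BRANCHED}, dropout
β ∈ {0.05, 0.15, 0.25}, false positives α ∈ {0.001, 0.01} and doublets
δ ∈ {0.0, 0.2}, solving each instance with `z = ⌈α·#ones⌉` and
classifying by Bayes factor with the branched prior fitted per `m` from
an independent branched-only calibration run (disjoint seed stream).
The package's default experiment uses 150 cells, m ∈ {10, 25}, 2
replicates and a 15 s per-instance solver cap (the acceptance script
uses 1 replicate); these problem sizes keep a full sweep on one CPU in
the tens of minutes while leaving the per-instance inference problem
non-trivial.  Classification quality at this scale tracks the
larger-matrix behavior because the decision statistic `β̂` is an
intensive quantity, and a short solver cap is benign for the same
reason: the rare capped instance returns a near-optimal incumbent whose
slight `y` inflation barely moves `β̂`.  Calibration instances use a
replicate stream disjoint from evaluation *and* a distinct founding
topology per error condition — the fitted prior must capture
topology-to-topology variation of `β̂`, which dominates its spread;
fitting many noise conditions on a single founding tree would produce a
spuriously tight prior whose thin tails lose to the fat-tailed linear
hypothesis even far from its mean.  Expected behavior: accuracy well
above 0.85 with a large separation (≥ 0.2) between median `β̂` on
branched versus linear instances.

## Evaluation metrics

*Ancestor–descendant (AD) distance*: the symmetric difference of the
ordered ancestor–descendant mutation-pair sets of two edge-labeled
trees, with pairs on a single edge excluded.  A solved linear matrix is
read as a path tree whose edges are groups of mutations with identical
one-states.  Raw cardinality is reported (no normalization).  AD
distance is a pseudometric: zero between trees with equal pair sets,
symmetric, non-negative.

*Confusion summary*: overall accuracy, per-(truth, label) counts, and
per-truth medians of `β̂` and `K` over a grid results table.

## Known limitations

* Worst-case solver time is exponential; large branched matrices may
  return `FEASIBLE_TIMEOUT` incumbents.  The objective from an incumbent
  upper-bounds the true minimum, slightly inflating `β̂`; the status is
  always propagated so callers can decide whether to re-run longer.
* The hypothesis test conditions on the solver's single optimal `y`;
  co-optimal solutions with different flip sets do not change `y`, but
  model uncertainty over trees is not integrated.
* Doublet removal is not performed; consistent with the OR-merge model,
  high doublet rates make branched data look *more* linear, so doublet
  filtering should precede classification when δ is large.
* The moment fit for the branched prior assumes the calibration `β̂`
  values lie strictly inside (0, 1); degenerate calibrations fall back
  to the theoretical default with a warning.
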