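# Methods

## Problem and model

Matched miRNA/mRNA expression profiles carry information about which
miRNAs repress which mRNAs, but correlation alone cannot separate direct
regulation from shared upstream causes. This package treats the gene set
as a causal Bayesian network: vertices are the expression levels of
miRNAs, mRNAs, and TF-coding mRNAs; a directed edge means the parent
regulates the child, and the graph is assumed acyclic. Target prediction
is cast as estimating the *intervention* effect of each miRNA on each
mRNA — how the mRNA's expression would move if the miRNA's expression
were set externally — and ranking candidate targets by the magnitude of
that effect.

Two kinds of experimentally validated knowledge are integrated:
transcriptional TF→miRNA regulation and post-transcriptional miRNA→mRNA
repression. A knowledge pair becomes a **constant edge**: inserted into
the graph directed regulator→target, never removed by an independence
test, and never re-oriented. Constant edges do participate in
conditioning sets, which is precisely how one validated edge can expose
a spurious one (conditioning on the validated target separates two
spuriously linked regulators), and they seed orientation propagation so
that neighbouring undirected edges become directed.

## Structure learning

Learning is constraint-based (PC-style) under a joint-Gaussian working
assumption:

1. **Skeleton.** Start from the complete undirected graph. For growing
   conditioning-set sizes 0..`max_cond_size`, remove an edge (i, j) when
   some subset S of either endpoint's current neighbourhood makes the
   Fisher-z partial-correlation test accept independence:
   z = arctanh(r<sub>ij·S</sub>), statistic √(n−|S|−3)·|z| against the
   standard normal, independence when p > `alpha`. The deletion phase is
   the order-independent ("stable") variant: neighbourhoods are
   snapshotted per level, so the result does not depend on gene order.
   The separating set of every removed pair is recorded. Constant edges
   are never tested.
2. **v-structures.** An unshielded triple i−j−k (i, k non-adjacent)
   orients as the collider i→j←k when (a) j is not in the recorded
   separating set of (i, k) **and** (b) i and k test *dependent* given
   {j}. Requirement (b) is the definitional form of a v-structure and is
   essential in practice: two co-targets of one miRNA are often so weakly
   correlated that they separate with an empty set, and the sepset
   criterion alone would then orient a false collider *into* the miRNA,
   reversing true regulatory edges. Conflicts resolve deterministically
   (lexicographic first-wins); a conflict with a constant edge always
   resolves in favour of the knowledge and is logged. Orientations that
   would close a directed cycle are skipped.
3. **Propagation.** The four standard pattern-completion (Meek) rules
   direct every remaining edge whose orientation is forced by "no new
   v-structure, no directed cycle". The public `orientation_closure`
   raises on an edge forced both ways (the signature of contradictory
   knowledge); inside `learn_structure` conflicts from finite-sample
   artifacts keep the first orientation and are logged, because a single
   noisy triple must not abort a whole experiment. Contradictory
   knowledge itself is caught earlier: the constant-edge set must be
   acyclic or learning refuses to start.

Variants tried and rejected during development: conditioning the
v-structure test on sepset∪{j} (CPC-flavoured) and orienting triples in
order of collider-evidence p-values (max-p flavoured). Both performed
slightly worse here, because strong residual dependence given {j} more
often reflects a *missed weak shielding edge* than a true collider.

## Causal effect estimation

For jointly Gaussian variables and a known DAG, the total causal effect
of X on Y is the coefficient of X in the OLS regression of Y on X and
the parents of X (back-door adjustment for the cause's parent set), and
it is zero when Y is itself a parent of X. The regression includes an
intercept and the data are not standardised, so effects are on the
expression scale (expression change per unit expression change). The
adjustment set is deliberately the *cause's* parents: adjusting for the
effect's parents would condition on the very edge under estimation.

Because learning only identifies the graph up to its equivalence class
(plus knowledge), the effect of a miRNA is a set of values across
consistent orientations. Following the intervention-calculus (IDA)
construction, the package enumerates parent sets locally: subsets S of
the cause's undirected neighbours are admissible when directing S into
the cause creates no new collider there (every member of S adjacent to
every other prospective parent). The reported value is the member of
smallest magnitude — a lower bound on the true effect size — with sign
preserved and ties broken by the deterministic enumeration order. On
patterns (CPDAGs) the local set of values provably equals the set from
orienting the whole graph; `enumerate_consistent_dags` provides the
exhaustive oracle and the equality is checked to 1e-8 on random small
patterns. For maximally oriented graphs with background knowledge the
local method can in principle admit a parent set with no global
extension, making the bound conservative; this is a known limitation.
A per-cause budget (`max_parent_sets`, default 4096) truncates the
enumeration to smaller subset sizes for pathologically dense
neighbourhoods, with a logged warning.

The zero branch matters for interpretation: any true edge whose
orientation the data cannot pin down (or gets wrong) yields a zero lower
bound and drops to the bottom of the ranking. This is the honest price
of reporting identifiable lower bounds rather than correlations.

## Simulation design

Ground truth is a random DAG: a uniformly drawn topological order, each
forward pair added independently with probability `edge_prob`, and only
role-admissible edges kept — TF-coding mRNAs may regulate miRNAs and
mRNAs (TF-coding included), miRNAs may repress mRNAs (TF-coding
included), plain mRNAs are sinks. "mRNA" targets include TF transcripts
because a TF transcript is an mRNA. Expression follows the linear
structural equations

    x_i = b_i + Σ_{j ∈ pa(i)} w_{j→i} x_j + ε_i

with regulatory weights w ~ U([−1, −0.1] ∪ [0.1, 1]) (no near-zero
effects), intercepts b ~ N(0, 1), and non-Gaussian noise, by default
ε ~ Uniform(−1, 1) — bounded, symmetric, simple — with Laplace and
Student-t(5) available. Knowledge subsets are sampled from the true
edges of each type through a per-type permutation keyed only by the seed,
so the subsets are *nested* across the fraction grid by construction and
sweeps are monotone in what the learner is given.

Sweep defaults are full scale (50 networks × ~1000 nodes × 250/500
samples). The test and validation profile is deliberately
smaller — 10–20 networks × 100 nodes × 250 samples, `edge_prob` = 0.2
(≈ 190 realised edges, mean out-degree ≈ 2, ≈ 90 true miRNA→mRNA edges
per network) — chosen once as a realistic desk-scale profile. Role
fractions default to 10% miRNA / 10% TF-coding / 80% mRNA.

What the generator does *not* emulate: count noise of RNA-seq,
probe-level measurement error, cell-type mixture, feedback loops
(the model is acyclic by assumption), and miRNA–miRNA or mRNA→mRNA
(non-TF) regulation. Passing tests therefore demonstrate correctness of
the machinery and the qualitative knowledge-integration behaviour, not
performance on any particular real dataset.

## Evaluation

Precision, recall and F = 2pr/(p+r) are computed against the true
miRNA→mRNA edge set. Score matrices become predictions by taking the
top-N pairs globally with N equal to the number of true edges, which
makes precision = recall = F and removes the arbitrary cut-off from
method comparisons; per-miRNA top-k extraction exists for real-data use.
The sweep grid is 0–50% knowledge in 5% steps (11 points; the validation
profile uses {0, 0.25, 0.5}) for TF→miRNA, miRNA→mRNA and combined
knowledge; at fraction 0 the three types coincide and are computed once.
Monotonicity is asserted statistically (within one Monte-Carlo standard
error of the cell mean), not pointwise — the property concerns mean
curves over replicates, not individual networks.

Baselines share the ranking rule: |Pearson correlation|; |Lasso
coefficient| of each mRNA regressed on all miRNAs with the penalty
picked by seeded 5-fold cross-validation; and a pseudo-knock-out Z-score
that treats each miRNA's minimum-expression sample as its knock-out and
scores each mRNA by its z-score magnitude in that sample.

At the desk-scale validation profile the causal ranking beats the
Z-score heuristic by roughly a factor of three and improves monotonically
with knowledge, but trails plain Pearson correlation slightly
(≈ 0.03 in mean F) without knowledge: at n = 250 some weak shielding
edges are missed, the affected triples genuinely test dependent, false
colliders orient into miRNAs, and every reversed or undirected true edge
is zeroed by the lower bound. This trade-off is documented rather than
patched, and the corresponding check in the test suite is left to fail
when it falls outside one standard error.

## Numerical and engineering choices

- Correlations are clipped to 1 − 1e−12 before arctanh; singular
  correlation submatrices raise an error naming the offending genes in
  the single-test API, and are treated conservatively as dependence in
  the batched skeleton path.
- All iteration orders are lexicographic on gene identifiers; identical
  inputs give byte-identical outputs.
- Every stage derives its random generator from (seed, stage label), so
  adding a stage never perturbs another stage's draws.
- `alpha` defaults to 0.01 and `max_cond_size` to 3; both configurable.
  The conditioning-size cap bounds runtime on thousand-gene matrices.
- Rank-deficient regression designs raise with the collinear gene set
  named rather than silently pseudo-inverting.
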