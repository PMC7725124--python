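# Methods

## Model

A tumor phylogeny is a rooted tree whose root is the unmutated germline and
whose nodes carry labels from the set of mutation gains `m+` and losses
`m_l-`; a node may carry several labels (all events on the edge above it).
Under Dollo(k) each mutation is gained exactly once and lost at most `k`
times.  The *state* of a node is the set of mutations gained and not
subsequently lost on its root path; a cell attached at a node carries
exactly that state.  The data is an incomplete ternary matrix: a present /
absent call per (cell, mutation), or a missing entry where coverage was
insufficient.

Observation noise is a per-entry channel with false-negative rate `alpha`
(a present mutation read as absent — dominated by allelic dropout in
whole-genome-amplified single cells) and false-positive rate `beta`:

    P(I=1|F=1) = 1-alpha    P(I=0|F=1) = alpha
    P(I=1|F=0) = beta       P(I=0|F=0) = 1-beta

The target is the complete genotype matrix `F`, constrained to admit a
Dollo(k) phylogeny, that maximizes `sum log P(I|F)` over known entries.
Missing entries contribute exactly zero.  Because each `F(c,m)` is binary,
each term is affine in `F(c,m)` (slope `log((1-alpha)/beta)` and intercept
`log beta` for an observed 1; slope `log(alpha/(1-beta))` and intercept
`log(1-beta)` for an observed 0), which makes the likelihood a linear
objective.  Natural logarithms throughout; the base cancels in the argmax.
A per-entry `(alpha, beta)` override grid implements the non-uniform
variant of the channel; the command line exposes only the global rates.

## The ILP

The reduction: replace each mutation column by one gain column and `k` loss
columns.  `F` admits a Dollo(k) phylogeny iff the extended matrix has a
binary completion `E` that (a) is conflict-free — no pair of columns shows
all three row configurations (0,1), (1,0), (1,1), the classic
directed-perfect-phylogeny characterization — and (b) satisfies
`F(c,m) = E(c,m+) - sum_l E(c,m_l-)` with every difference in {0, 1}.

Variables (all binary): `E(c,p)` for every cell and extended column;
`F(c,m)` tied by the linking equality (binariness of `F` then enforces the
0/1 difference for free); witnesses `B(p,q,a,b)` for every *unordered*
column pair and `(a,b) in {(0,1),(1,0),(1,1)}`, pushed up by
`B(p,q,0,1) >= E(c,q)-E(c,p)` etc. for every cell, with
`B(p,q,0,1)+B(p,q,1,0)+B(p,q,1,1) <= 2` forbidding conflicts.  Unordered
pairs halve the witness count relative to the ordered formulation without
changing feasibility; pairs formed by the same mutation's gain and loss
columns are included (the linking constraint already rules (0,1) out for
them, so the witness rows are merely redundant).  For `n` cells, `m`
mutations and fixed `k` this is Θ(nm + m²) variables and Θ(nm²)
constraints.

Optional extras:

* **Loss cap** (`--max-del`): indicator `u(m,l) >= E(c, m_l-)` for all
  cells marks a loss column as *used*; `sum u <= max_losses` bounds the
  number of realized losses (loss columns identical to zero are simply
  unused and absent from the tree).
* **Symmetry breaking** (`k >= 2` only, off by default): loss copies of one
  mutation are interchangeable, so copy `l+1` may be used only if copy `l`
  is.
* **Sparsity tie-break** (`sparsity_weight`, default 0 in `build_model`,
  1e-6 per E-entry in the pipeline): among likelihood-optimal completions,
  prefer the one with fewest 1-entries.  The total perturbation is bounded
  by `1e-6 · n·m·(k+1)`, orders of magnitude below any single-entry
  log-likelihood gap at realistic rates, so the genotype optimum is
  unaffected; it only stops the solver from returning gratuitous gain/loss
  entries that clutter the extracted tree.

Error rates are clamped to `[1e-9, 1-1e-9]` before logs so noise-free
configurations stay usable; with clamped rates a "zero-noise" entry
mismatch costs ≈ 20.7 log units, which acts as an effectively hard
constraint.

### Solving

The solver interface is deliberately minimal (binary variables, sparse
linear constraints, time limit, incumbent access); the shipped adapter
drives HiGHS through `scipy.optimize.milp` with `mip_rel_gap = 0`.  HiGHS
runs deterministically here; `seed`/`threads` are accepted for interface
compatibility but not forwarded, because the scipy wrapper exposes neither.

When a time limit stops the search before an optimality proof, the
incumbent is returned (`status = "feasible-timeout"`).  HiGHS's own primal
heuristics start late on large instances of this model (the root LP alone
takes seconds at 100×30, k=1), so `solve` additionally constructs a basic
feasible solution — the best-likelihood member of {root-only tree, star of
all mutations, prevalence-ordered chain} — and returns whichever of it and
the solver incumbent scores better.  This is the usual MIP-start remedy,
kept deliberately simple: a strong domain-aware start would duplicate the
job of the refinement stage.  Every returned solution is validated:
conflict-freedom, the linking identities, and agreement (1e-6) between the
solver's objective and the log-likelihood recomputed from `F`.

## Tree extraction and cell attachment

A conflict-free completed matrix yields a tree by the standard directed
perfect-phylogeny construction: columns sorted by decreasing count (ties by
index), identical columns merged onto a single node carrying all their
labels, all-zero columns omitted.  The deterministic order makes outputs
bit-reproducible.  Cells may attach to any node, not only leaves: attaching
to an internal node equals attaching to an implicit unlabeled leaf child,
and per-cell likelihood maximization (ties to the smallest node id) is
globally optimal because cells are independent given the tree.

With losses, the tree explaining a matrix is *not unique* — the ancestral
order of two mutations can be inverted by trading a loss — so all
correctness guarantees in the tests are stated at the level of genotype
matrices and of mutation-pair relations, never of tree shape.

## Hill climbing

A neighbor of a tree prunes the subtree at a non-root node `u` and
reattaches it as a child of any node `v` outside that subtree
(`v ≠ parent(u)`).  Loss labels invalidated by the move — the mutation is
no longer acquired above, or was already lost higher on the same path — are
contracted, on both the moved subtree and the remainder (the conservative
reading; contraction can only remove losses, so the Dollo(k) bound is
preserved).  The full neighborhood is quadratic in tree size, so each
iteration scores `neighbor_samples` (default 30) uniformly random valid
moves — drawn by enumerating the valid pair set, which is exact, cheap at
these sizes, and handles the no-move case — and relocates only on *strict*
improvement; plateaus do not move, preventing seed-dependent drift across
likelihood ties.  The loop runs `max_iterations` (default 100) iterations
regardless of acceptance and returns the best tree, attachment and
log-likelihood ever evaluated, which is therefore never below the start's.
Scores are recomputed from scratch per neighbor (no incremental caching):
one vectorized cells × nodes × mutations pass, microseconds at desk scale.
Defaults were chosen so a default run on a 100×30 instance finishes in
seconds; both are exposed (`--ns`, `--mi`).  With a fixed seed the full
trajectory is reproducible.

## Simulator

The generator emulates the reference study design: a random clonal tree of
`n_subclones` nodes grown by uniform parent choice; each of `n_mutations`
mutations assigned to a uniformly random subclone (a subclone node may
carry several gains or none); `n_deletions` deletion nodes, each attached
as a new child of a uniformly chosen node whose state still contains an
undeleted mutation, deleting a uniformly chosen eligible mutation from the
parent's state — deleted mutations are pairwise distinct, so the truth is
always Dollo(1).  Cells attach independently and uniformly with repetition
over *all* tree nodes: subclones, deletion nodes (otherwise losses would be
unobservable) and the germline root (normal cells, which real single-cell
datasets contain).  Noise: flip 1→0 with `alpha`, 0→1 with `beta`, then
mask each entry as missing with `gamma` independently; masking last is
observationally equivalent to any order since a masked entry hides its
value.  Defaults are the reference configuration: 9 subclones, 100 cells ×
30 mutations, 5 deletions, `alpha = 0.1`, `beta = 1e-4`, `gamma = 0.1`.

What the simulator does *not* emulate: doublets, clone-size-weighted
sampling, copy-number events beyond point losses, site- or cell-specific
error rates.  Tests passing on these simulations therefore demonstrate
correctness of the machinery under the stated generative model, not
robustness to those real-data effects.

## Accuracy measures

Both measures look only at gain placements, so loss handling is neither
rewarded nor penalized.  An ordered pair (x, y) is ancestor–descendant
(AD) when x's gain node is a proper ancestor of y's; an unordered pair is
different-lineage (DL) when neither gain is an ancestor of the other and
they sit on distinct nodes.  Each measure is the balanced F1 of the truth
relation set against the inferred one.  Conventions: pairs gained at the
very same node (co-occurring on one edge), in either tree, fit neither
relation and are excluded from both universes; a mutation absent from the
inferred tree keeps its truth pairs in the recall denominator as
unpreserved; an empty denominator scores 1 when the opposite set is also
empty, else 0.

## Scale of the shipped checks

The exhaustive ILP cross-check enumerates every Dollo(1) tree on 3
mutations (all parent functions over gains plus each loss subset, reduced
to maximal reachable-state collections) against 4-cell instances; the
refinement checks run ten 100×30 instances with a 10 s solver budget; the
simulator statistics pool 100 replicates of the reference configuration.
These sizes keep the whole suite within a few minutes on one core while
exercising every stage at or above the reference study's dimensions.

## Known limitations

* `alpha` and `beta` are inputs, not estimated from data.
* The ILP grows as `n·m²`; beyond a few hundred cells × ~50 mutations,
  expect to rely on the timeout + refinement path rather than proofs of
  optimality.
* Tree-level conclusions inherit the non-identifiability of loss placement;
  compare matrices or pair relations, not topologies.
* The DOT parser used by `evaluate` reads the dialect this package writes
  (uncollapsed, attachment-free); it is not a general Graphviz parser.
* No doublet handling and no bulk/VAF integration.
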