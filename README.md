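# dollophy

Tumor phylogeny inference from single-cell DNA sequencing under the
**Dollo(k)** evolutionary model: each somatic mutation is acquired exactly
once and may be lost at most *k* times (Dollo(0) is the perfect phylogeny of
the infinite-sites assumption; Dollo(1) is the persistent phylogeny).
Allowing a small number of mutation losses matters for cancer data, where
large deletions can remove previously acquired mutations from a subclone.

The input is an incomplete binary cell × mutation matrix *I* with entries
present (1), absent (0) or missing (2/`?`), plus the sequencing error rates:
the false-negative rate α (allelic dropout) and false-positive rate β.
dollophy searches for the complete genotype matrix *F* that admits a
Dollo(k) phylogeny and maximizes the observation log-likelihood

```
max Σ_c Σ_m log P(I[c,m] | F[c,m])        P(1|1) = 1-α   P(0|1) = α
                                          P(1|0) = β     P(0|0) = 1-β
```

with missing entries contributing nothing. The search is exact in principle:
every mutation column is split into a gain column m⁺ and k loss columns
m₁⁻…m_k⁻, and *F* has a Dollo(k) phylogeny iff this *extended* matrix has a
completion with no conflicting column pair — no two columns exhibiting all
of the row configurations (0,1), (1,0) and (1,1).  That characterization
becomes a binary ILP: variables E(c,p) for the completed extended matrix,
F(c,m) = E(c,m⁺) − Σᵢ E(c,mᵢ⁻) linking genotypes to gains and losses, and
witness variables B(p,q,a,b) whose sum is capped to forbid conflicts, with
the (linear) log-likelihood of *F* as objective.  Because the ILP can be
stopped by a timeout with only an incumbent, the extracted tree is then
refined by randomized hill climbing over Subtree-Prune-and-Reattach moves,
contracting any loss node the move invalidates (which preserves the
Dollo(k) bound).

The package also ships the matching clonal-tree simulator (random subclone
tree, uniform mutation assignment, distinct-mutation deletion nodes, α/β
flip noise and γ missing-entry masking) and the two standard tree-accuracy
measures: the **ancestor–descendant** and **different-lineage** F-scores
over mutation pairs.

## Worked example

Simulate a small tumor, infer the tree, and score it against the truth:

```bash
dollophy simulate --subclones 5 --cells 40 --mutations 10 --deletions 2 \
    -a 0.05 -b 0.0001 -g 0.05 --seed 7 --outdir sim
dollophy infer -i sim/observed.txt -a 0.05 -b 0.0001 -k 1 --seed 7 \
    --ns 20 --mi 30 -o inferred.gv --out-matrix F.txt --report report.json
dollophy evaluate --truth sim/truth_tree.gv --inferred inferred.gv
```

which prints

```
wrote simulation bundle to sim
status=optimal ilp_ll=-8.767083 final_ll=-8.767083 losses=4
ad_f    dl_f
0.842105        0.615385
```

Reading the output: the solver proved optimality (`status=optimal`), so the
hill climb cannot improve the log-likelihood (−8.77) and keeps the ILP
tree, which realizes 4 mutation losses.  The accuracy scores against the
ground-truth tree are below 1 even at the likelihood optimum: once losses
are allowed, several distinct trees can explain the same genotype matrix
equally well, so the ancestral order of some mutation pairs is genuinely
not identifiable from 40 noisy cells.  `inferred.gv` is Graphviz DOT with
loss nodes drawn red; `report.json` records solver status, ILP and post-HC
log-likelihoods, the realized loss count, wall time and the full
configuration.

The same pipeline is available as a scikit-learn-style estimator:

```python
from dollophy import DolloPhylogeny
est = DolloPhylogeny(alpha=0.05, beta=1e-4, k=1, random_state=7).fit(X)
est.tree_, est.F_, est.log_likelihood_, est.n_losses_
```

where `X` is a cells × mutations array over {0, 1, 2} (or NaN for missing).

## Layout

- `src/dollophy/matrix.py` — 0/1/2 matrix dialect and container
- `src/dollophy/error_model.py` — observation likelihood and its linearization
- `src/dollophy/extended.py` — gain/loss column space and conflict tests
- `src/dollophy/ilp.py`, `solvers.py` — the ILP and MILP backends
- `src/dollophy/tree.py` — phylogeny structure, extraction, attachment, DOT
- `src/dollophy/hillclimb.py` — SPR neighborhood and hill climbing
- `src/dollophy/simulate.py` — clonal-tree simulator
- `src/dollophy/metrics.py` — AD / DL F-measures
- `src/dollophy/estimator.py`, `cli.py` — estimator front end and CLI

See `docs/methods.md` for the model, the numerical choices and the known
limitations.
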