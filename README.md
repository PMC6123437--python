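# netrsf — network-reweighted random survival forests

`netrsf` is for computational biologists who want to predict censored
survival outcomes from gene or lncRNA expression **and** walk away with a
compact, biologically grounded prognostic signature. Plain random
survival forests (RSF) predict well in-cohort but generalize poorly and
rank genes with no regard to biology; `netrsf` biases the forest toward
genes that matter in a gene-interaction network.

## The method

1. **Topological weights.** Univariate Cox regression gives each gene a
   P-value; the seed vector W₀ ∝ −log(Pᵢ) is propagated over the
   network's row-stochastic transition matrix **M** by a random walk with
   restart, W_{t+1} = (1 − r)MᵀW_t + rW₀ (r = 0.3, convergence at
   ‖ΔW‖₁ < 10⁻¹⁰). The fixed point W∞ scores each gene's topological
   importance: high degree, strong survival association, and
   well-connected neighbourhoods all raise it.
2. **Reweighted forest.** An RSF (ntree bootstrap trees, log-rank
   splitting, ≥ nodesize deaths per leaf, Nelson–Aalen leaf hazards)
   whose per-node candidate genes are sampled *proportionally to W∞*
   instead of uniformly. Risk = Σ over training event times of the
   tree-averaged cumulative hazard.
3. **Elimination.** Breiman–Cutler permutation importance, averaged over
   repeated forests per level, discards the lowest 10 % of genes per
   level down to two genes.
4. **Signature search.** From the 10-gene level, all 2¹⁰ − 1 = 1023 Cox
   PH combinations are fitted; the signature balancing held-out Harrell
   C-index against gene count is selected.

Evaluation: Harrell's C, mean-cutoff high/low stratification,
Kaplan–Meier curves, log-rank tests, and a permutation-null credibility
check (outcome-permuted training must score C ≈ 0.5). A synthetic-data
generator (scale-free or modular networks, module-correlated expression,
Cox-exponential survival with hub-placed signal and calibrated
censoring) makes every stage testable offline with known ground truth.

See `docs/methods.md` for assumptions, parameter semantics and numerical
conventions.

## Worked example

```python
import numpy as np
from netrsf import synthetic, datasets, forest, pipeline, cox
from netrsf.evaluation import concordance_index

# a synthetic cohort: 100 genes on a scale-free network, survival signal
# (beta = 1) on the 10 biggest hubs, 30% censoring
cfg = synthetic.SimulationConfig(n_genes=100, n_samples=400, n_signal=10,
                                 beta=1.0, censoring_rate=0.3, seed=1)
net, ds, truth = synthetic.simulate_dataset(cfg)
train, test = datasets.split(ds, 0.5, seed=3)

# topological weights from Cox-seeded network propagation
weights, cox_results = pipeline.topological_weights(train, net)

# the reweighted forest and its held-out concordance
f = forest.fit_forest(train, train.expression.feature_ids, weights,
                      forest.ForestConfig(ntree=100, seed=1))
risk = forest.predict_risk(f, test.expression)
c = concordance_index(risk, test.survival.time, test.survival.event)
print(f"held-out C-index: {c.c_index:.4f} over {c.usable_pairs} usable pairs")

# eliminate to the 10-gene level, then search all 1023 combinations
kept = cox.screen(cox_results, 0.05)
levels = pipeline.iterative_elimination(
    train, kept, weights, forest.ForestConfig(ntree=25, seed=1),
    [test], n_models=2)
ten = next(lr for lr in levels if lr.n_features == 10)
records = pipeline.exhaustive_search(list(ten.features), train, [test])
sig = pipeline.select_signature(records)
print(f"signature: {'+'.join(sig.features)}  test C = {sig.test_c[0]:.4f}")
print(f"signal genes recovered at 10-gene level: "
      f"{len(set(ten.features) & set(truth['signal_genes']))}/10")
```

Output:

```
held-out C-index: 0.8316 over 17683 usable pairs
signature: g00+g01+g03+g04+g05+g08+g12+g16+g25  test C = 0.9002
signal genes recovered at 10-gene level: 9/10
```

The forest concentrates its splits on the hub signal genes (high
topological weight *and* survival association), so the held-out C-index
sits far above chance and nine of the ten planted signal genes survive
to the 10-gene level; the exhaustive Cox search then squeezes further
performance out of that set (on this strongly-signalled cohort the
balance rule keeps nine genes — on weaker real-data signal it prunes
much harder).

The same workflow is available from the shell:

```bash
netrsf simulate --seed 1 --out fixtures/
netrsf weights --network fixtures/network_edges.tsv --cox-pvalues pvals.tsv --out w.tsv
netrsf fit --train expr.tsv --surv clinical.tsv --weights w.tsv --model-out forest.bin
netrsf predict --model forest.bin --expr test_expr.tsv --out risk.tsv
netrsf evaluate --risk risk.tsv --surv clinical.tsv --out report.json
netrsf run --config pipeline.json --out results/   # full pipeline
```

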