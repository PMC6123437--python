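# Methods

## The model

`netrsf` predicts censored survival outcomes from gene (or lncRNA)
expression and distills compact prognostic signatures, biasing every step
toward genes that are *topologically important* in a gene-interaction
network. The premise is biological: highly connected genes tend to have
coherent expression variation and a lower chance of correlating with
outcome by accident, so a model steered toward them should generalize
better across cohorts and yield signatures with clearer biological
meaning.

The pipeline has four stages.

### 1. Topological weights (random walk with restart)

Let **M** be the row-normalized adjacency matrix of the interaction
network and **W**₀ a seed distribution over its nodes. The walk iterates

    W_{t+1} = (1 − r) Mᵀ W_t + r W₀

until ‖W_{t+1} − W_t‖₁ < tol. The fixed point **W**∞ is the vector of
topological weights. Seeds are `−log(P_i)` of each gene's univariate Cox
Wald P-value, L1-normalized; genes without a P-value (unmeasured genes,
non-gene network nodes) seed at zero but still collect mass through their
neighbours.

Parameters: restart probability `r = 0.3` (the conventional propagation
setting; larger r keeps mass nearer the seeds), `tol = 1e-10`,
`max_iter = 10000`. The log base of the seed transform is irrelevant — it
cancels under L1 normalization. "Unit vector" is implemented as L1 (not
L2) normalization: with a row-stochastic **M**, every iterate is then a
probability distribution and mass conservation becomes a testable
invariant; the fixed point of the L2-normalized variant has no such
interpretation. Dangling nodes receive a self-loop before normalization
so that **M** stays row-stochastic. Iteration is plain power iteration —
the map contracts in L1 with ratio ≤ (1 − r), so acceleration is
unnecessary at these sizes; a direct linear solve of
(I − (1−r)Mᵀ)W = rW₀ is used as an independent oracle in tests, never in
the implementation.

### 2. The reweighted survival forest

An ensemble of `ntree` survival trees (default 1000), each grown on an
independent with-replacement bootstrap. At every node, `mtry` candidate
genes (default ⌊√p⌋) are drawn **without replacement with probability
proportional to their topological weight** — implemented as an
exponential race, which is distributionally identical to sequential
proportional draws. Zero-weight genes become drawable only after all
positive-weight genes are exhausted, so sparse seed vectors never make
`mtry` infeasible. With uniform weights the model is an ordinary random
survival forest; this reduction is verified against scikit-survival's
implementation.

Splitting maximizes the absolute standardized two-group log-rank
statistic |O − E|/√V over every candidate gene and every midpoint between
consecutive distinct in-node values (deterministic exhaustive scan, no
random cutpoints). A split is admissible only if **each child contains at
least `nodesize` deaths** (default 3); a node with fewer than 2·nodesize
deaths becomes a leaf. Enforcing the deaths constraint at the split (not
merely as a stopping rule) is what guarantees the audited invariant that
every leaf of every tree holds ≥ nodesize deaths. Ties on the statistic
resolve to the lowest feature index, then the smallest cutpoint —
reproducibility is preferred over any unstated alternative. Note that the
standardized statistic can legitimately peak at an unbalanced cutpoint
even when a "perfect" balanced separator exists; the exhaustive-scan
oracle tests cover this.

Each leaf carries the Nelson–Aalen cumulative hazard H(t) = Σ d_i/Y_i of
its bootstrap members (deaths processed before censorings at tied
timestamps). A sample's risk score is the sum over the training
event-time grid of its tree-averaged cumulative hazard, evaluated
right-continuously; higher is worse. Out-of-bag (OOB) error is
1 − Harrell's C of the OOB-ensemble risk.

Randomness: one master seed; per-tree generators are spawned from a
`SeedSequence` keyed by tree index, so increasing `ntree` never reshuffles
earlier trees, and a fixed seed reproduces the forest, its VIMP and its
predictions bit for bit.

### 3. Importance-based elimination

Variable importance is Breiman–Cutler permutation VIMP: for each tree and
each gene the tree actually splits on, the gene's out-of-bag values are
permuted within that tree's OOB set and the OOB samples re-dropped; VIMP
is the resulting increase in OOB error (positive = important). Genes
never used by any split have VIMP exactly zero. At each elimination
level, `n_models` forests differing only in seed are fitted on the fixed
training set; genes are ranked by their mean VIMP across those forests
and the lowest max(1, ⌊0.1·p⌋) are discarded (the max(·) guarantees
progress at small p, where ⌊0.1·p⌋ = 0), iterating down to two genes.
Every model's C-index on every test set is recorded per level, which is
what the weighted-vs-uniform Wilcoxon signed-rank comparison consumes.

### 4. Exhaustive signature search

From the 10-gene level, a Cox proportional-hazards model is fitted for
every nonempty gene subset (2¹⁰ − 1 = 1023 models; a hard cap of 20 genes
guards the 2^k growth). Fits use partial-likelihood maximization with the
Efron tie approximation and Wald P-values (lifelines defaults; the Newton
precision is tightened to 1e-11 so coefficients agree with an independent
implementation to ~1e-9). Singular (collinear) or non-convergent
combinations are flagged and retained, never silently dropped. A
signature's risk score is the plain linear predictor Σβᵢxᵢ.

Selection balances held-out C-index against signature size: among
combinations whose held-out C (mean over test sets) is within `epsilon`
(default 0.01) of the best, the smallest wins; ties go to the higher C,
then the lexicographically first combination. "Balancing accuracy against
signature size" is inherently a judgement call, so the rule is made
explicit and configurable rather than left to inspection.

### Evaluation

Harrell's C counts, over all usable pairs, the fraction where the
shorter-surviving patient has the higher predicted risk; a pair is usable
iff the smaller observed time carries an event, pairs with equal observed
times are usable only when exactly one is an event, and tied risks count
0.5. Patients are stratified high/low at the **training-cohort mean**
risk (a sample exactly at the cutoff goes low; the same cutoff is reused
for external cohorts). Strata are compared with Kaplan–Meier curves and
the two-group log-rank test; median survival is the smallest time with
S(t) ≤ 0.5, reported as not-reached otherwise.

### Credibility (permutation-null) check

Jointly permuting the training (time, event) pairs — preserving the
censoring marginal — refitting the weighted forest, and scoring the
untouched test cohort must give C ≈ 0.5. This is the main guard against
the selection machinery manufacturing signal from noise, and it is the
quantity `scripts/acceptance.py` recomputes.

## Co-expression networks

When no curated interaction network is available, one can be built from
expression: all-pairs Pearson correlation, two-sided Student P on n − 2
df, Benjamini–Hochberg adjustment over all p(p−1)/2 tests jointly, and a
hard threshold (default adjusted P < 1e-7). Thresholding the adjusted
value is the default (it controls the FDR of the edge set); `adjust=False`
switches to thresholding the raw P for workflows that prefer it. Edge correlations are
stored as metadata only — transition probabilities are uniform over
out-neighbours (unweighted adjacency).

## The synthetic-data generator

The generator provides ground truth for every stage:

* **Network** — preferential attachment (`scale_free`, attachment 2),
  giving the heavy-tailed hub structure the method's premise assumes, or
  a stochastic block model (`modular_blocks`, p_in = 0.25, p_out = 0.01).
* **Expression** — one standard-normal draw per sample with
  equicorrelation ρ (default 0.3) inside each of `n_modules` (default 5)
  equal gene blocks, unit marginal variance. For the block topology the
  expression modules coincide with the network blocks; for the scale-free
  topology they are independent consecutive blocks (correlation structure
  and topology are separate knobs).
* **Survival** — exponential event times with hazard
  λ·exp(β·Σ x_signal), λ = 0.1, β = 1 on the `n_signal` = 10
  highest-degree hubs by default (`signal_on="random"` probes the
  unfavourable regime). Exponential rather than Weibull baseline: the
  simplest generator satisfying proportional hazards. Independent
  exponential censoring is calibrated by bisection on its rate against
  the realized event times to hit the target censoring fraction
  (default 0.3, achieved within ±0.1).

What the generator does *not* emulate: microarray noise models, batch
effects, platform-specific probe structure, non-proportional hazards, or
informative censoring. Passing tests therefore demonstrate correctness of
the algorithms and the claimed qualitative behaviours (hub-signal
recovery, weighted-over-uniform advantage, chance-level nulls) under the
model's own assumptions — not clinical performance on real cohorts.

## Problem sizes used in the shipped checks

The automated checks run reduced-but-faithful configurations chosen as
realistic desk-scale experiments: permutation null and weighted-vs-uniform
comparisons on 100-gene, 200+200-sample hub cohorts (ntree = 100 and 25);
the reduction-to-RSF comparison on a censoring-free 10-gene, 150-sample
cohort (50 seeds; censoring-free so the deaths-per-leaf constraint
coincides exactly with the reference's samples-per-leaf constraint);
signal recovery on 300-gene, 300+300-sample cohorts with 20 hub signal
genes, 2 forests per elimination level at ntree = 20. Forest defaults
(ntree = 1000, nodesize = 3, mtry = ⌊√p⌋, r = 0.3, Cox screen at
P < 0.05) are the analysis-scale settings.

## Known limitations

* Tree growth is exact and deterministic but quadratic-ish in node size
  via the (samples × candidates × event-times) scan; it is tuned for
  cohorts of hundreds of samples and screened gene sets, not for
  p ≫ 10⁴ without prior screening.
* The split statistic uses float32 accumulation in the vectorized scan
  (float64 in the scalar reference); on adversarially near-tied splits
  the chosen cutpoint may differ from exact arithmetic.
* Proportional hazards is assumed throughout the Cox stages; the forest
  itself is distribution-free.
* `compare_methods` reports per-level Wilcoxon P-values without
  multiplicity adjustment; adjust downstream if many levels are scanned.
* Repeated random train/test partitioning is deliberately not a bespoke
  operation — script `split` + the pipeline for that.
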