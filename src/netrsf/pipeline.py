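"""Experiment orchestration: topological weighting, iterative VIMP-based
feature elimination, weighted-vs-uniform comparison, exhaustive Cox
combination search, signature selection, and the permutation-null
credibility check.

The elimination loop discards the lowest-ranked max(1, floor(0.1 * p))
features per level (ranked by mean permutation VIMP over the level's
repeated forests) until two features remain. Repeated models at a level
differ only in their random seed; the train/test partition stays fixed.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy import stats

from . import cox
from .datasets import Dataset
from .drw import WalkConfig, WeightVector, directed_random_walk, initial_weights
from .evaluation import concordance_index
from .forest import Forest, ForestConfig, fit_forest, permutation_vimp, predict_risk
from .network import InteractionNetwork, row_normalize

logger = logging.getLogger(__name__)

__all__ = [
    "LevelRecord",
    "SearchRecord",
    "SelectionRule",
    "topological_weights",
    "elimination_schedule",
    "iterative_elimination",
    "compare_methods",
    "exhaustive_search",
    "select_signature",
    "permutation_null",
    "apply_outcome_permutation",
    "feature_frequency",
]


@dataclass
class LevelRecord:
    """One elimination level: the surviving feature set and every repeated
    model's held-out C-index on every test set."""

    n_features: int
    features: tuple[str, ...]
    c_index: dict          # test-set index -> list of C over repeated models
    mean_vimp: dict        # feature -> mean VIMP across the level's models


@dataclass
class SearchRecord:
    features: tuple[str, ...]
    train_c: float | None
    test_c: tuple | None   # one C per test set
    flagged: bool = False

    def heldout_score(self) -> float:
        """Mean held-out C across test sets (selection score)."""
        return float(np.mean(self.test_c))


@dataclass
class SelectionRule:
    """Balance rule: among combinations within ``epsilon`` C-index of the
    best, prefer the fewest features."""

    epsilon: float = 0.01

    def __post_init__(self) -> None:
        if self.epsilon < 0:
            raise ValueError("epsilon must be nonnegative")


def topological_weights(
    train: Dataset,
    net: InteractionNetwork,
    features: list[str] | None = None,
    walk: WalkConfig | None = None,
    seed_mode: str = "cox",
) -> tuple[WeightVector, list[cox.UnivariateCoxResult]]:
    """Univariate Cox seeding + restart walk over the network.

    Returns the stationary weight vector over network nodes together with
    the univariate Cox results used for seeding (empty for
    ``seed_mode='uniform'``). Only genes present in both the network and
    the expression matrix are seeded; others start at 0 and acquire mass
    through the walk.
    """
    M = row_normalize(net)
    if seed_mode == "uniform":
        return directed_random_walk(M, WeightVector.uniform(net.node_ids), walk), []
    if seed_mode != "cox":
        raise ValueError(f"unknown seed_mode {seed_mode!r}")
    if features is None:
        in_net = set(net.node_ids)
        features = [f for f in train.expression.feature_ids if f in in_net]
    results = cox.univariate_cox(train, features)
    pvals = {r.feature: r.p for r in results}
    w0 = initial_weights(pvals, net)
    return directed_random_walk(M, w0, walk), results


def elimination_schedule(p0: int) -> list[int]:
    """Feature-set sizes per level: p -> p - max(1, floor(0.1 p)) down to 2."""
    if p0 < 3:
        raise ValueError("elimination needs at least 3 starting features")
    sizes = [p0]
    while sizes[-1] > 2:
        p = sizes[-1]
        sizes.append(p - max(1, math.floor(0.1 * p)))
    if sizes[-1] < 2:
        sizes[-1] = 2
    return sizes


def _level_seed(master: int, level: int, model: int) -> int:
    ss = np.random.SeedSequence((master, level, model))
    return int(ss.generate_state(1, dtype=np.uint32)[0] % (2**31))


def iterative_elimination(
    train: Dataset,
    initial_features: list[str],
    weights: WeightVector,
    cfg: ForestConfig,
    test_sets: list[Dataset],
    n_models: int = 100,
) -> list[LevelRecord]:
    """Iterative 10 % VIMP elimination down to two features.

    At each level ``n_models`` forests (distinct derived seeds) are fitted
    on the fixed training set; their mean VIMP ranks the features and every
    model's C-index on every test set is recorded.
    """
    current = list(initial_features)
    if len(current) < 3:
        raise ValueError("need at least 3 initial features")
    records: list[LevelRecord] = []
    for level, _size in enumerate(elimination_schedule(len(current))):
        p = len(current)
        vimp_sum = np.zeros(p)
        cs: dict[int, list[float]] = {i: [] for i in range(len(test_sets))}
        for m in range(n_models):
            cfg_m = replace(cfg, seed=_level_seed(cfg.seed, level, m))
            forest = fit_forest(train, current, weights.restrict(current), cfg_m)
            vt = permutation_vimp(forest, train, rng=np.random.default_rng(cfg_m.seed))
            vimp_sum += vt.vimp
            for i, ts in enumerate(test_sets):
                risk = predict_risk(forest, ts.expression)
                cs[i].append(
                    concordance_index(risk, ts.survival.time, ts.survival.event).c_index
                )
        mean_vimp = vimp_sum / n_models
        records.append(
            LevelRecord(p, tuple(current), cs, dict(zip(current, mean_vimp.tolist())))
        )
        if p <= 2:
            break
        k = max(1, math.floor(0.1 * p))
        # drop the k lowest-VIMP features; ties broken by feature id
        ranked = sorted(zip(mean_vimp, current), key=lambda kv: (kv[0], kv[1]))
        dropped = {f for _, f in ranked[:k]}
        current = [f for f in current if f not in dropped]
    return records


def compare_methods(
    levels_a: list[LevelRecord], levels_b: list[LevelRecord]
) -> pd.DataFrame:
    """Per-level paired comparison of two elimination runs.

    For every level and test set: median C-index of each run and the
    two-sided Wilcoxon signed-rank P on the paired per-model C-indices.
    All-zero difference vectors report P = 1.
    """
    if len(levels_a) != len(levels_b):
        raise ValueError("mismatched number of levels")
    rows = []
    for la, lb in zip(levels_a, levels_b):
        if la.n_features != lb.n_features or set(la.c_index) != set(lb.c_index):
            raise ValueError("mismatched level structure")
        for ts in sorted(la.c_index):
            a = np.asarray(la.c_index[ts], dtype=float)
            b = np.asarray(lb.c_index[ts], dtype=float)
            if a.shape != b.shape:
                raise ValueError("mismatched repeat counts")
            if np.allclose(a, b):
                p = 1.0
            else:
                p = float(stats.wilcoxon(a, b, alternative="two-sided").pvalue)
            rows.append(
                {
                    "level": la.n_features,
                    "test_set": ts,
                    "median_a": float(np.median(a)),
                    "median_b": float(np.median(b)),
                    "p": p,
                }
            )
    return pd.DataFrame(rows)


def exhaustive_search(
    genes: list[str], train: Dataset, tests: list[Dataset]
) -> list[SearchRecord]:
    """Cox PH models for every nonempty subset of ``genes`` (2^k - 1 fits).

    Singular or non-convergent combinations are flagged and retained so the
    record list always covers the full power set minus the empty set.
    """
    genes = list(genes)
    if not 1 <= len(genes) <= 20:
        raise ValueError("exhaustive search supports 1..20 genes (2^k growth)")
    records: list[SearchRecord] = []
    for k in range(1, len(genes) + 1):
        for combo in itertools.combinations(genes, k):
            try:
                model = cox.fit_signature(train, list(combo))
            except cox.SingularFitError:
                records.append(SearchRecord(combo, None, None, flagged=True))
                continue
            risk_tr = cox.signature_risk(model, train.expression)
            c_tr = concordance_index(
                risk_tr, train.survival.time, train.survival.event
            ).c_index
            c_tests = tuple(
                concordance_index(
                    cox.signature_risk(model, ts.expression),
                    ts.survival.time,
                    ts.survival.event,
                ).c_index
                for ts in tests
            )
            records.append(SearchRecord(combo, c_tr, c_tests))
    return records


def select_signature(
    records: list[SearchRecord], rule: SelectionRule | None = None
) -> SearchRecord:
    """Balance rule: within epsilon of the best held-out C, fewest features;
    ties by higher C, then lexicographic combination."""
    rule = rule or SelectionRule()
    ok = [r for r in records if not r.flagged]
    if not ok:
        raise ValueError("all search records are flagged")
    best = max(r.heldout_score() for r in ok)
    eligible = [r for r in ok if r.heldout_score() >= best - rule.epsilon]
    return min(eligible, key=lambda r: (len(r.features), -r.heldout_score(), r.features))


def apply_outcome_permutation(ds: Dataset, perm: np.ndarray) -> Dataset:
    """Jointly permute (time, event) pairs across samples."""
    surv = ds.survival
    permuted = type(surv)(
        list(surv.sample_ids), surv.time[perm], surv.event[perm],
        surv.covariates.iloc[perm].reset_index(drop=True) if surv.covariates is not None else None,
    )
    return Dataset(ds.expression, permuted)


def permutation_null(
    train: Dataset,
    tests: list[Dataset],
    weights: WeightVector,
    cfg: ForestConfig,
    n_perm: int = 20,
    features: list[str] | None = None,
) -> dict:
    """Null C-index distributions from outcome-permuted training data.

    Each replicate jointly permutes the training (time, event) pairs,
    refits the weighted forest and records the C-index on every test set.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    features = list(features) if features is not None else list(train.expression.feature_ids)
    out: dict[int, list[float]] = {i: [] for i in range(len(tests))}
    for r in range(n_perm):
        seed_r = _level_seed(cfg.seed, 10_000 + r, 0)
        rng = np.random.default_rng(seed_r)
        perm = rng.permutation(train.n_samples)
        ds_perm = apply_outcome_permutation(train, perm)
        forest = fit_forest(ds_perm, features, weights.restrict(features), replace(cfg, seed=seed_r))
        for i, ts in enumerate(tests):
            risk = predict_risk(forest, ts.expression)
            out[i].append(
                concordance_index(risk, ts.survival.time, ts.survival.event).c_index
            )
    return out


def feature_frequency(model_features: list, k: int | None = None) -> list[tuple[str, int]]:
    """Top-k feature frequency over repeated models.

    ``model_features`` is one iterable of selected features per model;
    features are ranked by how often they appear (ties lexicographic).
    """
    if not model_features:
        raise ValueError("at least one model required")
    counts: dict[str, int] = {}
    for feats in model_features:
        for f in feats:
            counts[f] = counts.get(f, 0) + 1
    ranked = sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))
    return ranked if k is None else ranked[:k]
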