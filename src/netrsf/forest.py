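"""The reweighted random survival forest (network-weighted RSF).

Each of ``ntree`` survival trees is grown on an independent with-replacement
bootstrap of the training samples. At every node, ``mtry`` candidate genes
are drawn *without replacement with probability proportional to their
topological weight* (sequential weighted sampling); the node is split at
the (gene, cutpoint) pair maximizing the two-group log-rank statistic,
subject to both children holding at least ``nodesize`` deaths. Leaves carry
the Nelson-Aalen cumulative hazard of their members. A sample's predicted
risk is the sum over the training event-time grid of its tree-averaged
cumulative hazard; higher means higher risk. With uniform weights the model
reduces to an ordinary random survival forest.

Variable importance is Breiman-Cutler permutation VIMP: the increase in
out-of-bag prediction error (1 - Harrell C of the OOB ensemble risk) when a
gene's out-of-bag values are permuted within each tree.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np

from .datasets import Dataset, ExpressionMatrix
from .drw import WeightVector
from .evaluation import concordance_index

__all__ = [
    "ForestConfig",
    "HazardFunction",
    "Tree",
    "Forest",
    "ImportanceTable",
    "weighted_feature_sample",
    "logrank_split_statistic",
    "best_split",
    "nelson_aalen",
    "grow_tree",
    "fit_forest",
    "predict_risk",
    "oob_risk",
    "oob_error",
    "permutation_vimp",
]


@dataclass
class ForestConfig:
    """ntree bootstrap trees; mtry candidate genes per split (default
    floor(sqrt(p))); nodesize = minimum deaths per leaf; one master seed."""

    ntree: int = 1000
    mtry: int | None = None
    nodesize: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.ntree < 1:
            raise ValueError("ntree must be positive")
        if self.nodesize < 1:
            raise ValueError("nodesize must be >= 1")
        if self.mtry is not None and self.mtry < 1:
            raise ValueError("mtry must be positive")

    def resolved_mtry(self, p: int) -> int:
        m = self.mtry if self.mtry is not None else max(1, math.floor(math.sqrt(p)))
        if m > p:
            raise ValueError(f"mtry={m} exceeds number of features p={p}")
        return m


@dataclass
class HazardFunction:
    """Nelson-Aalen cumulative hazard step function H(t) = sum d_i / Y_i."""

    times: np.ndarray  # increasing distinct event times
    chf: np.ndarray    # H at each event time (nondecreasing)

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.chf = np.asarray(self.chf, dtype=float)
        if self.times.shape != self.chf.shape:
            raise ValueError("time grid and hazard values differ in length")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("time grid must be strictly increasing")
        if np.any(np.diff(self.chf) < 0) or (self.chf < 0).any():
            raise ValueError("cumulative hazard must be nonnegative and nondecreasing")

    def evaluate(self, t) -> np.ndarray:
        """Right-continuous step evaluation: H(t) = 0 before the first event."""
        t = np.asarray(t, dtype=float)
        idx = np.searchsorted(self.times, t, side="right")
        padded = np.concatenate([[0.0], self.chf])
        return padded[idx]


def nelson_aalen(times, events) -> HazardFunction:
    """Nelson-Aalen estimator over a (possibly censored) sample."""
    times = np.asarray(times, dtype=float)
    events = np.asarray(events).astype(bool)
    if times.size == 0:
        raise ValueError("empty input to nelson_aalen")
    taus = np.unique(times[events])
    if taus.size == 0:
        return HazardFunction(np.empty(0), np.empty(0))
    # deaths are processed before censorings at tied timestamps
    at_risk = (times[:, None] >= taus[None, :]).sum(axis=0)
    deaths = ((times[:, None] == taus[None, :]) & events[:, None]).sum(axis=0)
    return HazardFunction(taus, np.cumsum(deaths / at_risk))


def weighted_feature_sample(weights, mtry: int, rng: np.random.Generator) -> np.ndarray:
    """mtry distinct feature indices, drawn sequentially without replacement
    with probability proportional to weight.

    Implemented as an exponential race (Efraimidis-Spirakis), which is
    distributionally identical to sequential proportional draws. Features
    with zero weight become sampleable only after every positive-weight
    feature is exhausted (uniform tail padding).
    """
    w = np.asarray(weights, dtype=float)
    p = w.size
    if mtry > p:
        raise ValueError(f"mtry={mtry} exceeds number of features {p}")
    if (w < 0).any():
        raise ValueError("weights must be nonnegative")
    pos = np.flatnonzero(w > 0)
    zero = np.flatnonzero(w == 0)
    keys = rng.exponential(size=pos.size) / w[pos]
    order = pos[np.argsort(keys, kind="stable")]
    if mtry <= order.size:
        return order[:mtry]
    pad = rng.permutation(zero)[: mtry - order.size]
    return np.concatenate([order, pad])


def logrank_split_statistic(times, events, left_mask) -> float:
    """Absolute standardized two-group log-rank statistic |O - E| / sqrt(V)."""
    times = np.asarray(times, dtype=float)
    events = np.asarray(events).astype(bool)
    left = np.asarray(left_mask).astype(bool)
    if left.all() or not left.any():
        raise ValueError("both groups must be nonempty")
    if not events.any():
        raise ValueError("at least one event required")
    taus = np.unique(times[events])
    num = 0.0
    var = 0.0
    for t in taus:
        at = times >= t
        Y = at.sum()
        YL = (at & left).sum()
        d = ((times == t) & events).sum()
        dL = ((times == t) & events & left).sum()
        num += dL - YL * d / Y
        if Y > 1:
            var += d * (YL / Y) * (1 - YL / Y) * (Y - d) / (Y - 1)
    if var <= 0:
        return 0.0
    return float(abs(num) / math.sqrt(var))


def _scan_splits(Xc: np.ndarray, t: np.ndarray, e: np.ndarray, nodesize: int):
    """Vectorized log-rank scan over every candidate column and cutpoint.

    Returns (stat matrix, threshold matrix, order) where rows index split
    positions (prefix sizes 1..n-1 in each column's sorted order) and
    invalid splits hold -inf. All candidate columns are scanned jointly.
    """
    n, k = Xc.shape
    taus = np.unique(t[e])
    order = np.argsort(Xc, axis=0, kind="stable")
    Xs = np.take_along_axis(Xc, order, axis=0)
    Ts = t[order]                           # (n, k)
    Es = e[order]
    # left-prefix at-risk counts per event time; deaths in a prefix need no
    # dense tensor: summed over event times they are just the prefix event
    # count (cumE below)
    A = Ts[:, :, None] >= taus[None, None, :]
    YL = A.cumsum(axis=0, dtype=np.float32)[:-1]     # (n-1, k, m)
    Y = (t[:, None] >= taus[None, :]).sum(axis=0).astype(float)
    d = np.array([(t[e] == tau).sum() for tau in taus], dtype=float)
    haz = (d / Y).astype(np.float32)
    cumE = np.cumsum(Es, axis=0)
    dtot = int(e.sum())
    OE = cumE[:-1] - np.einsum("skm,m->sk", YL, haz)
    cvar = np.where(Y > 1, d * (Y - d) / np.maximum(Y - 1, 1), 0.0)
    c1 = (cvar / Y).astype(np.float32)
    c2 = (cvar / Y**2).astype(np.float32)
    V = np.einsum("skm,m->sk", YL, c1) - np.einsum("skm,skm,m->sk", YL, YL, c2)
    with np.errstate(divide="ignore", invalid="ignore"):
        stat = np.where(V > 1e-12, np.abs(OE) / np.sqrt(np.maximum(V, 0.0)), 0.0)
    valid = (
        (Xs[:-1] < Xs[1:])
        & (cumE[:-1] >= nodesize)
        & (dtot - cumE[:-1] >= nodesize)
    )
    stat[~valid] = -np.inf
    thresh = 0.5 * (Xs[:-1] + Xs[1:])
    return stat, thresh, order


def best_split(
    X: np.ndarray,
    t: np.ndarray,
    e: np.ndarray,
    candidates: np.ndarray,
    nodesize: int,
):
    """Best (feature, cutpoint) over all candidates and midpoints, or None.

    Candidates are scanned in ascending feature-index order; ties on the
    log-rank statistic resolve to the lowest feature index, then the
    smallest cutpoint.
    """
    candidates = np.sort(np.asarray(candidates))
    if candidates.size == 0:
        raise ValueError("candidate set is empty")
    if not e.any():
        return None
    stat, thresh, order = _scan_splits(X[:, candidates], t, e.astype(bool), nodesize)
    col_best = stat.max(axis=0)
    j = int(np.argmax(col_best))
    if not np.isfinite(col_best[j]):
        return None
    i = int(np.argmax(stat[:, j]))
    feature = int(candidates[j])
    threshold = float(thresh[i, j])
    left_mask = X[:, feature] <= threshold
    return feature, threshold, left_mask, float(stat[i, j])


@dataclass
class Tree:
    """Flat-array survival tree.

    ``feature[i] == -1`` marks node i as a leaf; then ``leaf_chf_sum[i]`` is
    its Nelson-Aalen cumulative hazard summed over the training event-time
    grid and ``leaf_hazard[i]`` the full step function.
    """

    feature: np.ndarray
    threshold: np.ndarray
    left: np.ndarray
    right: np.ndarray
    leaf_chf_sum: np.ndarray
    leaf_hazard: list
    leaf_n_deaths: np.ndarray
    used_features: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=int))

    @property
    def n_leaves(self) -> int:
        return int((self.feature == -1).sum())

    def descend(self, X: np.ndarray, override_col: int | None = None,
                override_vals: np.ndarray | None = None) -> np.ndarray:
        """Vectorized descent; returns the leaf node index per row of X.

        ``override_col``/``override_vals`` substitute one column's values
        without copying X (used by permutation importance).
        """
        node = np.zeros(X.shape[0], dtype=int)
        while True:
            f = self.feature[node]
            active = f >= 0
            if not active.any():
                return node
            rows = np.flatnonzero(active)
            fa = f[rows]
            vals = X[rows, fa]
            if override_col is not None:
                ov = fa == override_col
                if ov.any():
                    vals = vals.copy()
                    vals[ov] = override_vals[rows[ov]]
            go_left = vals <= self.threshold[node[rows]]
            node[rows] = np.where(go_left, self.left[node[rows]], self.right[node[rows]])


class _TreeBuilder:
    def __init__(self, X, t, e, cfg: ForestConfig, weights, grid, rng):
        self.X, self.t, self.e = X, t, e
        self.cfg = cfg
        self.weights = weights
        self.grid = grid
        self.rng = rng
        self.mtry = cfg.resolved_mtry(X.shape[1])
        self.feature: list[int] = []
        self.threshold: list[float] = []
        self.left: list[int] = []
        self.right: list[int] = []
        self.leaf_sum: list[float] = []
        self.leaf_haz: list = []
        self.leaf_deaths: list[int] = []

    def _new_node(self) -> int:
        for lst, v in (
            (self.feature, -1),
            (self.threshold, np.nan),
            (self.left, -1),
            (self.right, -1),
            (self.leaf_sum, 0.0),
            (self.leaf_haz, None),
            (self.leaf_deaths, 0),
        ):
            lst.append(v)
        return len(self.feature) - 1

    def _make_leaf(self, node: int, idx: np.ndarray) -> None:
        hz = nelson_aalen(self.t[idx], self.e[idx])
        self.leaf_haz[node] = hz
        self.leaf_sum[node] = float(hz.evaluate(self.grid).sum())
        self.leaf_deaths[node] = int(self.e[idx].sum())

    def build(self, idx: np.ndarray) -> int:
        node = self._new_node()
        deaths = int(self.e[idx].sum())
        if deaths < 2 * self.cfg.nodesize:
            self._make_leaf(node, idx)
            return node
        cand = weighted_feature_sample(self.weights, self.mtry, self.rng)
        found = best_split(self.X[idx], self.t[idx], self.e[idx], cand, self.cfg.nodesize)
        if found is None:
            self._make_leaf(node, idx)
            return node
        feat, thr, left_mask, _stat = found
        self.feature[node] = feat
        self.threshold[node] = thr
        l = self.build(idx[left_mask])
        r = self.build(idx[~left_mask])
        self.left[node] = l
        self.right[node] = r
        return node

    def finish(self) -> Tree:
        feat = np.asarray(self.feature, dtype=int)
        return Tree(
            feature=feat,
            threshold=np.asarray(self.threshold, dtype=float),
            left=np.asarray(self.left, dtype=int),
            right=np.asarray(self.right, dtype=int),
            leaf_chf_sum=np.asarray(self.leaf_sum, dtype=float),
            leaf_hazard=self.leaf_haz,
            leaf_n_deaths=np.asarray(self.leaf_deaths, dtype=int),
            used_features=np.unique(feat[feat >= 0]),
        )


def grow_tree(
    X: np.ndarray,
    times: np.ndarray,
    events: np.ndarray,
    cfg: ForestConfig,
    weights: np.ndarray,
    rng: np.random.Generator,
    grid: np.ndarray | None = None,
) -> Tree:
    """Grow one survival tree on the given (bootstrap) sample rows."""
    e = np.asarray(events).astype(bool)
    if int(e.sum()) < cfg.nodesize:
        raise ValueError("bootstrap sample holds fewer deaths than nodesize")
    if grid is None:
        grid = np.unique(np.asarray(times, dtype=float)[e])
    builder = _TreeBuilder(X, np.asarray(times, dtype=float), e, cfg, weights, grid, rng)
    builder.build(np.arange(X.shape[0]))
    return builder.finish()


@dataclass
class Forest:
    """The fitted ensemble plus everything needed for OOB evaluation."""

    trees: list
    event_time_grid: np.ndarray
    feature_ids: list[str]
    weights: np.ndarray
    config: ForestConfig
    inbag: list          # per tree: bootstrap row indices into the training set
    oob: np.ndarray      # (ntree, n_train) bool
    n_train: int

    FORMAT_VERSION = 1   # pickle payloads carry this for forward compatibility

    @property
    def ntree(self) -> int:
        return len(self.trees)


def _tree_rngs(seed: int, ntree: int) -> list[np.random.Generator]:
    # children are a pure function of (seed, tree index): growing ntree
    # later never reshuffles earlier trees
    children = np.random.SeedSequence(seed).spawn(ntree)
    return [np.random.default_rng(c) for c in children]


def fit_forest(
    ds: Dataset,
    features: list[str],
    weights: WeightVector | np.ndarray,
    cfg: ForestConfig,
) -> Forest:
    """Fit the weighted survival forest on a training dataset."""
    features = list(features)
    X = ds.expression.matrix_for(features)
    t = ds.survival.time
    e = ds.survival.event.astype(bool)
    if not e.any():
        raise ValueError("training data contains zero events")
    if isinstance(weights, WeightVector):
        w = weights.restrict(features)
    else:
        w = np.asarray(weights, dtype=float)
        if w.shape != (len(features),):
            raise ValueError("weight array length does not match features")
    if w.sum() <= 0:
        warnings.warn("all feature weights are zero; falling back to uniform sampling")
        w = np.ones(len(features))
    cfg.resolved_mtry(len(features))  # validate early
    n = X.shape[0]
    grid = np.unique(t[e])
    trees, inbag_list = [], []
    oob = np.zeros((cfg.ntree, n), dtype=bool)
    for b, rng in enumerate(_tree_rngs(cfg.seed, cfg.ntree)):
        while True:
            inbag = rng.integers(0, n, size=n)
            if e[inbag].sum() >= cfg.nodesize:
                break
        tree = grow_tree(X[inbag], t[inbag], e[inbag], cfg, w, rng, grid=grid)
        trees.append(tree)
        inbag_list.append(inbag)
        mask = np.ones(n, dtype=bool)
        mask[np.unique(inbag)] = False
        oob[b] = mask
    return Forest(trees, grid, features, w, cfg, inbag_list, oob, n)


def _leaf_sums(forest: Forest, X: np.ndarray) -> np.ndarray:
    """(ntree, n) matrix of per-tree leaf CHF sums for each sample."""
    out = np.empty((forest.ntree, X.shape[0]))
    for b, tree in enumerate(forest.trees):
        out[b] = tree.leaf_chf_sum[tree.descend(X)]
    return out


def predict_risk(forest: Forest, samples: ExpressionMatrix | np.ndarray) -> np.ndarray:
    """Ensemble risk score: tree-averaged CHF summed over the event grid."""
    if isinstance(samples, ExpressionMatrix):
        X = samples.matrix_for(forest.feature_ids)
    else:
        X = np.asarray(samples, dtype=float)
        if X.shape[1] != len(forest.feature_ids):
            raise ValueError("sample matrix width does not match model features")
    return _leaf_sums(forest, X).mean(axis=0)


def oob_risk(forest: Forest, ds: Dataset) -> np.ndarray:
    """Out-of-bag ensemble risk; NaN for samples in-bag in every tree."""
    X = ds.expression.matrix_for(forest.feature_ids)
    L = _leaf_sums(forest, X)
    cnt = forest.oob.sum(axis=0)
    with np.errstate(invalid="ignore"):
        risk = np.where(cnt > 0, (L * forest.oob).sum(axis=0) / np.maximum(cnt, 1), np.nan)
    return risk


def oob_error(forest: Forest, ds: Dataset) -> float:
    """1 - Harrell C-index of OOB ensemble risk against observed survival."""
    risk = oob_risk(forest, ds)
    covered = ~np.isnan(risk)
    if not covered.any():
        raise ValueError("no sample is out-of-bag in any tree")
    if not covered.all():
        warnings.warn(f"dropping {int((~covered).sum())} samples with no OOB coverage")
    c = concordance_index(risk[covered], ds.survival.time[covered], ds.survival.event[covered])
    return 1.0 - c.c_index


@dataclass
class ImportanceTable:
    """Per-feature Breiman-Cutler permutation VIMP (positive = important)."""

    features: list[str]
    vimp: np.ndarray

    def as_dict(self) -> dict:
        return dict(zip(self.features, self.vimp.tolist()))

    def ranked(self) -> list[tuple[str, float]]:
        return sorted(zip(self.features, self.vimp), key=lambda kv: (-kv[1], kv[0]))


def permutation_vimp(forest: Forest, ds: Dataset, rng: np.random.Generator | int = 0) -> ImportanceTable:
    """Breiman-Cutler VIMP: per-tree OOB permutation of each used feature.

    Features never chosen by any split have VIMP exactly 0 (their
    permutation cannot change any descent path).
    """
    if isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(rng)
    X = ds.expression.matrix_for(forest.feature_ids)
    t, e = ds.survival.time, ds.survival.event
    L = _leaf_sums(forest, X)
    cnt = forest.oob.sum(axis=0).astype(float)
    covered = cnt > 0
    base_sum = (L * forest.oob).sum(axis=0)
    base_risk = base_sum[covered] / cnt[covered]
    base_err = 1.0 - concordance_index(base_risk, t[covered], e[covered]).c_index
    p = len(forest.feature_ids)
    delta = np.zeros((p, forest.n_train))
    touched = np.zeros(p, dtype=bool)
    for b, tree in enumerate(forest.trees):
        oob_idx = np.flatnonzero(forest.oob[b])
        if oob_idx.size == 0:
            continue
        Xo = X[oob_idx]
        for f in tree.used_features:
            perm_vals = Xo[rng.permutation(oob_idx.size), f]
            leaves = tree.descend(Xo, override_col=int(f), override_vals=perm_vals)
            delta[f, oob_idx] += tree.leaf_chf_sum[leaves] - L[b, oob_idx]
            touched[f] = True
    vimp = np.zeros(p)
    for f in np.flatnonzero(touched):
        risk_f = (base_sum[covered] + delta[f, covered]) / cnt[covered]
        err_f = 1.0 - concordance_index(risk_f, t[covered], e[covered]).c_index
        vimp[f] = err_f - base_err
    return ImportanceTable(list(forest.feature_ids), vimp)
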