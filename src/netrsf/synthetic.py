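"""Synthetic networks, expression and survival data with known ground truth.

The generator emulates the statistical structure the method assumes:
(a) a sparse interaction network with hubs (preferential attachment) or
dense modular blocks; (b) an expression matrix with correlated gene
modules (equicorrelated multivariate normal, unit marginal variance);
(c) survival times from a Cox-exponential model whose linear predictor
runs over designated signal genes, with independent exponential
right-censoring calibrated by bisection to a target censoring rate.

By default the signal genes are the highest-degree hubs, realizing the
premise that topologically important genes carry survival signal;
``signal_on="random"`` places it on random genes to probe the unfavorable
regime.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

from .datasets import Dataset, ExpressionMatrix, SurvivalTable
from .network import InteractionNetwork

__all__ = [
    "SimulationConfig",
    "simulate_network",
    "simulate_expression",
    "simulate_survival",
    "simulate_dataset",
    "make_fixture",
]


@dataclass
class SimulationConfig:
    """Knobs of the generator; defaults give a hub-signal cohort.

    n_genes/n_samples set the matrix size; ``topology`` chooses between a
    preferential-attachment graph ("scale_free") and a block model
    ("modular_blocks"). ``n_signal`` genes (hubs by default) each receive
    Cox coefficient ``beta``. ``baseline_hazard`` is the exponential event
    rate at linear predictor 0 (arbitrary time units); ``censoring_rate``
    is the target fraction of censored samples. ``rho`` is the shared
    within-module expression correlation over ``n_modules`` equal blocks.
    """

    n_genes: int = 100
    n_samples: int = 200
    topology: str = "scale_free"
    n_signal: int = 10
    beta: float = 1.0
    baseline_hazard: float = 0.1
    censoring_rate: float = 0.3
    rho: float = 0.3
    n_modules: int = 5
    n_blocks: int = 4
    p_in: float = 0.25
    p_out: float = 0.01
    attachment: int = 2
    signal_on: str = "hubs"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genes < 10:
            raise ValueError("need at least 10 genes")
        if self.topology not in ("scale_free", "modular_blocks"):
            raise ValueError(f"unknown topology {self.topology!r}")
        if not 0.0 <= self.rho < 1.0:
            raise ValueError("rho must lie in [0, 1) for a positive-definite structure")
        if not 0.0 < self.censoring_rate < 1.0:
            raise ValueError("censoring_rate must lie in (0, 1)")
        if self.signal_on not in ("hubs", "random"):
            raise ValueError("signal_on must be 'hubs' or 'random'")
        if self.n_signal > self.n_genes:
            raise ValueError("more signal genes than genes")

    def gene_ids(self) -> list[str]:
        width = len(str(self.n_genes - 1))
        return [f"g{i:0{width}d}" for i in range(self.n_genes)]

    def module_map(self) -> dict[str, int]:
        """Equal consecutive modules used for the expression correlation."""
        genes = self.gene_ids()
        size = max(1, self.n_genes // self.n_modules)
        return {g: min(i // size, self.n_modules - 1) for i, g in enumerate(genes)}


def simulate_network(cfg: SimulationConfig) -> InteractionNetwork:
    """Scale-free (preferential attachment) or modular block network."""
    genes = cfg.gene_ids()
    if cfg.topology == "scale_free":
        g = nx.barabasi_albert_graph(cfg.n_genes, cfg.attachment, seed=cfg.seed)
    else:
        sizes = [cfg.n_genes // cfg.n_blocks] * cfg.n_blocks
        sizes[-1] += cfg.n_genes - sum(sizes)
        probs = [[cfg.p_in if i == j else cfg.p_out for j in range(cfg.n_blocks)]
                 for i in range(cfg.n_blocks)]
        g = nx.stochastic_block_model(sizes, probs, seed=cfg.seed)
    edges = [(genes[u], genes[v]) for u, v in sorted(g.edges())]
    return InteractionNetwork.from_edges(edges, directed=False, nodes=genes)


def signal_genes(cfg: SimulationConfig, net: InteractionNetwork) -> list[str]:
    """The designated signal genes: top-degree hubs (default) or random."""
    if cfg.signal_on == "hubs":
        deg = dict(net.graph.out_degree())
        ranked = sorted(net.node_ids, key=lambda n: (-deg.get(n, 0), n))
        return sorted(ranked[: cfg.n_signal])
    rng = np.random.default_rng(np.random.SeedSequence((cfg.seed, 7)))
    return sorted(rng.choice(cfg.gene_ids(), size=cfg.n_signal, replace=False).tolist())


def simulate_expression(
    cfg: SimulationConfig, rng: np.random.Generator | None = None
) -> ExpressionMatrix:
    """Module-equicorrelated standard-normal expression (genes x samples)."""
    rng = rng or np.random.default_rng(np.random.SeedSequence((cfg.seed, 1)))
    genes = cfg.gene_ids()
    modules = cfg.module_map()
    mod_idx = np.array([modules[g] for g in genes])
    z_mod = rng.standard_normal((cfg.n_modules, cfg.n_samples))
    eps = rng.standard_normal((cfg.n_genes, cfg.n_samples))
    vals = np.sqrt(cfg.rho) * z_mod[mod_idx] + np.sqrt(1.0 - cfg.rho) * eps
    width = len(str(cfg.n_samples - 1))
    samples = [f"s{i:0{width}d}" for i in range(cfg.n_samples)]
    return ExpressionMatrix(genes, samples, vals)


def _calibrate_censor_rate(event_times: np.ndarray, u_cens: np.ndarray, target: float) -> float:
    """Bisection on the exponential censoring rate lambda_c.

    The censoring fraction mean(-log(u)/lc < T) is monotone increasing in
    lc, so plain bisection on log-rate converges.
    """
    def frac(lc: float) -> float:
        return float(np.mean(-np.log(u_cens) / lc < event_times))

    lo, hi = 1e-12, 1e12
    for _ in range(200):
        mid = np.sqrt(lo * hi)
        if frac(mid) < target:
            lo = mid
        else:
            hi = mid
    return np.sqrt(lo * hi)


def simulate_survival(
    expr: ExpressionMatrix,
    cfg: SimulationConfig,
    signal: list[str],
    rng: np.random.Generator | None = None,
) -> SurvivalTable:
    """Cox-exponential survival over the signal genes, right-censored."""
    missing = [g for g in signal if g not in expr.feature_ids]
    if missing:
        raise ValueError(f"signal genes absent from expression: {missing}")
    rng = rng or np.random.default_rng(np.random.SeedSequence((cfg.seed, 2)))
    Xs = expr.matrix_for(signal)
    lp = cfg.beta * Xs.sum(axis=1)
    u_event = rng.random(expr.n_samples)
    event_time = -np.log(u_event) / (cfg.baseline_hazard * np.exp(lp))
    u_cens = rng.random(expr.n_samples)
    lc = _calibrate_censor_rate(event_time, u_cens, cfg.censoring_rate)
    cens_time = -np.log(u_cens) / lc
    observed = np.minimum(event_time, cens_time)
    event = (event_time <= cens_time).astype(int)
    observed = np.maximum(observed, np.finfo(float).tiny)
    return SurvivalTable(list(expr.sample_ids), observed, event)


def simulate_dataset(cfg: SimulationConfig) -> tuple[InteractionNetwork, Dataset, dict]:
    """One cohort: network, aligned dataset and the ground-truth record."""
    net = simulate_network(cfg)
    sig = signal_genes(cfg, net)
    expr = simulate_expression(cfg)
    surv = simulate_survival(expr, cfg, sig)
    truth = {
        "signal_genes": sig,
        "beta": {g: cfg.beta for g in sig},
        "module_map": cfg.module_map(),
        "censoring_rate_target": cfg.censoring_rate,
        "seed": cfg.seed,
    }
    return net, Dataset(expr, surv), truth


def make_fixture(cfg: SimulationConfig, out_dir: str) -> dict:
    """Write expression/survival/network TSVs plus a ground-truth JSON.

    Deterministic given ``cfg.seed``; returns the file paths.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    net, ds, truth = simulate_dataset(cfg)
    paths = {
        "expression": out / "expression.tsv",
        "survival": out / "survival.tsv",
        "network": out / "network_edges.tsv",
        "truth": out / "truth.json",
    }
    df = ds.expression.to_frame()
    df.index.name = "feature_id"
    df.to_csv(paths["expression"], sep="\t", float_format="%.10g")
    pd.DataFrame(
        {
            "sample_id": ds.survival.sample_ids,
            "time": ds.survival.time,
            "event": ds.survival.event,
        }
    ).to_csv(paths["survival"], sep="\t", index=False, float_format="%.10g")
    net.to_edge_list(str(paths["network"]))
    with open(paths["truth"], "w") as fh:
        json.dump(truth, fh, indent=1, sort_keys=True)
    return {k: str(v) for k, v in paths.items()}
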