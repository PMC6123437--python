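"""Topological gene weights from a random walk with restart.

The walk iterates W_{t+1} = (1-r) M^T W_t + r W_0 on the row-stochastic
transition matrix M of the interaction network, restarting with probability
r at the seed distribution W_0. W_0 holds -log(P_i) of each gene's
univariate Cox P-value (L1-normalized); genes without a P-value seed at 0
but still receive mass through the network. The stationary distribution
W_inf is the vector of topological weights.

With L1-normalized seeds and a row-stochastic M every iterate is itself a
probability distribution, which is why "unit vector" is interpreted as L1
normalization throughout (the log base of -log(P) cancels under it).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .network import InteractionNetwork, TransitionMatrix

logger = logging.getLogger(__name__)

__all__ = ["WalkConfig", "WeightVector", "initial_weights", "directed_random_walk", "rank_by_weight"]


@dataclass
class WalkConfig:
    """Restart probability, L1 convergence threshold and iteration cap."""

    r: float = 0.3
    tol: float = 1e-10
    max_iter: int = 10000

    def __post_init__(self) -> None:
        if not 0.0 < self.r <= 1.0:
            raise ValueError("restart probability r must be in (0, 1]")
        if self.tol <= 0 or self.max_iter < 1:
            raise ValueError("tol must be positive and max_iter >= 1")


@dataclass
class WeightVector:
    """Nonnegative, L1-normalized weights over an ordered node list."""

    node_order: list[str]
    w: np.ndarray
    iterations: int | None = field(default=None, compare=False)

    def __post_init__(self) -> None:
        self.w = np.asarray(self.w, dtype=float)
        if self.w.shape != (len(self.node_order),):
            raise ValueError("weight length does not match node order")
        if (self.w < 0).any():
            raise ValueError("weights must be nonnegative")
        if abs(self.w.sum() - 1.0) > 1e-9:
            raise ValueError("weights must sum to 1 (L1-normalized)")

    @classmethod
    def uniform(cls, nodes: list[str]) -> "WeightVector":
        n = len(nodes)
        return cls(list(nodes), np.full(n, 1.0 / n))

    def restrict(self, features: list[str], missing: str = "error") -> np.ndarray:
        """Raw (un-renormalized) weights for the given feature order.

        ``missing='zero'`` assigns weight 0 to features absent from the
        vector; the default raises.
        """
        idx = {n: i for i, n in enumerate(self.node_order)}
        out = np.empty(len(features))
        for j, f in enumerate(features):
            if f in idx:
                out[j] = self.w[idx[f]]
            elif missing == "zero":
                out[j] = 0.0
            else:
                raise KeyError(f"feature {f!r} has no weight")
        return out


def initial_weights(pvalues: dict, net: InteractionNetwork) -> WeightVector:
    """Seed distribution W_0: -log(P_i) per seeded node, L1-normalized.

    Nodes of the network without a P-value get seed weight 0. P-values of
    exactly 0 are clamped to the smallest positive float (logged).
    """
    order = net.node_ids
    w = np.zeros(len(order))
    tiny = np.finfo(float).tiny
    n_clamped = 0
    for i, node in enumerate(order):
        if node not in pvalues:
            continue
        p = float(pvalues[node])
        if p < 0 or p > 1:
            raise ValueError(f"P-value for {node!r} outside [0, 1]: {p}")
        if p == 0.0:
            p = tiny
            n_clamped += 1
        w[i] = -np.log(p)
    if n_clamped:
        logger.warning("clamped %d zero P-values to %.3g", n_clamped, tiny)
    s = w.sum()
    if s <= 0:
        raise ValueError("no seed signal: all initial weights are zero")
    return WeightVector(order, w / s)


def directed_random_walk(
    M: TransitionMatrix, w0: WeightVector, cfg: WalkConfig | None = None
) -> WeightVector:
    """Iterate the restart walk to its stationary distribution W_inf.

    Plain power iteration; stops when the L1 change between successive
    iterates drops below ``cfg.tol``. The returned vector carries the
    iteration count in its ``iterations`` field.
    """
    cfg = cfg or WalkConfig()
    if w0.node_order != M.node_order:
        raise ValueError("weight vector and transition matrix node orders differ")
    MT = M.M.T
    w = w0.w.copy()
    for it in range(1, cfg.max_iter + 1):
        w_next = (1.0 - cfg.r) * (MT @ w) + cfg.r * w0.w
        delta = np.abs(w_next - w).sum()
        w = w_next
        if delta < cfg.tol:
            # guard against accumulated floating drift
            return WeightVector(list(M.node_order), w / w.sum(), iterations=it)
    raise RuntimeError(f"random walk did not converge within {cfg.max_iter} iterations")


def rank_by_weight(w: WeightVector) -> list[str]:
    """Nodes in nonincreasing weight order; ties broken lexicographically."""
    return [n for n, _ in sorted(zip(w.node_order, w.w), key=lambda kv: (-kv[1], kv[0]))]
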