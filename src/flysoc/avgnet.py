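"""Averaging node-unaligned networks by graph matching.

Networks from different experimental repeats have no node correspondence
(each repeat uses a new group of flies), so the naive element-wise mean
of their adjacency matrices is meaningless. Two networks W1, W2 are
aligned by the permutation P minimizing the Frobenius norm
||W1 - P W2 P^T||; since exact minimization is an NP-hard quadratic
assignment problem, the graduated assignment algorithm is used: a
doubly-stochastic relaxation updated by softassign (exponentiated
compatibility gradient followed by Sinkhorn row/column balancing) with
the inverse temperature annealed geometrically, discretized at the end
by a maximum-weight bipartite matching.

The average of k networks is the incremental running mean: M starts at
W1 and each subsequent W_i is aligned to the current M before being
absorbed with weight 1/i.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import linear_sum_assignment

logger = logging.getLogger(__name__)

__all__ = [
    "frobenius_objective",
    "match_graphs",
    "average_networks",
    "AverageNetwork",
    "GraduatedAssignmentConfig",
]


def _check_permutation(p: np.ndarray) -> None:
    p = np.asarray(p)
    n = p.shape[0]
    if p.shape != (n, n) or not np.array_equal(p, p.astype(bool).astype(p.dtype)):
        raise ValueError("P must be a square 0/1 matrix")
    if not (np.all(p.sum(axis=0) == 1) and np.all(p.sum(axis=1) == 1)):
        raise ValueError("P must have exactly one 1 per row and column")


def frobenius_objective(w1: np.ndarray, w2: np.ndarray, p: np.ndarray) -> float:
    """||W1 - P W2 P^T||_F for a permutation matrix P."""
    w1, w2, p = (np.asarray(m, dtype=float) for m in (w1, w2, p))
    if w1.shape != w2.shape or w1.shape[0] != w1.shape[1]:
        raise ValueError("W1 and W2 must be square and of equal size")
    _check_permutation(p)
    return float(np.linalg.norm(w1 - p @ w2 @ p.T))


@dataclass(frozen=True)
class GraduatedAssignmentConfig:
    beta0: float = 0.5
    rate: float = 1.075
    beta_max: float = 200.0
    sinkhorn_iters: int = 30
    sinkhorn_tol: float = 1e-6
    inner_iters: int = 10      # softassign repeats per temperature
    inner_tol: float = 1e-5
    refine_kicks: int = 60     # iterated-local-search restarts after projection


def match_graphs(
    w1: np.ndarray,
    w2: np.ndarray,
    config: GraduatedAssignmentConfig | None = None,
) -> np.ndarray:
    """Approximate argmin over permutations of ||W1 - P W2 P^T||_F.

    Graduated assignment: the doubly-stochastic iterate M is repeatedly
    replaced by softassign(exp(beta * Q)) where Q = W1 M W2^T + W1^T M W2
    is the gradient of the matching score <W1, P W2 P^T>, with beta
    annealed from ``beta0`` by ``rate`` up to ``beta_max``; the final M
    is projected to the nearest permutation by maximum-weight bipartite
    matching. The identity permutation is returned instead whenever it
    scores at least as well (the result never degrades the objective
    relative to no matching).
    """
    cfg = config or GraduatedAssignmentConfig()
    w1 = np.asarray(w1, dtype=float)
    w2 = np.asarray(w2, dtype=float)
    if w1.shape != w2.shape or w1.ndim != 2 or w1.shape[0] != w1.shape[1]:
        raise ValueError("W1 and W2 must be square and of equal size")
    n = w1.shape[0]
    if n == 1:
        return np.eye(1)

    m = np.full((n, n), 1.0 / n)
    beta = cfg.beta0
    converged = True
    while beta <= cfg.beta_max:
        # softassign to (near) fixed point at this temperature
        for _ in range(cfg.inner_iters):
            m_prev = m
            q = w1 @ m @ w2.T + w1.T @ m @ w2
            m, converged = _softassign(q, beta, cfg)
            if np.abs(m - m_prev).max() < cfg.inner_tol:
                break
        beta *= cfg.rate
    if not converged:
        logger.warning(
            "Sinkhorn not fully balanced at final beta; projecting current state"
        )

    _, cols = linear_sum_assignment(-m)
    cols, _ = _two_opt(w1, w2, cols)
    if cfg.refine_kicks > 0:
        cols = _iterated_local_search(w1, w2, cols, cfg.refine_kicks)
    p = np.zeros((n, n))
    p[np.arange(n), cols] = 1.0
    if frobenius_objective(w1, w2, p) > frobenius_objective(w1, w2, np.eye(n)):
        return np.eye(n)
    return p


def _softassign(q, beta, cfg):
    """exp(beta * Q) row-shifted for overflow safety, then Sinkhorn."""
    m = np.exp(beta * (q - q.max(axis=1, keepdims=True)))
    m = np.maximum(m, 1e-300)
    for _ in range(cfg.sinkhorn_iters):
        m = m / m.sum(axis=1, keepdims=True)
        m = m / m.sum(axis=0, keepdims=True)
        if np.abs(m.sum(axis=1) - 1.0).max() < cfg.sinkhorn_tol:
            return m, True
    return m, False


def _objective_cols(w1, w2, cols):
    return float(np.linalg.norm(w1 - w2[np.ix_(cols, cols)]))


def _two_opt(w1: np.ndarray, w2: np.ndarray, cols: np.ndarray):
    """Pairwise-swap hill climbing on the discretized permutation.

    The permutation maps row r to column cols[r]; the conjugated matrix
    is W2[cols][:, cols]. Swaps are accepted while they reduce the
    Frobenius objective (bounded number of passes)."""
    cols = cols.copy()
    n = len(cols)
    current = _objective_cols(w1, w2, cols)
    for _ in range(40):  # passes; terminates earlier at a local optimum
        improved = False
        for i in range(n - 1):
            for j in range(i + 1, n):
                cols[i], cols[j] = cols[j], cols[i]
                cand = _objective_cols(w1, w2, cols)
                if cand < current - 1e-12:
                    current = cand
                    improved = True
                else:
                    cols[i], cols[j] = cols[j], cols[i]
        if not improved:
            break
    return cols, current


def _iterated_local_search(w1, w2, cols, kicks):
    """Deterministic perturb-and-descend around the annealed solution:
    a random 3-cycle kick followed by 2-opt descent, keeping the best.
    The kick stream is internally seeded, so results are reproducible."""
    n = len(cols)
    best, best_obj = cols.copy(), _objective_cols(w1, w2, cols)
    rng = np.random.default_rng(0xA5F1)
    for _ in range(kicks):
        cand = best.copy()
        idx = rng.choice(n, size=min(3, n), replace=False)
        cand[idx] = cand[np.roll(idx, 1)]
        cand, obj = _two_opt(w1, w2, cand)
        if obj < best_obj - 1e-12:
            best, best_obj = cand, obj
    return best


@dataclass
class AverageNetwork:
    """Running mean of permutation-aligned matrices (Algorithm state)."""

    matrix: np.ndarray
    k: int
    permutations: list[np.ndarray] = field(default_factory=list)
    order: list[int] = field(default_factory=list)

    def recompute_mean(self, nets: list[np.ndarray]) -> np.ndarray:
        """Batch mean (1/k) sum_i P_i W_i P_i^T from the stored
        permutations — must equal ``matrix`` (associativity check)."""
        acc = np.zeros_like(self.matrix)
        for idx, p in zip(self.order, self.permutations):
            acc += p @ np.asarray(nets[idx], dtype=float) @ p.T
        return acc / self.k


def average_networks(
    nets: list[np.ndarray],
    config: GraduatedAssignmentConfig | None = None,
    anchor: str = "first",
) -> AverageNetwork:
    """Incremental average of k node-unaligned networks.

    M is initialized to the anchor network; for each further W_i the
    permutation R = match_graphs(M, W_i) aligns W_i to the current mean,
    W_i° = R W_i R^T, and M <- ((i-1)/i) M + (1/i) W_i°.

    ``anchor='first'`` keeps the given order; ``anchor='median'`` starts
    from the network with median total weight (order otherwise kept).
    """
    if len(nets) < 1:
        raise ValueError("need at least one network")
    mats = [np.asarray(w, dtype=float) for w in nets]
    shape = mats[0].shape
    if any(m.shape != shape for m in mats):
        raise ValueError("all networks must have equal size")

    order = list(range(len(mats)))
    if anchor == "median":
        totals = [m.sum() for m in mats]
        first = int(np.argsort(totals)[len(totals) // 2])
        order = [first] + [i for i in order if i != first]
    elif anchor != "first":
        raise ValueError("anchor must be 'first' or 'median'")

    n = shape[0]
    m_mean = mats[order[0]].copy()
    perms = [np.eye(n)]
    for count, idx in enumerate(order[1:], start=2):
        w_i = mats[idx]
        r = match_graphs(m_mean, w_i, config)
        w_aligned = r @ w_i @ r.T
        m_mean = ((count - 1) / count) * m_mean + (1.0 / count) * w_aligned
        perms.append(r)
    return AverageNetwork(matrix=m_mean, k=len(mats), permutations=perms, order=order)
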