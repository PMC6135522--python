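"""Directed weighted social-interaction networks and their parameters.

The network of a tracked group is an N x N adjacency matrix of touch-
interaction counts: row = interactor, column = interacted, zero diagonal
(no self-interaction). Before computing parameters the matrix is
normalized by its maximum weight, so weights lie in [0, 1].

Nine parameters quantify each network:

individual  in-degree, out-degree, degree (binary edge counts; degree =
            in + out) and their weighted versions (strengths, sums of
            normalized weights);
local       clustering coefficient (Fagiolo's weighted directed form)
            and betweenness centrality (shortest paths with edge length
            1/weight, the Brain Connectivity Toolbox convention);
global      assortativity (total-degree correlation over directed
            edges), global efficiency (mean inverse shortest-path
            length over ordered pairs), transitivity (closed / total
            directed triplets on the binarized graph), density, and
            weighted total interaction (sum of normalized weights; the
            raw-count total is exported alongside).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

from .interaction import TouchInteraction

__all__ = [
    "SocialNetwork",
    "build_adjacency",
    "degrees",
    "clustering_coefficient",
    "betweenness_centrality",
    "global_metrics",
    "network_parameters",
    "relabel_by_outgoing",
]


@dataclass
class SocialNetwork:
    """Interaction-count adjacency with its max-normalized weights."""

    counts: np.ndarray
    fly_ids: np.ndarray = field(default=None)  # original 1-based labels

    def __post_init__(self):
        c = np.asarray(self.counts)
        if c.ndim != 2 or c.shape[0] != c.shape[1]:
            raise ValueError("counts must be square")
        if np.any(c < 0):
            raise ValueError("counts must be non-negative")
        if np.any(np.diag(c) != 0):
            raise ValueError("no self-interaction: diagonal must be zero")
        self.counts = c
        if self.fly_ids is None:
            self.fly_ids = np.arange(1, len(c) + 1)

    @property
    def n(self) -> int:
        return self.counts.shape[0]

    @property
    def weights(self) -> np.ndarray:
        """Counts normalized by the maximum weight (all-zero stays zero)."""
        m = self.counts.max()
        return self.counts / m if m > 0 else self.counts.astype(float)

    def to_digraph(self) -> nx.DiGraph:
        """networkx view with 'count', 'weight' and 'length' (1/weight)."""
        g = nx.DiGraph()
        g.add_nodes_from(range(self.n))
        w = self.weights
        for i, j in zip(*np.nonzero(self.counts)):
            g.add_edge(
                int(i), int(j),
                count=int(self.counts[i, j]),
                weight=float(w[i, j]),
                length=1.0 / float(w[i, j]),
            )
        return g


def build_adjacency(
    events: list[TouchInteraction], n_flies: int
) -> SocialNetwork:
    """Tally interaction events into the count matrix."""
    counts = np.zeros((n_flies, n_flies), dtype=int)
    for ev in events:
        i, j = ev.interactor_id, ev.interacted_id
        if not (1 <= i <= n_flies and 1 <= j <= n_flies):
            raise ValueError(f"event {ev} references a fly outside 1..{n_flies}")
        if i == j:
            raise ValueError(f"self-interaction event rejected: {ev}")
        counts[i - 1, j - 1] += 1
    return SocialNetwork(counts)


def degrees(net: SocialNetwork) -> pd.DataFrame:
    """Binary and weighted in/out/total degrees per node."""
    a = (net.counts > 0).astype(int)
    w = net.weights
    return pd.DataFrame(
        {
            "fly_id": net.fly_ids,
            "in_degree": a.sum(axis=0),
            "out_degree": a.sum(axis=1),
            "degree": a.sum(axis=0) + a.sum(axis=1),
            "weighted_in_degree": w.sum(axis=0),
            "weighted_out_degree": w.sum(axis=1),
            "weighted_degree": w.sum(axis=0) + w.sum(axis=1),
        }
    )


def clustering_coefficient(net: SocialNetwork) -> np.ndarray:
    """Fagiolo's clustering coefficient for weighted directed networks.

    With W-hat the element-wise cube root of the normalized weights,

        C_i = [(W-hat + W-hat^T)^3]_ii / (2 [d_i^tot (d_i^tot - 1) - 2 d_i^<->])

    where d_i^tot is the total binary degree and d_i^<-> the number of
    reciprocated neighbors. Nodes with a zero denominator get C_i = 0.
    """
    w_hat = np.cbrt(net.weights)
    a = (net.counts > 0).astype(int)
    d_tot = a.sum(axis=0) + a.sum(axis=1)
    d_bi = (a & a.T).sum(axis=1)
    s = w_hat + w_hat.T
    num = np.diagonal(s @ s @ s)
    denom = 2.0 * (d_tot * (d_tot - 1) - 2 * d_bi)
    return np.divide(num, denom, out=np.zeros(net.n), where=denom > 0)


def betweenness_centrality(net: SocialNetwork) -> np.ndarray:
    """Fraction of all-pairs shortest paths through each node.

    Directed, endpoints excluded, equal splitting among equally short
    paths; edge length is the inverse normalized weight.
    """
    bc = nx.betweenness_centrality(
        net.to_digraph(), normalized=True, weight="length"
    )
    return np.array([bc[i] for i in range(net.n)])


def global_metrics(net: SocialNetwork) -> dict:
    """The five global parameters (see module docstring).

    Assortativity is undefined (NaN) when the degree variance over edges
    vanishes, e.g. on a complete graph.
    """
    n = net.n
    a = (net.counts > 0).astype(int)
    w = net.weights
    g = net.to_digraph()

    # global efficiency: mean over ordered pairs of 1 / shortest length
    eff = 0.0
    if n > 1:
        acc = 0.0
        for src, lengths in nx.all_pairs_dijkstra_path_length(g, weight="length"):
            for dst, dist in lengths.items():
                if dst != src and dist > 0:
                    acc += 1.0 / dist
        eff = acc / (n * (n - 1))

    density = a.sum() / (n * (n - 1)) if n > 1 else 0.0

    # directed transitivity: closed over total directed triplets,
    # the global counterpart of the Fagiolo coefficient on the binary graph
    s = a + a.T
    d_tot = a.sum(axis=0) + a.sum(axis=1)
    d_bi = (a & a.T).sum(axis=1)
    closed = np.trace(np.linalg.matrix_power(s, 3)) / 2.0
    total = float(np.sum(d_tot * (d_tot - 1) - 2 * d_bi))
    transitivity = closed / total if total > 0 else 0.0

    # total-degree assortativity over directed edges
    src, dst = np.nonzero(a)
    if len(src) >= 2:
        x, y = d_tot[src].astype(float), d_tot[dst].astype(float)
        if x.std() > 0 and y.std() > 0:
            assort = float(np.corrcoef(x, y)[0, 1])
        else:
            assort = math.nan
    else:
        assort = math.nan

    return {
        "assortativity": assort,
        "global_efficiency": float(eff),
        "transitivity": float(transitivity),
        "density": float(density),
        "weighted_total_interaction": float(w.sum()),
        "raw_total_interaction": int(net.counts.sum()),
        "unweighted_total_interaction": int(a.sum()),
    }


def network_parameters(net: SocialNetwork) -> tuple[pd.DataFrame, dict]:
    """All nine parameters: a per-node table and the global dictionary."""
    per_node = degrees(net)
    per_node["clustering_coefficient"] = clustering_coefficient(net)
    per_node["betweenness_centrality"] = betweenness_centrality(net)
    return per_node, global_metrics(net)


def relabel_by_outgoing(net: SocialNetwork) -> tuple[SocialNetwork, np.ndarray]:
    """Relabel nodes 1..N in ascending order of out-going activity.

    Sorted by weighted out-degree; ties broken by weighted in-degree,
    then original index. Returns the relabeled network and the
    permutation ``perm`` such that new node k is old node perm[k].
    """
    w = net.weights
    perm = np.lexsort((np.arange(net.n), w.sum(axis=0), w.sum(axis=1)))
    new_counts = net.counts[np.ix_(perm, perm)]
    return SocialNetwork(new_counts, fly_ids=net.fly_ids[perm]), perm
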