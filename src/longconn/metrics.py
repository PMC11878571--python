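"""Weighted graph metrics for streamline-count connectomes.

Implements the global measures (mean degree, transitivity, modularity Q,
global efficiency) and nodal measures (strength, participation coefficient,
eigenvector centrality, local efficiency) on the weighted, undirected,
zero-diagonal adjacency of a connectome. Controllability measures live in
:mod:`longconn.control`; :func:`global_metrics` and :func:`nodal_metrics`
assemble the full sets.

Conventions (documented in the package methods note):

* "degree" means weighted strength — the sum of streamline weights at a node;
* transitivity is the Onnela geometric-mean triangle intensity over the
  number of connected triplets;
* shortest-path edge length is the reciprocal of the weight;
* community structure comes from seeded Louvain at resolution γ, and the
  participation coefficient uses that same partition.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from networkx import Graph
from networkx.algorithms.community import louvain_communities
from scipy.sparse.csgraph import dijkstra

from .control import average_controllability, mean_controllability, modal_controllability, normalize_adjacency
from .io import Connectome

__all__ = [
    "GlobalMetricSet",
    "Partition",
    "node_strength",
    "mean_degree",
    "transitivity",
    "modularity",
    "modularity_q",
    "global_efficiency",
    "participation_coefficient",
    "eigenvector_centrality",
    "local_efficiency",
    "global_metrics",
    "nodal_metrics",
    "GLOBAL_METRIC_NAMES",
    "NODAL_METRIC_NAMES",
]

GLOBAL_METRIC_NAMES = (
    "mean_degree",
    "transitivity",
    "modularity_q",
    "global_efficiency",
    "mean_average_controllability",
    "mean_modal_controllability",
)

NODAL_METRIC_NAMES = (
    "strength",
    "participation_coefficient",
    "eigenvector_centrality",
    "local_efficiency",
    "average_controllability",
    "modal_controllability",
)


@dataclass(frozen=True)
class Partition:
    """Community assignment with the resolution and seed that produced it."""

    labels: np.ndarray
    resolution_gamma: float
    seed: int

    def __post_init__(self) -> None:
        labels = np.asarray(self.labels, dtype=int)
        uniq = np.unique(labels)
        if not np.array_equal(uniq, np.arange(len(uniq))):
            raise ValueError("community labels must be contiguous from 0")
        object.__setattr__(self, "labels", labels)

    @property
    def n_communities(self) -> int:
        return int(self.labels.max()) + 1


@dataclass(frozen=True)
class GlobalMetricSet:
    mean_degree: float
    transitivity: float
    modularity_q: float
    global_efficiency: float
    mean_average_controllability: float
    mean_modal_controllability: float

    def as_dict(self) -> dict[str, float]:
        return {name: getattr(self, name) for name in GLOBAL_METRIC_NAMES}


def _weights(c: Connectome | np.ndarray) -> np.ndarray:
    if isinstance(c, Connectome):
        return c.matrix
    return np.asarray(c, dtype=float)


def node_strength(c: Connectome | np.ndarray) -> np.ndarray:
    """Weighted degree: total streamline weight attached to each node."""
    return _weights(c).sum(axis=1)


def mean_degree(c: Connectome | np.ndarray) -> float:
    """Average weighted strength over nodes."""
    return float(node_strength(c).mean())


def transitivity(c: Connectome | np.ndarray) -> float:
    """Onnela weighted transitivity: geometric-mean triangle intensity over
    the number of connected triplets, with weights scaled by the network
    maximum so the value lies in [0, 1]. 0 when no triplets exist."""
    w = _weights(c)
    if w.shape[0] < 3 or w.max() == 0:
        return 0.0
    w13 = np.cbrt(w / w.max())
    triangles = float(np.trace(w13 @ w13 @ w13))
    k = (w > 0).sum(axis=1)
    triplets = float((k * (k - 1)).sum())
    if triplets == 0:
        return 0.0
    return triangles / triplets


def modularity_q(
    w: np.ndarray, labels: np.ndarray, gamma: float = 1.0
) -> float:
    """Newman weighted modularity of a given partition.

    Q = (1/2m) Σ_ij [w_ij − γ k_i k_j / 2m] δ(c_i, c_j), summed over ordered
    pairs including i = j (the diagonal is zero for connectomes).
    """
    w = np.asarray(w, dtype=float)
    labels = np.asarray(labels)
    two_m = w.sum()
    if two_m <= 0:
        raise ValueError("empty network")
    k = w.sum(axis=1)
    same = labels[:, None] == labels[None, :]
    return float(((w - gamma * np.outer(k, k) / two_m) * same).sum() / two_m)


def modularity(
    c: Connectome | np.ndarray, gamma: float = 1.0, seed: int = 0
) -> tuple[Partition, float]:
    """Seeded Louvain partition at resolution ``gamma`` and its modularity Q."""
    w = _weights(c)
    if w.sum() <= 0:
        raise ValueError("empty network")
    g = Graph()
    g.add_nodes_from(range(w.shape[0]))
    ii, jj = np.nonzero(np.triu(w, k=1))
    g.add_weighted_edges_from(zip(ii.tolist(), jj.tolist(), w[ii, jj].tolist()))
    communities = louvain_communities(g, weight="weight", resolution=gamma, seed=seed)
    labels = np.empty(w.shape[0], dtype=int)
    # relabel communities by smallest member for determinism independent of set order
    for new, comm in enumerate(sorted(communities, key=min)):
        labels[list(comm)] = new
    part = Partition(labels=labels, resolution_gamma=gamma, seed=seed)
    return part, modularity_q(w, labels, gamma)


def _pairwise_efficiency(w: np.ndarray) -> float:
    """Mean of inverse shortest-path length over ordered node pairs
    (edge length = 1/weight; unreachable pairs contribute 0)."""
    n = w.shape[0]
    if n < 2:
        return 0.0
    with np.errstate(divide="ignore"):
        lengths = np.where(w > 0, 1.0 / w, np.inf)
    d = dijkstra(lengths, directed=False)
    with np.errstate(divide="ignore"):
        inv = 1.0 / d
    np.fill_diagonal(inv, 0.0)
    inv[~np.isfinite(inv)] = 0.0
    return float(inv.sum() / (n * (n - 1)))


def global_efficiency(c: Connectome | np.ndarray) -> float:
    """Average inverse shortest-path length in the weighted network."""
    return _pairwise_efficiency(_weights(c))


def participation_coefficient(
    c: Connectome | np.ndarray, partition: Partition | np.ndarray
) -> np.ndarray:
    """PC_i = 1 − Σ_s (κ_is / k_i)², with κ_is the strength of node i into
    community s. Nodes with zero strength get PC = 0."""
    w = _weights(c)
    labels = partition.labels if isinstance(partition, Partition) else np.asarray(partition)
    n_comm = int(labels.max()) + 1
    onehot = np.eye(n_comm)[labels]  # n x s
    kappa = w @ onehot  # strength of each node into each community
    k = w.sum(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        frac2 = (kappa / k[:, None]) ** 2
    pc = 1.0 - frac2.sum(axis=1)
    pc[k == 0] = 0.0
    return pc


def eigenvector_centrality(c: Connectome | np.ndarray) -> np.ndarray:
    """Principal eigenvector of the weight matrix, nonnegative, unit 2-norm.

    For a disconnected graph this is the Perron vector of the component with
    the largest spectral radius; an all-zero graph is rejected.
    """
    w = _weights(c)
    if w.sum() == 0:
        raise ValueError("no edges")
    vals, vecs = np.linalg.eigh(w)
    v = vecs[:, -1]
    # Perron vector has entries of a single sign; orient nonnegative
    if v.sum() < 0:
        v = -v
    v = np.clip(v, 0.0, None)
    return v / np.linalg.norm(v)


def local_efficiency(c: Connectome | np.ndarray) -> np.ndarray:
    """Per-node global efficiency of the subgraph induced by its neighbours;
    0 for nodes with fewer than two neighbours."""
    w = _weights(c)
    n = w.shape[0]
    out = np.zeros(n)
    for i in range(n):
        nbrs = np.flatnonzero(w[i] > 0)
        if len(nbrs) < 2:
            continue
        out[i] = _pairwise_efficiency(w[np.ix_(nbrs, nbrs)])
    return out


def global_metrics(
    c: Connectome | np.ndarray, gamma: float = 1.0, seed: int = 0
) -> GlobalMetricSet:
    """Assemble all six global measures of one connectome."""
    w = _weights(c)
    if w.sum() <= 0:
        raise ValueError("empty network")
    _, q = modularity(w, gamma=gamma, seed=seed)
    a = normalize_adjacency(w)
    return GlobalMetricSet(
        mean_degree=mean_degree(w),
        transitivity=transitivity(w),
        modularity_q=q,
        global_efficiency=global_efficiency(w),
        mean_average_controllability=mean_controllability(average_controllability(a)),
        mean_modal_controllability=mean_controllability(modal_controllability(a)),
    )


def nodal_metrics(
    c: Connectome, gamma: float = 1.0, seed: int = 0
) -> pd.DataFrame:
    """Per-parcel table of the six nodal measures.

    The participation coefficient uses the Louvain modularity partition of
    the same connectome (resolution ``gamma``, seeded).
    """
    w = c.matrix
    part, _ = modularity(w, gamma=gamma, seed=seed)
    a = normalize_adjacency(w)
    return pd.DataFrame(
        {
            "parcel_id": list(c.parcel_ids),
            "strength": node_strength(w),
            "participation_coefficient": participation_coefficient(w, part),
            "eigenvector_centrality": eigenvector_centrality(w),
            "local_efficiency": local_efficiency(w),
            "average_controllability": average_controllability(a),
            "modal_controllability": modal_controllability(a),
        }
    )
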