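"""Independent brute-force oracles used to verify the fast implementations.

Everything here is written the slow, obvious way — explicit loops,
exhaustive enumeration, truncated series — and deliberately shares no code
with the package.
"""

from __future__ import annotations

from itertools import product

import numpy as np
from scipy.stats import rankdata


def strength_oracle(w: np.ndarray) -> np.ndarray:
    n = w.shape[0]
    out = np.zeros(n)
    for i in range(n):
        for j in range(n):
            out[i] += w[i, j]
    return out


def transitivity_oracle(w: np.ndarray) -> float:
    """Onnela weighted transitivity (weights scaled by the maximum) by
    exhaustive ordered-triplet enumeration."""
    n = w.shape[0]
    if w.max() > 0:
        w = w / w.max()
    num = 0.0
    for i in range(n):
        for j in range(n):
            for k in range(n):
                if i != j and j != k and k != i:
                    num += (w[i, j] * w[j, k] * w[k, i]) ** (1.0 / 3.0)
    den = 0.0
    for i in range(n):
        deg = sum(1 for j in range(n) if w[i, j] > 0)
        den += deg * (deg - 1)
    return num / den if den > 0 else 0.0


def shortest_paths_oracle(w: np.ndarray) -> np.ndarray:
    """All-pairs shortest paths with edge length 1/weight (Floyd–Warshall)."""
    n = w.shape[0]
    d = np.full((n, n), np.inf)
    for i in range(n):
        d[i, i] = 0.0
        for j in range(n):
            if i != j and w[i, j] > 0:
                d[i, j] = 1.0 / w[i, j]
    for k in range(n):
        for i in range(n):
            for j in range(n):
                if d[i, k] + d[k, j] < d[i, j]:
                    d[i, j] = d[i, k] + d[k, j]
    return d


def global_efficiency_oracle(w: np.ndarray) -> float:
    n = w.shape[0]
    if n < 2:
        return 0.0
    d = shortest_paths_oracle(w)
    total = 0.0
    for i in range(n):
        for j in range(n):
            if i != j and np.isfinite(d[i, j]) and d[i, j] > 0:
                total += 1.0 / d[i, j]
    return total / (n * (n - 1))


def local_efficiency_oracle(w: np.ndarray) -> np.ndarray:
    n = w.shape[0]
    out = np.zeros(n)
    for i in range(n):
        nbrs = [j for j in range(n) if w[i, j] > 0]
        if len(nbrs) < 2:
            continue
        sub = w[np.ix_(nbrs, nbrs)]
        out[i] = global_efficiency_oracle(sub)
    return out


def participation_oracle(w: np.ndarray, labels: np.ndarray) -> np.ndarray:
    n = w.shape[0]
    out = np.zeros(n)
    for i in range(n):
        k = sum(w[i, j] for j in range(n))
        if k == 0:
            continue
        acc = 0.0
        for s in np.unique(labels):
            kappa = sum(w[i, j] for j in range(n) if labels[j] == s)
            acc += (kappa / k) ** 2
        out[i] = 1.0 - acc
    return out


def modularity_q_oracle(w: np.ndarray, labels: np.ndarray, gamma: float = 1.0) -> float:
    two_m = w.sum()
    k = w.sum(axis=1)
    q = 0.0
    n = w.shape[0]
    for i in range(n):
        for j in range(n):
            if labels[i] == labels[j]:
                q += w[i, j] - gamma * k[i] * k[j] / two_m
    return q / two_m


def all_partitions(items: list):
    """Every set partition of ``items`` (Bell-number enumeration)."""
    if not items:
        yield []
        return
    head, rest = items[0], items[1:]
    for part in all_partitions(rest):
        for i in range(len(part)):
            yield part[:i] + [part[i] + [head]] + part[i + 1 :]
        yield [[head]] + part


def best_modularity_oracle(w: np.ndarray, gamma: float = 1.0):
    """Exhaustive search for the maximum-modularity partition (small n only)."""
    n = w.shape[0]
    best_q, best_labels = -np.inf, None
    for part in all_partitions(list(range(n))):
        labels = np.empty(n, dtype=int)
        for c, comm in enumerate(part):
            labels[comm] = c
        q = modularity_q_oracle(w, labels, gamma)
        if q > best_q:
            best_q, best_labels = q, labels
    return best_labels, best_q


def eigenvector_centrality_oracle(w: np.ndarray) -> np.ndarray:
    """Principal eigenvector via the general (non-symmetric) eigensolver."""
    vals, vecs = np.linalg.eig(w)
    idx = int(np.argmax(vals.real))
    v = np.abs(vecs[:, idx].real)
    return v / np.linalg.norm(v)


def average_controllability_series_oracle(a: np.ndarray, n_terms: int = 500) -> np.ndarray:
    """Σ_{t<n_terms} ||A^t e_i||² summed term by term."""
    n = a.shape[0]
    out = np.zeros(n)
    for i in range(n):
        x = np.zeros(n)
        x[i] = 1.0
        for _ in range(n_terms):
            out[i] += float(x @ x)
            x = a @ x
    return out


def modal_controllability_oracle(a: np.ndarray) -> np.ndarray:
    vals, vecs = np.linalg.eig(a)
    lam = vals.real
    v = vecs.real
    # eig returns unit-norm columns for real symmetric input
    return ((v**2) * (1.0 - lam**2)).sum(axis=1)


def wilcoxon_exact_oracle(early: np.ndarray, late: np.ndarray) -> float:
    """Two-sided signed-rank p by full 2ⁿ sign-assignment enumeration."""
    diff = np.asarray(late, dtype=float) - np.asarray(early, dtype=float)
    d = diff[diff != 0]
    n = len(d)
    ranks = rankdata(np.abs(d))
    w_plus = float(ranks[d > 0].sum())
    total = float(ranks.sum())
    stats = []
    for signs in product((0, 1), repeat=n):
        stats.append(sum(r for r, s in zip(ranks, signs) if s))
    stats = np.asarray(stats, dtype=float)
    lo, hi = min(w_plus, total - w_plus), max(w_plus, total - w_plus)
    p = ((stats <= lo).sum() + (stats >= hi).sum()) / len(stats)
    return min(1.0, float(p))


def random_weighted_graph(rng: np.random.Generator, n: int, density: float = 0.7) -> np.ndarray:
    """Symmetric nonnegative weighted adjacency with zero diagonal."""
    w = rng.uniform(0.5, 5.0, size=(n, n))
    mask = rng.random((n, n)) < density
    w = np.triu(w * mask, k=1)
    w = w + w.T
    return w
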