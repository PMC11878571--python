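"""Linear network control metrics: average and modal controllability.

The dynamical model is the discrete-time linear system
``x(t+1) = A x(t) + B u(t)`` with ``A = W / (1 + λ_max(W))`` — the raw
weighted adjacency scaled so its spectral radius is below one — and
single-node input ``B = e_i``, the dominant convention in the
structural-connectome control literature.

* Average controllability of node i is the trace of the infinite-horizon
  controllability Gramian ``W_i = Σ_{t≥0} A^t e_i e_i' (A')^t``, i.e. the
  solution of the discrete Lyapunov equation ``W_i = A W_i A' + e_i e_i'``.
  For symmetric A the trace reduces in closed form to
  ``trace(W_i) = [(I − A²)^{-1}]_{ii}``, which is how it is computed here
  (one dense solve for all nodes at once).
* Modal controllability of node i is ``φ_i = Σ_j (1 − λ_j²) v_ij²`` over the
  eigenpairs (λ_j, v_j) of A.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.linalg

__all__ = [
    "SystemMatrix",
    "normalize_adjacency",
    "average_controllability",
    "modal_controllability",
    "mean_controllability",
]


@dataclass(frozen=True)
class SystemMatrix:
    """Normalized symmetric system matrix A with spectral radius < 1."""

    matrix: np.ndarray
    normalization_constant: float

    def __post_init__(self) -> None:
        a = np.asarray(self.matrix, dtype=float)
        if a.ndim != 2 or a.shape[0] != a.shape[1]:
            raise ValueError("system matrix must be square")
        if not np.allclose(a, a.T, atol=1e-9):
            raise ValueError("system matrix must be symmetric")
        object.__setattr__(self, "matrix", a)

    @property
    def n(self) -> int:
        return self.matrix.shape[0]


def normalize_adjacency(w: np.ndarray) -> SystemMatrix:
    """Scale a weighted adjacency to ``A = W / (1 + λ_max(W))``.

    λ_max is the largest eigenvalue of W; for a nonnegative symmetric matrix
    this is its spectral radius, so A has spectral radius strictly below 1.
    An all-zero matrix maps to the (valid) zero system.
    """
    w = np.asarray(w, dtype=float)
    if not np.allclose(w, w.T, atol=1e-9):
        raise ValueError("adjacency must be symmetric")
    if not w.any():
        return SystemMatrix(matrix=np.zeros_like(w), normalization_constant=1.0)
    lam_max = float(scipy.linalg.eigh(w, eigvals_only=True, subset_by_index=(w.shape[0] - 1, w.shape[0] - 1))[0])
    c = 1.0 + lam_max
    return SystemMatrix(matrix=w / c, normalization_constant=c)


def _check_stable(eigvals: np.ndarray) -> None:
    rho = float(np.abs(eigvals).max()) if eigvals.size else 0.0
    if rho >= 1.0:
        raise ValueError(f"system is not stable: spectral radius {rho:.6g} >= 1")


def average_controllability(a: SystemMatrix | np.ndarray) -> np.ndarray:
    """Trace of the single-input controllability Gramian for each node.

    Every entry is ≥ 1 (the t = 0 identity term), with equality exactly when
    the node is isolated.
    """
    m = a.matrix if isinstance(a, SystemMatrix) else np.asarray(a, dtype=float)
    lam, v = scipy.linalg.eigh(m)
    _check_stable(lam)
    # trace W_i = Σ_t (A^{2t})_{ii} = Σ_j v_ij^2 / (1 − λ_j^2)
    return (v**2 / (1.0 - lam**2)).sum(axis=1)


def modal_controllability(a: SystemMatrix | np.ndarray) -> np.ndarray:
    """φ_i = Σ_j (1 − λ_j²) v_ij² — the capacity of node i to steer the
    system into its hard-to-reach (fast-decaying) modes. Entries lie in
    (0, 1] for a stable symmetric system."""
    m = a.matrix if isinstance(a, SystemMatrix) else np.asarray(a, dtype=float)
    if not np.allclose(m, m.T, atol=1e-9):
        raise ValueError("modal controllability requires a symmetric system matrix")
    lam, v = scipy.linalg.eigh(m)
    _check_stable(lam)
    return (v**2 * (1.0 - lam**2)).sum(axis=1)


def mean_controllability(values: np.ndarray) -> float:
    """Arithmetic mean of a per-node controllability vector."""
    values = np.asarray(values, dtype=float)
    if values.size == 0:
        raise ValueError("empty controllability vector")
    return float(values.mean())
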