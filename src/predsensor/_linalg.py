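"""Stationary-distribution solvers for finite column-stochastic chains.

All chains in this package are column-stochastic: ``p_next = P @ p``.  Both
solvers return the Cesaro (time-averaged) limit of the chain from a given
initial distribution: for irreducible chains this is the unique stationary
distribution; for reducible chains it weights each recurrent class by the
probability of being absorbed there from the init, with transient states
getting zero mass.

* :func:`stationary_exact` decomposes the dense matrix into strongly
  connected components, solves each recurrent class by a direct linear
  solve, and computes absorption weights through the transient block.  It is
  exact, deterministic and immune to slow mixing; used for environments and
  as a fallback.
* :func:`stationary_from_matvec` power-iterates the "lazy" chain (P + I)/2,
  which is aperiodic, has the same per-class stationary distributions and
  the same absorption weights as P, so its pointwise limit equals the Cesaro
  limit of P while converging geometrically.  Used for large structured
  joint chains where a matvec is much cheaper than a dense solve.
"""

from __future__ import annotations

from typing import Callable

import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components

__all__ = [
    "ConvergenceError",
    "stationary_exact",
    "stationary_from_matvec",
    "stationary_dense",
]


class ConvergenceError(RuntimeError):
    """Raised when power iteration fails to reach the requested tolerance.

    Carries the final L1 residual ``||P p - p||_1`` in :attr:`residual`.
    """

    def __init__(self, message: str, residual: float):
        super().__init__(message)
        self.residual = residual


def _class_stationary(Pc: np.ndarray) -> np.ndarray:
    """Stationary distribution of an irreducible column-stochastic block."""
    n = Pc.shape[0]
    if n == 1:
        return np.ones(1)
    A = Pc - np.eye(n)
    A[-1, :] = 1.0  # replace one redundant row with the normalization
    b = np.zeros(n)
    b[-1] = 1.0
    pi = np.linalg.solve(A, b)
    pi = np.clip(pi, 0.0, None)
    return pi / pi.sum()


def stationary_exact(P: np.ndarray, init: np.ndarray | None = None) -> np.ndarray:
    """Cesaro-limit stationary distribution by recurrent-class decomposition.

    ``init`` (default uniform) only matters when the chain has several
    recurrent classes: each class receives the probability of absorption
    there from ``init``.
    """
    P = np.asarray(P, dtype=float)
    n = P.shape[0]
    if init is None:
        init = np.full(n, 1.0 / n)
    init = np.asarray(init, dtype=float)

    # adjacency[src, dest] for csgraph; our convention is P[dest, src]
    ncomp, labels = connected_components(csr_matrix(P.T > 0), connection="strong")
    # a component is recurrent iff no edge leaves it
    leaves = np.zeros(ncomp, dtype=bool)
    dest_idx, src_idx = np.nonzero(P)
    cross = labels[dest_idx] != labels[src_idx]
    leaves[labels[src_idx[cross]]] = True
    recurrent = [c for c in range(ncomp) if not leaves[c]]

    p = np.zeros(n)
    if len(recurrent) == 1:
        members = np.where(labels == recurrent[0])[0]
        p[members] = _class_stationary(P[np.ix_(members, members)])
        return p

    transient = ~np.isin(labels, recurrent)
    tr = np.where(transient)[0]
    weights = {}
    if tr.size:
        Q = P[np.ix_(tr, tr)]  # transient -> transient, [dest, src]
        lhs = np.eye(tr.size) - Q.T
    for c in recurrent:
        members = np.where(labels == c)[0]
        w = init[members].sum()
        if tr.size:
            a = P[np.ix_(members, tr)].sum(axis=0)  # one-step into class c
            b_abs = np.linalg.solve(lhs, a)
            w += float(init[tr] @ b_abs)
        if w > 0:
            p[members] = w * _class_stationary(P[np.ix_(members, members)])
        weights[c] = w
    total = p.sum()
    if total <= 0:
        raise ValueError("no recurrent mass found; invalid chain")
    return p / total


def stationary_from_matvec(
    matvec: Callable[[np.ndarray], np.ndarray],
    init: np.ndarray,
    tol: float = 1e-12,
    max_iter: int = 200_000,
) -> np.ndarray:
    """Cesaro-limit stationary distribution via lazy power iteration.

    Parameters
    ----------
    matvec
        Applies the column-stochastic transition: ``matvec(p) = P @ p``.
    init
        Starting distribution (nonnegative, sums to 1).
    tol
        Target L1 distance to the limit, estimated from the observed
        per-step contraction rate.
    max_iter
        Hard cap on lazy-chain steps; exceeding it raises
        :class:`ConvergenceError` carrying the residual.
    """
    p = np.asarray(init, dtype=float).copy()
    p /= p.sum()
    prev_change = np.inf
    change = np.inf
    for _ in range(max_iter):
        q = 0.5 * (p + matvec(p))
        q /= q.sum()  # damp floating-point drift
        prev_change, change = change, float(np.abs(q - p).sum())
        p = q
        if change < 1e-16:
            break
        if np.isfinite(prev_change) and prev_change > 0:
            rate = change / prev_change
            if rate < 1.0 and change * rate / (1.0 - rate) < tol and change < tol:
                break
    else:
        residual = float(np.abs(matvec(p) - p).sum())
        raise ConvergenceError(
            f"stationary distribution did not converge in {max_iter} iterations "
            f"(residual {residual:.3e})",
            residual,
        )
    p = np.clip(p, 0.0, None)
    return p / p.sum()


def stationary_dense(P: np.ndarray, init: np.ndarray | None = None) -> np.ndarray:
    """Stationary distribution of a dense column-stochastic matrix (exact)."""
    return stationary_exact(P, init)
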