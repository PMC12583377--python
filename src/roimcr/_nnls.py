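"""Multi-right-hand-side non-negative least squares.

Solves ``min_{X >= 0} ||A X - B||_F`` for many columns of B sharing one
coefficient matrix A, grouping columns by passive set so each distinct
active-set pattern costs a single batched normal-equation solve
(fast combinatorial NNLS, Van Benthem & Keenan style). The alternating
least squares loop calls this twice per iteration, so it is the hot path.
"""

from __future__ import annotations

import numpy as np

__all__ = ["nnls_multiple"]

_MAX_OUTER = 200


def _solve_passive(AtA: np.ndarray, AtB: np.ndarray, passive: np.ndarray) -> np.ndarray:
    """Least-squares solution restricted to each column's passive set.

    Columns sharing a passive-set pattern are solved together.
    """
    n, p = AtB.shape
    X = np.zeros((n, p))
    if p == 0:
        return X
    # group columns by identical passive pattern
    codes = np.packbits(passive, axis=0).T  # p x ceil(n/8)
    _, first, inverse = np.unique(codes, axis=0, return_index=True, return_inverse=True)
    for g, col0 in enumerate(first):
        cols = np.nonzero(inverse == g)[0]
        mask = passive[:, col0]
        if not mask.any():
            continue
        sub = np.ix_(mask, mask)
        try:
            sol = np.linalg.solve(AtA[sub], AtB[np.ix_(mask, cols)])
        except np.linalg.LinAlgError:
            sol = np.linalg.lstsq(AtA[sub], AtB[np.ix_(mask, cols)], rcond=None)[0]
        X[np.ix_(mask, cols)] = sol
    return X


def nnls_multiple(A: np.ndarray, B: np.ndarray, tol: float | None = None) -> np.ndarray:
    """Solve ``min_{X>=0} ||A X - B||_F`` column-wise.

    Parameters
    ----------
    A : (m, n) coefficient matrix.
    B : (m, p) right-hand sides.
    tol : optimality tolerance on the dual (gradient) condition; defaults to
        a machine-precision scale of ``A``.

    Returns
    -------
    X : (n, p) non-negative solution matrix.
    """
    A = np.asarray(A, dtype=float)
    B = np.asarray(B, dtype=float)
    if B.ndim == 1:
        B = B[:, None]
    m, n = A.shape
    p = B.shape[1]
    AtA = A.T @ A
    AtB = A.T @ B
    if tol is None:
        tol = 10 * np.finfo(float).eps * np.linalg.norm(AtA, 1) * max(m, n)

    # start from the unconstrained solution: columns already feasible are done
    X = np.linalg.lstsq(AtA, AtB, rcond=None)[0]
    passive = X > 0
    infeasible = (X < 0).any(axis=0)
    X[:, ~infeasible] = np.maximum(X[:, ~infeasible], 0.0)
    active_cols = np.nonzero(infeasible)[0]
    if active_cols.size == 0:
        return X

    Xw = np.zeros((n, active_cols.size))
    Pw = passive[:, active_cols].copy()
    AtBw = AtB[:, active_cols]

    for _ in range(_MAX_OUTER):
        Z = _solve_passive(AtA, AtBw, Pw)
        # inner loop: clip infeasible passive variables
        for _ in range(n + 1):
            bad = (Z < -tol) & Pw
            badcols = bad.any(axis=0)
            if not badcols.any():
                break
            cur = Xw[:, badcols]
            step = Z[:, badcols]
            neg = bad[:, badcols]
            with np.errstate(divide="ignore", invalid="ignore"):
                alpha = np.where(neg, cur / (cur - step), np.inf)
            a = np.min(alpha, axis=0)
            cur = cur + a * (step - cur)
            newP = Pw[:, badcols] & ~(np.abs(cur) <= tol * 10) | (cur > tol * 10)
            # variables driven to zero leave the passive set
            newP = Pw[:, badcols] & (cur > tol * 10)
            Pw[:, badcols] = newP
            Xw[:, badcols] = np.maximum(cur, 0.0)
            Z[:, badcols] = _solve_passive(AtA, AtBw[:, badcols], Pw[:, badcols])
        Xw = np.maximum(Z, 0.0)
        # optimality: gradient w = AtB - AtA X must be <= tol on active set
        W = AtBw - AtA @ Xw
        W[Pw] = -np.inf
        grow = W > tol
        growcols = grow.any(axis=0)
        if not growcols.any():
            break
        idx = np.argmax(np.where(grow, W, -np.inf), axis=0)
        Pw[idx[growcols], np.nonzero(growcols)[0]] = True

    X[:, active_cols] = Xw
    return X
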