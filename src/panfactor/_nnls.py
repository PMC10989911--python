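"""Multi-column nonnegative least squares via block principal pivoting.

Solves ``min_{X >= 0} ||A X - B||_F`` given the normal-equation matrices
``AtA = A'A`` (k x k, positive definite) and ``AtB = A'B`` (k x n).  Columns
are independent problems; columns sharing the same passive set are solved
together with one Cholesky/solve call, which keeps the factor-update step of
the alternating NMF fast even for thousands of gene families.

The exchange rules follow the standard block principal pivoting scheme: full
exchange of infeasible variables while the infeasibility count decreases,
a bounded number of full-exchange retries otherwise, then single-variable
(largest index) exchange which guarantees termination.
"""

from __future__ import annotations

import numpy as np

__all__ = ["nnls_blockpivot"]


def _grouped_solve(AtA: np.ndarray, AtB: np.ndarray, passive: np.ndarray, X: np.ndarray, cols: np.ndarray) -> None:
    """Solve the unconstrained systems restricted to each column's passive set."""
    if cols.size == 0:
        return
    patterns = passive[:, cols]
    # group columns by identical passive-set pattern
    keys = np.packbits(patterns, axis=0).T
    order = np.lexsort(keys.T[::-1])
    sorted_cols = cols[order]
    sorted_keys = keys[order]
    boundaries = np.any(np.diff(sorted_keys, axis=0) != 0, axis=1)
    starts = np.concatenate(([0], np.flatnonzero(boundaries) + 1, [sorted_cols.size]))
    for a, b in zip(starts[:-1], starts[1:]):
        group = sorted_cols[a:b]
        mask = passive[:, group[0]]
        X[:, group] = 0.0
        if not mask.any():
            continue
        sub = AtA[np.ix_(mask, mask)]
        rhs = AtB[np.ix_(mask, group)]
        try:
            sol = np.linalg.solve(sub, rhs)
        except np.linalg.LinAlgError:
            sol = np.linalg.lstsq(sub, rhs, rcond=None)[0]
        X[np.ix_(np.flatnonzero(mask), group)] = sol


def nnls_blockpivot(
    AtA: np.ndarray,
    AtB: np.ndarray,
    tol: float = 1e-12,
    max_iter: int = 200,
    _ridge_retry: bool = True,
) -> np.ndarray:
    """Return the k x n nonnegative minimizer of ``||A X - B||_F`` columnwise.

    Termination of block principal pivoting is only guaranteed for positive
    definite ``AtA``; a singular system (collinear columns of ``A``) can make
    the pivoting cycle, in which case the solve is retried once with a tiny
    diagonal ridge that picks one of the equivalent minimizers.
    """
    AtA = np.asarray(AtA, dtype=float)
    AtB = np.asarray(AtB, dtype=float)
    k, n = AtB.shape
    X = np.zeros((k, n))
    Y = -AtB.copy()  # dual (gradient) at X = 0
    passive = np.zeros((k, n), dtype=bool)

    retries = np.full(n, 3, dtype=int)  # full-exchange credit per column
    best_inf = np.full(n, k + 1, dtype=int)

    for _ in range(max_iter):
        infeasible = (passive & (X < -tol)) | (~passive & (Y < -tol))
        counts = infeasible.sum(axis=0)
        active_cols = np.flatnonzero(counts > 0)
        if active_cols.size == 0:
            break

        improved = counts[active_cols] < best_inf[active_cols]
        imp_cols = active_cols[improved]
        best_inf[imp_cols] = counts[imp_cols]
        retries[imp_cols] = 3

        stuck = active_cols[~improved]
        has_credit = retries[stuck] > 0
        retries[stuck[has_credit]] -= 1
        full_cols = np.concatenate((imp_cols, stuck[has_credit]))
        single_cols = stuck[~has_credit]

        if full_cols.size:
            passive[:, full_cols] ^= infeasible[:, full_cols]
        for j in single_cols:
            idx = np.flatnonzero(infeasible[:, j]).max()
            passive[idx, j] = not passive[idx, j]

        changed = np.concatenate((full_cols, single_cols))
        _grouped_solve(AtA, AtB, passive, X, changed)
        Y[:, changed] = AtA @ X[:, changed] - AtB[:, changed]
        # exact zeros on the complementary sets for numerical hygiene
        colmask = np.zeros(n, dtype=bool)
        colmask[changed] = True
        X[~passive & colmask[None, :]] = 0.0
        Y[passive & colmask[None, :]] = 0.0
    else:
        if not _ridge_retry:
            raise RuntimeError("block principal pivoting failed to terminate")
        ridge = 1e-10 * max(np.trace(AtA) / k, np.finfo(float).tiny)
        return nnls_blockpivot(
            AtA + ridge * np.eye(k), AtB, tol=tol, max_iter=max_iter, _ridge_retry=False
        )

    np.clip(X, 0.0, None, out=X)
    return X
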