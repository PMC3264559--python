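"""Low-rank SVD imputation of missing aCGH entries.

Missing log2 ratios (a fraction of a percent in typical two-channel
arrays) are estimated by iterating a truncated-SVD reconstruction:
missing cells start at zero (the data are median-centered), the matrix is
approximated at rank ``k``, the approximation overwrites the missing cells
only, and the loop repeats until the relative change of the imputed values
is below tolerance.
"""

from __future__ import annotations

import warnings

import numpy as np
from scipy.sparse.linalg import svds
from sklearn.base import BaseEstimator, TransformerMixin

__all__ = ["SVDImputer", "impute_missing_svd"]


class SVDImputer(TransformerMixin, BaseEstimator):
    """Iterative truncated-SVD completion of a matrix with NaN entries.

    Parameters
    ----------
    rank : int, default 5
        Rank of the truncated reconstruction; must be below the smaller
        matrix dimension.
    tol : float, default 1e-6
        Convergence threshold on the relative Frobenius change of the
        imputed entries between iterations.
    max_iter : int, default 100
        Iteration cap; non-convergence completes with a warning rather
        than failing (``converged_`` records the outcome).

    Attributes
    ----------
    converged_ : bool
    n_iter_ : int
    """

    def __init__(self, rank: int = 5, tol: float = 1e-6, max_iter: int = 100):
        self.rank = rank
        self.tol = tol
        self.max_iter = max_iter

    def fit(self, X, y=None):
        self.fit_transform(X)
        return self

    def fit_transform(self, X, y=None) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        if X.ndim != 2:
            raise ValueError("expected a 2-D matrix")
        mask = np.isnan(X)
        frac = mask.mean()
        if frac >= 0.5:
            raise ValueError(f"missing fraction {frac:.2f} >= 0.5; refusing to impute")
        if self.rank >= min(X.shape):
            raise ValueError(
                f"rank {self.rank} must be below the smaller dimension {min(X.shape)}"
            )
        if not mask.any():
            self.converged_, self.n_iter_ = True, 0
            return X.copy()

        filled = X.copy()
        filled[mask] = 0.0
        prev = filled[mask]
        self.converged_ = False
        self.n_iter_ = 0
        for it in range(1, self.max_iter + 1):
            approx = self._truncated(filled)
            filled[mask] = approx[mask]
            cur = filled[mask]
            denom = np.linalg.norm(cur)
            change = np.linalg.norm(cur - prev) / (denom if denom > 0 else 1.0)
            prev = cur.copy()
            self.n_iter_ = it
            if change < self.tol:
                self.converged_ = True
                break
        if not self.converged_:
            warnings.warn(
                f"SVD imputation did not converge in {self.max_iter} iterations",
                RuntimeWarning,
            )
        return filled

    def transform(self, X):
        return self.fit_transform(X)

    def _truncated(self, M: np.ndarray) -> np.ndarray:
        k = self.rank
        if k <= min(M.shape) - 1 and min(M.shape) > 2:
            u, s, vt = svds(M, k=k)
        else:
            u, s, vt = np.linalg.svd(M, full_matrices=False)
            u, s, vt = u[:, :k], s[:k], vt[:k]
        return (u * s) @ vt


def impute_missing_svd(matrix, rank: int = 5, tol: float = 1e-6, max_iter: int = 100):
    """Complete a matrix with NaN-marked missing entries.

    Returns ``(completed, converged)``; observed entries pass through
    unchanged.
    """
    imp = SVDImputer(rank=rank, tol=tol, max_iter=max_iter)
    out = imp.fit_transform(matrix)
    return out, imp.converged_
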