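"""Generalized SVD of a pair of patient-matched matrices.

Two datasets ``D1`` (tumor, M1 x N) and ``D2`` (normal, M2 x N) that share
their patient axis are decomposed simultaneously into

    D1 = sum_n  sigma1_n * u1_n  v_n^T
    D2 = sum_n  sigma2_n * u2_n  v_n^T

where the *probelets* ``v_n`` (patterns of variation across the patients,
unit norm but in general non-orthogonal) are shared by both datasets, and
the *arraylets* ``u1_n`` / ``u2_n`` (patterns across each dataset's probes)
are orthonormal within each dataset.  The non-negative weights
``sigma1_n, sigma2_n`` measure how much of each dataset's information a
component carries; their ratio defines an angular distance

    theta_n = arctan(sigma1_n / sigma2_n) - pi/4   in [-pi/4, pi/4]

with +pi/4 tumor-exclusive, -pi/4 normal-exclusive and 0 common to both.
Components are reported in decreasing angular distance.

The factorization is computed stably for tall matrices by a QR of the
stacked pair followed by the cosine-sine decomposition of the stacked
orthonormal factor (an SVD of one block); the equivalent N x N generalized
symmetric-definite eigenproblem on the Gram matrices is kept out of the
implementation and used only as an independent test oracle.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
from scipy import linalg
from sklearn.base import BaseEstimator

from .paired import PairedMatrices

__all__ = [
    "PairedGSVD",
    "compute_gsvd",
    "reconstruct",
    "weight_fractions",
    "generalized_entropy",
    "angular_distances",
]

_DATASETS = ("tumor", "normal")


def angular_distances(sigma1, sigma2) -> np.ndarray:
    """Angular distance theta_n = arctan(sigma1_n/sigma2_n) - pi/4.

    ``sigma2_n = 0`` maps to +pi/4 (tumor-exclusive) and ``sigma1_n = 0``
    to -pi/4 (normal-exclusive); a component with both weights zero is
    undefined and raises.
    """
    s1 = np.asarray(sigma1, dtype=float)
    s2 = np.asarray(sigma2, dtype=float)
    if s1.shape != s2.shape:
        raise ValueError("weight vectors must have the same length")
    if np.any(s1 < 0) or np.any(s2 < 0):
        raise ValueError("weights must be non-negative")
    both_zero = (s1 == 0) & (s2 == 0)
    if np.any(both_zero):
        idx = int(np.flatnonzero(both_zero)[0])
        raise ValueError(f"component {idx} has zero weight in both datasets")
    return np.arctan2(s1, s2) - np.pi / 4


def generalized_entropy(p) -> float:
    """Generalized normalized Shannon entropy of a weight-fraction vector.

    ``-(1/log N) * sum p_n log p_n`` with ``0 log 0 = 0``.  Zero means all
    information sits in a single component; one means a flat spectrum.
    """
    p = np.asarray(p, dtype=float)
    n = p.size
    if n < 2:
        raise ValueError("entropy needs at least two components")
    if np.any(p < -1e-12):
        raise ValueError("fractions must be non-negative")
    if abs(p.sum() - 1.0) > 1e-8:
        raise ValueError(f"fractions must sum to 1 (got {p.sum()!r})")
    p = np.clip(p, 0.0, 1.0)
    nz = p[p > 0]
    return float(-(nz * np.log(nz)).sum() / np.log(n)) + 0.0  # avoid -0.0


def _check_dataset(dataset: str) -> str:
    if dataset not in _DATASETS:
        raise ValueError(f"dataset must be one of {_DATASETS}, got {dataset!r}")
    return dataset


class PairedGSVD(BaseEstimator):
    """Exact paired decomposition (GSVD) of two patient-matched matrices.

    Parameters
    ----------
    rank_tol : float, default 1e-10
        Relative singular-value cutoff below which a dataset is declared
        rank deficient (each matrix must have full column rank).

    Attributes (after :meth:`fit`)
    ------------------------------
    tumor_arraylets_ : ndarray (M1, N), orthonormal columns
    normal_arraylets_ : ndarray (M2, N), orthonormal columns
    probelets_ : ndarray (N, N); row ``n`` is the unit-norm probelet v_n
    tumor_weights_, normal_weights_ : ndarray (N,), non-negative
    angular_distances_ : ndarray (N,), decreasing, in [-pi/4, pi/4]
    order_ : ndarray (N,) — permutation mapping reported positions back to
        the raw cosine-sine ordering (largest generalized singular value
        first); components are stored already sorted, so
        ``angular_distances_`` is decreasing.
    """

    def __init__(self, rank_tol: float = 1e-10):
        self.rank_tol = rank_tol

    # ------------------------------------------------------------------ fit

    def fit(self, paired, y=None) -> "PairedGSVD":
        if not isinstance(paired, PairedMatrices):
            d1, d2 = paired
            paired = PairedMatrices(np.asarray(d1), np.asarray(d2))
        d1, d2 = paired.tumor_matrix, paired.normal_matrix
        n = paired.n_patients

        for name, mat in (("tumor", d1), ("normal", d2)):
            sv = linalg.svdvals(mat)
            if sv[0] == 0 or sv[-1] < self.rank_tol * sv[0]:
                raise ValueError(
                    f"{name} dataset is rank deficient "
                    f"(smallest/largest singular value {sv[-1]:.3e}/{sv[0]:.3e})"
                )

        # QR of the stacked pair, then CS decomposition of the stacked
        # orthonormal factor via an SVD of its tumor block.
        q, r = linalg.qr(np.vstack([d1, d2]), mode="economic")
        q1, q2 = q[: d1.shape[0]], q[d1.shape[0]:]
        u1, c, wt = linalg.svd(q1, full_matrices=False)
        c = np.clip(c, 0.0, 1.0)
        q2w = q2 @ wt.T
        s = np.sqrt(np.sum(q2w**2, axis=0))
        if np.any(s <= 0):
            raise ValueError("normal dataset is rank deficient in the pair")
        u2 = q2w / s

        y_rows = wt @ r                      # N x N, rows y_n^T
        norms = np.sqrt(np.sum(y_rows**2, axis=1))
        v = y_rows / norms[:, None]
        sigma1 = c * norms
        sigma2 = s * norms

        # sign convention: probelet median non-negative (largest-magnitude
        # entry positive on a zero median); flip arraylets consistently.
        med = np.median(v, axis=1)
        flip = med < 0
        zero_med = med == 0
        if np.any(zero_med):
            big = v[zero_med, :][
                np.arange(zero_med.sum()), np.argmax(np.abs(v[zero_med, :]), axis=1)
            ]
            flip[zero_med] = big < 0
        sign = np.where(flip, -1.0, 1.0)
        v *= sign[:, None]
        u1 *= sign
        u2 *= sign

        theta = angular_distances(sigma1, sigma2)
        order = np.lexsort((-sigma1, -theta))  # theta desc, then sigma1 desc

        self.tumor_arraylets_ = u1[:, order]
        self.normal_arraylets_ = u2[:, order]
        self.probelets_ = v[order]
        self.tumor_weights_ = sigma1[order]
        self.normal_weights_ = sigma2[order]
        self.angular_distances_ = theta[order]
        self.order_ = order
        self.n_components_ = n
        self.patient_ids_ = list(paired.patient_ids)
        self.tumor_probe_ids_ = list(paired.tumor_probe_ids)
        self.normal_probe_ids_ = list(paired.normal_probe_ids)
        return self

    # ----------------------------------------------------------- accessors

    def _weights(self, dataset: str) -> np.ndarray:
        _check_dataset(dataset)
        return self.tumor_weights_ if dataset == "tumor" else self.normal_weights_

    def _arraylets(self, dataset: str) -> np.ndarray:
        _check_dataset(dataset)
        return self.tumor_arraylets_ if dataset == "tumor" else self.normal_arraylets_

    def generalized_singular_values(self) -> np.ndarray:
        """Weight ratios sigma1_n / sigma2_n, in reported order."""
        return self.tumor_weights_ / self.normal_weights_

    def reconstruct(self, dataset: str, components=None) -> np.ndarray:
        """Sum of the selected rank-1 components for one dataset.

        ``components`` holds 0-based positions in the reported (angular
        distance sorted) order; ``None`` selects all, and an empty
        selection yields the zero matrix.
        """
        u = self._arraylets(dataset)
        sig = self._weights(dataset)
        n = self.n_components_
        if components is None:
            idx = np.arange(n)
        else:
            idx = np.atleast_1d(np.asarray(components, dtype=int))
            if idx.size and (idx.min() < 0 or idx.max() >= n):
                raise IndexError(f"component indices must lie in [0, {n})")
        if idx.size == 0:
            return np.zeros((u.shape[0], self.probelets_.shape[1]))
        return (u[:, idx] * sig[idx]) @ self.probelets_[idx]

    def weight_fractions(self, dataset: str) -> np.ndarray:
        """p_n = sigma_n^2 / sum_k sigma_k^2 for one dataset."""
        sig = self._weights(dataset)
        total = float(np.sum(sig**2))
        if total == 0:
            raise ValueError(f"all {dataset} weights are zero")
        return sig**2 / total

    def entropy(self, dataset: str) -> float:
        """Generalized normalized Shannon entropy of one dataset."""
        return generalized_entropy(self.weight_fractions(dataset))

    def summary(self):
        """Per-component summary table (pandas DataFrame)."""
        import pandas as pd

        return pd.DataFrame(
            {
                "component": np.arange(1, self.n_components_ + 1),
                "sigma_tumor": self.tumor_weights_,
                "sigma_normal": self.normal_weights_,
                "angular_distance": self.angular_distances_,
                "fraction_tumor": self.weight_fractions("tumor"),
                "fraction_normal": self.weight_fractions("normal"),
            }
        )


# ------------------------------------------------------------ thin wrappers

def compute_gsvd(paired, rank_tol: float = 1e-10) -> PairedGSVD:
    """Decompose a :class:`~gsvdcna.paired.PairedMatrices`; returns the
    fitted :class:`PairedGSVD` (which carries the full factorization)."""
    return PairedGSVD(rank_tol=rank_tol).fit(paired)


def reconstruct(fact: PairedGSVD, dataset: str, components=None) -> np.ndarray:
    return fact.reconstruct(dataset, components)


def weight_fractions(fact: PairedGSVD, dataset: str) -> np.ndarray:
    return fact.weight_fractions(dataset)
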