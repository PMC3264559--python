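"""Container for a pair of patient-matched copy-number matrices.

Tumor and normal aCGH datasets measured on the same patients generally use
different (probe-independent) probe sets, so the two matrices share only
their column (patient) axis.  ``PairedMatrices`` validates exactly that
structure before a decomposition is attempted.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np


@dataclass
class PairedMatrices:
    """Two real matrices sharing the patient (column) dimension.

    Parameters
    ----------
    tumor_matrix : ndarray of shape (M1, N)
        Centered log2 copy-number ratios, tumor probes x patients.
    normal_matrix : ndarray of shape (M2, N)
        Centered log2 copy-number ratios, normal probes x patients.
    patient_ids : sequence of length N
        Shared patient identifiers, in column order.
    tumor_probe_ids, normal_probe_ids : sequences
        Row identifiers per dataset; must be free of duplicates.

    Both matrices must be complete (imputation happens upstream) and tall:
    at least as many probes as patients in each dataset.
    """

    tumor_matrix: np.ndarray
    normal_matrix: np.ndarray
    patient_ids: Sequence[str] = field(default=None)
    tumor_probe_ids: Sequence[str] = field(default=None)
    normal_probe_ids: Sequence[str] = field(default=None)

    def __post_init__(self) -> None:
        self.tumor_matrix = np.asarray(self.tumor_matrix, dtype=float)
        self.normal_matrix = np.asarray(self.normal_matrix, dtype=float)
        if self.tumor_matrix.ndim != 2 or self.normal_matrix.ndim != 2:
            raise ValueError("tumor_matrix and normal_matrix must be 2-D")
        m1, n1 = self.tumor_matrix.shape
        m2, n2 = self.normal_matrix.shape
        if n1 != n2:
            raise ValueError(
                f"patient axes differ: tumor has {n1} columns, normal has {n2}"
            )
        if self.patient_ids is None:
            self.patient_ids = [f"P{i}" for i in range(n1)]
        self.patient_ids = list(self.patient_ids)
        if len(self.patient_ids) != n1:
            raise ValueError("patient_ids length does not match column count")
        if self.tumor_probe_ids is None:
            self.tumor_probe_ids = [f"T{i}" for i in range(m1)]
        if self.normal_probe_ids is None:
            self.normal_probe_ids = [f"N{i}" for i in range(m2)]
        self.tumor_probe_ids = list(self.tumor_probe_ids)
        self.normal_probe_ids = list(self.normal_probe_ids)
        for name, ids, m in (
            ("tumor_probe_ids", self.tumor_probe_ids, m1),
            ("normal_probe_ids", self.normal_probe_ids, m2),
        ):
            if len(ids) != m:
                raise ValueError(f"{name} length does not match row count")
            if len(set(ids)) != len(ids):
                raise ValueError(f"{name} contains duplicates")
        if m1 < n1 or m2 < n1:
            raise ValueError(
                "each dataset needs at least as many probes as patients "
                f"(shapes {self.tumor_matrix.shape} and {self.normal_matrix.shape})"
            )
        for name, mat in (("tumor", self.tumor_matrix), ("normal", self.normal_matrix)):
            if not np.all(np.isfinite(mat)):
                raise ValueError(
                    f"{name} matrix contains missing or non-finite entries; "
                    "impute before constructing PairedMatrices"
                )

    @property
    def n_patients(self) -> int:
        return self.tumor_matrix.shape[1]
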