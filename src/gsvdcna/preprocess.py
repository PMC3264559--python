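"""From per-sample aCGH profile tables to clean patient-matched matrices.

The pipeline stages, in the order they are applied:

1. ``qc_filter_arrays``   — drop arrays whose signal-to-background pass
   fraction is not above threshold (default: more than 90% of probes).
2. ``filter_probes``      — within each tissue, keep probes with valid
   data in at least 99% of that tissue's arrays; the tumor and normal
   datasets may and usually do retain different probe sets.
3. ``center_autosomal_median`` — subtract each profile's autosomal median
   from every value (X included), so 0 means no copy-number change.
4. ``impute`` (see :mod:`gsvdcna.impute`) — complete the small fraction of
   missing entries per tissue by low-rank SVD.
5. ``collapse_patient_medians`` — per-probe median over a patient's
   replicate arrays, one profile per patient.
6. ``assemble_paired``    — restrict both tissues to the shared patients,
   in a fixed (sorted) order, producing a
   :class:`~gsvdcna.paired.PairedMatrices`.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .impute import impute_missing_svd
from .paired import PairedMatrices

__all__ = [
    "ProfileSet",
    "qc_filter_arrays",
    "filter_probes",
    "center_autosomal_median",
    "collapse_patient_medians",
    "assemble_paired",
    "preprocess_pair",
]

logger = logging.getLogger(__name__)

PROBE_COLUMNS = ["chromosome", "arm", "start"]
SAMPLE_COLUMNS = ["patient_id", "tissue", "qc_pass_fraction"]


@dataclass
class ProfileSet:
    """A tissue's profiles: probe annotation, value matrix, sample metadata.

    probes : DataFrame indexed by probe_id with columns
        ``chromosome`` (``"1"``–``"22"`` or ``"X"``), ``arm`` (``"p"``/``"q"``)
        and ``start`` (1-based bp).
    values : DataFrame, probes x samples, log2 sample/reference ratios with
        NaN marking missing measurements.
    samples : DataFrame indexed by sample_id with columns ``patient_id``,
        ``tissue`` and ``qc_pass_fraction``.
    """

    probes: pd.DataFrame
    values: pd.DataFrame
    samples: pd.DataFrame

    def __post_init__(self) -> None:
        if not self.probes.index.is_unique:
            raise ValueError("duplicate probe ids")
        if not self.values.index.equals(self.probes.index):
            raise ValueError("values rows must match the probe table")
        if list(self.values.columns) != list(self.samples.index):
            raise ValueError("values columns must match the sample table")
        if (self.probes["start"] <= 0).any():
            raise ValueError("probe positions must be positive (1-based)")

    @property
    def autosomal_mask(self) -> np.ndarray:
        return (self.probes["chromosome"] != "X").to_numpy()

    def subset_probes(self, probe_ids) -> "ProfileSet":
        return ProfileSet(
            self.probes.loc[probe_ids], self.values.loc[probe_ids], self.samples
        )

    def subset_samples(self, sample_ids) -> "ProfileSet":
        return ProfileSet(
            self.probes, self.values[list(sample_ids)], self.samples.loc[list(sample_ids)]
        )


def qc_filter_arrays(profiles: ProfileSet, sb_pass_fraction_min: float = 0.90) -> ProfileSet:
    """Keep arrays whose QC pass fraction is *strictly* above the minimum."""
    frac = profiles.samples["qc_pass_fraction"].astype(float)
    keep = frac > sb_pass_fraction_min
    dropped = profiles.samples.index[~keep]
    if len(dropped):
        logger.info("QC dropped %d arrays: %s", len(dropped), list(dropped))
    return profiles.subset_samples(profiles.samples.index[keep])


def filter_probes(
    tumor: ProfileSet, normal: ProfileSet, min_valid_fraction: float = 0.99
):
    """Per-tissue probe selection by valid-data fraction.

    A probe enters a tissue's dataset when the fraction of that tissue's
    arrays with an observed value at the probe is at least
    ``min_valid_fraction``; the two tissues are filtered independently and
    may retain different probe sets.  Returns the two filtered
    :class:`ProfileSet` objects.
    """
    if not 0 < min_valid_fraction <= 1:
        raise ValueError("min_valid_fraction must lie in (0, 1]")
    out = []
    for pset in (tumor, normal):
        if pset.values.shape[1] == 0:
            raise ValueError("a tissue has no arrays after QC")
        valid = pset.values.notna().mean(axis=1)
        out.append(pset.subset_probes(pset.probes.index[valid >= min_valid_fraction]))
    return tuple(out)


def center_autosomal_median(profiles: ProfileSet) -> ProfileSet:
    """Subtract each profile's observed autosomal median from all values."""
    auto = profiles.values.loc[profiles.autosomal_mask]
    med = auto.median(axis=0, skipna=True)
    if med.isna().any():
        bad = list(med.index[med.isna()])
        raise ValueError(f"no autosomal data in profiles: {bad}")
    return ProfileSet(profiles.probes, profiles.values - med, profiles.samples)


def collapse_patient_medians(profiles: ProfileSet) -> ProfileSet:
    """One profile per patient: per-probe median over the patient's arrays."""
    patients = profiles.samples["patient_id"]
    collapsed = profiles.values.T.groupby(patients.to_numpy()).median().T
    tissue = profiles.samples["tissue"].iloc[0] if len(profiles.samples) else "tumor"
    meta = pd.DataFrame(
        {
            "patient_id": collapsed.columns,
            "tissue": tissue,
            "qc_pass_fraction": 1.0,
        },
        index=pd.Index(collapsed.columns, name="sample_id"),
    )
    return ProfileSet(profiles.probes, collapsed, meta)


def assemble_paired(tumor: ProfileSet, normal: ProfileSet) -> PairedMatrices:
    """Pair the two per-patient matrices on their shared patients.

    Columns are restricted to the patient intersection, in sorted order;
    excluded patients are logged.  Both matrices must be complete.
    """
    t_pat = list(tumor.values.columns)
    n_pat = list(normal.values.columns)
    shared = sorted(set(t_pat) & set(n_pat))
    if not shared:
        raise ValueError("no patients shared between the tumor and normal sets")
    excluded = sorted(set(t_pat).symmetric_difference(n_pat))
    if excluded:
        logger.info("excluding %d unmatched patients: %s", len(excluded), excluded)
    return PairedMatrices(
        tumor.values[shared].to_numpy(),
        normal.values[shared].to_numpy(),
        patient_ids=shared,
        tumor_probe_ids=list(tumor.probes.index),
        normal_probe_ids=list(normal.probes.index),
    )


def preprocess_pair(
    tumor: ProfileSet,
    normal: ProfileSet,
    sb_pass_fraction_min: float = 0.90,
    min_valid_fraction: float = 0.99,
    impute_rank: int = 5,
    impute_tol: float = 1e-6,
):
    """Full preprocessing chain; returns (PairedMatrices, per-tissue ProfileSets).

    Stages: QC-select arrays, per-tissue probe filtering, per-profile
    autosomal-median centering, per-tissue SVD imputation, per-patient
    replicate collapsing, patient-matched assembly.
    """
    tumor = qc_filter_arrays(tumor, sb_pass_fraction_min)
    normal = qc_filter_arrays(normal, sb_pass_fraction_min)
    tumor, normal = filter_probes(tumor, normal, min_valid_fraction)
    processed = []
    for pset in (tumor, normal):
        pset = center_autosomal_median(pset)
        if pset.values.isna().any().any():
            rank = min(impute_rank, min(pset.values.shape) - 1)
            completed, converged = impute_missing_svd(
                pset.values.to_numpy(), rank=rank, tol=impute_tol
            )
            if not converged:
                logger.warning("imputation flagged non-convergence")
            pset = ProfileSet(
                pset.probes,
                pd.DataFrame(completed, index=pset.values.index, columns=pset.values.columns),
                pset.samples,
            )
        processed.append(collapse_patient_medians(pset))
    tumor_p, normal_p = processed
    return assemble_paired(tumor_p, normal_p), tumor_p, normal_p
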