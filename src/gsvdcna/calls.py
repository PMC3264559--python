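"""Copy-number calling rules for whole chromosomes, arms and segments.

All rules share one robust spread estimate per profile: the standard
deviation of the mean copy numbers of the autosomal chromosome units
about the autosomal genomic mean, computed after dropping a configurable
set of outlying units (by default chromosome 7, arm 9p and chromosome
10 — the gain/loss trio that dominates the tumor pattern).  A chromosome
with an excluded arm is evaluated arm by arm, so the intact arm still
contributes to the baseline.

Rules (two-sided, strict inequalities):

* gender — female when the normal profile's mean X level exceeds the
  autosomal genomic mean by more than twice the (unexcluded) baseline SD;
* chromosome/arm gain or loss — unit mean deviating from the genomic mean
  by more than twice the exclusion-robust SD;
* segment gain or loss — segment mean deviating by more than twice the
  robust SD from the genomic mean, or by more than one SD from its
  chromosome's mean provided that deviation has the same sign as the
  deviation from the genomic mean.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .segmentation import Segment

__all__ = [
    "CopyNumberCall",
    "robust_baseline_sd",
    "assign_gender",
    "call_chromosomes",
    "call_segment",
    "cohort_frequencies",
]

DEFAULT_EXCLUDE = frozenset({"7", "9p", "10"})


@dataclass
class CopyNumberCall:
    patient_id: str
    target: str
    call: str                 # "gain" | "loss" | "none"
    deviation_sd: float       # deviation in baseline-SD units
    baseline: str             # "genomic" | "chromosomal"


def _chromosome_units(probes: pd.DataFrame, exclude: frozenset):
    """Autosomal units: whole chromosomes, split into arms when one arm is
    excluded.  Yields (label, row mask, excluded?)."""
    excluded_arms = {e for e in exclude if e[-1] in "pq"}
    split_chroms = {e[:-1] for e in excluded_arms}
    chrom = probes["chromosome"].astype(str)
    arm = probes["arm"].astype(str)
    for c in chrom.unique():
        if c == "X":
            continue
        cmask = (chrom == c).to_numpy()
        if c in split_chroms:
            for a in ("p", "q"):
                m = cmask & (arm == a).to_numpy()
                if m.any():
                    yield f"{c}{a}", m, f"{c}{a}" in exclude or c in exclude
        else:
            yield c, cmask, c in exclude


def robust_baseline_sd(values, probes: pd.DataFrame, exclude=DEFAULT_EXCLUDE):
    """(autosomal genomic mean, SD of included unit means about it).

    The genomic mean averages the autosomal probes outside the excluded
    units; the SD is the root-mean-square deviation of the included unit
    means about that genomic mean.
    """
    values = np.asarray(values, dtype=float)
    exclude = frozenset(exclude)
    units = list(_chromosome_units(probes, exclude))
    included = [(lbl, m) for lbl, m, exc in units if not exc]
    if len(included) < 3:
        raise ValueError(
            f"only {len(included)} chromosome units remain after excluding {sorted(exclude)}"
        )
    keep = np.zeros(len(probes), dtype=bool)
    for _, m in included:
        keep |= m
    gmean = float(values[keep].mean())
    unit_means = np.array([values[m].mean() for _, m in included])
    sd = float(np.sqrt(np.mean((unit_means - gmean) ** 2)))
    return gmean, sd


def assign_gender(normal_values, probes: pd.DataFrame) -> str:
    """Copy-number gender call from a patient's normal profile.

    Female when the mean X-chromosome level exceeds the autosomal genomic
    mean by strictly more than twice the baseline SD (no exclusions for a
    normal genome); male otherwise.
    """
    normal_values = np.asarray(normal_values, dtype=float)
    xmask = (probes["chromosome"].astype(str) == "X").to_numpy()
    if not xmask.any():
        raise ValueError("no X-chromosome probes in the normal probe table")
    gmean, sd = robust_baseline_sd(normal_values, probes, exclude=frozenset())
    return "female" if normal_values[xmask].mean() - gmean > 2 * sd else "male"


def call_chromosomes(
    tumor_values,
    probes: pd.DataFrame,
    patient_id: str = "",
    exclude=DEFAULT_EXCLUDE,
) -> list[CopyNumberCall]:
    """Gain/loss calls for every autosomal chromosome unit of one profile.

    Units whose mean deviates from the autosomal genomic mean by more
    than twice the exclusion-robust SD are called; arms of a chromosome
    with an excluded arm (for example 9p and 9q) are evaluated separately.
    """
    tumor_values = np.asarray(tumor_values, dtype=float)
    exclude = frozenset(exclude)
    gmean, sd = robust_baseline_sd(tumor_values, probes, exclude)
    calls = []
    for label, mask, _ in _chromosome_units(probes, exclude):
        dev = tumor_values[mask].mean() - gmean
        if sd > 0:
            dev_sd = dev / sd
        else:
            dev_sd = 0.0 if dev == 0 else float(np.sign(dev)) * float("inf")
        if sd > 0 and dev > 2 * sd:
            call = "gain"
        elif sd > 0 and dev < -2 * sd:
            call = "loss"
        else:
            call = "none"
        calls.append(CopyNumberCall(patient_id, label, call, float(dev_sd), "genomic"))
    return calls


def call_segment(
    tumor_values,
    segment: Segment,
    probes: pd.DataFrame,
    patient_id: str = "",
    exclude=DEFAULT_EXCLUDE,
) -> CopyNumberCall:
    """Gain/loss call for one segment of one tumor profile.

    Called when the segment mean deviates by more than twice the robust
    SD from the autosomal genomic mean, or by more than one SD from its
    chromosome's mean with the same sign as the genomic-mean deviation.
    """
    tumor_values = np.asarray(tumor_values, dtype=float)
    seg_mask = np.zeros(len(probes), dtype=bool)
    seg_mask[segment.start_index:segment.end_index + 1] = True
    if not seg_mask.any():
        raise ValueError("segment covers no probes in this profile")
    gmean, sd = robust_baseline_sd(tumor_values, probes, frozenset(exclude))
    chrom_mask = (probes["chromosome"].astype(str) == segment.chromosome).to_numpy()
    seg_mean = tumor_values[seg_mask].mean()
    g_dev = seg_mean - gmean
    c_dev = seg_mean - tumor_values[chrom_mask].mean()
    target = f"{segment.chromosome}:{segment.start_bp}-{segment.end_bp}"
    if sd == 0:
        return CopyNumberCall(patient_id, target, "none", 0.0, "genomic")
    if abs(g_dev) > 2 * sd:
        call = "gain" if g_dev > 0 else "loss"
        return CopyNumberCall(patient_id, target, call, float(g_dev / sd), "genomic")
    if abs(c_dev) > sd and np.sign(c_dev) == np.sign(g_dev) and g_dev != 0:
        call = "gain" if c_dev > 0 else "loss"
        return CopyNumberCall(patient_id, target, call, float(c_dev / sd), "chromosomal")
    return CopyNumberCall(patient_id, target, "none", float(g_dev / sd), "genomic")


def cohort_frequencies(calls: list[CopyNumberCall]) -> pd.DataFrame:
    """Fraction of patients with a gain and with a loss, per target.

    ``calls`` pools the per-patient calls; each (patient, target) pair is
    expected once.  Gain, loss and none fractions partition each target.
    """
    if not calls:
        raise ValueError("no calls supplied")
    df = pd.DataFrame([c.__dict__ for c in calls])
    n_patients = df["patient_id"].nunique()
    out = []
    for target, grp in df.groupby("target", sort=False):
        out.append(
            {
                "target": target,
                "gain_fraction": (grp["call"] == "gain").sum() / n_patients,
                "loss_fraction": (grp["call"] == "loss").sum() / n_patients,
                "none_fraction": (grp["call"] == "none").sum() / n_patients,
            }
        )
    return pd.DataFrame(out)
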