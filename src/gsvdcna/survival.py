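"""Patient classification by pattern weight and survival comparisons.

A tumor-exclusive probelet lists, per patient, the weight of the global
CNA pattern in that patient's profile.  Patients split three ways around
a small cutoff ``c`` (0.02 for the reference cohort):

* ``high``         — score > c (pattern present; shorter survival),
* ``low``          — |score| <= c (pattern negligible; longer survival),
* ``unclassified`` — score < -c (large negative weight, rare).

Cohorts decomposed separately rescale the cutoff by the Euclidean-norm
ratio of the scores over the patients both cohorts share; profiles
without a matched normal are classified by the Pearson correlation of
their profile with a stored reference arraylet under the same rule.

Kaplan-Meier curves, log-rank tests and Cox proportional-hazards fits
(Efron tie handling) are provided through lifelines; p-values are
reported unadjusted.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines import statistics as lls
from lifelines.exceptions import ConvergenceError
from sklearn.base import BaseEstimator

__all__ = [
    "PatientClass",
    "ProbeletClassifier",
    "CorrelationClassifier",
    "classify_by_probelet",
    "classify_by_correlation",
    "scale_cutoff",
    "km_estimate",
    "logrank_test",
    "cox_ph",
    "dichotomize_age",
]

logger = logging.getLogger(__name__)


@dataclass
class PatientClass:
    patient_id: str
    label: str      # "high" | "low" | "unclassified" | "rejected"
    score: float
    reason: str = ""


def _threeway(scores: np.ndarray, cutoff: float) -> np.ndarray:
    labels = np.where(
        scores > cutoff, "high", np.where(scores < -cutoff, "unclassified", "low")
    )
    return labels


class ProbeletClassifier(BaseEstimator):
    """Three-way thresholding of probelet entries (scores).

    ``score > cutoff`` is ``high``, ``|score| <= cutoff`` is ``low``,
    ``score < -cutoff`` is ``unclassified`` (both comparators strict, the
    boundary falls to ``low``).
    """

    def __init__(self, cutoff: float = 0.02):
        self.cutoff = cutoff

    def fit(self, X=None, y=None):
        if self.cutoff <= 0:
            raise ValueError("cutoff must be positive")
        return self

    def predict(self, scores) -> np.ndarray:
        self.fit()
        return _threeway(np.asarray(scores, dtype=float), self.cutoff)


class CorrelationClassifier(BaseEstimator):
    """Classify stand-alone tumor profiles against a reference arraylet.

    The score is the Pearson correlation between a profile's observed
    values and the reference arraylet over the shared probes; profiles
    observing fewer than ``min_overlap`` of the arraylet's probes are
    rejected.  The three-way cutoff rule matches
    :class:`ProbeletClassifier`.
    """

    def __init__(self, cutoff: float = 0.15, min_overlap: float = 0.975):
        self.cutoff = cutoff
        self.min_overlap = min_overlap

    def fit(self, reference_arraylet):
        ref = np.asarray(reference_arraylet, dtype=float)
        if ref.ndim != 1:
            raise ValueError("reference arraylet must be 1-D")
        self.reference_ = ref
        return self

    def predict_score(self, profile) -> tuple[float, str]:
        """(Pearson correlation, rejection reason or '')."""
        x = np.asarray(profile, dtype=float)
        if x.shape != self.reference_.shape:
            raise ValueError("profile and reference arraylet lengths differ")
        obs = np.isfinite(x)
        frac = obs.mean()
        if frac < self.min_overlap:
            return np.nan, f"probe overlap {frac:.4f} below {self.min_overlap}"
        r = np.corrcoef(x[obs], self.reference_[obs])[0, 1]
        return float(r), ""

    def predict(self, profiles: pd.DataFrame) -> list[PatientClass]:
        """Classify each column of a probes x patients DataFrame."""
        if self.cutoff <= 0:
            raise ValueError("cutoff must be positive")
        out = []
        for pid in profiles.columns:
            score, reason = self.predict_score(profiles[pid].to_numpy())
            if reason:
                out.append(PatientClass(str(pid), "rejected", score, reason))
            else:
                label = str(_threeway(np.array([score]), self.cutoff)[0])
                out.append(PatientClass(str(pid), label, score))
        return out


def classify_by_probelet(entries, cutoff: float = 0.02, patient_ids=None):
    """Three-way classification of probelet entries; see
    :class:`ProbeletClassifier`."""
    entries = np.asarray(entries, dtype=float)
    labels = ProbeletClassifier(cutoff=cutoff).fit().predict(entries)
    if patient_ids is None:
        patient_ids = [str(i) for i in range(entries.size)]
    return [
        PatientClass(str(p), str(l), float(s))
        for p, l, s in zip(patient_ids, labels, entries)
    ]


def classify_by_correlation(
    profiles: pd.DataFrame, reference_arraylet, cutoff: float = 0.15,
    min_overlap: float = 0.975
) -> list[PatientClass]:
    """Correlation-based classification of tumor-only profiles; see
    :class:`CorrelationClassifier`."""
    clf = CorrelationClassifier(cutoff=cutoff, min_overlap=min_overlap)
    return clf.fit(reference_arraylet).predict(profiles)


def scale_cutoff(base_cutoff: float, reference_scores, new_scores) -> float:
    """Carry a classification cutoff to a new cohort or score type.

    Both score vectors are restricted to (and aligned on) the patients
    the cohorts share; the cutoff scales by the ratio of the Euclidean
    norms, new over reference.
    """
    ref = np.asarray(reference_scores, dtype=float)
    new = np.asarray(new_scores, dtype=float)
    if ref.size == 0 or ref.size != new.size:
        raise ValueError("score vectors must be non-empty and aligned")
    ref_norm = np.linalg.norm(ref)
    if ref_norm == 0:
        raise ValueError("reference scores have zero norm")
    return float(base_cutoff * np.linalg.norm(new) / ref_norm)


# ------------------------------------------------------------- survival

def _check_times(times) -> np.ndarray:
    t = np.asarray(times, dtype=float)
    if np.any(t < 0):
        raise ValueError("survival times must be non-negative")
    return t


def km_estimate(times, events, groups):
    """Kaplan-Meier product-limit curves per group.

    Returns ``{group: {"n", "n_events", "median", "survival"}}`` where
    ``median`` is the earliest time with survival <= 1/2 (``inf`` when
    never reached) and ``survival`` is a time-indexed Series.
    """
    t = _check_times(times)
    e = np.asarray(events, dtype=bool)
    g = np.asarray(groups)
    out = {}
    for label in pd.unique(g):
        m = g == label
        if not m.any():
            continue
        kmf = KaplanMeierFitter()
        kmf.fit(t[m], e[m])
        out[label] = {
            "n": int(m.sum()),
            "n_events": int(e[m].sum()),
            "median": float(kmf.median_survival_time_),
            "survival": kmf.survival_function_.iloc[:, 0],
        }
    return out


def logrank_test(times, events, groups):
    """Two-group log-rank test; returns (chi-square, p) with 1 df."""
    t = _check_times(times)
    e = np.asarray(events, dtype=bool)
    g = np.asarray(groups)
    labels = pd.unique(g)
    if len(labels) != 2:
        raise ValueError(f"log-rank test needs exactly two groups, got {len(labels)}")
    if not e.any():
        raise ValueError("no observed events")
    a = g == labels[0]
    res = lls.logrank_test(t[a], t[~a], event_observed_A=e[a], event_observed_B=e[~a])
    return float(res.test_statistic), float(res.p_value)


def cox_ph(times, events, covariates: pd.DataFrame) -> pd.DataFrame:
    """Cox proportional-hazards fit (Efron ties) over one or more covariates.

    Returns a table indexed by covariate with columns ``coef``,
    ``hazard_ratio``, ``p``, ``hr_ci_low`` and ``hr_ci_high``.  Binary or
    categorical covariates must be pre-coded numerically (for example
    high = 1, low = 0; older = 1, younger = 0).
    """
    t = _check_times(times)
    e = np.asarray(events, dtype=bool)
    if not e.any():
        raise ValueError("no observed events")
    cov = covariates.astype(float)
    for name in cov.columns:
        if cov[name].nunique() < 2:
            raise ValueError(f"covariate {name!r} is constant")
    df = cov.copy()
    df["_time"] = t
    df["_event"] = e.astype(int)
    cph = CoxPHFitter()
    try:
        cph.fit(df, duration_col="_time", event_col="_event")
    except ConvergenceError as err:  # pragma: no cover - diagnostic path
        raise RuntimeError(f"Cox fit did not converge: {err}") from err
    summ = cph.summary
    return pd.DataFrame(
        {
            "coef": summ["coef"],
            "hazard_ratio": summ["exp(coef)"],
            "p": summ["p"],
            "hr_ci_low": summ["exp(coef) lower 95%"],
            "hr_ci_high": summ["exp(coef) upper 95%"],
        }
    )


def dichotomize_age(ages, threshold: float = 50.0) -> pd.Series:
    """Split ages into ``older`` (> threshold) and ``younger`` (<= threshold).

    Patients with missing age are dropped (and logged); a result with a
    single group triggers a warning only.
    """
    s = pd.Series(ages, dtype=float)
    missing = s.index[s.isna()]
    if len(missing):
        logger.info("excluding %d patients with missing age: %s",
                    len(missing), list(missing))
    s = s.dropna()
    labels = pd.Series(np.where(s > threshold, "older", "younger"), index=s.index)
    if labels.nunique() < 2:
        logger.warning("all patients fall on one side of the age threshold")
    return labels
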