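"""End-to-end orchestration: profiles in, factorization + reports out.

``run_pipeline`` chains preprocessing, the paired decomposition,
probelet-annotation enrichment, segmentation of the leading tumor
arraylet, copy-number calls, patient classification and survival
analysis, writing every artifact plus a run log (package version, seed,
thresholds) into one output directory.  With tumor-only input and a
stored reference arraylet it runs the correlation-classification
(validation-set) path instead of the decomposition.
"""

from __future__ import annotations

import datetime
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .calls import assign_gender, call_chromosomes, call_segment, cohort_frequencies
from .decomposition import PairedGSVD
from .enrichment import probelet_enrichment
from .io import (
    read_clinical_table,
    read_profile_table,
    save_factorization,
    write_segments_bed,
)
from .preprocess import preprocess_pair, qc_filter_arrays, center_autosomal_median, \
    collapse_patient_medians
from .segmentation import segment_signal
from .survival import (
    classify_by_correlation,
    classify_by_probelet,
    cox_ph,
    dichotomize_age,
    km_estimate,
    logrank_test,
)

__all__ = ["RunConfig", "run_pipeline"]

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Inputs, thresholds and output location for one pipeline run."""

    tumor_profiles: str
    clinical: str
    out_dir: str
    tumor_samples: str | None = None
    normal_profiles: str | None = None
    normal_samples: str | None = None
    reference_arraylet: str | None = None   # tumor-only (validation) mode
    qc_min: float = 0.90
    probe_valid_min: float = 0.99
    cutoff: float = 0.02
    correlation_cutoff: float = 0.15
    alpha: float = 0.01
    n_perm: int = 1000
    impute_rank: int = 5
    age_threshold: float = 50.0
    seed: int = 0
    interpret_positions: tuple = field(default=None)

    def __post_init__(self):
        if not (0 <= self.qc_min <= 1 and 0 < self.probe_valid_min <= 1):
            raise ValueError("QC and probe-validity thresholds must lie in [0, 1]")
        if self.cutoff <= 0 or self.correlation_cutoff <= 0:
            raise ValueError("classification cutoffs must be positive")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must lie in (0, 1)")
        if self.normal_profiles is None and self.reference_arraylet is None:
            raise ValueError(
                "need either normal profiles (paired mode) or a reference "
                "arraylet (tumor-only mode)"
            )


def _stage(name):
    def deco(fn):
        def wrapped(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except Exception as err:
                raise RuntimeError(f"pipeline stage {name!r} failed: {err}") from err
        return wrapped
    return deco


def _survival_analysis(clinical: pd.DataFrame, labels: pd.Series,
                       age_threshold: float) -> dict:
    merged = clinical.join(labels.rename("cls"), how="inner")
    merged = merged[merged["cls"].isin(["high", "low"])]
    t = merged["survival_months"].astype(float)
    e = merged["event"].astype(bool)
    km = km_estimate(t, e, merged["cls"])
    report = {
        "groups": {
            str(k): {"n": v["n"], "n_events": v["n_events"], "median": v["median"]}
            for k, v in km.items()
        }
    }
    if merged["cls"].nunique() == 2 and e.any():
        chi2, p = logrank_test(t, e, merged["cls"])
        report["logrank"] = {"chi_square": chi2, "p": p}
        meds = {k: v["median"] for k, v in km.items()}
        if all(np.isfinite(list(meds.values()))):
            report["median_difference"] = abs(meds["low"] - meds["high"])
        cov = pd.DataFrame({"high": (merged["cls"] == "high").astype(float)})
        cox = cox_ph(t, e, cov)
        report["cox_univariate_class"] = _cox_row(cox, "high")
        if "age_at_diagnosis" in merged:
            ages = dichotomize_age(merged["age_at_diagnosis"], age_threshold)
            sub = merged.loc[ages.index]
            if ages.nunique() == 2:
                cov_age = pd.DataFrame({"older": (ages == "older").astype(float)})
                report["cox_univariate_age"] = _cox_row(
                    cox_ph(sub["survival_months"], sub["event"].astype(bool), cov_age),
                    "older")
                cov_both = pd.DataFrame({
                    "high": (sub["cls"] == "high").astype(float).to_numpy(),
                    "older": (ages == "older").astype(float).to_numpy(),
                }, index=sub.index)
                biv = cox_ph(sub["survival_months"], sub["event"].astype(bool), cov_both)
                report["cox_bivariate"] = {
                    "high": _cox_row(biv, "high"), "older": _cox_row(biv, "older")
                }
    return report


def _cox_row(cox: pd.DataFrame, name: str) -> dict:
    r = cox.loc[name]
    return {"hazard_ratio": float(r["hazard_ratio"]), "p": float(r["p"]),
            "ci": [float(r["hr_ci_low"]), float(r["hr_ci_high"])]}


def run_pipeline(config: RunConfig) -> Path:
    """Execute the full analysis; returns the output directory."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    log_lines = [
        f"{datetime.datetime.now().isoformat()} gsvdcna {__version__}",
        f"seed={config.seed}",
        f"thresholds={json.dumps({k: v for k, v in asdict(config).items() if isinstance(v, (int, float))})}",
    ]
    clinical = _stage("read_clinical")(read_clinical_table)(config.clinical)
    tumor = _stage("read_tumor")(read_profile_table)(
        config.tumor_profiles, config.tumor_samples, tissue="tumor")

    if config.normal_profiles is None:
        result = _tumor_only(config, tumor, clinical, out, log_lines)
    else:
        result = _paired(config, tumor, clinical, out, log_lines)

    (out / "run.log").write_text("\n".join(log_lines) + "\n")
    with open(out / "survival.json", "w") as fh:
        json.dump(result, fh, indent=2, sort_keys=True)
    return out


@_stage("tumor_only_classification")
def _tumor_only(config, tumor, clinical, out, log_lines):
    ref = pd.read_csv(config.reference_arraylet, sep="\t", index_col="probe_id")
    ref = ref.iloc[:, 0]
    tumor = qc_filter_arrays(tumor, config.qc_min)
    tumor = center_autosomal_median(tumor)
    tumor = collapse_patient_medians(tumor)
    profiles = tumor.values.reindex(ref.index)
    classes = classify_by_correlation(profiles, ref.to_numpy(),
                                      cutoff=config.correlation_cutoff)
    cls_df = pd.DataFrame([c.__dict__ for c in classes])
    cls_df.to_csv(out / "classes.tsv", sep="\t", index=False)
    labels = cls_df.set_index("patient_id")["label"]
    log_lines.append(f"mode=tumor_only n_patients={len(labels)}")
    return _survival_analysis(clinical, labels, config.age_threshold)


@_stage("paired_analysis")
def _paired(config, tumor, clinical, out, log_lines):
    normal = _stage("read_normal")(read_profile_table)(
        config.normal_profiles, config.normal_samples, tissue="normal")
    paired, tumor_p, normal_p = _stage("preprocess")(preprocess_pair)(
        tumor, normal,
        sb_pass_fraction_min=config.qc_min,
        min_valid_fraction=config.probe_valid_min,
        impute_rank=config.impute_rank,
    )
    fact = _stage("gsvd")(PairedGSVD().fit)(paired)
    save_factorization(fact, out / "factorization")
    n = fact.n_components_
    log_lines.append(f"mode=paired n_patients={n}")

    # enrichment of the extreme and the most-common probelets
    positions = config.interpret_positions
    if positions is None:
        common = int(np.argmin(np.abs(fact.angular_distances_)))
        positions = sorted({0, 1, common, n - 2, n - 1})
    categorical = [c for c in ("gender", "center", "batch", "scan_date")
                   if c in clinical.columns]
    tables = []
    for pos in positions:
        for direction in ("largest", "smallest"):
            tables.append(_stage("interpret")(probelet_enrichment)(
                fact, pos, clinical[categorical], direction=direction))
    pd.concat(tables, ignore_index=True).to_csv(
        out / "enrichment.tsv", sep="\t", index=False)

    # segmentation of the leading (most tumor-exclusive) arraylet
    segments = _stage("segment")(segment_signal)(
        fact.tumor_arraylets_[:, 0], tumor_p.probes,
        alpha=config.alpha, n_perm=config.n_perm, seed=config.seed)
    write_segments_bed(segments, out / "segments.bed")

    # per-patient copy-number calls and cohort frequencies
    calls = []
    genders = {}
    t_vals = tumor_p.values[fact.patient_ids_]
    n_vals = normal_p.values[fact.patient_ids_]
    for pid in fact.patient_ids_:
        tv = t_vals[pid].to_numpy()
        calls.extend(call_chromosomes(tv, tumor_p.probes, patient_id=pid))
        for seg in segments:
            calls.append(call_segment(tv, seg, tumor_p.probes, patient_id=pid))
        genders[pid] = assign_gender(n_vals[pid].to_numpy(), normal_p.probes)
    pd.DataFrame([c.__dict__ for c in calls]).to_csv(
        out / "calls.tsv", sep="\t", index=False)
    cohort_frequencies(calls).to_csv(out / "frequencies.tsv", sep="\t", index=False)
    pd.Series(genders, name="copy_number_gender").rename_axis("patient_id").to_csv(
        out / "genders.tsv", sep="\t")

    # classification by the leading probelet and survival analysis
    classes = classify_by_probelet(fact.probelets_[0], cutoff=config.cutoff,
                                   patient_ids=fact.patient_ids_)
    cls_df = pd.DataFrame([c.__dict__ for c in classes])
    cls_df.to_csv(out / "classes.tsv", sep="\t", index=False)
    labels = cls_df.set_index("patient_id")["label"]
    return _survival_analysis(clinical, labels, config.age_threshold)
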