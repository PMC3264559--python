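"""Readers and writers for the package's tab-delimited dialects.

Profile tables
    ``<probes+values>.tsv`` — columns ``probe_id``, ``chromosome``,
    ``arm``, ``start``, then one column per sample with log2 ratios;
    ``NA`` or an empty field marks a missing measurement.
    ``<samples>.tsv`` — columns ``sample_id``, ``patient_id``, ``tissue``,
    ``qc_pass_fraction``.

Clinical table
    keyed by ``patient_id`` with the annotation and outcome columns
    (gender, center, batch, scan_date, age_at_diagnosis, chemotherapy,
    survival_months, event).

Factorization directory
    ``tumor_arraylets.tsv`` / ``normal_arraylets.tsv`` (probes x
    components), ``probelets.tsv`` (components x patients) and
    ``summary.tsv`` (per-component weights, angular distance, fractions),
    components ordered by decreasing angular distance.

Segments
    a BED-style table (0-based half-open, per the BED convention; inputs
    are 1-based inclusive) with mean level, p-value and probe index range
    in extra columns.
"""

from __future__ import annotations

import warnings
from pathlib import Path

import numpy as np
import pandas as pd

from .decomposition import PairedGSVD
from .preprocess import ProfileSet
from .segmentation import Segment

__all__ = [
    "read_profile_table",
    "write_profile_table",
    "read_clinical_table",
    "write_clinical_table",
    "save_factorization",
    "load_factorization",
    "write_segments_bed",
    "read_segments_bed",
]

_MISSING = {"NA", ""}
_PROBE_META = ["chromosome", "arm", "start"]


def read_profile_table(path, samples_path=None, tissue: str = "tumor") -> ProfileSet:
    """Read a profile TSV (and optional sample-metadata TSV) into a
    :class:`~gsvdcna.preprocess.ProfileSet`.

    Malformed rows fail with their line number; duplicate probe ids fail.
    Without a metadata file every sample is its own patient with a QC
    pass fraction of 1.
    """
    path = Path(path)
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        n_cols = len(header)
        for lineno, line in enumerate(fh, start=2):
            if len(line.rstrip("\n").split("\t")) != n_cols:
                raise ValueError(f"{path}:{lineno}: expected {n_cols} columns")
    if header[:4] != ["probe_id"] + _PROBE_META:
        raise ValueError(f"{path}: header must start with probe_id, {', '.join(_PROBE_META)}")
    df = pd.read_csv(path, sep="\t", dtype={"probe_id": str, "chromosome": str},
                     na_values=["NA", ""], keep_default_na=False)
    if df["probe_id"].duplicated().any():
        dup = df.loc[df["probe_id"].duplicated(), "probe_id"].iloc[0]
        raise ValueError(f"{path}: duplicate probe id {dup!r}")
    df = df.set_index("probe_id")
    probes = df[_PROBE_META].copy()
    probes["start"] = probes["start"].astype(int)
    values = df.drop(columns=_PROBE_META).astype(float)
    if samples_path is not None:
        samples = pd.read_csv(samples_path, sep="\t", dtype={"sample_id": str,
                                                             "patient_id": str})
        samples = samples.set_index("sample_id")
        samples = samples.loc[list(values.columns)]
    else:
        samples = pd.DataFrame(
            {"patient_id": list(values.columns), "tissue": tissue,
             "qc_pass_fraction": 1.0},
            index=pd.Index(values.columns, name="sample_id"),
        )
    return ProfileSet(probes, values, samples)


def write_profile_table(pset: ProfileSet, path, samples_path=None) -> None:
    out = pset.probes.join(pset.values)
    out.index.name = "probe_id"
    # %.17g guarantees an exact float round trip
    out.to_csv(path, sep="\t", na_rep="NA", float_format="%.17g")
    if samples_path is not None:
        pset.samples.to_csv(samples_path, sep="\t")


def read_clinical_table(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"patient_id": str})
    if "patient_id" not in df.columns:
        raise ValueError(f"{path}: clinical table needs a patient_id column")
    return df.set_index("patient_id")


def write_clinical_table(clinical: pd.DataFrame, path) -> None:
    clinical.to_csv(path, sep="\t")


# ----------------------------------------------------------- factorization

def save_factorization(fact: PairedGSVD, outdir) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    comp = [f"c{i + 1}" for i in range(fact.n_components_)]
    pd.DataFrame(fact.tumor_arraylets_, index=fact.tumor_probe_ids_,
                 columns=comp).to_csv(outdir / "tumor_arraylets.tsv", sep="\t",
                                      index_label="probe_id", float_format="%.12g")
    pd.DataFrame(fact.normal_arraylets_, index=fact.normal_probe_ids_,
                 columns=comp).to_csv(outdir / "normal_arraylets.tsv", sep="\t",
                                      index_label="probe_id", float_format="%.12g")
    pd.DataFrame(fact.probelets_, index=comp,
                 columns=fact.patient_ids_).to_csv(outdir / "probelets.tsv", sep="\t",
                                                   index_label="component",
                                                   float_format="%.12g")
    fact.summary().to_csv(outdir / "summary.tsv", sep="\t", index=False,
                          float_format="%.12g")


def load_factorization(outdir) -> PairedGSVD:
    outdir = Path(outdir)
    u1 = pd.read_csv(outdir / "tumor_arraylets.tsv", sep="\t", index_col="probe_id")
    u2 = pd.read_csv(outdir / "normal_arraylets.tsv", sep="\t", index_col="probe_id")
    v = pd.read_csv(outdir / "probelets.tsv", sep="\t", index_col="component")
    summ = pd.read_csv(outdir / "summary.tsv", sep="\t")
    fact = PairedGSVD()
    fact.tumor_arraylets_ = u1.to_numpy()
    fact.normal_arraylets_ = u2.to_numpy()
    fact.probelets_ = v.to_numpy()
    fact.tumor_weights_ = summ["sigma_tumor"].to_numpy()
    fact.normal_weights_ = summ["sigma_normal"].to_numpy()
    fact.angular_distances_ = summ["angular_distance"].to_numpy()
    fact.order_ = np.arange(len(summ))
    fact.n_components_ = len(summ)
    fact.patient_ids_ = list(v.columns)
    fact.tumor_probe_ids_ = list(u1.index)
    fact.normal_probe_ids_ = list(u2.index)
    return fact


# ---------------------------------------------------------------- segments

_BED_COLUMNS = ["chromosome", "bed_start", "bed_end", "arm", "mean", "p_value",
                "start_index", "end_index"]


def write_segments_bed(segments: list[Segment], path) -> None:
    """Write segments as a BED-compatible table.

    Input coordinates are 1-based inclusive; BED is 0-based half-open, so
    a segment [s, e] becomes (s-1, e).  Unsorted input is sorted on write
    with a warning.
    """
    rows = [
        {
            "chromosome": s.chromosome,
            "bed_start": s.start_bp - 1,
            "bed_end": s.end_bp,
            "arm": s.arm,
            "mean": s.mean,
            "p_value": s.p_value,
            "start_index": s.start_index,
            "end_index": s.end_index,
        }
        for s in segments
    ]
    df = pd.DataFrame(rows, columns=_BED_COLUMNS)
    # keep the input's chromosome (genome) order; sort within chromosomes
    rank = {c: i for i, c in enumerate(dict.fromkeys(df["chromosome"]))}
    sorted_df = (
        df.assign(_rank=df["chromosome"].map(rank))
        .sort_values(["_rank", "bed_start"], kind="stable", ignore_index=True)
        .drop(columns="_rank")
    )
    if not df.reset_index(drop=True).equals(sorted_df):
        warnings.warn("segments were not sorted; sorting on write")
        df = sorted_df
    with open(path, "w") as fh:
        fh.write("# BED convention: 0-based half-open intervals\n")
        df.to_csv(fh, sep="\t", index=False, float_format="%.12g")


def read_segments_bed(path) -> list[Segment]:
    df = pd.read_csv(path, sep="\t", comment="#", dtype={"chromosome": str})
    return [
        Segment(
            chromosome=r["chromosome"],
            arm=r["arm"],
            start_index=int(r["start_index"]),
            end_index=int(r["end_index"]),
            start_bp=int(r["bed_start"]) + 1,
            end_bp=int(r["bed_end"]),
            mean=float(r["mean"]),
            p_value=float(r["p_value"]),
        )
        for _, r in df.iterrows()
    ]
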