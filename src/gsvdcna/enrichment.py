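"""Annotation enrichment of probelets and rank-sum group comparisons.

A probelet orders the patients by relative copy number; the patients with
the largest (or smallest) entries form a group whose over-representation
in each clinical/experimental annotation (gender, center, batch, scan
date, ...) is scored with an exact hypergeometric upper-tail probability.
P-values are reported unadjusted; a Bonferroni column is emitted alongside
for the reader's discretion but never gates anything.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction
from itertools import combinations
from math import comb

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "EnrichmentRecord",
    "hypergeometric_tail",
    "probelet_enrichment",
    "ranksum_compare",
]


@dataclass
class EnrichmentRecord:
    probelet: int
    direction: str            # "largest" | "smallest"
    annotation: str
    label: str
    n_population: int
    n_annotated: int
    k_group: int
    k_overlap: int
    p_value: float


def hypergeometric_tail(
    n_population: int, n_annotated: int, k_group: int, k_overlap: int
) -> float:
    """Exact upper-tail hypergeometric probability.

    Probability of at least ``k_overlap`` annotated members in a draw of
    ``k_group`` from a population of ``n_population`` containing
    ``n_annotated`` annotated members, computed by exact integer summation
    (the float returned is the nearest double to the exact rational).
    """
    N, n, K, k = n_population, n_annotated, k_group, k_overlap
    if not (0 <= k <= K <= N) or not (0 <= n <= N):
        raise ValueError(f"inconsistent counts N={N}, n={n}, K={K}, k={k}")
    if k > n:
        return 0.0
    num = sum(comb(n, j) * comb(N - n, K - j) for j in range(k, min(K, n) + 1))
    return float(Fraction(num, comb(N, K)))


def _tail_by_enumeration(N: int, n: int, K: int, k: int) -> float:
    """Brute-force oracle: enumerate all size-K subsets (tiny N only)."""
    annotated = set(range(n))
    hits = sum(
        1 for grp in combinations(range(N), K) if len(annotated & set(grp)) >= k
    )
    return hits / comb(N, K)


def probelet_enrichment(
    fact,
    probelet: int,
    annotations: pd.DataFrame,
    group_size: int | None = None,
    direction: str = "largest",
) -> pd.DataFrame:
    """Enrichment of a probelet's extreme patients in each annotation label.

    Patients are ranked by their entry in probelet ``probelet`` (0-based
    position in the reported order of ``fact``); the top (``largest``) or
    bottom (``smallest``) ``group_size`` patients form the group.  For each
    categorical column of ``annotations`` (indexed by patient id) and each
    of its labels, the hypergeometric upper-tail p-value of the overlap is
    computed.  When ``group_size`` is None it defaults per label to that
    label's population count, so a perfectly aligned annotation can reach
    a full overlap.  Records are returned sorted by p-value.
    """
    if direction not in ("largest", "smallest"):
        raise ValueError("direction must be 'largest' or 'smallest'")
    n = fact.n_components_
    if not 0 <= probelet < n:
        raise ValueError(f"unknown probelet index {probelet}")
    entries = pd.Series(fact.probelets_[probelet], index=fact.patient_ids_)
    annotations = annotations.loc[annotations.index.intersection(entries.index)]
    pop = entries.loc[annotations.index]
    n_pop = len(pop)
    ranked = pop.sort_values(ascending=(direction == "smallest"), kind="stable")

    records = []
    for column in annotations.columns:
        col = annotations[column].dropna().astype(str)
        for label in sorted(col.unique()):
            members = set(col.index[col == label])
            K = group_size if group_size is not None else len(members)
            if K > n_pop:
                raise ValueError(f"group_size {K} exceeds population {n_pop}")
            group = set(ranked.index[:K])
            k = len(group & members)
            records.append(
                EnrichmentRecord(
                    probelet=probelet,
                    direction=direction,
                    annotation=column,
                    label=label,
                    n_population=n_pop,
                    n_annotated=len(members),
                    k_group=K,
                    k_overlap=k,
                    p_value=hypergeometric_tail(n_pop, len(members), K, k),
                )
            )
    table = pd.DataFrame([r.__dict__ for r in records]).sort_values(
        "p_value", kind="stable", ignore_index=True
    )
    table["p_bonferroni"] = np.minimum(table["p_value"] * len(table), 1.0)
    return table


def ranksum_compare(values, labels):
    """Mann-Whitney-Wilcoxon comparison of two groups.

    Returns ``(U, p)`` where ``U`` counts, for the first group, the pairs
    it wins (ties count 1/2).  For combined sample sizes up to 12 the
    two-sided p-value is computed by exact enumeration of all group
    assignments (valid with ties); larger samples use the normal
    approximation with tie correction.
    """
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels)
    uniq = np.unique(labels)
    if uniq.size != 2:
        raise ValueError(f"need exactly two groups, got {uniq.size}")
    a = values[labels == uniq[0]]
    b = values[labels == uniq[1]]
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be non-empty")

    u_obs = _u_statistic(a, b)
    n_tot = a.size + b.size
    if n_tot <= 12:
        # exact null: every size-|a| subset of the pooled values equally likely
        pooled = np.concatenate([a, b])
        mid = a.size * b.size / 2.0
        dev_obs = abs(u_obs - mid)
        count = 0
        total = 0
        for idx in combinations(range(n_tot), a.size):
            mask = np.zeros(n_tot, dtype=bool)
            mask[list(idx)] = True
            u = _u_statistic(pooled[mask], pooled[~mask])
            total += 1
            if abs(u - mid) >= dev_obs - 1e-12:
                count += 1
        return float(u_obs), count / total
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method="asymptotic")
    return float(res.statistic), float(res.pvalue)


def _u_statistic(a: np.ndarray, b: np.ndarray) -> float:
    diff = a[:, None] - b[None, :]
    return float((diff > 0).sum() + 0.5 * (diff == 0).sum())
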