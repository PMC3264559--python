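"""Change-point segmentation of a copy-number signal along the genome.

A simplified binary segmentation in the spirit of CBS: within each
chromosome the split maximizing the two-sample |t| statistic between the
flanking stretches is located, its significance is calibrated by
permuting the chromosome's values and re-maximizing, and accepted splits
are recursed into.  The resulting segments tile each chromosome.  The
splitter is deliberately pluggable behind :func:`segment_signal`, so a
full circular implementation can be substituted without touching callers.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

__all__ = ["Segment", "BinarySegmenter", "segment_signal"]


@dataclass
class Segment:
    """A constant-level stretch of probes within one chromosome.

    Probe indices are inclusive positions in genome order; bp coordinates
    are 1-based inclusive.
    """

    chromosome: str
    arm: str
    start_index: int
    end_index: int
    start_bp: int
    end_bp: int
    mean: float
    p_value: float

    @property
    def n_probes(self) -> int:
        return self.end_index - self.start_index + 1


def _max_t_split(x: np.ndarray, min_width: int):
    """Best split of ``x`` into two stretches by pooled-variance |t|.

    Returns (split index k — left part is x[:k] — and |t|); (None, 0)
    when no admissible split exists.  Zero pooled variance with a mean
    difference yields an infinite statistic (a perfect, noiseless step).
    """
    n = x.size
    if n < 2 * min_width:
        return None, 0.0
    ks = np.arange(min_width, n - min_width + 1)
    c1 = np.cumsum(x)
    c2 = np.cumsum(x**2)
    total, total2 = c1[-1], c2[-1]
    nl = ks.astype(float)
    nr = n - nl
    sl, sr = c1[ks - 1], total - c1[ks - 1]
    ssl, ssr = c2[ks - 1], total2 - c2[ks - 1]
    ml, mr = sl / nl, sr / nr
    within = (ssl - nl * ml**2) + (ssr - nr * mr**2)
    with np.errstate(divide="ignore", invalid="ignore"):
        pooled = within / max(n - 2, 1)
        t = np.abs(ml - mr) / np.sqrt(pooled * (1 / nl + 1 / nr))
    t = np.where((within <= 1e-30) & (np.abs(ml - mr) > 0), np.inf, t)
    t = np.nan_to_num(t, nan=0.0, posinf=np.inf)
    best = int(np.argmax(t))
    return int(ks[best]), float(t[best])


def _max_t_only(x: np.ndarray, min_width: int) -> float:
    return _max_t_split(x, min_width)[1]


class BinarySegmenter(BaseEstimator):
    """Recursive max-|t| segmentation with permutation-calibrated splits.

    Parameters
    ----------
    alpha : float, default 0.01
        Acceptance level for a split's permutation p-value.
    n_perm : int, default 1000
        Permutations per tested split; fewer than 100 is refused (the p
        resolution would be coarser than alpha).
    min_width : int, default 3
        Minimum probes on each side of a split.
    seed : int or None
        Seed for the permutation generator.
    """

    def __init__(self, alpha: float = 0.01, n_perm: int = 1000,
                 min_width: int = 3, seed: int | None = None):
        self.alpha = alpha
        self.n_perm = n_perm
        self.min_width = min_width
        self.seed = seed

    def fit(self, values, probes: pd.DataFrame):
        """Segment ``values`` (genome order, aligned with ``probes``).

        ``probes`` needs columns ``chromosome``, ``arm``, ``start``.
        Fitted attribute ``segments_`` is the list of :class:`Segment`.
        """
        if self.n_perm < 100:
            raise ValueError("n_perm must be at least 100")
        values = np.asarray(values, dtype=float)
        if values.size != len(probes):
            raise ValueError("values and probe table lengths differ")
        rng = np.random.default_rng(self.seed)
        segments: list[Segment] = []
        offset = 0
        for chrom in probes["chromosome"].unique():
            mask = (probes["chromosome"] == chrom).to_numpy()
            idx = np.flatnonzero(mask)
            x = values[idx]
            sub = probes.iloc[idx]
            if x.size < self.min_width:
                raise ValueError(
                    f"chromosome {chrom} has {x.size} probes < min_width {self.min_width}"
                )
            for lo, hi, p in self._recurse(x, rng):
                block = sub.iloc[lo:hi + 1]
                # a segment spanning the centromere is labeled by its first arm
                segments.append(
                    Segment(
                        chromosome=str(chrom),
                        arm=str(block["arm"].iloc[0]),
                        start_index=int(idx[lo]),
                        end_index=int(idx[hi]),
                        start_bp=int(block["start"].iloc[0]),
                        end_bp=int(block["start"].iloc[-1]),
                        mean=float(x[lo:hi + 1].mean()),
                        p_value=p,
                    )
                )
            offset += x.size
        self.segments_ = segments
        return self

    def _recurse(self, x: np.ndarray, rng, base: int = 0, parent_p: float = 1.0):
        """Yield (lo, hi, p_value) inclusive index spans within x's frame.

        A segment reports the permutation p-value of the accepted split
        that delimited it (1.0 for a chromosome that was never split).
        """
        split, t_obs = _max_t_split(x, self.min_width)
        if split is None or t_obs == 0.0:
            yield base, base + x.size - 1, parent_p
            return
        exceed = 0
        perm = x.copy()
        for _ in range(self.n_perm):
            rng.shuffle(perm)
            if _max_t_only(perm, self.min_width) >= t_obs:
                exceed += 1
        p = (exceed + 1) / (self.n_perm + 1)
        if p < self.alpha:
            yield from self._recurse(x[:split], rng, base, p)
            yield from self._recurse(x[split:], rng, base + split, p)
        else:
            yield base, base + x.size - 1, parent_p if parent_p < 1.0 else p


def segment_signal(values, probes: pd.DataFrame, alpha: float = 0.01,
                   n_perm: int = 1000, min_width: int = 3,
                   seed: int | None = None) -> list[Segment]:
    """Segment a genome-ordered signal; see :class:`BinarySegmenter`."""
    return BinarySegmenter(alpha=alpha, n_perm=n_perm, min_width=min_width,
                           seed=seed).fit(values, probes).segments_
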