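"""Strand-resolved depth, relative coverage and coverage-fraction tables.

Relative coverage (rc) of a position is its read depth divided by the mean
depth over all reference positions; it is computed for the plus strand, the
minus strand and both pooled, each series normalized by its own mean.  The
coverage-fraction table reports, for a descending list of rc thresholds,
the percentage of positions lying strictly below each threshold — the
standard summary of how much of a genome is critically under-covered.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .genome import BASE_INDEX, BASE_ORDER, ReferenceGenome

DEFAULT_RC_THRESHOLDS = (0.50, 0.25, 0.10, 0.05, 0.01)

#: strand axis order in BaseCountMatrix arrays
STRAND_ORDER = ("+", "-")


@dataclass
class StrandDepthProfile:
    """Per-position read depth split by alignment strand."""

    plus: np.ndarray
    minus: np.ndarray

    def __post_init__(self) -> None:
        self.plus = np.asarray(self.plus, dtype=np.int64)
        self.minus = np.asarray(self.minus, dtype=np.int64)
        if self.plus.shape != self.minus.shape or self.plus.ndim != 1:
            raise ValueError("plus and minus depth arrays must be 1-D and equal length")
        if (self.plus < 0).any() or (self.minus < 0).any():
            raise ValueError("depths must be non-negative")

    def __len__(self) -> int:
        return len(self.plus)

    @property
    def total(self) -> np.ndarray:
        return self.plus + self.minus


class BaseCountMatrix:
    """Per-position, per-strand counts of observed A/C/G/T bases.

    Stored as an int64 array of shape ``(L, 2, 4)`` with strand axis ordered
    (+, -) and base axis ordered A, C, G, T.  Row sums over the base axis
    reproduce the strand depth profile.
    """

    def __init__(self, counts: np.ndarray):
        counts = np.asarray(counts, dtype=np.int64)
        if counts.ndim != 3 or counts.shape[1:] != (2, 4):
            raise ValueError("counts must have shape (L, 2, 4)")
        if (counts < 0).any():
            raise ValueError("counts must be non-negative")
        self.counts = counts

    @classmethod
    def zeros(cls, length: int) -> "BaseCountMatrix":
        return cls(np.zeros((length, 2, 4), dtype=np.int64))

    def __len__(self) -> int:
        return self.counts.shape[0]

    def depth_profile(self) -> StrandDepthProfile:
        d = self.counts.sum(axis=2)
        return StrandDepthProfile(plus=d[:, 0], minus=d[:, 1])

    @property
    def total_depth(self) -> np.ndarray:
        return self.counts.sum(axis=(1, 2))

    @property
    def mean_total_depth(self) -> float:
        return float(self.total_depth.mean())

    def pooled(self) -> np.ndarray:
        """Strand-pooled (L, 4) base counts."""
        return self.counts.sum(axis=1)


@dataclass
class RelativeCoverageProfile:
    """Per-position relative coverage for total / plus / minus series.

    A series whose strand has zero depth everywhere is undefined; it is
    stored as all-NaN with a NaN denominator rather than divided by zero.
    """

    rc_total: np.ndarray
    rc_plus: np.ndarray
    rc_minus: np.ndarray
    mean_total: float
    mean_plus: float
    mean_minus: float

    def __len__(self) -> int:
        return len(self.rc_total)

    def series(self, which: str) -> np.ndarray:
        try:
            return {"total": self.rc_total, "plus": self.rc_plus, "minus": self.rc_minus}[which]
        except KeyError:
            raise ValueError(f"unknown series {which!r}; expected total/plus/minus") from None

    def defined(self, which: str) -> bool:
        return not np.isnan(
            {"total": self.mean_total, "plus": self.mean_plus, "minus": self.mean_minus}[which]
        )


def _normalize(depth: np.ndarray) -> tuple[np.ndarray, float]:
    mean = float(depth.mean())
    if mean == 0.0:
        return np.full(len(depth), np.nan), float("nan")
    return depth / mean, mean


def relative_coverage(depth: StrandDepthProfile) -> RelativeCoverageProfile:
    """Normalize each depth series by its own genome-wide mean.

    By construction ``mean(rc) == 1`` (to floating tolerance) for every
    defined series, and the profile is invariant under scaling all depths
    by a positive constant.
    """
    if len(depth) < 1:
        raise ValueError("empty depth profile")
    rc_total, m_total = _normalize(depth.total.astype(float))
    rc_plus, m_plus = _normalize(depth.plus.astype(float))
    rc_minus, m_minus = _normalize(depth.minus.astype(float))
    return RelativeCoverageProfile(rc_total, rc_plus, rc_minus, m_total, m_plus, m_minus)


@dataclass
class CoverageFractionTable:
    """Percentage of positions with rc strictly below each threshold.

    ``data`` maps series name (Total/Plus/Min) to a tuple of percentages
    aligned with ``thresholds``; full precision is kept here and rounding
    to two decimals happens only in :meth:`to_frame`.
    """

    thresholds: tuple[float, ...]
    data: dict[str, tuple[float, ...]] = field(default_factory=dict)

    def percent(self, series: str, threshold: float) -> float:
        return self.data[series][self.thresholds.index(threshold)]

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.data, index=[f"<{t:.2f}" for t in self.thresholds])
        return df.round(2)


def coverage_fraction_table(
    rc: RelativeCoverageProfile,
    thresholds: Sequence[float] = DEFAULT_RC_THRESHOLDS,
) -> CoverageFractionTable:
    """Tabulate the fraction of the genome below each rc threshold.

    Thresholds must be strictly descending and in (0, 1); membership uses
    strict inequality, so within a column the percentages are non-increasing
    as the threshold decreases.
    """
    thresholds = tuple(float(t) for t in thresholds)
    if any(not (0.0 < t < 1.0) for t in thresholds):
        raise ValueError("thresholds must lie in (0, 1)")
    if any(a <= b for a, b in zip(thresholds, thresholds[1:])):
        raise ValueError("thresholds must be strictly descending")
    out: dict[str, tuple[float, ...]] = {}
    for label, which in (("Total", "total"), ("Plus", "plus"), ("Min", "minus")):
        if not rc.defined(which):
            out[label] = tuple(float("nan") for _ in thresholds)
            continue
        series = rc.series(which)
        out[label] = tuple(100.0 * float(np.mean(series < t)) for t in thresholds)
    return CoverageFractionTable(thresholds=thresholds, data=out)


def depth_from_alignments(
    alignments: Iterable,
    ref: ReferenceGenome,
) -> tuple[StrandDepthProfile, BaseCountMatrix]:
    """Count aligned read bases per position and strand.

    Accepts an iterable of :class:`pysam.AlignedSegment` (e.g. the stream
    from :func:`mitostrand.io.read_alignments`).  Unmapped, secondary and
    supplementary records are skipped.  A forward-strand read contributes to
    the plus series, a reverse-strand read to the minus series.  Counting is
    base-level: positions a read spans via a deletion contribute neither to
    base counts nor to depth.
    """
    counts = BaseCountMatrix.zeros(len(ref))
    arr = counts.counts
    for read in alignments:
        if read.is_unmapped or read.is_secondary or read.is_supplementary:
            continue
        if read.reference_name != ref.name:
            raise ValueError(
                f"alignment reference {read.reference_name!r} does not match "
                f"genome {ref.name!r}"
            )
        strand = 1 if read.is_reverse else 0
        seq = read.query_sequence
        if seq is None:
            continue
        for qpos, rpos in read.get_aligned_pairs(matches_only=True):
            base = seq[qpos]
            idx = BASE_INDEX.get(base)
            if idx is not None and rpos < len(ref):
                arr[rpos, strand, idx] += 1
    return counts.depth_profile(), counts


def downsample(
    counts: BaseCountMatrix, target_mean: float, seed: int
) -> BaseCountMatrix:
    """Binomially thin a pileup to a target mean total depth.

    Every observed base is retained independently with probability
    ``target_mean / current_mean``, which preserves strand and base
    proportions in expectation.  If the target exceeds the current mean the
    input is returned unchanged with a warning.
    """
    if target_mean <= 0:
        raise ValueError("target_mean must be positive")
    current = counts.mean_total_depth
    if current == 0.0:
        raise ValueError("cannot down-sample an empty pileup")
    if target_mean > current:
        warnings.warn(
            f"target mean {target_mean:g} exceeds current mean {current:g}; "
            "returning input unchanged",
            stacklevel=2,
        )
        return counts
    rng = np.random.default_rng(seed)
    p = target_mean / current
    return BaseCountMatrix(rng.binomial(counts.counts, p))
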