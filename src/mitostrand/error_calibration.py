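"""Sequencing-error baseline estimation and detection-threshold policy.

The error baseline of a platform is estimated from a well-typed control
sequence (e.g. a plasmid sequenced to very high depth): at every position
the ratio of non-reference to total observed bases is computed, true
variant positions are excluded, and the unweighted average of the
per-position ratios is the platform's average error rate.  A heteroplasmy
detection threshold is then placed a safety factor above that baseline:
candidate minor-allele fractions are accepted only strictly above the
threshold.
"""
from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .genome import ReferenceGenome
from .strand_coverage import BaseCountMatrix

DEFAULT_MULTIPLIER = 5.0
DEFAULT_FLOOR = 0.01


@dataclass
class PositionErrorProfile:
    """Per-position non-reference base fraction with an exclusion mask.

    ``fraction`` is NaN wherever the position is excluded or has no
    observed bases; ``total`` holds the observed base count (both strands
    pooled) and ``excluded`` the mask of true-variant positions removed
    from the baseline.
    """

    fraction: np.ndarray
    total: np.ndarray
    excluded: np.ndarray

    def usable(self) -> np.ndarray:
        return ~self.excluded & (self.total > 0)


def position_error(
    counts: BaseCountMatrix,
    ref: ReferenceGenome,
    exclude: Iterable[int] = (),
) -> PositionErrorProfile:
    """Non-reference base fraction per position, strands pooled.

    ``exclude`` lists 1-based positions carrying true variants; they are
    masked so genuine heteroplasmy does not inflate the error baseline.
    Only substitutions enter the index: the denominator is observed bases,
    so deletions contribute nothing.
    """
    if len(counts) != len(ref):
        raise ValueError(
            f"pileup covers {len(counts)} positions but reference has {len(ref)}"
        )
    pooled = counts.pooled()
    total = pooled.sum(axis=1)
    ref_idx = ref.base_indices()
    L = len(ref)
    ref_count = np.where(ref_idx >= 0, pooled[np.arange(L), np.clip(ref_idx, 0, 3)], 0)
    excluded = np.zeros(L, dtype=bool)
    for p in exclude:
        if not 1 <= p <= L:
            raise ValueError(f"excluded position {p} outside genome of length {L}")
        excluded[p - 1] = True
    excluded |= ref_idx < 0  # ambiguous reference bases cannot define "non-reference"
    with np.errstate(invalid="ignore", divide="ignore"):
        frac = (total - ref_count) / total
    frac = np.where(~excluded & (total > 0), frac, np.nan)
    return PositionErrorProfile(fraction=frac, total=total, excluded=excluded)


@dataclass
class ErrorSummary:
    """Average error rate, per sample and aggregated across samples.

    ``mean`` is the across-sample mean of the per-sample averages and
    ``sd`` their sample (n-1) standard deviation (NaN with fewer than two
    samples).  ``defined`` is False when no usable position existed.
    """

    per_sample: tuple[float, ...]
    mean: float
    sd: float
    defined: bool = True


def average_error_rate(profile: PositionErrorProfile) -> ErrorSummary:
    """Unweighted mean of per-position non-reference fractions."""
    usable = profile.usable()
    if not usable.any():
        return ErrorSummary(per_sample=(), mean=float("nan"), sd=float("nan"), defined=False)
    m = float(np.nanmean(profile.fraction[usable]))
    return ErrorSummary(per_sample=(m,), mean=m, sd=float("nan"))


def aggregate_error_rates(per_sample_means: Sequence[float]) -> ErrorSummary:
    """Across-sample mean and sample (n-1) standard deviation."""
    vals = tuple(float(v) for v in per_sample_means)
    if not vals:
        return ErrorSummary(per_sample=(), mean=float("nan"), sd=float("nan"), defined=False)
    mean = float(np.mean(vals))
    sd = float(np.std(vals, ddof=1)) if len(vals) > 1 else float("nan")
    return ErrorSummary(per_sample=vals, mean=mean, sd=sd)


def detection_threshold(
    summary: ErrorSummary,
    multiplier: float = DEFAULT_MULTIPLIER,
    floor: float = DEFAULT_FLOOR,
) -> float:
    """Detection threshold as a fraction, in whole percents.

    The threshold is the smallest whole percent lying strictly above
    ``multiplier x mean error``, but never below ``floor``.  Placing it
    strictly above the scaled baseline keeps a margin even when the scaled
    value falls exactly on a percent boundary; at the ~0.2-0.35% error
    rates typical of a well-behaved short-read run this yields the 2%
    working point, and the policy is monotone in the error rate.
    """
    if not summary.defined:
        raise ValueError("error summary is undefined; cannot derive a threshold")
    if multiplier <= 0 or floor < 0:
        raise ValueError("multiplier must be positive and floor non-negative")
    raw = multiplier * summary.mean
    # smallest whole percent strictly greater than raw (tolerate fp dust)
    above = (math.floor(raw * 100.0 + 1e-12) + 1) / 100.0
    return max(floor, above)


def is_callable(allele_fraction: float, threshold: float) -> bool:
    """A candidate is callable iff its fraction is strictly above threshold."""
    return allele_fraction > threshold
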