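"""Call-set vs truth-panel concordance and heteroplasmy summaries.

Variants use the mtDNA HGVS-like m.-notation: substitutions ``m.7989T>C``,
insertions between flanking positions ``m.5899_5900insC`` and deletions
``m.3106del`` / ``m.8470_13446del``.  A truth panel (typically Sanger
results) is compared against a massively-parallel-sequencing call set per
sample and dataset: a truth variant counts as detected only when an
identical (position, kind, alleles) call exists; extra calls are those
absent from the truth panel.  Heteroplasmy is summarized as the mean and
sample standard deviation of per-method minor-allele fractions (percent).
"""
from __future__ import annotations

import re
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from typing import Iterable, Sequence

__all__ = [
    "VariantCall",
    "TruthSet",
    "ConcordanceRow",
    "parse_mt_variant",
    "compare_callsets",
    "detection_rate",
    "heteroplasmy_summary",
    "round_half_up",
]

_SUB_RE = re.compile(r"^m\.(\d+)([ACGT])>([ACGT])$")
_INS_RE = re.compile(r"^m\.(\d+)_(\d+)ins([ACGT]+)$")
_DEL_RE = re.compile(r"^m\.(\d+)(?:_(\d+))?del([ACGT]*)$")


def round_half_up(value: float, ndigits: int = 1) -> float:
    """Decimal round-half-up, matching how printed tables round .x5 up."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(value)).quantize(q, rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class VariantCall:
    """A single variant; identity is (kind, position/interval, alleles).

    Allele fraction (minor-allele percent), sample and dataset labels ride
    along but do not participate in equality, so matching against a truth
    panel compares only the genomic change itself.
    """

    position: int
    kind: str  # substitution | insertion | deletion
    ref: str
    alt: str
    end: int | None = None
    fraction: float | None = field(default=None, compare=False)
    sample: str | None = field(default=None, compare=False)
    dataset: str | None = field(default=None, compare=False)

    def __post_init__(self) -> None:
        if self.kind == "substitution":
            if len(self.ref) != 1 or len(self.alt) != 1 or self.end is not None:
                raise ValueError("substitution needs single ref and alt base and no interval")
        elif self.kind == "insertion":
            if self.end != self.position + 1 or not self.alt or self.ref:
                raise ValueError("insertion uses flanking positions p_p+1 and a non-empty alt")
        elif self.kind == "deletion":
            if self.alt:
                raise ValueError("deletion carries no alt allele")
        else:
            raise ValueError(f"unknown variant kind {self.kind!r}")

    def format(self) -> str:
        """Canonical m.-notation round-tripping :func:`parse_mt_variant`."""
        if self.kind == "substitution":
            return f"m.{self.position}{self.ref}>{self.alt}"
        if self.kind == "insertion":
            return f"m.{self.position}_{self.end}ins{self.alt}"
        span = f"{self.position}_{self.end}" if self.end and self.end != self.position else f"{self.position}"
        return f"m.{span}del{self.ref}"


def parse_mt_variant(
    text: str,
    fraction: float | None = None,
    sample: str | None = None,
    dataset: str | None = None,
) -> VariantCall:
    """Parse m.-notation into a :class:`VariantCall`.

    Raises ``ValueError`` naming the offending token on malformed input.
    """
    text = text.strip()
    m = _SUB_RE.match(text)
    if m:
        return VariantCall(
            position=int(m.group(1)), kind="substitution", ref=m.group(2), alt=m.group(3),
            fraction=fraction, sample=sample, dataset=dataset,
        )
    m = _INS_RE.match(text)
    if m:
        p, q = int(m.group(1)), int(m.group(2))
        if q != p + 1:
            raise ValueError(
                f"malformed insertion {text!r}: flanking positions must be adjacent"
            )
        return VariantCall(
            position=p, end=q, kind="insertion", ref="", alt=m.group(3),
            fraction=fraction, sample=sample, dataset=dataset,
        )
    m = _DEL_RE.match(text)
    if m:
        p = int(m.group(1))
        q = int(m.group(2)) if m.group(2) else None
        if q is not None and q < p:
            raise ValueError(f"malformed deletion {text!r}: interval end before start")
        return VariantCall(
            position=p, end=q, kind="deletion", ref=m.group(3) or "", alt="",
            fraction=fraction, sample=sample, dataset=dataset,
        )
    raise ValueError(f"cannot parse variant notation {text!r}")


@dataclass
class TruthSet:
    """Per-sample truth variants established by the reference method."""

    by_sample: dict[str, list[VariantCall]] = field(default_factory=dict)

    def add(self, sample: str, variant: VariantCall) -> None:
        entries = self.by_sample.setdefault(sample, [])
        if variant in entries:
            raise ValueError(f"duplicate truth entry {variant.format()} for sample {sample}")
        entries.append(variant)

    def variants(self, sample: str) -> list[VariantCall]:
        return list(self.by_sample.get(sample, []))


@dataclass
class ConcordanceRow:
    """Detected / false-negative / extra counts for one sample x dataset."""

    sample: str
    dataset: str
    n_truth: int
    n_detected: int
    n_false_negative: int
    n_extra: int

    def __post_init__(self) -> None:
        if min(self.n_truth, self.n_detected, self.n_false_negative, self.n_extra) < 0:
            raise ValueError("concordance counts must be non-negative")
        if self.n_detected + self.n_false_negative != self.n_truth:
            raise ValueError(
                f"detected ({self.n_detected}) + FN ({self.n_false_negative}) "
                f"must equal truth ({self.n_truth})"
            )


def _in_region(v: VariantCall, region: tuple[int, int]) -> bool:
    lo, hi = region
    end = v.end or v.position
    return lo <= v.position and end <= hi


def compare_callsets(
    truth: TruthSet,
    calls: Iterable[VariantCall],
    sample: str,
    dataset: str,
    equivalence_regions: Sequence[tuple[int, int]] | None = None,
) -> ConcordanceRow:
    """Match a call set against the truth panel for one sample.

    Matching is exact on (position, kind, alleles) by default.  Optional
    ``equivalence_regions`` declare polymorphic intervals (homopolymeric
    stretches whose insertions are not alignable to unique positions) in
    which insertion calls are matched by net inserted length instead: if
    the total inserted length inside the region agrees between truth and
    calls, the region's truth insertions count as detected and its calls
    are not counted extra.
    """
    truth_vars = truth.variants(sample)
    call_list = [c for c in calls]
    matched_truth = [False] * len(truth_vars)
    matched_call = [False] * len(call_list)

    call_pool: dict[VariantCall, list[int]] = {}
    for j, c in enumerate(call_list):
        call_pool.setdefault(c, []).append(j)
    for i, t in enumerate(truth_vars):
        idxs = call_pool.get(t)
        if idxs:
            matched_truth[i] = True
            matched_call[idxs.pop(0)] = True

    if equivalence_regions:
        for region in equivalence_regions:
            t_idx = [
                i for i, t in enumerate(truth_vars)
                if not matched_truth[i] and t.kind == "insertion" and _in_region(t, region)
            ]
            c_idx = [
                j for j, c in enumerate(call_list)
                if not matched_call[j] and c.kind == "insertion" and _in_region(c, region)
            ]
            if not t_idx or not c_idx:
                continue
            t_len = sum(len(truth_vars[i].alt) for i in t_idx)
            c_len = sum(len(call_list[j].alt) for j in c_idx)
            if t_len == c_len:
                for i in t_idx:
                    matched_truth[i] = True
                for j in c_idx:
                    matched_call[j] = True

    n_truth = len(truth_vars)
    n_detected = sum(matched_truth)
    n_extra = sum(1 for m in matched_call if not m)
    return ConcordanceRow(
        sample=sample,
        dataset=dataset,
        n_truth=n_truth,
        n_detected=n_detected,
        n_false_negative=n_truth - n_detected,
        n_extra=n_extra,
    )


def detection_rate(rows: Sequence[ConcordanceRow], ndigits: int | None = 1) -> float:
    """Pooled detection rate: 100 x sum(detected) / sum(truth), in percent.

    Reported to one decimal by default (``ndigits=None`` for full
    precision).  Undefined when the pooled truth count is zero.
    """
    if not rows:
        raise ValueError("need at least one concordance row")
    total_truth = sum(r.n_truth for r in rows)
    total_detected = sum(r.n_detected for r in rows)
    if total_truth == 0:
        raise ValueError("detection rate undefined: pooled truth count is zero")
    rate = 100.0 * total_detected / total_truth
    return rate if ndigits is None else round_half_up(rate, ndigits)


def heteroplasmy_summary(
    fractions: Sequence[float], ndigits: int | None = 1
) -> tuple[float, float]:
    """Mean and sample (n-1) standard deviation of allele-fraction percents.

    Requires at least two values (the sd is otherwise undefined); rounded
    half-up to one decimal by default, matching tabular presentation.
    """
    vals = [float(v) for v in fractions]
    if len(vals) < 2:
        raise ValueError("need at least two allele fractions for a mean/sd summary")
    n = len(vals)
    mean = sum(vals) / n
    var = sum((v - mean) ** 2 for v in vals) / (n - 1)
    sd = var ** 0.5
    if ndigits is None:
        return mean, sd
    return round_half_up(mean, ndigits), round_half_up(sd, ndigits)
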