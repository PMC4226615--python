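"""Circular reference genomes and two-letter base-class utilities.

The human mitochondrial genome is a small circular molecule (16,569 bp in
the canonical reference).  Throughout this package the "plus" strand is the
reference (light, L) strand — the C-rich strand the canonical reference
sequence is written on — and the "minus" strand is its G-rich complement.
Positions are 1-based at every public interface; internal arrays are
0-based.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

BASE_ORDER = "ACGT"
BASE_INDEX = {b: i for i, b in enumerate(BASE_ORDER)}

#: The six unordered two-letter base classes.  "AC content" of a window is
#: the fraction of its positions holding an A or a C — a base-class content,
#: not an adjacent-dinucleotide frequency.
PAIR_CLASSES = ("GC", "AT", "AC", "GT", "CT", "AG")

COMPLEMENT_BASE = {"A": "T", "T": "A", "C": "G", "G": "C", "N": "N"}

#: Watson-Crick image of each base class (AC on one strand reads GT on the
#: other; GC and AT are self-complementary).
COMPLEMENT_CLASS = {"GC": "GC", "AT": "AT", "AC": "GT", "GT": "AC", "CT": "AG", "AG": "CT"}

_VALID_LETTERS = frozenset("ACGTN")


def class_members(pair_class: str) -> tuple[str, str]:
    """Return the two bases of a pair class, validating the class name."""
    if pair_class not in PAIR_CLASSES:
        raise ValueError(
            f"unknown pair class {pair_class!r}; expected one of {PAIR_CLASSES}"
        )
    return pair_class[0], pair_class[1]


def reverse_complement(sequence: str) -> str:
    return "".join(COMPLEMENT_BASE[b] for b in reversed(sequence))


@dataclass(frozen=True)
class ReferenceGenome:
    """A named reference sequence over {A,C,G,T} (N tolerated, flagged).

    Parameters
    ----------
    name : label used to match alignment files and written to FASTA headers.
    sequence : upper-case base string; lower case input is normalized.
    circular : whether coordinate arithmetic wraps around the origin.
    """

    name: str
    sequence: str
    circular: bool = True

    def __post_init__(self) -> None:
        object.__setattr__(self, "sequence", self.sequence.upper())
        if len(self.sequence) < 1:
            raise ValueError("reference sequence must have length >= 1")
        bad = set(self.sequence) - _VALID_LETTERS
        if bad:
            pos = next(
                i for i, b in enumerate(self.sequence, start=1) if b in bad
            )
            raise ValueError(
                f"invalid symbol {self.sequence[pos - 1]!r} at position {pos}; "
                "alphabet is ACGT (N tolerated)"
            )

    def __len__(self) -> int:
        return len(self.sequence)

    @property
    def has_ambiguous(self) -> bool:
        return "N" in self.sequence

    def base_indices(self) -> np.ndarray:
        """Map the sequence to indices into ACGT; N maps to -1."""
        lut = np.full(128, -1, dtype=np.int8)
        for b, i in BASE_INDEX.items():
            lut[ord(b)] = i
        return lut[np.frombuffer(self.sequence.encode(), dtype=np.uint8)]

    def class_indicator(self, pair_class: str) -> np.ndarray:
        """Per-position 0/1 indicator of membership in a base class."""
        a, b = class_members(pair_class)
        arr = np.frombuffer(self.sequence.encode(), dtype=np.uint8)
        return ((arr == ord(a)) | (arr == ord(b))).astype(float)


def circular_window_content(indicator: np.ndarray, window: int) -> np.ndarray:
    """Centered moving average of an indicator with circular wrap-around.

    The window covers offsets ``[-(window//2), window - window//2 - 1]``
    around each position, so a 150-nt window spans 75 bases upstream and 74
    downstream.  Returns an array of local content fractions in [0, 1].
    """
    if window < 1:
        raise ValueError("window must be >= 1")
    x = np.asarray(indicator, dtype=float)
    n = len(x)
    if window > n:
        raise ValueError(f"window ({window}) exceeds genome length ({n})")
    left = window // 2
    right = window - left - 1
    ext = np.concatenate([x[n - left:], x, x[:right]]) if left or right else x
    c = np.concatenate([[0.0], np.cumsum(ext)])
    return (c[window:] - c[:-window]) / window
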