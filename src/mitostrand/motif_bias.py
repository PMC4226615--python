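"""Base-class composition in fixed bins and composition-vs-coverage curves.

The analysis divides the circular genome into consecutive 150-nt bins,
computes the percentage content of a two-letter base class (GC, AT, AC, GT,
CT or AG) in each bin, and relates it to the mean relative coverage of the
bin.  Grouping bins into 10-point content bands yields a "bias curve":
mean relative coverage as a function of local composition, per strand.
Plus-strand coverage collapsing in the high-AC bands while the minus strand
stays near 1 is the signature of the strand-specific amplification bias.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple

import numpy as np
import pandas as pd

from .genome import PAIR_CLASSES, ReferenceGenome, class_members
from .strand_coverage import RelativeCoverageProfile

DEFAULT_BIN_SIZE = 150
DEFAULT_BAND_WIDTH = 10


def pair_content(sequence: str, pair_class: str) -> float:
    """Percentage of positions whose base belongs to the two-letter class."""
    a, b = class_members(pair_class)
    if not sequence:
        raise ValueError("empty sequence")
    n = 0
    for i, base in enumerate(sequence, start=1):
        if base in "ACGT":
            n += base == a or base == b
        else:
            raise ValueError(f"non-ACGT symbol {base!r} at position {i}")
    return 100.0 * n / len(sequence)


@dataclass
class CompositionBins:
    """Per-bin base-class content percentages over a genome.

    Bins are consecutive, non-overlapping, ``bin_size`` wide and 1-based.
    On a circular genome the final short remainder wraps around to borrow
    its missing bases from the genome start, so every bin holds exactly
    ``bin_size`` bases (16569 = 110 x 150 + 69, hence 111 bins, the last
    covering 16501-16569 plus 1-81).  Complement identities hold per bin:
    GC+AT = AC+GT = CT+AG = 100.
    """

    genome_length: int
    bin_size: int
    starts: np.ndarray  # 1-based bin start positions
    content: dict[str, np.ndarray]  # pair class -> per-bin percentages
    wrap: bool = True

    @property
    def n_bins(self) -> int:
        return len(self.starts)

    def bin_positions(self, i: int) -> np.ndarray:
        """0-based genome positions covered by bin ``i`` (wrap-aware)."""
        start0 = int(self.starts[i]) - 1
        if self.wrap or i < self.n_bins - 1:
            return np.arange(start0, start0 + self.bin_size) % self.genome_length
        return np.arange(start0, self.genome_length)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"start": self.starts, **self.content})


def binned_composition(
    ref: ReferenceGenome, bin_size: int = DEFAULT_BIN_SIZE, wrap: bool | None = None
) -> CompositionBins:
    """Compute all six base-class contents in fixed-width bins.

    ``wrap`` defaults to the genome's circularity; with ``wrap=False`` the
    final bin is truncated at the genome end instead of borrowing from the
    start.  Contents are computed on the reference (plus/L) strand; the
    minus strand's contents follow from the complement identities
    (AC there equals GT here, and so on).
    """
    if bin_size < 1:
        raise ValueError("bin_size must be >= 1")
    if wrap is None:
        wrap = ref.circular
    L = len(ref)
    n_bins = -(-L // bin_size)  # ceil
    starts = np.arange(n_bins) * bin_size + 1
    indicators = {pc: ref.class_indicator(pc) for pc in PAIR_CLASSES}
    content = {pc: np.empty(n_bins) for pc in PAIR_CLASSES}
    for i in range(n_bins):
        start0 = i * bin_size
        stop0 = start0 + bin_size
        if stop0 <= L:
            idx = slice(start0, stop0)
            width = bin_size
        elif wrap:
            idx = np.arange(start0, stop0) % L
            width = bin_size
        else:
            idx = slice(start0, L)
            width = L - start0
        for pc, ind in indicators.items():
            content[pc][i] = 100.0 * float(ind[idx].sum()) / width
    return CompositionBins(
        genome_length=L, bin_size=bin_size, starts=starts, content=content, wrap=wrap
    )


class BandStat(NamedTuple):
    """One content band of a bias curve."""

    lower: float  # inclusive
    upper: float  # exclusive, except the top band which is closed at 100
    mean_rc: float  # NaN when the band holds no bins
    n_bins: int


@dataclass
class BiasCurve:
    """Mean relative coverage as a function of base-class content band."""

    pair_class: str
    strand: str  # total / plus / minus
    band_width: float
    bands: list[BandStat]

    def band(self, lower: float) -> BandStat:
        for b in self.bands:
            if b.lower == lower:
                return b
        raise KeyError(f"no band starting at {lower}")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.bands)


def bias_curve(
    bins: CompositionBins,
    rc: RelativeCoverageProfile,
    pair_class: str,
    strand: str = "total",
    band_width: float = DEFAULT_BAND_WIDTH,
) -> BiasCurve:
    """Group bins into content bands and average their relative coverage.

    For every bin the mean of the selected rc series over the bin's
    positions is computed; bins are then grouped into bands
    [0,10), [10,20), ..., [90,100] of their content percentage, and each
    band reports the mean of its bins' means together with the bin count.
    Empty bands carry ``n_bins = 0`` and a NaN mean.
    """
    class_members(pair_class)
    if bins.genome_length != len(rc):
        raise ValueError(
            f"composition bins cover {bins.genome_length} positions but the "
            f"coverage profile has {len(rc)}"
        )
    if not (0 < band_width <= 100):
        raise ValueError("band_width must lie in (0, 100]")
    series = rc.series(strand)
    content = bins.content[pair_class]
    bin_means = np.array([float(series[bins.bin_positions(i)].mean()) for i in range(bins.n_bins)])

    n_bands = int(np.ceil(100.0 / band_width))
    bands: list[BandStat] = []
    for k in range(n_bands):
        lo = k * band_width
        hi = min(lo + band_width, 100.0)
        if k == n_bands - 1:
            mask = (content >= lo) & (content <= hi)  # top band closed at 100
        else:
            mask = (content >= lo) & (content < hi)
        n = int(mask.sum())
        mean_rc = float(bin_means[mask].mean()) if n else float("nan")
        bands.append(BandStat(lo, hi, mean_rc, n))
    return BiasCurve(pair_class=pair_class, strand=strand, band_width=band_width, bands=bands)
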