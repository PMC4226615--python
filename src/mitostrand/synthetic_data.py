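"""Generative model for strand-biased, error-bearing mtDNA-like pileups.

This module emulates the data produced by resequencing a long-range-PCR
amplified circular genome on a short-read instrument:

* a circular reference with controlled two-letter base-class composition
  (so AC-rich regions can be laid down deliberately);
* per-position, per-strand base counts at a target mean depth, with a
  strand-asymmetric sampling weight that is a monotone non-increasing
  function of the local base-class content — the generative inverse of the
  observed phenomenon that plus-strand coverage collapses in AC/CT-rich
  regions while the minus strand is unaffected;
* uniform strand-symmetric substitution errors (no indels, no homopolymer
  or flow-space error modes);
* heteroplasmic variants placed at specified allele fractions before error
  is applied, so truth fractions are well defined;
* a truth manifest echoing the configuration and recording realized
  quantities.

The default depth model is pileup-level: per-strand depths are Poisson with
rate ``mean_depth/2`` times the strand's sampling weight.  A read-level
simulator (:func:`simulate_reads`) is available for building alignment-file
fixtures; the pileup model is the tested default.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, NamedTuple, Sequence

import numpy as np
import yaml

from .genome import (
    BASE_INDEX,
    BASE_ORDER,
    PAIR_CLASSES,
    ReferenceGenome,
    circular_window_content,
    class_members,
)
from .strand_coverage import BaseCountMatrix

__all__ = [
    "BiasModel",
    "SimulationConfig",
    "Variant",
    "TruthManifest",
    "generate_reference",
    "simulate_base_counts",
    "simulate_reads",
    "write_sam",
    "step_weight",
    "mtdna_demo_reference",
    "default_bias_model",
]


def step_weight(threshold: float = 0.8, low: float = 0.02) -> Callable[[np.ndarray], np.ndarray]:
    """Step bias weight: 1 below the content threshold, ``low`` at or above.

    Mirrors the observed regime change where plus-strand coverage drops
    almost to zero once local AC content reaches ~80%.
    """
    if not 0.0 <= low <= 1.0:
        raise ValueError("low weight must lie in [0, 1]")

    def fn(content):
        content = np.asarray(content, dtype=float)
        return np.where(content < threshold, 1.0, low)

    return fn


@dataclass
class BiasModel:
    """Strand-asymmetric sampling bias driven by local base-class content.

    ``weight_fn`` maps local content fraction in [0, 1] to a plus-strand
    sampling weight in [0, 1]; it must be monotone non-increasing with
    ``weight_fn(0) == 1``.  The minus-strand weight is fixed at 1.  Local
    content is measured on a centered circular window (default 150 nt,
    matching the analysis bin width).
    """

    pair_class: str
    weight_fn: Callable[[np.ndarray], np.ndarray]
    window: int = 150

    def __post_init__(self) -> None:
        class_members(self.pair_class)
        if self.window < 1:
            raise ValueError("window must be >= 1")
        grid = np.linspace(0.0, 1.0, 101)
        w = np.asarray(self.weight_fn(grid), dtype=float)
        if abs(w[0] - 1.0) > 1e-9:
            raise ValueError("weight_fn(0) must equal 1")
        if (w < -1e-12).any() or (w > 1 + 1e-12).any():
            raise ValueError("weight_fn must map into [0, 1]")
        if (np.diff(w) > 1e-9).any():
            raise ValueError("weight_fn must be monotone non-increasing")

    def plus_weights(self, ref: ReferenceGenome) -> np.ndarray:
        content = circular_window_content(ref.class_indicator(self.pair_class), self.window)
        return np.clip(np.asarray(self.weight_fn(content), dtype=float), 0.0, 1.0)


class Variant(NamedTuple):
    """A substitution to simulate: 1-based position, ref, alt, allele fraction."""

    position: int
    ref: str
    alt: str
    fraction: float


@dataclass
class SimulationConfig:
    mean_depth: float
    error_rate: float = 0.0
    variants: tuple[Variant, ...] = ()
    seed: int = 0

    def __post_init__(self) -> None:
        if self.mean_depth <= 0:
            raise ValueError("mean_depth must be positive")
        if not 0.0 <= self.error_rate <= 0.05:
            raise ValueError("error_rate must lie in [0, 0.05]")
        self.variants = tuple(Variant(*v) for v in self.variants)
        for v in self.variants:
            if not 0.0 <= v.fraction <= 1.0:
                raise ValueError(f"allele fraction out of [0,1] for {v}")

    def validate_against(self, ref: ReferenceGenome) -> None:
        for v in self.variants:
            if not 1 <= v.position <= len(ref):
                raise ValueError(f"variant position {v.position} outside genome of length {len(ref)}")
            actual = ref.sequence[v.position - 1]
            if actual != v.ref:
                raise ValueError(
                    f"variant at {v.position} declares ref {v.ref!r} but genome has {actual!r}"
                )
            if v.alt not in BASE_ORDER or v.alt == v.ref:
                raise ValueError(f"invalid alt allele for variant at {v.position}")


@dataclass
class TruthManifest:
    """Echo of the simulation inputs plus realized quantities."""

    genome_name: str
    genome_length: int
    mean_depth: float
    error_rate: float
    seed: int
    bias_pair_class: str | None
    realized_mean_depth: float
    realized_error_rate: float
    total_bases: int
    variants: list[dict] = field(default_factory=list)
    n_reads: int | None = None

    def to_yaml(self) -> str:
        return yaml.safe_dump(
            {
                "genome": {"name": self.genome_name, "length": self.genome_length},
                "config": {
                    "mean_depth": self.mean_depth,
                    "error_rate": self.error_rate,
                    "seed": self.seed,
                    "bias_pair_class": self.bias_pair_class,
                },
                "realized": {
                    "mean_depth": self.realized_mean_depth,
                    "error_rate": self.realized_error_rate,
                    "total_bases": self.total_bases,
                    "n_reads": self.n_reads,
                },
                "variants": self.variants,
            },
            sort_keys=False,
        )


def generate_reference(
    length: int,
    segments: Sequence[tuple[str, float, int]],
    seed: int,
    name: str | None = None,
) -> ReferenceGenome:
    """Build a circular reference from base-class composition segments.

    Each segment is ``(pair_class, target_content_fraction, segment_length)``;
    within a segment, exactly ``round(target * segment_length)`` positions
    receive a base from the pair class (uniformly one of its two letters)
    and the rest a base from the complementary pair, in random order.  The
    exact-count construction keeps the realized content within half a
    percentage point of the target regardless of segment length.
    """
    segments = list(segments)
    total = sum(seg_len for _, _, seg_len in segments)
    if total != length:
        raise ValueError(
            f"segment lengths sum to {total}, which does not match requested length {length}"
        )
    rng = np.random.default_rng(seed)
    parts: list[np.ndarray] = []
    for pair_class, target, seg_len in segments:
        members = class_members(pair_class)
        if not 0.0 <= target <= 1.0:
            raise ValueError(f"target fraction {target} outside [0, 1]")
        if seg_len < 1:
            raise ValueError("segment length must be >= 1")
        others = tuple(sorted(set(BASE_ORDER) - set(members)))
        n_in = int(round(target * seg_len))
        letters = np.concatenate(
            [
                rng.choice(list(members), size=n_in),
                rng.choice(list(others), size=seg_len - n_in),
            ]
        )
        parts.append(rng.permutation(letters))
    sequence = "".join(np.concatenate(parts))
    return ReferenceGenome(name=name or f"synthetic_{length}", sequence=sequence, circular=True)


_OTHER_BASES = {b: tuple(i for i in range(4) if i != BASE_INDEX[b]) for b in BASE_ORDER}


def _apply_substitution_errors(
    counts: np.ndarray, error_rate: float, rng: np.random.Generator
) -> int:
    """Substitute each sequenced base to one of the 3 others with prob e.

    Mutates ``counts`` (shape (L, 2, 4)) in place; returns the number of
    substituted bases.
    """
    if error_rate == 0.0:
        return 0
    total_err = 0
    # per source base: remove Binomial(c, e) and redistribute uniformly
    moved = np.zeros_like(counts)
    for b in range(4):
        src = counts[:, :, b]
        errs = rng.binomial(src, error_rate)
        total_err += int(errs.sum())
        dest = rng.multinomial(errs.ravel(), [1 / 3, 1 / 3, 1 / 3]).reshape(errs.shape + (3,))
        others = [i for i in range(4) if i != b]
        moved[:, :, b] -= errs
        for k, o in enumerate(others):
            moved[:, :, o] += dest[:, :, k]
    counts += moved
    return total_err


def simulate_base_counts(
    ref: ReferenceGenome,
    cfg: SimulationConfig,
    bias: BiasModel | None = None,
) -> tuple[BaseCountMatrix, TruthManifest]:
    """Draw a strand-resolved pileup under the generative model.

    Per-strand depths are Poisson: the minus strand at rate
    ``mean_depth / 2`` everywhere, the plus strand at rate
    ``mean_depth / 2 × weight_fn(local content)`` (weight 1 when ``bias``
    is None, giving a balanced 50/50 strand split with expected total depth
    ``mean_depth``).  Variant alleles are drawn Binomial(depth, fraction)
    before errors; every sequenced base is then substituted uniformly to one
    of the three other bases with probability ``error_rate``.
    """
    cfg.validate_against(ref)
    rng = np.random.default_rng(cfg.seed)
    L = len(ref)
    ref_idx = ref.base_indices()
    if (ref_idx < 0).any():
        raise ValueError("cannot simulate over ambiguous (N) reference positions")

    half = cfg.mean_depth / 2.0
    w_plus = bias.plus_weights(ref) if bias is not None else np.ones(L)
    plus_d = rng.poisson(half * w_plus)
    minus_d = rng.poisson(np.full(L, half))

    counts = np.zeros((L, 2, 4), dtype=np.int64)
    counts[np.arange(L), 0, ref_idx] = plus_d
    counts[np.arange(L), 1, ref_idx] = minus_d

    variant_records: list[dict] = []
    for v in cfg.variants:
        i = v.position - 1
        r, a = BASE_INDEX[v.ref], BASE_INDEX[v.alt]
        alt_counts = [int(rng.binomial(int(counts[i, s, r]), v.fraction)) for s in (0, 1)]
        for s, n_alt in enumerate(alt_counts):
            counts[i, s, r] -= n_alt
            counts[i, s, a] += n_alt
        depth_i = int(plus_d[i] + minus_d[i])
        realized = (sum(alt_counts) / depth_i) if depth_i else float("nan")
        variant_records.append(
            {
                "position": v.position,
                "ref": v.ref,
                "alt": v.alt,
                "target_fraction": float(v.fraction),
                "realized_fraction": float(realized),
                "depth": depth_i,
            }
        )

    n_err = _apply_substitution_errors(counts, cfg.error_rate, rng)
    total_bases = int(counts.sum())
    manifest = TruthManifest(
        genome_name=ref.name,
        genome_length=L,
        mean_depth=cfg.mean_depth,
        error_rate=cfg.error_rate,
        seed=cfg.seed,
        bias_pair_class=bias.pair_class if bias is not None else None,
        realized_mean_depth=total_bases / L,
        realized_error_rate=(n_err / total_bases) if total_bases else float("nan"),
        total_bases=total_bases,
        variants=variant_records,
    )
    return BaseCountMatrix(counts), manifest


class SimRead(NamedTuple):
    name: str
    start: int  # 0-based leftmost reference position
    reverse: bool
    sequence: str


def simulate_reads(
    ref: ReferenceGenome,
    cfg: SimulationConfig,
    bias: BiasModel | None = None,
    read_length: int = 150,
) -> tuple[list[SimRead], TruthManifest]:
    """Read-level counterpart of :func:`simulate_base_counts`.

    Reads are placed uniformly without crossing the origin (so the fixture
    stays a plain linear alignment file); minus-strand reads are drawn at
    the balanced rate and plus-strand candidates are thinned by the bias
    weight at the read midpoint.  Variants and substitution errors are
    applied per read base exactly as in the pileup model.
    """
    cfg.validate_against(ref)
    L = len(ref)
    if read_length > L:
        raise ValueError("read_length exceeds genome length")
    rng = np.random.default_rng(cfg.seed)
    n_each = int(round(cfg.mean_depth * L / (2 * read_length)))
    w_plus = bias.plus_weights(ref) if bias is not None else np.ones(L)

    var_at: dict[int, Variant] = {v.position - 1: v for v in cfg.variants}
    seq_arr = np.array(list(ref.sequence))

    reads: list[SimRead] = []
    n_err = 0
    alt_seen = {i: 0 for i in var_at}
    cover = {i: 0 for i in var_at}
    serial = 0
    for strand, reverse in ((0, False), (1, True)):
        starts = rng.integers(0, L - read_length + 1, size=n_each)
        if strand == 0:
            keep = rng.random(n_each) < w_plus[starts + read_length // 2]
            starts = starts[keep]
        for s0 in starts:
            s0 = int(s0)
            bases = seq_arr[s0 : s0 + read_length].copy()
            for i in range(s0, s0 + read_length):
                v = var_at.get(i)
                if v is not None:
                    cover[i] += 1
                    if rng.random() < v.fraction:
                        bases[i - s0] = v.alt
                        alt_seen[i] += 1
            if cfg.error_rate:
                hit = rng.random(read_length) < cfg.error_rate
                for j in np.nonzero(hit)[0]:
                    choices = [b for b in BASE_ORDER if b != bases[j]]
                    bases[j] = choices[rng.integers(0, 3)]
                    n_err += 1
            reads.append(SimRead(f"r{serial:07d}", s0, reverse, "".join(bases)))
            serial += 1

    total_bases = len(reads) * read_length
    manifest = TruthManifest(
        genome_name=ref.name,
        genome_length=L,
        mean_depth=cfg.mean_depth,
        error_rate=cfg.error_rate,
        seed=cfg.seed,
        bias_pair_class=bias.pair_class if bias is not None else None,
        realized_mean_depth=total_bases / L,
        realized_error_rate=(n_err / total_bases) if total_bases else float("nan"),
        total_bases=total_bases,
        variants=[
            {
                "position": i + 1,
                "ref": var_at[i].ref,
                "alt": var_at[i].alt,
                "target_fraction": float(var_at[i].fraction),
                "realized_fraction": (alt_seen[i] / cover[i]) if cover[i] else float("nan"),
                "depth": cover[i],
            }
            for i in sorted(var_at)
        ],
        n_reads=len(reads),
    )
    return reads, manifest


def write_sam(reads: Sequence[SimRead], ref: ReferenceGenome, path) -> None:
    """Write simulated reads as a coordinate-sorted plain-text SAM file."""
    with open(path, "w") as fh:
        fh.write("@HD\tVN:1.6\tSO:coordinate\n")
        fh.write(f"@SQ\tSN:{ref.name}\tLN:{len(ref)}\n")
        for r in sorted(reads, key=lambda r: r.start):
            flag = 16 if r.reverse else 0
            fh.write(
                f"{r.name}\t{flag}\t{ref.name}\t{r.start + 1}\t60\t"
                f"{len(r.sequence)}M\t*\t0\t0\t{r.sequence}\t*\n"
            )


# --- study-condition defaults -------------------------------------------------

#: mtDNA-like base-class layout: background at the mitochondrial genome's
#: overall AC content (~62%) with two AC-rich (92%) blocks of 900 nt,
#: together ~11% of the genome — emulating the regional plus-strand
#: coverage troughs that affect roughly a tenth of the molecule.  Segment
#: lengths are multiples of the 150-nt bin so rich blocks align with
#: analysis bins, and blocks are long relative to the 150-nt bias window so
#: their interiors sit fully inside the suppressed regime.
MTDNA_DEMO_SEGMENTS: tuple[tuple[str, float, int], ...] = (
    ("AC", 0.62, 4500),
    ("AC", 0.92, 900),
    ("AC", 0.62, 5400),
    ("AC", 0.92, 900),
    ("AC", 0.62, 4869),
)

MTDNA_LENGTH = 16569


def mtdna_demo_reference(seed: int = 0) -> ReferenceGenome:
    """A 16,569-nt circular genome with AC-rich blocks (see MTDNA_DEMO_SEGMENTS)."""
    return generate_reference(MTDNA_LENGTH, MTDNA_DEMO_SEGMENTS, seed=seed, name="mt_demo")


def default_bias_model() -> BiasModel:
    """Plus-strand suppression (weight 0.02) at local AC content >= 80%."""
    return BiasModel(pair_class="AC", weight_fn=step_weight(0.8, 0.02), window=150)


_TRANSITION = {"A": "G", "G": "A", "C": "T", "T": "C"}

#: (position, minor-allele fraction) pairs for the demo heteroplasmies,
#: spanning the 1-60% range at which heteroplasmy is typically reported,
#: including two below-5% cases near the detection threshold.
DEMO_HETEROPLASMIES: tuple[tuple[int, float], ...] = (
    (2500, 0.12),
    (5609, 0.04),
    (7453, 0.53),
    (8207, 0.02),
    (12071, 0.16),
)


def demo_variants(ref: ReferenceGenome) -> tuple[Variant, ...]:
    """Transition heteroplasmies at fixed positions/fractions on ``ref``."""
    out = []
    for pos, frac in DEMO_HETEROPLASMIES:
        r = ref.sequence[pos - 1]
        out.append(Variant(pos, r, _TRANSITION[r], frac))
    return tuple(out)
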