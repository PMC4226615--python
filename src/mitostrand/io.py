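"""Readers and writers: FASTA, alignment files, pileup TSV, variant tables.

The package's native pileup dialect is a plain tab-separated file with a
``#``-prefixed header naming the reference and its length, then one row per
(position, strand) holding the observed A/C/G/T counts::

    # reference=mt_demo length=16569
    position	strand	count_A	count_C	count_G	count_T
    1	+	1483	2	0	1
    1	-	1490	1	1	0

Every writer/reader pair round-trips bit-identically on valid data.
"""
from __future__ import annotations

import hashlib
import warnings
from contextlib import contextmanager
from importlib import resources
from pathlib import Path
from typing import Iterator

import numpy as np
import pandas as pd
import pysam
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .genome import ReferenceGenome
from .strand_coverage import BaseCountMatrix
from .variant_concordance import ConcordanceRow, VariantCall, parse_mt_variant

# --- FASTA -------------------------------------------------------------------


def read_fasta(path) -> ReferenceGenome:
    """Read a single-record FASTA into a :class:`ReferenceGenome`.

    Case is normalized to upper; ambiguous N bases are tolerated with a
    warning; multi-record files are rejected listing the record names.
    """
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise ValueError(f"no FASTA records in {path}")
    if len(records) > 1:
        names = ", ".join(r.id for r in records)
        raise ValueError(f"expected a single FASTA record in {path}, found: {names}")
    rec = records[0]
    ref = ReferenceGenome(name=rec.id, sequence=str(rec.seq).upper())
    if ref.has_ambiguous:
        warnings.warn(f"reference {ref.name} contains ambiguous N bases", stacklevel=2)
    return ref


def write_fasta(ref: ReferenceGenome, path, width: int = 70) -> None:
    rec = SeqRecord(Seq(ref.sequence), id=ref.name, description="")
    with open(path, "w") as fh:
        SeqIO.write([rec], fh, "fasta")


# --- alignment files ---------------------------------------------------------


@contextmanager
def read_alignments(path, reference: str | None = None) -> Iterator:
    """Yield mapped primary alignment records from a SAM/BAM file.

    Secondary and supplementary records are filtered out here; callers see
    only primary mapped reads.  ``reference``, when given, must exist in
    the file header.
    """
    mode = "rb" if str(path).endswith(".bam") else "r"
    af = pysam.AlignmentFile(str(path), mode, check_sq=False)
    try:
        if reference is not None and reference not in af.references:
            raise ValueError(
                f"reference {reference!r} not in alignment file (has {list(af.references)})"
            )
        n_skipped = 0

        def stream():
            nonlocal n_skipped
            for read in af.fetch(until_eof=True):
                if read.is_unmapped or read.is_secondary or read.is_supplementary:
                    n_skipped += 1
                    continue
                yield read

        yield stream()
    finally:
        af.close()


# --- pileup TSV --------------------------------------------------------------

_PILEUP_COLUMNS = ["position", "strand", "count_A", "count_C", "count_G", "count_T"]


def write_pileup(counts: BaseCountMatrix, ref: ReferenceGenome, path) -> None:
    """Write per-position, per-strand base counts in the native TSV dialect."""
    L = len(counts)
    if L != len(ref):
        raise ValueError("pileup length does not match reference length")
    arr = counts.counts
    with open(path, "w") as fh:
        fh.write(f"# reference={ref.name} length={L}\n")
        fh.write("\t".join(_PILEUP_COLUMNS) + "\n")
        for i in range(L):
            for s, strand in enumerate("+-"):
                a, c, g, t = (int(x) for x in arr[i, s])
                fh.write(f"{i + 1}\t{strand}\t{a}\t{c}\t{g}\t{t}\n")


def read_pileup(path) -> tuple[BaseCountMatrix, str, int]:
    """Read the native pileup dialect; returns (counts, reference name, length)."""
    with open(path) as fh:
        header = fh.readline().strip()
        if not header.startswith("#"):
            raise ValueError(f"pileup {path} lacks the '# reference=... length=...' header")
        meta = dict(
            tok.split("=", 1) for tok in header.lstrip("#").split() if "=" in tok
        )
        try:
            name = meta["reference"]
            length = int(meta["length"])
        except KeyError as exc:
            raise ValueError(f"pileup header missing field {exc}") from None
        df = pd.read_csv(fh, sep="\t")
    if list(df.columns) != _PILEUP_COLUMNS:
        raise ValueError(f"unexpected pileup columns {list(df.columns)}")
    if (df["position"] < 1).any() or (df["position"] > length).any():
        raise ValueError("pileup positions outside declared reference length")
    dup = df.duplicated(subset=["position", "strand"])
    if dup.any():
        raise ValueError("pileup holds more than one row per (position, strand)")
    arr = np.zeros((length, 2, 4), dtype=np.int64)
    strand_idx = df["strand"].map({"+": 0, "-": 1})
    if strand_idx.isna().any():
        raise ValueError("pileup strand column must be '+' or '-'")
    vals = df[["count_A", "count_C", "count_G", "count_T"]].to_numpy()
    if (vals < 0).any():
        raise ValueError("pileup counts must be non-negative")
    arr[df["position"].to_numpy() - 1, strand_idx.to_numpy()] = vals
    return BaseCountMatrix(arr), name, length


# --- tabular outputs with traceable metadata ---------------------------------


def config_digest(payload: str) -> str:
    return hashlib.sha256(payload.encode()).hexdigest()[:12]


def write_table(df: pd.DataFrame, path, metadata: dict | None = None) -> None:
    """Write a TSV with ``#``-prefixed metadata header lines."""
    with open(path, "w") as fh:
        for key, value in (metadata or {}).items():
            fh.write(f"# {key}={value}\n")
        df.to_csv(fh, sep="\t", index=False)


def read_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#")


# --- variant tables ----------------------------------------------------------


def read_variant_table(path) -> list[VariantCall]:
    """Read a calls/truth TSV: columns sample, dataset, variant, fraction_pct.

    ``fraction_pct`` may be empty; the variant column uses m.-notation.
    """
    df = read_table(path)
    required = {"sample", "dataset", "variant"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"variant table missing columns {sorted(missing)}")
    calls = []
    for row in df.itertuples(index=False):
        frac = getattr(row, "fraction_pct", None)
        frac = None if frac is None or pd.isna(frac) else float(frac)
        calls.append(
            parse_mt_variant(
                row.variant, fraction=frac, sample=str(row.sample), dataset=str(row.dataset)
            )
        )
    return calls


def read_concordance_counts(path=None) -> list[ConcordanceRow]:
    """Read a published-counts table into concordance rows.

    Columns: sample, platform, prep, n_truth, n_detected, n_false_negative,
    n_extra.  ``path=None`` loads the packaged panel of published Sanger-vs-
    MPS counts (six samples, three library preparations per platform).
    """
    if path is None:
        path = resources.files("mitostrand") / "data" / "sanger_concordance_counts.tsv"
    df = read_table(path)
    rows = []
    for r in df.itertuples(index=False):
        rows.append(
            ConcordanceRow(
                sample=str(r.sample),
                dataset=f"{r.platform}/{r.prep}",
                n_truth=int(r.n_truth),
                n_detected=int(r.n_detected),
                n_false_negative=int(r.n_false_negative),
                n_extra=int(r.n_extra),
            )
        )
    return rows


def read_heteroplasmy_panel(path=None) -> pd.DataFrame:
    """Read a heteroplasmy panel: sample, variant, platform, prep, fraction_pct.

    ``path=None`` loads the packaged panel of published per-method
    minor-allele fractions for the heteroplasmic variants.
    """
    if path is None:
        path = resources.files("mitostrand") / "data" / "heteroplasmy_panel.tsv"
    df = read_table(path)
    required = {"sample", "variant", "platform", "prep", "fraction_pct"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"heteroplasmy panel missing columns {sorted(missing)}")
    return df
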