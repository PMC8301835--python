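"""TSS-anchored GC-content profiles of promoter sequence context.

For every gene a fixed window around its transcription start site
(position 0 = TSS, default −300..+200 bp) is extracted on the coding
strand — minus-strand genes are reverse-complemented so +1 is always the
first transcribed position.  The per-position fraction of G/C across a
gene set, lightly smoothed, is the GC profile; comparing the profiles of
two gene sets against the all-gene background follows the standard
promoter-stability readout (GC content as a proxy for duplex stability).
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq

from .annotation import GenomeAnnotation

DEFAULT_UPSTREAM = 300
DEFAULT_DOWNSTREAM = 200
DEFAULT_SMOOTHING = 21

_VALID = frozenset("ACGTN")


@dataclass(frozen=True)
class PromoterContext:
    """Coding-strand sequence spanning [−upstream, +downstream) around one TSS."""

    gene_id: str
    sequence: str
    upstream: int
    downstream: int
    flagged: bool = False  # >50% ambiguous bases

    def __post_init__(self) -> None:
        if len(self.sequence) != self.upstream + self.downstream:
            raise ValueError(
                f"{self.gene_id}: context length {len(self.sequence)} != "
                f"{self.upstream + self.downstream}"
            )


@dataclass(frozen=True)
class GCProfile:
    """Mean GC fraction per position relative to the TSS, across a gene set."""

    positions: np.ndarray
    values: np.ndarray  # smoothed
    raw_values: np.ndarray
    smoothing: int
    n_sequences: int
    set_name: str = "set"


def _circular_slice(seq: str, start: int, end: int) -> str:
    """seq[start:end) on a circular sequence; start may be negative, end > len."""
    L = len(seq)
    span = end - start
    if span > L:
        raise ValueError("slice longer than the chromosome")
    start %= L
    if start + span <= L:
        return seq[start : start + span]
    return seq[start:] + seq[: start + span - L]


def read_genome(fasta: str | Path) -> str:
    """Read a single-contig genome FASTA; bases outside {A,C,G,T,N} are rejected."""
    records = list(SeqIO.parse(str(fasta), "fasta"))
    if len(records) != 1:
        raise ValueError(f"{fasta}: expected exactly one contig, found {len(records)}")
    seq = str(records[0].seq).upper()
    bad = set(seq) - _VALID
    if bad:
        raise ValueError(f"{fasta}: unsupported characters {sorted(bad)}")
    return seq


def extract_contexts(
    fasta: str | Path,
    annotation: GenomeAnnotation,
    upstream: int = DEFAULT_UPSTREAM,
    downstream: int = DEFAULT_DOWNSTREAM,
    gene_ids: Iterable[str] | None = None,
    circular: bool = True,
) -> list[PromoterContext]:
    """Extract the promoter context of each gene from the genome sequence.

    Plus-strand gene at TSS t: genomic ``[t-upstream, t+downstream)``.
    Minus-strand gene: reverse complement of
    ``[t-downstream+1, t+upstream+1)``, so the returned string always reads
    5'→3' on the coding strand with the TSS at index ``upstream``.
    Extraction wraps through the origin on circular chromosomes; with
    ``circular=False`` genes whose context crosses a boundary are dropped
    with a logged count.
    """
    if isinstance(fasta, str) and set(fasta) <= _VALID and fasta:
        seq = fasta  # raw chromosome sequence passed directly
    else:
        seq = read_genome(fasta)
    if len(seq) != annotation.chromosome_length:
        raise ValueError(
            f"FASTA length {len(seq)} != annotation chromosome_length "
            f"{annotation.chromosome_length}"
        )
    ids = annotation.gene_ids if gene_ids is None else list(gene_ids)
    contexts: list[PromoterContext] = []
    n_dropped = 0
    span = upstream + downstream
    for gid in ids:
        t = annotation.tss(gid)
        strand = annotation.strand(gid)
        if strand == "+":
            start, end = t - upstream, t + downstream
        else:
            start, end = t - downstream + 1, t + upstream + 1
        if not circular and (start < 0 or end > len(seq)):
            n_dropped += 1
            continue
        s = _circular_slice(seq, start, end)
        if strand == "-":
            s = str(Seq(s).reverse_complement())
        n_frac = s.count("N") / span
        contexts.append(
            PromoterContext(gid, s, upstream, downstream, flagged=n_frac > 0.5)
        )
    if n_dropped:
        warnings.warn(f"{n_dropped} gene(s) dropped: context crosses a contig boundary")
    return contexts


def _smooth(values: np.ndarray, width: int) -> np.ndarray:
    """Centered moving average, NaN-aware, edge windows renormalized."""
    finite = np.isfinite(values)
    filled = np.where(finite, values, 0.0)
    kernel = np.ones(width)
    num = np.convolve(filled, kernel, mode="same")
    den = np.convolve(finite.astype(float), kernel, mode="same")
    with np.errstate(invalid="ignore", divide="ignore"):
        return np.where(den > 0, num / den, np.nan)


def gc_profile(
    contexts: Sequence[PromoterContext],
    smoothing: int = DEFAULT_SMOOTHING,
    set_name: str = "set",
) -> GCProfile:
    """Per-position mean GC fraction across contexts, then smoothed.

    N bases are excluded from both numerator and denominator; positions
    with no usable base are NaN and flagged with a warning.
    """
    if not contexts:
        raise ValueError("no promoter contexts supplied")
    up, down = contexts[0].upstream, contexts[0].downstream
    if any(c.upstream != up or c.downstream != down for c in contexts):
        raise ValueError("contexts have mismatched spans")
    span = up + down
    if smoothing % 2 == 0 or not 1 <= smoothing <= span:
        raise ValueError("smoothing width must be odd and within the span")
    arr = np.frombuffer(
        "".join(c.sequence for c in contexts).encode("ascii"), dtype="S1"
    ).reshape(len(contexts), span)
    is_gc = (arr == b"G") | (arr == b"C")
    is_n = arr == b"N"
    usable = (~is_n).sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        raw = np.where(usable > 0, is_gc.sum(axis=0) / usable, np.nan)
    if (usable == 0).any():
        warnings.warn("positions with no unambiguous base: profile undefined there")
    smoothed = _smooth(raw, smoothing) if smoothing > 1 else raw.copy()
    positions = np.arange(-up, down)
    return GCProfile(positions, smoothed, raw, smoothing, len(contexts), set_name)


def compare_gc_profiles(
    set_a: GCProfile, set_b: GCProfile, all_genes: GCProfile
) -> tuple[pd.DataFrame, float]:
    """Align two set profiles with the all-gene background.

    Returns the per-position table (position, gc_all, gc_setA, gc_setB,
    diff) and the mean A−B difference over the span.
    """
    for p in (set_a, set_b):
        if not np.array_equal(p.positions, all_genes.positions) or p.smoothing != all_genes.smoothing:
            raise ValueError("profiles have mismatched spans or smoothing")
    diff = set_a.values - set_b.values
    table = pd.DataFrame(
        {
            "position": all_genes.positions,
            "gc_all": all_genes.values,
            "gc_setA": set_a.values,
            "gc_setB": set_b.values,
            "diff": diff,
        }
    )
    return table, float(np.nanmean(diff))


def write_gc_table(table: pd.DataFrame, path: str | Path) -> None:
    table.to_csv(path, sep="\t", index=False, float_format="%.6g")
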