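"""Circular-chromosome gene annotation.

Coordinates are 0-based, half-open and circular throughout the package:
every TSS lies in ``[0, chromosome_length)`` and windows or promoter
contexts may wrap through the origin.  GFF3 input (1-based, inclusive) is
converted at the boundary.
"""
from __future__ import annotations

import io
import re
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

STRANDS = frozenset({"+", "-"})

_LENGTH_RE = re.compile(r"#\s*chromosome_length\s*=\s*(\d+)")


class AnnotationError(ValueError):
    """Raised for malformed or inconsistent annotation input."""


@dataclass(frozen=True)
class GenomeAnnotation:
    """Gene TSS positions and strands on one circular chromosome.

    Parameters
    ----------
    chromosome_length
        Length of the circular chromosome in base pairs.
    genes
        DataFrame with columns ``gene_id`` (unique), ``tss`` (0-based,
        ``0 <= tss < chromosome_length``) and ``strand`` (``+``/``-``).
    """

    chromosome_length: int
    genes: pd.DataFrame

    def __post_init__(self) -> None:
        if self.chromosome_length <= 0:
            raise AnnotationError("chromosome_length must be positive")
        required = {"gene_id", "tss", "strand"}
        if not required.issubset(self.genes.columns):
            raise AnnotationError(f"annotation table needs columns {sorted(required)}")
        dup = self.genes["gene_id"].duplicated()
        if dup.any():
            names = self.genes.loc[dup, "gene_id"].tolist()[:5]
            raise AnnotationError(f"duplicate gene_id(s): {names}")
        bad = (self.genes["tss"] < 0) | (self.genes["tss"] >= self.chromosome_length)
        if bad.any():
            g = self.genes.loc[bad].iloc[0]
            raise AnnotationError(
                f"gene {g['gene_id']!r} has tss {g['tss']} outside "
                f"[0, {self.chromosome_length})"
            )
        if not set(self.genes["strand"]).issubset(STRANDS):
            raise AnnotationError("strand must be '+' or '-'")
        # normalized dtypes + gene_id-indexed view for O(1) lookups
        tidy = self.genes.astype({"tss": np.int64}).reset_index(drop=True)
        object.__setattr__(self, "genes", tidy)
        object.__setattr__(self, "_by_id", tidy.set_index("gene_id"))

    # -- container protocol -------------------------------------------------
    def __len__(self) -> int:
        return len(self.genes)

    def __contains__(self, gene_id: str) -> bool:
        return gene_id in self._by_id.index

    @property
    def gene_ids(self) -> list[str]:
        return self.genes["gene_id"].tolist()

    @property
    def gene_id_set(self) -> frozenset[str]:
        return frozenset(self.genes["gene_id"])

    # -- lookups -------------------------------------------------------------
    def positions(self, gene_ids: Iterable[str] | None = None) -> np.ndarray:
        """TSS coordinates for ``gene_ids`` (all genes when None)."""
        if gene_ids is None:
            return self.genes["tss"].to_numpy()
        ids = list(gene_ids)
        missing = [g for g in ids if g not in self._by_id.index]
        if missing:
            raise KeyError(f"gene(s) not in annotation: {missing[:5]}")
        return self._by_id.loc[ids, "tss"].to_numpy()

    def tss(self, gene_id: str) -> int:
        return int(self._by_id.at[gene_id, "tss"])

    def strand(self, gene_id: str) -> str:
        return str(self._by_id.at[gene_id, "strand"])


def _load_tsv(path: Path) -> GenomeAnnotation:
    length = None
    with open(path) as fh:
        first = fh.readline()
    m = _LENGTH_RE.match(first)
    if m:
        length = int(m.group(1))
    df = pd.read_csv(path, sep="\t", comment=None, skiprows=1 if m else 0)
    if length is None:
        raise AnnotationError(
            f"{path}: TSV annotation must start with '#chromosome_length=<bp>'"
        )
    return GenomeAnnotation(chromosome_length=length, genes=df)


def _parse_gff_attributes(attr: str) -> dict[str, str]:
    out = {}
    for field in attr.strip().split(";"):
        if "=" in field:
            k, v = field.split("=", 1)
            out[k.strip()] = v.strip()
    return out


def _load_gff3(path: Path) -> GenomeAnnotation:
    length = None
    rows: list[str] = []
    with open(path) as fh:
        for line in fh:
            if line.startswith("##sequence-region"):
                parts = line.split()
                if len(parts) >= 4:
                    length = int(parts[3])
            elif line.startswith("#") or not line.strip():
                continue
            else:
                rows.append(line)
    if length is None:
        raise AnnotationError(f"{path}: missing '##sequence-region' directive")
    if not rows:
        return GenomeAnnotation(
            chromosome_length=length,
            genes=pd.DataFrame(columns=["gene_id", "tss", "strand"]),
        )
    cols = ["seqid", "source", "type", "start", "end", "score", "strand", "phase", "attributes"]
    df = pd.read_csv(
        io.StringIO("".join(rows)), sep="\t", names=cols, dtype={"start": int, "end": int}
    )
    df = df[df["type"] == "gene"]
    records = []
    for _, r in df.iterrows():
        attrs = _parse_gff_attributes(r["attributes"])
        gid = attrs.get("ID") or attrs.get("gene_id") or attrs.get("Name")
        if gid is None:
            raise AnnotationError(f"gene feature at {r['start']} lacks ID attribute")
        # 1-based inclusive -> 0-based TSS: start of transcription on each strand
        tss = r["start"] - 1 if r["strand"] == "+" else r["end"] - 1
        records.append((gid, tss, r["strand"]))
    genes = pd.DataFrame(records, columns=["gene_id", "tss", "strand"])
    return GenomeAnnotation(chromosome_length=length, genes=genes)


def load_annotation(path: str | Path, format: str | None = None) -> GenomeAnnotation:
    """Load a gene annotation from TSV or GFF3.

    TSV dialect: first line ``#chromosome_length=<bp>``, then a header
    ``gene_id<TAB>tss<TAB>strand`` with 0-based TSS coordinates.  GFF3:
    length from ``##sequence-region``; TSS is the feature start for
    ``+`` genes and ``end - 1`` (0-based) for ``-`` genes.
    """
    path = Path(path)
    if format is None:
        format = "gff3" if path.suffix.lower() in {".gff", ".gff3"} else "tsv"
    if format == "gff3":
        return _load_gff3(path)
    if format == "tsv":
        return _load_tsv(path)
    raise ValueError(f"unknown annotation format: {format!r}")


def write_annotation(ann: GenomeAnnotation, path: str | Path, format: str = "tsv") -> None:
    """Write an annotation in the dialect :func:`load_annotation` reads."""
    path = Path(path)
    if format == "tsv":
        with open(path, "w") as fh:
            fh.write(f"#chromosome_length={ann.chromosome_length}\n")
            ann.genes[["gene_id", "tss", "strand"]].to_csv(fh, sep="\t", index=False)
    elif format == "gff3":
        with open(path, "w") as fh:
            fh.write("##gff-version 3\n")
            fh.write(f"##sequence-region chr 1 {ann.chromosome_length}\n")
            for _, r in ann.genes.iterrows():
                # single-bp feature anchored at the TSS round-trips exactly
                pos = int(r["tss"]) + 1
                fh.write(
                    f"chr\tcouplonscan\tgene\t{pos}\t{pos}\t.\t{r['strand']}\t.\tID={r['gene_id']}\n"
                )
    else:
        raise ValueError(f"unknown annotation format: {format!r}")


def circular_distance(a: np.ndarray | int, b: np.ndarray | int, length: int) -> np.ndarray:
    """Shortest distance between positions on a circle of given length."""
    d = np.abs(np.asarray(a) - np.asarray(b)) % length
    return np.minimum(d, length - d)
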