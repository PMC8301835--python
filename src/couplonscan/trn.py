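"""Transcriptional regulatory network model: regulons and couplons.

A *regulon* is the set of genes targeted by one regulator (a NAP, a sigma
factor, or a global transcription factor).  A *couplon* is the
intersection of a NAP/global-TF regulon with a sigma-factor regulon —
the genes under joint control of that regulator pair.  Couplon membership
is unsigned: activation/repression annotations are kept as metadata but
do not stratify the intersection (an optional effect filter is provided).
"""
from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd
import yaml

from .annotation import GenomeAnnotation

REGULATOR_CLASSES = frozenset({"NAP", "sigma", "globalTF"})
EFFECTS = frozenset({"activation", "repression", "dual", "unknown"})

_EFFECT_ALIASES = {
    "+": "activation",
    "-": "repression",
    "+-": "dual",
    "-+": "dual",
    "?": "unknown",
    "activator": "activation",
    "repressor": "repression",
}


class TRNError(ValueError):
    """Raised for malformed regulatory-network input."""


class CouplonClassError(ValueError):
    """Raised when a couplon is built from the wrong regulator classes."""


def _canonical_effect(effect: str, line_no: int | None = None) -> str:
    e = str(effect).strip()
    e = _EFFECT_ALIASES.get(e, e.lower() if e.lower() in EFFECTS else e)
    e = _EFFECT_ALIASES.get(e, e)
    if e not in EFFECTS:
        where = f" (line {line_no})" if line_no is not None else ""
        raise TRNError(f"unknown effect {effect!r}{where}")
    return e


def _combine_effects(a: str, b: str) -> str:
    """Collapse duplicate regulator→target rows: conflicting signs become 'dual'."""
    if a == b:
        return a
    known = {a, b} - {"unknown"}
    if known == {"activation", "repression"} or "dual" in known:
        return "dual"
    return known.pop() if known else "unknown"


@dataclass(frozen=True)
class Regulon:
    """One regulator and its signed target set."""

    regulator: str
    regulator_class: str
    members: Mapping[str, str]  # gene_id -> effect

    def __post_init__(self) -> None:
        if self.regulator_class not in REGULATOR_CLASSES:
            raise TRNError(
                f"regulator_class must be one of {sorted(REGULATOR_CLASSES)}, "
                f"got {self.regulator_class!r}"
            )
        object.__setattr__(self, "members", dict(self.members))

    @property
    def gene_ids(self) -> frozenset[str]:
        return frozenset(self.members)

    @property
    def size(self) -> int:
        return len(self.members)

    def filtered(self, effects: Iterable[str]) -> "Regulon":
        """Sub-regulon restricted to the given effect signs."""
        keep = set(effects)
        return Regulon(
            self.regulator,
            self.regulator_class,
            {g: e for g, e in self.members.items() if e in keep},
        )


@dataclass(frozen=True)
class Couplon:
    """Intersection of a NAP/global-TF regulon with a sigma-factor regulon."""

    nap_or_tf: str
    sigma: str
    members: frozenset[str]
    parent_sizes: tuple[int, int]

    @property
    def name(self) -> str:
        return f"{self.nap_or_tf}/{self.sigma}"

    @property
    def size(self) -> int:
        return len(self.members)


@dataclass
class RegulonSet:
    """Regulons keyed by regulator name, tied to the annotation they reference.

    Member genes absent from the annotation are dropped at construction and
    counted in ``dropped_targets`` (per regulator) / ``n_dropped`` (total).
    ``regulator_genes`` optionally maps a regulator to its own gene in the
    annotation (used for regulator-vs-regulon expression comparisons).
    """

    regulons: dict[str, Regulon]
    annotation: GenomeAnnotation
    dropped_targets: dict[str, int] = field(default_factory=dict)
    regulator_genes: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        known = self.annotation.gene_id_set
        cleaned: dict[str, Regulon] = {}
        for name, reg in self.regulons.items():
            bad = reg.gene_ids - known
            if bad:
                self.dropped_targets[name] = self.dropped_targets.get(name, 0) + len(bad)
                reg = Regulon(
                    reg.regulator,
                    reg.regulator_class,
                    {g: e for g, e in reg.members.items() if g in known},
                )
            cleaned[name] = reg
        self.regulons = cleaned

    @property
    def n_dropped(self) -> int:
        return sum(self.dropped_targets.values())

    def __getitem__(self, name: str) -> Regulon:
        return self.regulons[name]

    def __contains__(self, name: str) -> bool:
        return name in self.regulons

    def __iter__(self):
        return iter(self.regulons.values())

    def __len__(self) -> int:
        return len(self.regulons)

    @property
    def names(self) -> list[str]:
        return list(self.regulons)

    def by_class(self, regulator_class: str) -> list[Regulon]:
        return [r for r in self if r.regulator_class == regulator_class]


def load_regulator_classes(path: str | Path) -> dict[str, str]:
    """Read a regulator→class map from YAML or JSON."""
    path = Path(path)
    with open(path) as fh:
        data = json.load(fh) if path.suffix == ".json" else yaml.safe_load(fh)
    if not isinstance(data, dict):
        raise TRNError(f"{path}: regulator class map must be a mapping")
    bad = {k: v for k, v in data.items() if v not in REGULATOR_CLASSES}
    if bad:
        raise TRNError(f"invalid regulator classes: {bad}")
    return dict(data)


def load_trn(
    path: str | Path,
    classes: Mapping[str, str] | str | Path,
    annotation: GenomeAnnotation,
) -> RegulonSet:
    """Load a regulator→target table (TSV: regulator, target, effect).

    ``classes`` maps each regulator to NAP / sigma / globalTF, either as a
    dict or as the path of a YAML/JSON file.  Targets missing from the
    annotation are dropped with a logged count; a regulator missing from
    the class map is a hard error.
    """
    if not isinstance(classes, Mapping):
        classes = load_regulator_classes(classes)
    path = Path(path)
    try:
        df = pd.read_csv(path, sep="\t", dtype=str)
    except pd.errors.EmptyDataError:
        warnings.warn(f"{path}: empty TRN file; returning empty RegulonSet")
        return RegulonSet({}, annotation)
    expected = ["regulator", "target", "effect"]
    if list(df.columns[:3]) != expected:
        raise TRNError(f"{path}: expected header {expected}, got {list(df.columns)}")
    if df.empty:
        warnings.warn(f"{path}: TRN has no rows; returning empty RegulonSet")
        return RegulonSet({}, annotation)
    bad_rows = df[expected].isna().any(axis=1)
    if bad_rows.any():
        # +2: header line plus 1-based numbering
        line = int(bad_rows.idxmax()) + 2
        raise TRNError(f"{path}: malformed row at line {line}")

    members: dict[str, dict[str, str]] = {}
    for i, row in enumerate(df.itertuples(index=False)):
        effect = _canonical_effect(row.effect, line_no=i + 2)
        reg = members.setdefault(row.regulator, {})
        reg[row.target] = (
            _combine_effects(reg[row.target], effect) if row.target in reg else effect
        )

    regulons = {}
    for name, targets in members.items():
        if name not in classes:
            raise TRNError(f"regulator {name!r} missing from the class map")
        regulons[name] = Regulon(name, classes[name], targets)
    return RegulonSet(regulons, annotation)


def write_trn(rs: RegulonSet, path: str | Path, classes_path: str | Path | None = None) -> None:
    """Write a RegulonSet in the TSV dialect :func:`load_trn` reads."""
    rows = [
        (reg.regulator, gene, effect)
        for reg in rs
        for gene, effect in sorted(reg.members.items())
    ]
    pd.DataFrame(rows, columns=["regulator", "target", "effect"]).to_csv(
        path, sep="\t", index=False
    )
    if classes_path is not None:
        with open(classes_path, "w") as fh:
            yaml.safe_dump(
                {r.regulator: r.regulator_class for r in rs}, fh, default_flow_style=False
            )


def build_couplon(a: Regulon, b: Regulon, force: bool = False) -> Couplon:
    """Intersect a NAP/global-TF regulon with a sigma-factor regulon.

    Membership ignores effect sign.  ``force=True`` permits exploratory
    pairings of any two regulator classes.
    """
    if not force:
        if a.regulator_class not in {"NAP", "globalTF"} or b.regulator_class != "sigma":
            raise CouplonClassError(
                f"couplon needs (NAP|globalTF, sigma); got "
                f"({a.regulator_class}, {b.regulator_class}) — pass force=True to override"
            )
    return Couplon(
        nap_or_tf=a.regulator,
        sigma=b.regulator,
        members=a.gene_ids & b.gene_ids,
        parent_sizes=(a.size, b.size),
    )


def couplon_table(rs: RegulonSet, naps: list[str], sigmas: list[str]) -> pd.DataFrame:
    """Grid of couplon sizes, NAP/global-TF rows × sigma columns."""
    missing = [n for n in list(naps) + list(sigmas) if n not in rs]
    if missing:
        raise TRNError(f"regulator(s) not in the network: {missing}")
    data = {
        s: [build_couplon(rs[n], rs[s], force=True).size for n in naps] for s in sigmas
    }
    return pd.DataFrame(data, index=list(naps))


def write_couplon_members(
    rs: RegulonSet, naps: list[str], sigmas: list[str], path: str | Path
) -> None:
    """Per-couplon member lists as TSV (couplon, gene)."""
    rows = []
    for n in naps:
        for s in sigmas:
            c = build_couplon(rs[n], rs[s], force=True)
            rows.extend((c.name, g) for g in sorted(c.members))
    pd.DataFrame(rows, columns=["couplon", "gene_id"]).to_csv(path, sep="\t", index=False)
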