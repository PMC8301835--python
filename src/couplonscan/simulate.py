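"""Synthetic genomes, regulatory networks and expression time-courses.

The generator plants exactly the structure the analysis modules look
for, so every pipeline stage is testable without external data:

* a circular chromosome (~4.6 Mb, ~4,000 genes) whose base composition
  follows a linear, replichore-symmetric GC gradient from the origin
  (GC-rich) to the terminus (GC-poor);
* regulons whose members cluster spatially around a configurable center
  and overlap sigma-factor regulons at configurable fractions (the
  planted couplons);
* a growth-phase expression matrix (default sampling 60, 120, 180, 300
  and 420 min after inoculation) where every gene follows one dominant
  temporal program — early, mid or late peaking — plus Gaussian noise,
  and couplon members can be set to follow their sigma parent's program.

A "fis_mutant" condition regenerates the time-course with the planted
late-phase repression removed: the late program no longer declines in
stationary phase, altering the profiles of late-program regulons while
leaving the others untouched.
"""
from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .annotation import GenomeAnnotation, circular_distance
from .temporal import ExpressionTimecourse
from .trn import Regulon, RegulonSet

DEFAULT_TIMEPOINTS = (60, 120, 180, 300, 420)

# Planted temporal programs over the five default timepoints.  The late
# program's stationary-phase decline is the planted repression that the
# "fis_mutant" condition removes.
PROGRAMS: dict[str, dict[str, tuple[float, ...]]] = {
    "wt": {
        "early": (1.0, 0.85, 0.45, 0.15, 0.05),
        "mid": (0.15, 0.55, 1.0, 0.5, 0.2),
        "late": (0.05, 0.1, 0.4, 1.0, 0.25),
        "flat": (0.5, 0.5, 0.5, 0.5, 0.5),
    },
    "fis_mutant": {
        "early": (1.0, 0.85, 0.45, 0.15, 0.05),
        "mid": (0.15, 0.55, 1.0, 0.5, 0.2),
        "late": (0.05, 0.1, 0.4, 0.9, 1.0),
        "flat": (0.5, 0.5, 0.5, 0.5, 0.5),
    },
}


@dataclass(frozen=True)
class RegulatorSpec:
    """Blueprint for one planted regulon."""

    name: str
    regulator_class: str  # NAP | sigma | globalTF
    size: int
    program: str = "flat"  # early | mid | late | flat
    spatial_center: int | None = None  # bp; None -> uniform members
    spatial_concentration: float = 0.0  # fraction within ±cluster_halfwidth of center
    overlaps: Mapping[str, float] = field(default_factory=dict)  # sigma name -> fraction


def default_regulators() -> tuple[RegulatorSpec, ...]:
    """A small regulator roster emulating the NAP / sigma / global-TF families."""
    return (
        RegulatorSpec("RpoD", "sigma", 800, program="early"),
        RegulatorSpec("RpoS", "sigma", 250, program="late",
                      spatial_center=2_300_000, spatial_concentration=0.3),
        RegulatorSpec("RpoH", "sigma", 120, program="mid"),
        RegulatorSpec("FIS", "NAP", 200, program="early",
                      spatial_center=200_000, spatial_concentration=0.6,
                      overlaps={"RpoD": 0.5, "RpoS": 0.25}),
        RegulatorSpec("H-NS", "NAP", 150, program="mid",
                      spatial_center=2_900_000, spatial_concentration=0.4,
                      overlaps={"RpoD": 0.4, "RpoS": 0.2}),
        RegulatorSpec("Lrp", "NAP", 120, program="mid", overlaps={"RpoD": 0.3}),
        RegulatorSpec("CRP", "globalTF", 300, program="early",
                      overlaps={"RpoD": 0.5, "RpoS": 0.2}),
    )


@dataclass(frozen=True)
class SimulationSpec:
    """Parameters of one synthetic dataset (defaults: the study conditions)."""

    seed: int = 0
    n_genes: int = 4_000
    chromosome_length: int = 4_600_000
    gc_ori: float = 0.56
    gc_ter: float = 0.48
    timepoints: tuple[int, ...] = DEFAULT_TIMEPOINTS
    noise_sd: float = 0.2  # fraction of each gene's program range
    baseline_scale: float = 100.0
    regulators: tuple[RegulatorSpec, ...] = field(default_factory=default_regulators)
    cluster_halfwidth: int = 100_000
    overlap_mode: str = "sample"  # "sample" | "exact"
    couplon_program: str = "sigma"  # couplon members follow "sigma" | "own" parent

    def __post_init__(self) -> None:
        for frac in (self.gc_ori, self.gc_ter):
            if not 0 <= frac <= 1:
                raise ValueError("GC fractions must be in [0, 1]")
        if list(self.timepoints) != sorted(set(self.timepoints)):
            raise ValueError("timepoints must be strictly increasing")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        for r in self.regulators:
            if r.size > self.n_genes:
                raise ValueError(f"regulon {r.name} larger than the genome")
            if not 0 <= r.spatial_concentration <= 1:
                raise ValueError(f"{r.name}: spatial_concentration outside [0, 1]")
            for s, f in r.overlaps.items():
                if not 0 <= f <= 1:
                    raise ValueError(f"{r.name}/{s}: overlap fraction outside [0, 1]")


def load_spec(path: str | Path) -> SimulationSpec:
    """Read a SimulationSpec from YAML."""
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    regs = data.pop("regulators", None)
    spec_kwargs = dict(data)
    if "timepoints" in spec_kwargs:
        spec_kwargs["timepoints"] = tuple(spec_kwargs["timepoints"])
    if regs is not None:
        spec_kwargs["regulators"] = tuple(RegulatorSpec(**r) for r in regs)
    return SimulationSpec(**spec_kwargs)


def write_spec(spec: SimulationSpec, path: str | Path) -> None:
    data = asdict(spec)
    data["timepoints"] = list(spec.timepoints)
    data["regulators"] = [
        {**asdict(r), "overlaps": dict(r.overlaps)} for r in spec.regulators
    ]
    with open(path, "w") as fh:
        yaml.safe_dump(data, fh, default_flow_style=False, sort_keys=False)


# ----------------------------------------------------------------------------
# genome


def _local_gc(positions: np.ndarray, spec: SimulationSpec) -> np.ndarray:
    """Linear GC gradient, symmetric on both replichores: gc_ori at the
    origin (position 0), gc_ter at the terminus (length/2)."""
    half = spec.chromosome_length / 2
    d = circular_distance(positions, 0, spec.chromosome_length) / half
    return spec.gc_ori + (spec.gc_ter - spec.gc_ori) * d


def generate_genome(
    spec: SimulationSpec, seed: int | None = None
) -> tuple[GenomeAnnotation, str]:
    """Sample TSS positions and a gradient-GC genome sequence.

    Returns the annotation and the chromosome sequence as a string.
    Deterministic for a fixed seed (defaults to ``spec.seed``).
    """
    if spec.n_genes > spec.chromosome_length / 100:
        raise ValueError("unrealistic gene density: need >= 100 bp per gene")
    rng = np.random.default_rng(spec.seed if seed is None else seed)
    L = spec.chromosome_length
    tss = np.sort(rng.choice(L, size=spec.n_genes, replace=False))
    strands = rng.choice(["+", "-"], size=spec.n_genes)
    width = len(str(spec.n_genes))
    genes = pd.DataFrame(
        {
            "gene_id": [f"g{i + 1:0{width}d}" for i in range(spec.n_genes)],
            "tss": tss,
            "strand": strands,
        }
    )
    ann = GenomeAnnotation(chromosome_length=L, genes=genes)

    gc = _local_gc(np.arange(L), spec)
    u = rng.random(L)
    v = rng.random(L)
    bases = np.where(
        u < gc, np.where(v < 0.5, b"G", b"C"), np.where(v < 0.5, b"A", b"T")
    ).astype("S1")
    return ann, bases.tobytes().decode("ascii")


def write_genome_fasta(sequence: str, path: str | Path, name: str = "chr") -> None:
    with open(path, "w") as fh:
        fh.write(f">{name}\n")
        for i in range(0, len(sequence), 70):
            fh.write(sequence[i : i + 70] + "\n")


# ----------------------------------------------------------------------------
# regulatory network


def _pick(rng: np.random.Generator, pool: np.ndarray, k: int) -> np.ndarray:
    if k > len(pool):
        raise ValueError(f"cannot draw {k} genes from a pool of {len(pool)}")
    return rng.choice(pool, size=k, replace=False)


def generate_trn(
    spec: SimulationSpec, annotation: GenomeAnnotation, seed: int | None = None
) -> RegulonSet:
    """Plant regulons with the configured spatial clustering and overlaps.

    Sigma regulons are drawn first; each NAP/global-TF regulon then takes
    its configured share of members from each sigma's member set
    (per-member Bernoulli in ``sample`` mode, exactly ``round(f * size)``
    in ``exact`` mode), fills its spatial-cluster quota from genes within
    ±cluster_halfwidth of its center, and draws the remainder uniformly.
    Each regulator is also assigned its own gene (recorded in
    ``RegulonSet.regulator_genes``), which follows the regulon's program
    in the generated time-course.
    """
    rng = np.random.default_rng(spec.seed + 1 if seed is None else seed)
    all_ids = np.asarray(annotation.gene_ids)
    tss = annotation.positions()
    members: dict[str, np.ndarray] = {}

    ordered = sorted(spec.regulators, key=lambda r: r.regulator_class != "sigma")
    for reg in ordered:
        chosen: list[str] = []
        chosen_set: set[str] = set()
        # genes of overlap-partner sigmas are off-limits for the non-shared
        # draws, so the planted intersection is exactly the shared sample
        off_limits: set[str] = set()
        if reg.regulator_class != "sigma":
            for sig_name, frac in reg.overlaps.items():
                if sig_name not in members:
                    raise ValueError(
                        f"{reg.name}: overlap partner {sig_name!r} is not a "
                        "generated sigma regulon"
                    )
                pool = np.array([g for g in members[sig_name] if g not in chosen_set])
                if spec.overlap_mode == "exact":
                    k = round(frac * reg.size)
                else:
                    k = int(rng.binomial(reg.size, frac))
                if k > min(len(pool), reg.size - len(chosen)):
                    raise ValueError(
                        f"infeasible overlap for pair ({reg.name}, {sig_name}): "
                        f"need {k} shared genes, {min(len(pool), reg.size - len(chosen))} available"
                    )
                if k > 0:
                    picked = _pick(rng, pool, k)
                    chosen.extend(picked)
                    chosen_set.update(picked)
                off_limits.update(members[sig_name])
        n_left = reg.size - len(chosen)
        if reg.spatial_center is not None and reg.spatial_concentration > 0:
            near = circular_distance(tss, reg.spatial_center, spec.chromosome_length) <= spec.cluster_halfwidth
            pool = np.array(
                [g for g in all_ids[near] if g not in chosen_set and g not in off_limits]
            )
            k = min(round(reg.spatial_concentration * reg.size), n_left, len(pool))
            if k > 0:
                picked = _pick(rng, pool, k)
                chosen.extend(picked)
                chosen_set.update(picked)
            n_left = reg.size - len(chosen)
        if n_left > 0:
            pool = np.array(
                [g for g in all_ids if g not in chosen_set and g not in off_limits]
            )
            picked = _pick(rng, pool, n_left)
            chosen.extend(picked)
            chosen_set.update(picked)
        members[reg.name] = np.asarray(chosen)

    regulons = {}
    regulator_genes = {}
    for reg in spec.regulators:
        effects = rng.choice(["activation", "repression"], size=reg.size)
        regulons[reg.name] = Regulon(
            reg.name, reg.regulator_class, dict(zip(members[reg.name], effects))
        )
        regulator_genes[reg.name] = str(rng.choice(all_ids))
    return RegulonSet(regulons, annotation, regulator_genes=regulator_genes)


# ----------------------------------------------------------------------------
# expression time-course


def _program_assignment(
    spec: SimulationSpec, rs: RegulonSet
) -> dict[str, str]:
    """Dominant program per gene.

    Regulon members take their regulator's program; genes shared between a
    NAP/global-TF regulon and a sigma regulon (couplon members) follow the
    sigma parent when ``couplon_program == "sigma"``.  Unregulated genes
    stay flat.  Each regulator's own gene follows its regulon's program.
    """
    prog_of = {r.name: r.program for r in spec.regulators}
    assign: dict[str, str] = {}
    non_sigma = [r for r in spec.regulators if r.regulator_class != "sigma"]
    sigmas = [r for r in spec.regulators if r.regulator_class == "sigma"]
    for reg in non_sigma:
        for g in rs[reg.name].gene_ids:
            assign[g] = prog_of[reg.name]
    for reg in sigmas:
        for g in rs[reg.name].gene_ids:
            if spec.couplon_program == "sigma" or g not in assign:
                assign[g] = prog_of[reg.name]
    for name, gene in rs.regulator_genes.items():
        assign[gene] = prog_of[name]
    return assign


def generate_timecourse(
    spec: SimulationSpec,
    rs: RegulonSet,
    seed: int | None = None,
    condition: str = "wt",
) -> ExpressionTimecourse:
    """Expression matrix: per-gene ``baseline · program(t)`` plus noise.

    Noise is Gaussian with sd ``noise_sd`` times the gene's program range
    (times the baseline for flat genes, whose program range is zero —
    unregulated genes still fluctuate); values are clipped at 0.
    ``condition="fis_mutant"`` swaps in the program set without the
    planted late-phase repression.
    """
    if condition not in PROGRAMS:
        raise ValueError(f"unknown condition {condition!r}")
    programs = PROGRAMS[condition]
    n_t = len(spec.timepoints)
    for name, shape in programs.items():
        if len(shape) != n_t:
            raise ValueError(f"program {name!r} does not match the timepoint design")
    rng = np.random.default_rng(spec.seed + 2 if seed is None else seed)
    assign = _program_assignment(spec, rs)
    ids = rs.annotation.gene_ids
    baselines = spec.baseline_scale * rng.lognormal(mean=0.0, sigma=0.5, size=len(ids))
    mat = np.empty((len(ids), n_t))
    for i, gid in enumerate(ids):
        shape = np.asarray(programs[assign.get(gid, "flat")])
        rng_range = np.ptp(shape)
        sd = spec.noise_sd * baselines[i] * (rng_range if rng_range > 0 else 1.0)
        mat[i] = baselines[i] * shape + rng.normal(0.0, sd, size=n_t) if sd > 0 else baselines[i] * shape
    np.clip(mat, 0.0, None, out=mat)
    df = pd.DataFrame(mat, index=pd.Index(ids, name="gene_id"), columns=list(spec.timepoints))
    return ExpressionTimecourse(df)


def generate_dataset(
    spec: SimulationSpec, condition: str = "wt"
) -> tuple[GenomeAnnotation, str, RegulonSet, ExpressionTimecourse]:
    """Genome + TRN + time-course from one spec (seeds derived from spec.seed)."""
    ann, seq = generate_genome(spec)
    rs = generate_trn(spec, ann)
    tc = generate_timecourse(spec, rs, condition=condition)
    return ann, seq, rs, tc
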