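"""End-to-end orchestration: inputs → couplons → spatial → temporal → GC.

A single structured YAML config drives the run.  Inputs are either real
files (annotation, TRN + class map, expression, FASTA) or a simulation
spec; stages whose inputs are missing are skipped and recorded, never
silently dropped.  Every output family is deterministic under a fixed
seed, and the manifest records versions, seeds, parameters and input
checksums.
"""
from __future__ import annotations

import hashlib
import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .annotation import GenomeAnnotation, load_annotation, write_annotation
from .promoter_gc import (
    DEFAULT_DOWNSTREAM,
    DEFAULT_SMOOTHING,
    DEFAULT_UPSTREAM,
    extract_contexts,
    gc_profile,
    write_gc_table,
)
from .simulate import (
    SimulationSpec,
    generate_genome,
    generate_timecourse,
    generate_trn,
    load_spec,
    write_genome_fasta,
)
from .spatial import (
    DEFAULT_SAMPLES,
    DEFAULT_STEP,
    DEFAULT_WINDOW,
    Z_THRESHOLD,
    make_grid,
    null_moments,
    set_z_profile,
    spatial_correlation,
    write_zprofile,
)
from .temporal import (
    DEFAULT_REMAP_FRACTION,
    DEFAULT_REMAP_REPS,
    load_timecourse,
    profile_correlation,
    remap_envelope,
    set_profile,
    write_profile,
    write_timecourse,
)
from .trn import (
    RegulonSet,
    build_couplon,
    couplon_table,
    load_trn,
    write_couplon_members,
    write_trn,
)

log = logging.getLogger("couplonscan")


@dataclass
class RunConfig:
    """Validated configuration of one pipeline run."""

    seed: int
    outdir: Path
    simulate: SimulationSpec | None = None
    annotation: Path | None = None
    fasta: Path | None = None
    trn: Path | None = None
    classes: Path | None = None
    expression: Path | None = None
    window: int = DEFAULT_WINDOW
    step: int = DEFAULT_STEP
    n_samples: int = DEFAULT_SAMPLES
    null_method: str = "monte-carlo"
    z_threshold: float = Z_THRESHOLD
    remap_fraction: float = DEFAULT_REMAP_FRACTION
    remap_reps: int = DEFAULT_REMAP_REPS
    gc_upstream: int = DEFAULT_UPSTREAM
    gc_downstream: int = DEFAULT_DOWNSTREAM
    gc_smoothing: int = DEFAULT_SMOOTHING

    def __post_init__(self) -> None:
        if self.simulate is None and self.annotation is None:
            raise ValueError("config needs either a simulation spec or an annotation path")
        for name in ("annotation", "fasta", "trn", "classes", "expression"):
            p = getattr(self, name)
            if p is not None:
                p = Path(p)
                setattr(self, name, p)
                if not p.exists():
                    raise FileNotFoundError(f"{name} file not found: {p}")
        self.outdir = Path(self.outdir)


def load_config(path: str | Path, outdir: str | Path | None = None) -> RunConfig:
    """Read a RunConfig from YAML; relative paths resolve against the config."""
    path = Path(path)
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    sim = data.pop("simulate", None)
    if isinstance(sim, dict):
        from .simulate import RegulatorSpec

        regs = sim.pop("regulators", None)
        if "timepoints" in sim:
            sim["timepoints"] = tuple(sim["timepoints"])
        if regs is not None:
            sim["regulators"] = tuple(RegulatorSpec(**r) for r in regs)
        sim = SimulationSpec(**sim)
    elif isinstance(sim, str):
        sim = load_spec(path.parent / sim)
    for key in ("annotation", "fasta", "trn", "classes", "expression"):
        if data.get(key):
            data[key] = path.parent / data[key]
    if outdir is not None:
        data["outdir"] = outdir
    return RunConfig(simulate=sim, **data)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _analysis_sets(rs: RegulonSet) -> tuple[dict[str, set[str]], list, list]:
    """All regulons plus every (NAP|globalTF) × sigma couplon with members."""
    naps = [r.regulator for r in rs if r.regulator_class in {"NAP", "globalTF"}]
    sigmas = [r.regulator for r in rs if r.regulator_class == "sigma"]
    sets: dict[str, set[str]] = {r.regulator: set(r.gene_ids) for r in rs}
    for n in naps:
        for s in sigmas:
            c = build_couplon(rs[n], rs[s])
            if c.size:
                sets[c.name] = set(c.members)
    return sets, naps, sigmas


def run_pipeline(config: RunConfig) -> dict[str, Any]:
    """Execute all runnable stages; returns (and writes) the run manifest."""
    out = config.outdir
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict[str, Any] = {
        "couplonscan_version": __version__,
        "seed": config.seed,
        "parameters": {
            "window": config.window,
            "step": config.step,
            "n_samples": config.n_samples,
            "null_method": config.null_method,
            "z_threshold": config.z_threshold,
            "remap_fraction": config.remap_fraction,
            "remap_reps": config.remap_reps,
            "gc_span": [-config.gc_upstream, config.gc_downstream],
            "gc_smoothing": config.gc_smoothing,
        },
        "inputs": {},
        "outputs": {},
        "skipped": {},
        "warnings": 0,
    }
    caught: list[warnings.WarningMessage] = []

    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always")

        # ---- stage 0: inputs -------------------------------------------------
        ann: GenomeAnnotation
        rs: RegulonSet | None = None
        sequence: str | None = None
        tc = None
        if config.simulate is not None:
            spec = config.simulate
            log.info("simulating dataset (seed=%d)", spec.seed)
            ann, sequence = generate_genome(spec)
            rs = generate_trn(spec, ann)
            tc = generate_timecourse(spec, rs)
            inputs_dir = out / "inputs"
            inputs_dir.mkdir(exist_ok=True)
            write_annotation(ann, inputs_dir / "annotation.tsv")
            write_genome_fasta(sequence, inputs_dir / "genome.fasta")
            write_trn(rs, inputs_dir / "trn.tsv", inputs_dir / "classes.yaml")
            write_timecourse(tc, inputs_dir / "expression.tsv")
            manifest["inputs"]["simulation_seed"] = spec.seed
        else:
            ann = load_annotation(config.annotation)
            manifest["inputs"]["annotation"] = _sha256(config.annotation)
            if config.trn is not None and config.classes is not None:
                rs = load_trn(config.trn, config.classes, ann)
                manifest["inputs"]["trn"] = _sha256(config.trn)
            if config.fasta is not None:
                from .promoter_gc import read_genome

                sequence = read_genome(config.fasta)
                manifest["inputs"]["fasta"] = _sha256(config.fasta)
            if config.expression is not None:
                tc = load_timecourse(config.expression)
                manifest["inputs"]["expression"] = _sha256(config.expression)

        if rs is None:
            raise ValueError("pipeline aborted at stage 'couplons': no TRN available")
        sets, naps, sigmas = _analysis_sets(rs)

        # ---- stage 1: couplon table -----------------------------------------
        table = couplon_table(rs, naps, sigmas)
        table.rename_axis("regulator").to_csv(out / "couplon_table.tsv", sep="\t")
        write_couplon_members(rs, naps, sigmas, out / "couplon_members.tsv")
        manifest["outputs"]["couplons"] = ["couplon_table.tsv", "couplon_members.tsv"]

        # ---- stage 2: spatial enrichment ------------------------------------
        grid = make_grid(ann.chromosome_length, config.window, config.step)
        spatial_dir = out / "spatial"
        spatial_dir.mkdir(exist_ok=True)
        profiles = {}
        nulls: dict[int, Any] = {}
        for i, (name, genes) in enumerate(sorted(sets.items())):
            n = len(genes)
            if n not in nulls:
                nulls[n] = null_moments(
                    n, grid, ann, config.n_samples, seed=config.seed, method=config.null_method
                )
            zp = set_z_profile(
                ann, genes, grid, threshold=config.z_threshold, set_name=name, null=nulls[n]
            )
            profiles[name] = zp
            safe = name.replace("/", "_")
            write_zprofile(zp, spatial_dir / f"{safe}.tsv", spatial_dir / f"{safe}.bed")
        correlations = {}
        for n in naps:
            for s in sigmas:
                cname = f"{n}/{s}"
                if cname not in profiles:
                    continue
                correlations[cname] = {
                    n: spatial_correlation(profiles[cname], profiles[n]).r,
                    s: spatial_correlation(profiles[cname], profiles[s]).r,
                }
        with open(spatial_dir / "correlations.json", "w") as fh:
            json.dump(correlations, fh, indent=2, sort_keys=True)
        manifest["outputs"]["spatial"] = sorted(p.name for p in spatial_dir.iterdir())

        # ---- stage 3: temporal profiles -------------------------------------
        if tc is None:
            manifest["skipped"]["temporal"] = "no expression input"
            log.warning("temporal stage skipped: no expression input")
        else:
            temporal_dir = out / "temporal"
            temporal_dir.mkdir(exist_ok=True)
            tprofiles = {}
            for name, genes in sorted(sets.items()):
                prof = set_profile(tc, genes, set_name=name)
                env = remap_envelope(
                    tc, genes, config.remap_fraction, config.remap_reps, seed=config.seed
                )
                prof = prof.with_envelope(env)
                tprofiles[name] = prof
                safe = name.replace("/", "_")
                write_profile(prof, temporal_dir / f"{safe}.tsv", temporal_dir / f"{safe}.json")
            tcorr = {
                a: {b: profile_correlation(tprofiles[a], tprofiles[b]) for b in tprofiles}
                for a in tprofiles
            }
            with open(temporal_dir / "correlations.json", "w") as fh:
                json.dump(tcorr, fh, indent=2, sort_keys=True)
            manifest["outputs"]["temporal"] = sorted(p.name for p in temporal_dir.iterdir())

        # ---- stage 4: promoter GC -------------------------------------------
        if sequence is None:
            manifest["skipped"]["gc"] = "no genome sequence input"
            log.warning("GC stage skipped: no genome sequence input")
        else:
            gc_dir = out / "gc"
            gc_dir.mkdir(exist_ok=True)
            contexts = {
                c.gene_id: c
                for c in extract_contexts(
                    sequence, ann, config.gc_upstream, config.gc_downstream
                )
            }
            all_prof = gc_profile(list(contexts.values()), config.gc_smoothing, "all")
            cols = {"position": all_prof.positions, "gc_all": all_prof.values}
            for name, genes in sorted(sets.items()):
                ctxs = [contexts[g] for g in sorted(genes) if g in contexts]
                if not ctxs:
                    continue
                prof = gc_profile(ctxs, config.gc_smoothing, name)
                cols[f"gc_{name.replace('/', '_')}"] = prof.values
            write_gc_table(pd.DataFrame(cols), gc_dir / "gc_profiles.tsv")
            manifest["outputs"]["gc"] = ["gc_profiles.tsv"]

    manifest["warnings"] = len(caught)
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest
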