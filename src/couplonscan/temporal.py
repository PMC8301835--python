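"""Growth-phase temporal expression profiles of regulons and couplons.

The profile of a gene set is computed in the fixed order: each member's
expression trace is min–max normalized to [0;1] individually, the
normalized traces are averaged per timepoint, and the averaged curve is
rescaled to [0;1] again.  The averaged curve's extremes *before* that
final rescale are reported alongside the profile (they measure how
coherent the set's expression is: a tight program keeps them near 0 and
1, incoherent sets compress toward 0.5).

Uncertainty envelopes follow the remapping scheme: a fraction of the
set's members is repeatedly replaced by random non-member genes, the
profile recomputed, and the per-timepoint standard deviation across
replicates reported.
"""
from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .trn import Regulon

DEFAULT_REMAP_FRACTION = 0.10
DEFAULT_REMAP_REPS = 100


class DegenerateProfileError(ValueError):
    """Raised when a constant pattern makes an operation undefined."""


@dataclass(frozen=True)
class ExpressionTimecourse:
    """Genes × timepoints expression matrix (timepoints in minutes).

    Rows containing missing values are dropped at construction and counted
    in ``n_dropped``.
    """

    values: pd.DataFrame  # index: gene_id, columns: int minutes
    n_dropped: int = 0

    def __post_init__(self) -> None:
        df = self.values
        if df.shape[1] < 2:
            raise ValueError("need at least 2 timepoints")
        cols = [int(c) for c in df.columns]
        if not all(a < b for a, b in zip(cols, cols[1:])):
            raise ValueError("timepoints must be strictly increasing")
        na = df.isna().any(axis=1)
        dropped = int(na.sum())
        df = df.loc[~na].astype(float)
        df.columns = cols
        object.__setattr__(self, "values", df)
        object.__setattr__(self, "n_dropped", self.n_dropped + dropped)

    @property
    def timepoints(self) -> np.ndarray:
        return np.asarray(self.values.columns, dtype=int)

    @property
    def gene_ids(self) -> frozenset[str]:
        return frozenset(self.values.index)

    def __len__(self) -> int:
        return len(self.values)

    def trace(self, gene_id: str) -> np.ndarray:
        return self.values.loc[gene_id].to_numpy()


def load_timecourse(path: str | Path) -> ExpressionTimecourse:
    """Read an expression TSV: header ``gene_id`` + one column per minute."""
    df = pd.read_csv(path, sep="\t", index_col="gene_id")
    df.columns = [int(c) for c in df.columns]
    return ExpressionTimecourse(df)


def write_timecourse(tc: ExpressionTimecourse, path: str | Path) -> None:
    tc.values.rename_axis("gene_id").to_csv(path, sep="\t", float_format="%.6g")


@dataclass(frozen=True)
class TemporalProfile:
    """[0;1]-normalized average expression curve of a gene set."""

    set_name: str
    timepoints: np.ndarray
    values: np.ndarray
    pre_norm_min: float
    pre_norm_max: float
    n_genes_used: int
    n_constant_excluded: int = 0
    degenerate: bool = False
    envelope: np.ndarray | None = None  # per-timepoint SD under remapping
    envelope_meta: dict | None = None

    def with_envelope(self, envelope: "RemapEnvelope") -> "TemporalProfile":
        return replace(
            self,
            envelope=envelope.sd,
            envelope_meta={
                "fraction": envelope.fraction,
                "n_reps": envelope.n_reps,
                "seed": envelope.seed,
                "mode": envelope.mode,
            },
        )


def normalize_unit(values: Sequence[float]) -> np.ndarray:
    """Min–max normalize a trace to [0;1]: ``x' = (x − min)/(max − min)``.

    Invariant under positive affine rescaling of the input.  Constant
    traces have no normalized form and raise ``DegenerateProfileError``.
    """
    x = np.asarray(values, dtype=float)
    if x.size < 2:
        raise ValueError("need at least 2 values")
    lo, hi = x.min(), x.max()
    if hi == lo:
        raise DegenerateProfileError("constant trace cannot be normalized to [0;1]")
    return (x - lo) / (hi - lo)


def _normalized_rows(tc: ExpressionTimecourse, genes: list[str]) -> tuple[np.ndarray, int]:
    """Per-gene [0;1] traces for the non-constant members; returns (matrix, n_constant)."""
    mat = tc.values.loc[genes].to_numpy()
    lo = mat.min(axis=1, keepdims=True)
    hi = mat.max(axis=1, keepdims=True)
    keep = (hi > lo).ravel()
    norm = (mat[keep] - lo[keep]) / (hi[keep] - lo[keep])
    return norm, int((~keep).sum())


def set_profile(
    tc: ExpressionTimecourse, gene_set: Iterable[str], set_name: str = "set"
) -> TemporalProfile:
    """Average the individually normalized member traces and rescale to [0;1].

    Genes absent from the time-course are ignored; constant genes are
    excluded and counted.  The pre-rescale extremes of the averaged curve
    are recorded as ``pre_norm_min`` / ``pre_norm_max``.
    """
    genes = sorted(set(gene_set) & tc.gene_ids)
    if not genes:
        raise ValueError(f"set {set_name!r}: no members present in the time-course")
    norm, n_constant = _normalized_rows(tc, genes)
    if norm.shape[0] == 0:
        raise ValueError(f"set {set_name!r}: all member traces are constant")
    avg = norm.mean(axis=0)
    lo, hi = float(avg.min()), float(avg.max())
    if hi > lo:
        values = (avg - lo) / (hi - lo)
        degenerate = False
    else:
        warnings.warn(f"set {set_name!r}: averaged curve is constant")
        values = np.full_like(avg, 0.5)
        degenerate = True
    return TemporalProfile(
        set_name=set_name,
        timepoints=tc.timepoints,
        values=values,
        pre_norm_min=lo,
        pre_norm_max=hi,
        n_genes_used=norm.shape[0],
        n_constant_excluded=n_constant,
        degenerate=degenerate,
    )


def profile_correlation(p: TemporalProfile, q: TemporalProfile) -> float:
    """Pearson r between two profiles over their (identical) timepoints.

    With the usual five-timepoint design the sample size is tiny; r is
    reported descriptively, without a p-value.
    """
    if not np.array_equal(p.timepoints, q.timepoints):
        raise ValueError("profiles have different timepoints")
    if np.ptp(p.values) == 0 or np.ptp(q.values) == 0:
        warnings.warn("constant profile: correlation undefined")
        return float("nan")
    return float(stats.pearsonr(p.values, q.values).statistic)


def regulator_vs_regulon(
    tc: ExpressionTimecourse, regulator_gene_id: str, regulon: Regulon | Iterable[str]
) -> float:
    """Pearson r between a regulator gene's own trace and its regulon profile."""
    if regulator_gene_id not in tc.gene_ids:
        raise KeyError(f"regulator gene {regulator_gene_id!r} absent from the time-course")
    reg_trace = normalize_unit(tc.trace(regulator_gene_id))
    members = regulon.gene_ids if isinstance(regulon, Regulon) else set(regulon)
    prof = set_profile(tc, members, set_name="regulon")
    if np.ptp(prof.values) == 0:
        warnings.warn("constant regulon profile: correlation undefined")
        return float("nan")
    return float(stats.pearsonr(reg_trace, prof.values).statistic)


@dataclass(frozen=True)
class RemapEnvelope:
    """Per-timepoint SD of a set profile under random member remapping."""

    sd: np.ndarray
    replicates: np.ndarray  # n_reps × timepoints, the recomputed profiles
    fraction: float
    n_reps: int
    seed: int | None
    mode: str


def remap_envelope(
    tc: ExpressionTimecourse,
    gene_set: Iterable[str],
    fraction: float = DEFAULT_REMAP_FRACTION,
    n_reps: int = DEFAULT_REMAP_REPS,
    seed: int | None = None,
    mode: str = "replace",
) -> RemapEnvelope:
    """Stability envelope of a set profile under partial remapping.

    ``mode="replace"`` (default): each replicate swaps
    ``round(fraction * |set|)`` members for genes drawn uniformly from
    outside the set, recomputes the profile, and the per-timepoint SD over
    replicates is returned.  ``mode="permute"`` instead permutes the
    trace-to-gene assignment among a random ``fraction`` of all genes
    genome-wide before recomputing the unmodified set's profile.
    """
    if not 0 <= fraction <= 1:
        raise ValueError("fraction must be in [0, 1]")
    if mode not in {"replace", "permute"}:
        raise ValueError(f"unknown remap mode {mode!r}")
    genes = sorted(set(gene_set) & tc.gene_ids)
    if not genes:
        raise ValueError("no set members present in the time-course")
    tps = tc.timepoints
    n_swap = round(fraction * len(genes))
    if n_swap == 0:
        warnings.warn("fraction rounds to 0 replaced members: envelope is zero")
        base = set_profile(tc, genes).values
        reps = np.tile(base, (n_reps, 1))
        return RemapEnvelope(np.zeros(len(tps)), reps, fraction, n_reps, seed, mode)

    rng = np.random.default_rng(seed)
    outside = sorted(tc.gene_ids - set(genes))
    all_genes = np.asarray(sorted(tc.gene_ids))
    reps = np.empty((n_reps, len(tps)))
    for i in range(n_reps):
        if mode == "replace":
            drop = rng.choice(len(genes), size=n_swap, replace=False)
            add = rng.choice(len(outside), size=min(n_swap, len(outside)), replace=False)
            remapped = [g for j, g in enumerate(genes) if j not in set(drop)]
            remapped += [outside[j] for j in add]
            reps[i] = set_profile(tc, remapped).values
        else:
            n_perm = round(fraction * len(all_genes))
            idx = rng.choice(len(all_genes), size=n_perm, replace=False)
            perm = rng.permutation(n_perm)
            relabel = dict(zip(all_genes[idx], all_genes[idx][perm]))
            shuffled = tc.values.rename(index=relabel)
            tc_i = ExpressionTimecourse(shuffled)
            reps[i] = set_profile(tc_i, genes).values
    return RemapEnvelope(reps.std(axis=0, ddof=1), reps, fraction, n_reps, seed, mode)


def compare_conditions(
    profiles_a: dict[str, TemporalProfile], profiles_b: dict[str, TemporalProfile]
) -> pd.DataFrame:
    """Pair per-set profiles from two conditions and correlate them.

    Returns one row per set with the two profiles' values and their
    Pearson r — the machinery behind wild-type vs mutant comparisons.
    """
    if set(profiles_a) != set(profiles_b):
        raise ValueError("conditions cover different sets")
    rows = []
    for name in sorted(profiles_a):
        p, q = profiles_a[name], profiles_b[name]
        if not np.array_equal(p.timepoints, q.timepoints):
            raise ValueError(f"set {name!r}: mismatched timepoints between conditions")
        rows.append(
            {
                "set": name,
                "r": profile_correlation(p, q),
                "n_genes_a": p.n_genes_used,
                "n_genes_b": q.n_genes_used,
            }
        )
    return pd.DataFrame(rows, columns=["set", "r", "n_genes_a", "n_genes_b"])


def write_profile(profile: TemporalProfile, path: str | Path, sidecar: str | Path | None = None) -> None:
    """Profile as TSV (time, value, envelope_sd) + JSON sidecar of metadata."""
    df = pd.DataFrame(
        {
            "time": profile.timepoints,
            "value": profile.values,
            "envelope_sd": profile.envelope if profile.envelope is not None else np.nan,
        }
    )
    df.to_csv(path, sep="\t", index=False, float_format="%.6g")
    if sidecar is not None:
        meta = {
            "set_name": profile.set_name,
            "pre_norm_min": profile.pre_norm_min,
            "pre_norm_max": profile.pre_norm_max,
            "n_genes_used": profile.n_genes_used,
            "n_constant_excluded": profile.n_constant_excluded,
            "degenerate": profile.degenerate,
            "envelope": profile.envelope_meta,
        }
        with open(sidecar, "w") as fh:
            json.dump(meta, fh, indent=2, sort_keys=True)
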