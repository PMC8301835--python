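# couplonscan

Analysis toolkit for the joint organization of bacterial transcriptional
regulation: **regulons** (the target-gene set of one regulator) and
**couplons** — the intersection of a nucleoid-associated protein (NAP) or
global transcription-factor regulon with a sigma-factor regulon, i.e. the
genes under joint control of a chromatin-shaping regulator and a specific
RNA-polymerase holoenzyme. The package is written for systems biologists
studying *E. coli*-like organisms who want to ask, for a given regulatory
network, annotation, genome sequence and growth time-course:

1. **Where** on the circular chromosome do a regulon's or couplon's genes
   sit — are they spatially clustered?
2. **When** during growth are they expressed, and does a couplon follow
   the temporal program of its NAP parent or its sigma parent?
3. **What** is the GC content (a duplex-stability proxy) of their
   promoter regions around the transcription start site (TSS)?

## Methods at a glance

**Couplons.** For regulons A (NAP or global TF) and B (sigma factor),
`couplon(A, B) = genes(A) ∩ genes(B)`, ignoring activation/repression
sign (signs are kept as metadata).

**Spatial enrichment.** Windows of w = 100 kb slide at s = 10 kb steps
around the circular chromosome (windows wrap through the origin). For a
gene set of size *n* out of *N* annotated genes, the count of member TSSs
in window *w* is standardized as

    Z_w = (observed_w − mean_w) / sd_w

against a null of 10,000 random *n*-gene sets drawn uniformly without
replacement (an analytic mode uses the equivalent hypergeometric moments
mean_w = n·k_w/N, var_w = n·(k_w/N)(1−k_w/N)(N−n)/(N−1)). Windows with
Z > 2 are called enriched, Z < −2 depleted. Spatial similarity of two
sets is the Pearson correlation of their Z-profiles.

**Temporal profiles.** Each member gene's expression trace over the
sampled times (default 60, 120, 180, 300, 420 min after inoculation) is
min–max normalized to [0;1]; the set profile is the per-timepoint average
of those traces, rescaled to [0;1], with the pre-rescale extremes
reported as a coherence measure. Profile similarity is Pearson r over
timepoints. Stability envelopes give the per-timepoint SD of the profile
when 10% of the set's members are repeatedly replaced by random
non-member genes.

**Promoter GC.** The −300..+200 bp context around each TSS is extracted
on the coding strand (minus-strand genes reverse-complemented, circular
extraction across the origin); the per-position G+C fraction across a
gene set, smoothed with a 21 bp moving average, is the GC profile.

**Synthetic data.** A generator plants all the structure the analyses
assume — a ~4.6 Mb circular chromosome with ~4,000 genes and a linear
origin→terminus GC gradient (0.56 → 0.48), regulons with configurable
spatial clustering and pairwise sigma overlaps, and time-courses in which
every gene follows an early-, mid- or late-peaking program plus Gaussian
noise. A mutant condition removes the planted late-phase repression, for
wild-type vs mutant contrasts.

## Worked example

`examples/` holds one short script per capability. For instance,
`python examples/02_spatial_enrichment.py` plants a regulon with 80% of
its 200 members near position 1 Mb and scans it:

```
FIS regulon: 29 of 460 windows enriched (Z > 2).
Strongest window starts at 900,000 bp with Z = 37.0 — the planted cluster sits at 1,000,000 bp.
Spatial correlation of the FIS/RpoD couplon with its FIS parent: r = 1.00 over 460 windows.
```

The enriched windows tile the planted cluster, and the couplon (drawn
from the regulon) reproduces its parent's spatial profile.
`python examples/03_temporal_profiles.py` shows the temporal side:

```
FIS/RpoS couplon (62 genes):
  r(couplon, RpoS regulon) = 1.00; r(couplon, FIS regulon) = -0.30
```

— couplon members were planted to follow the sigma parent's
stationary-phase program, so the couplon profile tracks RpoS, not FIS.
`python examples/04_promoter_gc.py` recovers the GC gradient:

```
Origin-proximal genes:   0.560
Terminus-proximal genes: 0.482
Mean Ori - Ter difference: +0.078 (planted gradient spans 0.08)
```

A command-line interface mirrors the stages
(`couplonscan simulate|spatial|temporal|gcprofile|run`); `run` executes
the whole pipeline from one YAML config and writes a manifest with
seeds, parameters and input checksums.

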