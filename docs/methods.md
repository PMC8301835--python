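# Methods

This note documents the models and procedures couplonscan implements,
the defaults it ships, and the choices made where the design was open.

## Data model and coordinate conventions

All coordinates are 0-based, half-open and circular. A gene is reduced
to its transcription start site (TSS) and strand; GFF3 input (1-based,
inclusive) is converted at the boundary, with the TSS taken as the
feature start on the plus strand and the feature end (minus one, in
0-based terms) on the minus strand. The chromosome length comes from the
GFF3 `##sequence-region` directive or a `#chromosome_length=` header in
the TSV dialect.

A regulon is a regulator (class NAP, sigma or globalTF) with a signed
target set. If the same regulator→target pair appears with conflicting
signs, the effect collapses to "dual". Couplon membership is the plain
intersection of the two parents' gene sets, **ignoring sign**: the
analyses treat joint targeting, not joint activation, as the defining
property. Signed sub-regulons are available through
`Regulon.filtered({"activation"})` for users who want the stricter
reading. Pairing is restricted to (NAP | globalTF) × sigma; exploratory
pairings require an explicit `force=True`.

Alternative sigma factors are handled as separate regulons (RpoS, RpoN,
RpoH, ...), never pooled into a single aggregate; a caller who wants a
pooled set can union the member sets explicitly.

## Spatial enrichment

The window grid lays `ceil(L / step)` windows of width `window_size`
(default 100 kb) every `step` bp (default 10 kb) around the circle; the
trailing windows wrap through the origin so coverage is uniform. The
10 kb step is a smoothing choice — tiling (`step = window_size`) is one
parameter away. A gene belongs to a window if its TSS lies inside it;
assignment by a point rather than the gene extent avoids a gene-length
bias. An optional grid `origin` offset makes the profile exactly
equivariant under joint rotation of coordinates and grid, which is also
the invariant the tests check.

The null model draws gene sets of the same size uniformly, without
replacement, from all annotated genes — not from random genomic
positions, so the null inherits the real gene-density landscape. Two
modes:

* **monte-carlo** (default): 10,000 resamples; per-window mean and
  sample SD (ddof = 1). The resample count and seed are recorded in
  every profile.
* **analytic**: the limit the Monte-Carlo mode converges to. The count
  in a window containing k of the N genes is hypergeometric, with
  mean n·k/N and variance n·(k/N)(1−k/N)(N−n)/(N−1). The test suite
  pins both modes to a complete subset enumeration on a small instance.

Z = (observed − mean)/sd; windows are called enriched when Z > 2 and
depleted when Z < −2, with no multiple-testing correction — the fixed
|Z| > 2 rule is the method being implemented, not a significance claim.
Windows with sd = 0 (e.g. a set comprising every gene) are "undefined"
rather than ±∞ and are excluded pairwise from profile correlations.
Profile similarity is Pearson r over the windows where both profiles are
defined; fewer than 3 usable windows is an error, zero variance is
flagged as undefined rather than silently returned.

## Temporal profiles

The fixed averaging order is: (1) min–max normalize each member gene's
trace to [0;1]; (2) average the normalized traces per timepoint;
(3) rescale the averaged curve to [0;1]. The extremes of the averaged
curve *before* step 3 are reported with each profile: they measure the
set's expression coherence (near 0 and 1 when members share one program,
compressed toward 0.5 when programs disagree). Genes are weighted
equally in the average. Constant traces have no [0;1] form and are
excluded (and counted) rather than mapped to 0.5, so degenerate rows
cannot flatten a set profile. Timepoints are carried in minutes and
never interpolated; profile correlations therefore have as many samples
as timepoints (five in the default design) and are reported without
p-values.

The remapping envelope replaces `round(fraction · |set|)` members
(default fraction 0.10) with genes drawn uniformly from outside the set,
recomputes the profile, and reports the per-timepoint SD over replicates
(default 100; the count is a package default, recorded with the seed in
the output). An alternative reading — permuting the trace-to-gene
assignment for a fraction of all genes genome-wide — is available as
`mode="permute"`; replacement is the default because it perturbs the set
definition, which is the quantity whose robustness is of interest.
Because every replicate is itself rescaled to [0;1], timepoints where
all replicates attain the shared minimum or maximum have an envelope SD
of exactly 0; the envelope measures shape stability between the pinned
extremes.

## Promoter GC profiles

The promoter context spans [−upstream, +downstream) around the TSS
(defaults −300..+200 bp; both configurable — the span and the 21 bp
smoothing width are declared package defaults, not values inferred from
any particular dataset). Minus-strand genes are reverse-complemented so
the returned string always reads 5′→3′ on the coding strand; the
minus-strand context covers genomic [tss−downstream+1, tss+upstream+1).
Extraction wraps across the origin on circular chromosomes; on
non-circular input, boundary-crossing genes are dropped with a count.
Bases other than A/C/G/T/N are rejected at load; N bases are excluded
from both numerator and denominator of the per-position G+C fraction,
and contexts that are mostly N are flagged. Smoothing is a centered
moving average whose edge windows are renormalized to the positions
actually present, so the profile mean is preserved up to edge effects.
GC content stands in for duplex thermodynamic stability; no
nearest-neighbor melting model is attempted.

## Synthetic data generator

The generator's defaults describe the emulated study system:

| parameter | default | meaning |
|---|---|---|
| n_genes | 4,000 | genes on the chromosome |
| chromosome_length | 4,600,000 bp | circular chromosome size |
| gc_ori / gc_ter | 0.56 / 0.48 | GC fraction at origin / terminus |
| timepoints | 60, 120, 180, 300, 420 min | sampling design (1–7 h after inoculation) |
| noise_sd | 0.2 | Gaussian noise, as a fraction of the gene's program range |
| window / step / resamples | 100 kb / 10 kb / 10,000 | spatial-scan defaults |
| remap fraction / reps | 0.10 / 100 | envelope defaults |

TSS positions are uniform on the circle. Base composition follows a
linear GC gradient from the origin (position 0) to the terminus (L/2),
symmetric on both replichores — the simplest shape with the intended
origin-rich / terminus-poor polarity — with bases drawn i.i.d. at the
local GC. Note that "origin-proximal" gene sets selected by rank span a
finite arc, so the realized GC difference between the 200 genes nearest
the origin and the 200 nearest the terminus is slightly below
gc_ori − gc_ter (about 0.076 rather than 0.080 at the defaults); tests
therefore compare measurements against the gradient evaluated at the
selected genes' positions (the construction truth), not against the
nominal endpoint difference.

Regulons draw a configured fraction of members from within ±100 kb of a
spatial center and the rest uniformly. Overlaps with sigma regulons are
planted by sampling shared members from the sigma's member set — per-
member Bernoulli at the configured fraction by default, or exactly
`round(fraction · size)` in "exact" mode — and the remaining members are
drawn from outside the overlap partners, so the planted couplon size is
not inflated by accidental intersections. When a regulator requests both
overlaps and clustering, the overlap quota is allocated first and the
cluster quota is capped by what remains.

Expression is `baseline_g · program(t)` plus Gaussian noise with sd
`noise_sd ×` the gene's program range, clipped at 0; baselines are
log-normal. Each gene follows one dominant program (no additive mixing,
which keeps recovery tests interpretable): its regulon's program, with
couplon members following the sigma parent by default
(`couplon_program="sigma"`). Unregulated genes get a flat program; since
a flat program has zero range, their noise is scaled by the baseline
instead — exactly constant rows would otherwise be dropped by the
constant-gene exclusion and make remapping envelopes degenerate, which
no real transcriptome exhibits. The planted programs peak early
(exponential), mid (transition) or late (stationary); the late program
declines at the final timepoint, and the "fis_mutant" condition removes
that decline, modelling loss of a stationary-phase repressor.

**What the generator does not emulate:** operon structure and strand
bias, macrodomain organization, distance-dependent co-expression,
library-size or count-noise properties of RNA-seq, regulatory cascades,
and any biophysics of supercoiling. Passing tests therefore show that
the analyses recover the statistical structure they target under clean
planted conditions — not that real data will be as well behaved.

## Numerical and degenerate-input policy

* Every stochastic routine takes a seed and records it (plus resample
  counts) in its output; the pipeline derives all stage seeds from one
  config seed and its manifest omits timestamps, so reruns are
  byte-identical.
* sd = 0 windows → call "undefined" (Z = 0 if the observation equals the
  degenerate null, NaN otherwise); constant expression traces →
  excluded, counted; constant averaged curves → flagged, value 0.5;
  constant profiles → correlation NaN with a warning.
* Monte-Carlo vs analytic null agreement is enforced in tests at 3
  standard errors; exhaustive-enumeration agreement at ≥6 decimals.
* Genes in the TRN but absent from the annotation are dropped with
  per-regulon counts; the same policy applies to expression rows with
  missing values.

## Problem sizes in the test suite

Unit tests run on scaled-down instances (hundreds of genes, hundreds of
kb) chosen so the whole suite completes in seconds while every planted
effect is still far above its sampling noise; the acceptance-style tests
use the full default scale (4,000 genes, 4.6 Mb, 10,000 resamples, 10
replicate seeds where replication is part of the claim).

## Known limitations

* The spatial null preserves only set size — not strand, operon
  membership or local density beyond what the annotation induces.
* Five timepoints make temporal correlations coarse descriptors; they
  are reported without inferential dressing by design.
* The sliding-window Z-profile is strongly autocorrelated (adjacent
  windows share 90% of their span at the defaults), so correlations
  between profiles have far fewer effective degrees of freedom than
  windows; treat small |r| differences accordingly.
* `couplon_table` computes all pairwise intersections directly, which is
  quadratic in the number of regulators — fine for the dozens of
  regulators this analysis targets.
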