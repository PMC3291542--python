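# Methods

This note documents the models and procedures implemented in imprintkit,
the defaults and why they were chosen, what the synthetic-data generators
do and do not emulate, and the numerical decisions taken where the
underlying conventions were genuinely open.

## Coordinates

All internal coordinates are 0-based half-open `[start, end)` (the BED
convention); interval length is `end − start` and zero-length intervals
are rejected. Printed locus strings `chrN:A–B` (hyphen or en-dash,
internal whitespace and thousands separators ignored) are read under the
same end-minus-start convention, so a printed pair whose difference is
1129 yields a 1129 bp interval. The parser never adjusts inputs to match
an externally stated length; if a printed length and its printed
endpoints disagree, the endpoints win and the discrepancy is the caller's
to resolve.

Oriented positions are bp downstream of a designated TSS: for a
plus-strand anchor the 5′ edge is `start`, for a minus-strand anchor it
is `end − 1` with the axis mirrored. When a gene has several annotated
TSSs, the 5′-most in transcript orientation is designated for profiling,
matching the convention of treating the major start site as the
reference point.

## CGI/TSS metagene profile

Each CGI of length L is extended by flanks of L/2 on both sides (odd L:
floor upstream, ceil downstream, conserving a total window of exactly
2L). A TSS falling in at least one extended window is associated to the
CGI whose body midpoint is nearest, with ties broken to the lower start
coordinate — the choice is arbitrary but must be deterministic. The
relative coordinate is computed against the *unclipped* window (windows
clipped at position 0 are flagged), which keeps the band-to-class
correspondence exact: r ∈ [0, 0.25) upstream flank, [0.25, 0.75) inside,
[0.75, 1) downstream flank, bin = ⌊100·r⌋ clamped to 99 so no TSS at the
oriented window end is dropped. Minus-strand genes are mirrored before
binning (configurable via `orient_by_strand`) so "upstream" always means
5′ of the gene.

Fractions use two denominators: percent associated is over all genes;
percent inside/upstream/downstream is over associated genes. With zero
genes (or zero associated genes) the undefined fractions are reported as
missing, never as 0.

Lookup is through a per-chromosome sorted index: an extended window spans
at most one CGI length either side of the body, so candidate CGIs for a
position are found by bisection over start coordinates within a
2×max-length bracket. This keeps genome-scale inputs (tens of thousands
of genes and CGIs) at interactive speed; an unknown chromosome yields an
empty candidate set rather than an error.

Note the mirror-equivariance of the profile (reflecting all coordinates
and flipping all strands leaves the profile unchanged) is exact for
even-length CGIs; for odd lengths the floor/ceil flank split breaks the
symmetry by a single base pair.

## Tiling-array relative intensity

Probes are ~50 bp every 100 bp with a cDNA and a genomic-DNA channel.
Processing order: drop probes with zero gDNA (no usable ratio), remove
probes overlapping masks (pseudogenes), form per-probe ratios
r = cDNA/gDNA, centre the ratio vector on its one-step Tukey biweight
location computed in log₂ space, back-transform and divide by the
arithmetic mean over the region so the region mean is exactly 1.

The biweight is the standard one-step estimator used for arrays: median
centre, scale c·MAD + ε (c = 5, ε = 1e−4, MAD unscaled), weights
(1 − u²)² vanishing for |u| ≥ 1, degenerate MAD returning the median. It
equals the arithmetic mean on outlier-free symmetric data and has bounded
response to a single arbitrarily large outlier. Log-space centring was
chosen because array ratios are conventionally treated on the log scale;
because the result is rescaled to region mean 1 regardless, the choice is
observationally minor.

Smoothing follows the display convention: overlapping windows of 9
probes advancing one probe at a time; window means grouped into
consecutive disjoint blocks of 20; each displayed point carries the mean
and sample SD of its 20 window means and sits at the central probe
position of its block. A trailing block with fewer than 20 windows is
emitted with its true window count and a `partial` flag, never silently
averaged as full. Consecutive displayed points are therefore 20 probes
(2 kb at the default pitch) apart — the resolution limit quoted for all
extent-recovery statements. The window step and block grouping phase are
exposed as parameters since only the window and block sizes are fixed by
the display convention.

## Region segmentation

The display region around an antisense macro ncRNA overlapping a sense
gene splits into three adjacent tiles in oriented coordinates: the
sense-gene-specific tile from the sense gene's 3′ end (the most negative
displayed position) to the TSS at 0, the sense/antisense overlap from 0
to `overlap_end`, and the transcript-specific tile from there to the
transcript 3′ end (defaults 28 kb and 118 kb, fully configurable). A
zero-width first tile is permitted so a display starting exactly at the
TSS remains representable.

## Transcript-extent calling

Extent calls compare a mutant to a wildtype profile on an identical point
grid (mismatched grids are an error; no resampling is attempted),
normally restricted to the transcript-specific segment.

*Reduction.* Detection requires k consecutive points with mutant mean
below (1 − δ) × wildtype mean (defaults δ = 0.25, k = 3). For a gradual
decline, the first point of that run lies systematically downstream of
the true onset — the run only fires once the loss exceeds δ, which for a
linear decline is δ × (decline length) past the onset. The reported
`reduction_start` is therefore the estimated onset: a least-squares line
is fitted to the declining flank of the mutant/wildtype ratio (points
between 15% and 95% of the pre-decline baseline, the baseline being the
median ratio upstream of the run) and solved for where it regains the
baseline, snapped to the nearest grid point and never later than the raw
run start. `refine_onset=False` returns the raw run start instead. On
noiseless linear declines the refined onset is exact up to grid snapping.

*Absence.* A point is at background when its mean is ≤ background mean +
z × background SD (default z = 2); detection requires a k-run. Because a
single noisy point would otherwise reset the run and postpone the call by
whole points, the detector uses hysteresis: once a confident k-run is
found, the absent stretch is extended backward over points still
consistent with background at a weaker bound (2z), and `absence_start` is
the first point of that stretch. Both fields are absent when no
qualifying run exists, and `reduction_start ≤ absence_start` is enforced.
All criterion parameters are recorded inside every call for
reproducibility.

*Background.* `estimate_background` uses the last few profile points (the
3′ tail) — valid only when the tail lies beyond the transcribed region,
as it does for a truncated mutant on a display extending past the
wildtype 3′ end; otherwise a measured background should be supplied. The
background mean is the average tail point mean; the background SD is the
average of the tail points' own SDs, i.e. the window-level variability
the error bars display, which is the scale on which a single point must
clear the background to count as signal. Using the scatter of tail point
means instead would produce a threshold only a fraction of a point-noise
SD above background and make calls fragile.

## Strand-ratio windows

Non-overlapping windows (default 3200 bp) tile the region left to right,
the last window possibly short. Reads are counted by 5′ position and
strand; the statistic is log₂((fwd + α)/(rev + α)) with pseudocount
α = 1. Windows overlapping any mask are flagged and carry no ratio, as do
windows with zero reads on both strands (with α = 0, a zero count on
either strand also suppresses the ratio rather than producing ±∞). The
statistic is exactly antisymmetric under a global strand swap.

## Bisulfite and imprinting summaries

Clone QC operationalises standard bisulfite quality control as two
configurable thresholds: non-CpG conversion ≥ 95% (a clone with no
non-CpG evidence fails outright) and ≥ 90% of CpG positions called.
Every exclusion carries its reason. Per-clone percent methylation is
100 × #M/(#M + #U); unreadable positions (N) are excluded from the
denominator rather than imputed. Allele summaries report per-clone
percentages, their mean/min/max, and the per-CpG methylated fraction
across clones; allele identity is metadata (amplicon/primer label plus
genotype), mirroring allele-specific amplification — no sequence
alignment is performed.

Comparative-Ct quantification uses 100 × E^(−ΔΔCt) with
ΔΔCt = (Ct_target − Ct_normaliser) − (same for the calibrator) and
efficiency E = 2 by default (exposed per assay; a sample identical to its
calibrator reads exactly 100%). Allelic imprinting is the
maternal:paternal quantity ratio divided by the ratio of a biallelic
reference condition, which therefore reads exactly 1. Band ratios are
the plain methylated/unmethylated intensity quotient.

The unpaired t-test defaults to the Student (equal-variance) form with a
Welch option; two constant equal groups return t = 0, p = 1 with a
warning rather than NaN. Stars follow the conventional mapping
(*** p < 0.001, ** p < 0.01, * p < 0.05, otherwise ns). Mendelian
segregation uses the Pearson chi-square goodness of fit against expected
class weights (df = classes − 1); both tests delegate the distributional
computation to scipy.

## Synthetic-data generators

All generators draw exclusively from `numpy.random.default_rng(seed)`,
so identical (seed, parameters) give bit-identical output; the truth dict
returned with each dataset records every generating parameter and is the
oracle for all recovery tests.

*Annotations.* Gene relation classes are drawn multinomially from the
requested fractions; each associated gene receives its own CGI (lengths
uniform on 500–2000 bp by default) spaced so extended windows never
overlap, making the intended association unambiguous, and its TSS is
placed uniformly over the integer positions whose oriented relative
coordinate lies strictly within the class band. Unassociated genes are
placed in the inter-CGI gaps. This emulates the positional structure
(class fractions, strand symmetry) but not CpG density, clustering of
real CGIs, or multi-gene CGIs.

*Tiling tracks.* The cDNA channel is sense level (occupying the
sense-specific and overlap tiles) + antisense level × initiation scale ×
decline factor (1 at `decline_start`, linearly to 0 at `truncation`, 0
beyond; an exponential decline is available) + a constant background
floor, all times multiplicative lognormal noise (log-scale SD 0.10 by
default — the array noise level used throughout the recovery claims);
the gDNA channel is constant times the same noise. The floor (5% of the
antisense unit level) represents non-specific hybridisation, without
which "absence" would be the degenerate comparison against exactly zero.
Three named scenarios encode the study conditions: full-length wildtype
(118 kb), a repeat-deletion allele declining from 68 kb and lost from
90 kb, and an island-deletion allele at half initiation lost from 73 kb.
Not emulated: probe-specific affinity, spatial artefacts, splice
structure (extent is modelled on the unspliced signal).

*Reads, clones, qPCR, litters.* Stranded reads are multinomial over
(segment × strand) cells with probability ∝ rate × length and uniform
positions. Bisulfite clones draw i.i.d. Bernoulli(p) CpG calls per
allele, inject no-calls at 2% and unconverted non-CpG counts as
Binomial(30, 1%) — within-clone correlation of real alleles is not
modelled, so real per-clone variance is underestimated. qPCR Ct values
are base − log_E(quantity) + Gaussian noise (SD 0.15 cycles). Litters are
multinomial over Mendelian class weights.

Because the generators are i.i.d. at the probe/CpG/read level, passing
recovery tests demonstrates correctness of the computations and
calibration of the estimators under the stated noise models — not
robustness to the correlated artefacts of real arrays or real bisulfite
data.

## Problem sizes used in tests and the acceptance script

Recovery tests run at the study's stated conditions: 5000 genes for
metagene fraction recovery (99% binomial CIs), 20 seeds of the 180 kb /
100 bp-pitch tiling geometry at 10% noise for extent recovery (tolerance
one displayed-point spacing, 2 kb), and 24 clones × 20 CpGs per bisulfite
regime. The acceptance script, whose job is to report stable point
estimates rather than test calibration, uses larger replication chosen
for estimator stability: 50 000 genes for the metagene fractions, 10
seeds per extent scenario, 50 clone sets per methylation regime, and
10–20 simulated differentiation sets for band and allelic ratios; each
reported value carries the problem size used.

## Known limitations

- The extent caller assumes a single monotone decline; multiple or
  non-monotone losses yield only the first qualifying boundary pair.
- Onset back-extrapolation presumes an approximately linear flank on the
  displayed-point scale; strongly convex declines will bias the onset
  estimate toward the detection run.
- The metagene profiler uses one designated TSS per gene; alternative
  promoters are not profiled separately.
- BED parsing is deliberately minimal (BED3/BED6); GFF3 and liftover are
  out of scope, as are read alignment and de novo CGI detection.
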