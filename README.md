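# imprintkit

Analysis toolkit for the positional, transcriptional and epigenetic
characterisation of an imprinted macro ncRNA locus — the configuration
exemplified by mouse *Airn*, an ~118 kb unspliced antisense RNA whose CpG
island (CGI) lies *downstream* of its transcription start site (TSS) and
whose paternal-specific expression silences the overlapped *Igf2r* gene
in cis.

It is written for genomicists who need to quantify this kind of locus from
standard light-weight inputs (BED annotations, tiling-array probe tables,
stranded read tables, bisulfite clone calls, qPCR Ct tables) without any
heavyweight pipeline, and for methodologists who want the individual
computations — metagene binning, robust array normalisation, transcript
extent calling, allelic ratios — as small, tested, composable functions.

## What it computes

**CGI/TSS metagene profile.** Each gene's TSS is associated to a CGI if it
falls within the CGI body extended by flanks of half the CGI length on
each side. The oriented relative coordinate *r* ∈ [0, 1) over this 2L
window (mirrored for minus-strand genes) is binned into 100 parts;
*r* ∈ [0.25, 0.75) is inside the CGI body, [0, 0.25) is the upstream
flank, [0.75, 1) the downstream flank. Summed over all CGIs this yields a
genome-scale picture of where TSSs sit relative to their CGIs.

**Tiling-array relative intensity and transcript extent.** Per-probe
ratios of a cDNA channel to a genomic-DNA channel (~50 bp probes every
100 bp) are Tukey-biweight centred in log₂ space and rescaled so the mean
over the analysis region is 1. Overlapping 9-probe windows are averaged
and grouped into displayed points of 20 window means (mean ± SD). Given a
mutant and a wildtype profile, the extent caller reports

- *reduction_start* — the onset of a sustained reduction, detected as
  `k` consecutive points with mutant mean < (1 − δ) × wildtype mean
  (defaults δ = 0.25, k = 3) and localised by back-extrapolating the
  declining mutant/wildtype ratio to its pre-decline baseline;
- *absence_start* — the first point of a `k`-run at or below
  background mean + z·SD (default z = 2), with hysteresis so a single
  noisy point cannot postpone the call.

**Strand-specific read windows.** Non-overlapping 3.2 kb windows tile a
region; the log₂(forward/reverse) read-count ratio (pseudocount α = 1) is
reported per window, with exon/pseudogene-masked windows excluded.

**Bisulfite and imprinting summaries.** Clone-level conversion QC
(conversion ≥ 95% at non-CpG cytosines, ≥ 90% CpGs called), per-clone
percent methylation over called CpGs, per-allele mean/min/max and per-CpG
fractions; methyl-sensitive band ratios; comparative-Ct expression
(100 × E^(−ΔΔCt)); maternal:paternal allelic ratios normalised to a
biallelic reference; unpaired t-tests with conventional significance
stars; and chi-square tests of Mendelian segregation.

**Synthetic data.** `imprintkit.simulate` generates seeded datasets with
the statistical structure each stage assumes — annotation sets with known
TSS/CGI relation classes, two-channel tiling tracks with configurable
decline/truncation, stranded reads, bisulfite clones, qPCR series and
litters — alongside ground-truth records, so every recovery claim in the
test suite is checked against a known truth.

## Worked example

Recover a transcript truncation from synthetic tiling arrays at the study
geometry (180 kb display region, 100 bp probe pitch, 10% array noise; the
mutant declines from 68 kb after the TSS and is lost from 90 kb):

```python
from imprintkit import simulate as sim
from imprintkit.pipeline import build_relative_profile
from imprintkit.tiling import call_extent, estimate_background

wt_probes, _, _ = sim.gen_tiling(sim.WILDTYPE, seed=1)
mut_probes, _, truth = sim.gen_tiling(sim.TDR_DELETION, seed=2)

wt = build_relative_profile(wt_probes, tss_genomic_pos=62_000)
mut = build_relative_profile(mut_probes, tss_genomic_pos=62_000)

call = call_extent(mut, wt, estimate_background(mut), segment=(28_000, 118_000))
print(f"true decline start : {truth['scenario']['decline_start']:>7.0f} bp")
print(f"called reduction   : {call.reduction_start:>7.0f} bp")
print(f"true truncation    : {truth['scenario']['truncation']:>7.0f} bp")
print(f"called absence     : {call.absence_start:>7.0f} bp")
```

prints

```
true decline start :   68000 bp
called reduction   :   67300 bp
true truncation    :   90000 bp
called absence     :   91300 bp
```

Both boundaries are recovered within one displayed-point spacing
(2 kb = 20 windows × 100 bp pitch), which is the resolution limit of the
smoothed display.

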