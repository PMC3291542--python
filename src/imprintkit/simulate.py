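"""Seeded generators emulating the data structure of an imprinted macro
ncRNA locus study, with ground truth for recovery testing.

Each generator draws from ``numpy.random.default_rng(seed)`` only, so
identical (seed, parameters) give identical output, and returns the
generated data together with a ``truth`` dict recording every generating
parameter.  The defaults are the study conditions: ~50 bp tiling probes
every 100 bp over a 180 kb display region (oriented -62..+118 kb around
the antisense TSS), segment boundaries at 0 and 28 kb, a 118 kb wildtype
transcript, and truncation scenarios at 68->90 kb (repeat deletion) and
73 kb with halved initiation (island deletion).
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .intervals import (
    STRAND_MINUS,
    STRAND_PLUS,
    AnnotationSet,
    GenomeInterval,
    TranscriptionStartSite,
)
from .methylation import BisulfiteClone, GenotypeCounts
from .profile import (
    RELATION_DOWNSTREAM,
    RELATION_INSIDE,
    RELATION_UNASSOCIATED,
    RELATION_UPSTREAM,
)
from .tiling import TilingProbe

_CLASS_BANDS = {
    RELATION_UPSTREAM: (0.0, 0.25),
    RELATION_INSIDE: (0.25, 0.75),
    RELATION_DOWNSTREAM: (0.75, 1.0),
}


def write_truth(truth: dict, path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump(truth, fh, indent=2, default=str)
        fh.write("\n")


# ---------------------------------------------------------------------------
# Annotation generator (CGIs + TSSs with known relation classes)
# ---------------------------------------------------------------------------

def gen_annotation(
    n_genes: int,
    fractions: dict[str, float],
    cgi_length_range: tuple[int, int] = (500, 2000),
    seed: int = 0,
    chrom: str = "chrS",
) -> tuple[AnnotationSet, dict]:
    """Synthetic CGIs with one TSS each, placed in a requested relation class.

    ``fractions`` maps {inside, upstream_flank, downstream_flank,
    unassociated} (short keys inside/upstream/downstream accepted) to
    probabilities summing to 1.  Each gene's class is drawn from those
    probabilities; its TSS is placed uniformly over the positions whose
    oriented relative coordinate falls in the class band.  CGIs are spaced
    so extended windows never overlap, making the intended association
    unambiguous.  Strands are assigned at random.
    """
    keymap = {
        "inside": RELATION_INSIDE,
        "upstream": RELATION_UPSTREAM,
        "downstream": RELATION_DOWNSTREAM,
        "unassociated": RELATION_UNASSOCIATED,
    }
    probs: dict[str, float] = {}
    for key, val in fractions.items():
        probs[keymap.get(key, key)] = float(val)
    if abs(sum(probs.values()) - 1.0) > 1e-9:
        raise ValueError("fractions must sum to 1")
    lo_len, hi_len = cgi_length_range
    if lo_len < 4 or hi_len < lo_len:
        raise ValueError("infeasible CGI length range")

    rng = np.random.default_rng(seed)
    class_names = [
        RELATION_INSIDE,
        RELATION_UPSTREAM,
        RELATION_DOWNSTREAM,
        RELATION_UNASSOCIATED,
    ]
    p = np.array([probs.get(c, 0.0) for c in class_names])
    classes = [class_names[i] for i in rng.choice(4, size=n_genes, p=p)]

    gap = 6 * hi_len  # keeps extended windows disjoint with room to spare
    cursor = 4 * hi_len
    n_unassoc_here = 0
    cgis: list[GenomeInterval] = []
    genes: list[TranscriptionStartSite] = []
    for gi, cls in enumerate(classes):
        gene_id = f"g{gi:05d}"
        strand = STRAND_PLUS if rng.random() < 0.5 else STRAND_MINUS
        if cls == RELATION_UNASSOCIATED:
            # inside the inter-CGI gap, clear of every extended window
            pos = cursor - 2 * hi_len + (n_unassoc_here % hi_len)
            n_unassoc_here += 1
            genes.append(TranscriptionStartSite(gene_id, chrom, pos, strand))
            continue
        n_unassoc_here = 0
        length = int(rng.integers(lo_len, hi_len + 1))
        cgi = GenomeInterval(chrom, cursor, cursor + length)
        cgis.append(cgi)
        vstart = cgi.start - length // 2
        win_len = 2 * length
        band_lo, band_hi = _CLASS_BANDS[cls]
        q_lo = int(np.ceil(band_lo * win_len))
        q_hi = int(np.ceil(band_hi * win_len)) - 1
        q = int(rng.integers(q_lo, q_hi + 1))  # oriented offset within window
        if strand == STRAND_PLUS:
            pos = vstart + q
        else:
            pos = vstart + win_len - 1 - q
        genes.append(TranscriptionStartSite(gene_id, chrom, pos, strand))
        cursor += length + gap

    truth = {
        "seed": seed,
        "n_genes": n_genes,
        "requested_fractions": {c: probs.get(c, 0.0) for c in class_names},
        "classes": classes,
    }
    return AnnotationSet(cgis=cgis, genes=genes, provenance="synthetic"), truth


# ---------------------------------------------------------------------------
# Tiling-array generator
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TilingScenario:
    """Generating parameters of one tiling-array track."""

    decline_start: float
    truncation: float
    initiation_scale: float = 1.0


# The study conditions: wildtype full length; repeat deletion declining from
# 68 kb with loss from 90 kb; island deletion with ~half initiation and loss
# from 73 kb.
WILDTYPE = TilingScenario(decline_start=118_000, truncation=118_000)
TDR_DELETION = TilingScenario(decline_start=68_000, truncation=90_000)
CGI_DELETION = TilingScenario(
    decline_start=28_000, truncation=73_000, initiation_scale=0.5
)


def _decline_factor(pos: np.ndarray, scenario: TilingScenario,
                    shape: str = "linear") -> np.ndarray:
    ds, tr = scenario.decline_start, scenario.truncation
    f = np.ones_like(pos, dtype=float)
    if tr > ds:
        in_decline = (pos >= ds) & (pos < tr)
        if shape == "linear":
            f[in_decline] = (tr - pos[in_decline]) / (tr - ds)
        elif shape == "exponential":
            # ~e^-4 residual at the truncation point, then hard zero
            f[in_decline] = np.exp(-4.0 * (pos[in_decline] - ds) / (tr - ds))
        else:
            raise ValueError(f"unknown decline shape {shape!r}")
    f[pos >= tr] = 0.0
    return f


def gen_tiling(
    scenario: TilingScenario = WILDTYPE,
    probe_len: int = 50,
    spacing: int = 100,
    region: tuple[int, int] = (-62_000, 118_000),
    overlap_end: int = 28_000,
    sense_level: float = 1.0,
    antisense_level: float = 1.0,
    background_level: float = 0.05,
    gdna_level: float = 100.0,
    noise_sd: float = 0.10,
    decline_shape: str = "linear",
    seed: int = 0,
    chrom: str = "chr17",
) -> tuple[list[TilingProbe], np.ndarray, dict]:
    """Two-channel tiling probes over the display region.

    The cDNA channel is the sum of a sense transcript occupying
    ``[region_start, overlap_end)``, an antisense transcript occupying
    ``[0, truncation)`` scaled by ``initiation_scale`` and a decline factor
    (1 at ``decline_start`` falling to 0 at ``truncation``), and a constant
    background floor; both channels carry multiplicative lognormal noise
    with log-scale sd ``noise_sd``.  Returns (probes, oriented probe
    positions, truth); probe genomic coordinates place the antisense TSS
    at ``-region_start`` so all coordinates are non-negative.
    """
    start, end = region
    if not (start <= 0 < overlap_end < end):
        raise ValueError("region must bracket the TSS and overlap boundary")
    if not (start <= scenario.decline_start <= scenario.truncation <= end):
        raise ValueError("decline/truncation must lie within the region")
    rng = np.random.default_rng(seed)

    positions = np.arange(start, end, spacing)
    sense = np.where((positions >= start) & (positions < overlap_end),
                     sense_level, 0.0)
    antisense = np.where(positions >= 0, antisense_level, 0.0)
    antisense = antisense * scenario.initiation_scale
    antisense = antisense * _decline_factor(positions, scenario, decline_shape)
    signal = sense + antisense + background_level

    cdna = signal * gdna_level * rng.lognormal(0.0, noise_sd, positions.size)
    gdna = gdna_level * rng.lognormal(0.0, noise_sd, positions.size)

    offset = -start
    probes = [
        TilingProbe(
            GenomeInterval(chrom, int(p) + offset, int(p) + offset + probe_len),
            float(cd), float(gd),
        )
        for p, cd, gd in zip(positions, cdna, gdna)
    ]
    truth = {
        "seed": seed,
        "scenario": asdict(scenario),
        "probe_len": probe_len,
        "spacing": spacing,
        "region": list(region),
        "overlap_end": overlap_end,
        "sense_level": sense_level,
        "antisense_level": antisense_level,
        "background_level": background_level,
        "noise_sd": noise_sd,
        "decline_shape": decline_shape,
        "genomic_offset": offset,
    }
    return probes, positions.astype(float), truth


# ---------------------------------------------------------------------------
# Stranded read generator
# ---------------------------------------------------------------------------

def gen_stranded_reads(
    segment_rates: Sequence[tuple[int, int, float, float]],
    n_reads: int,
    seed: int = 0,
    chrom: str = "chr17",
) -> tuple[list[tuple[str, int, str]], dict]:
    """Reads multinomial over (segment, strand) cells.

    ``segment_rates`` is a sequence of (start, end, fwd_rate, rev_rate) in
    genomic coordinates; the expected read count of each cell is
    proportional to rate x segment length.  Positions are uniform within
    the segment.
    """
    if n_reads < 0:
        raise ValueError("n_reads must be >= 0")
    cells = []
    weights = []
    for s, e, fwd, rev in segment_rates:
        if e <= s or fwd < 0 or rev < 0:
            raise ValueError("invalid segment rate entry")
        cells.append((s, e, STRAND_PLUS))
        weights.append(fwd * (e - s))
        cells.append((s, e, STRAND_MINUS))
        weights.append(rev * (e - s))
    w = np.asarray(weights, dtype=float)
    if w.sum() <= 0:
        raise ValueError("rates must not all be zero")
    rng = np.random.default_rng(seed)
    counts = rng.multinomial(n_reads, w / w.sum())
    reads: list[tuple[str, int, str]] = []
    for (s, e, strand), n in zip(cells, counts):
        for p in rng.integers(s, e, size=n):
            reads.append((chrom, int(p), strand))
    truth = {
        "seed": seed,
        "n_reads": n_reads,
        "segment_rates": [list(sr) for sr in segment_rates],
    }
    return reads, truth


def write_reads_bed6(reads: Sequence[tuple[str, int, str]], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("# imprintkit synthetic stranded reads (BED6)\n")
        for i, (chrom, pos, strand) in enumerate(reads):
            fh.write(f"{chrom}\t{pos}\t{pos + 1}\tread{i:07d}\t0\t{strand}\n")


# ---------------------------------------------------------------------------
# Bisulfite clone generator
# ---------------------------------------------------------------------------

def gen_bisulfite(
    n_clones: int = 24,
    n_cpgs: int = 20,
    p_methylation: float = 0.12,
    conversion_failure_rate: float = 0.01,
    no_call_rate: float = 0.02,
    noncpg_sites: int = 30,
    seed: int = 0,
    allele: str = "paternal",
    amplicon: str = "F4+R9",
) -> tuple[list[BisulfiteClone], dict]:
    """Clones with i.i.d. Bernoulli CpG methylation plus conversion QC counts.

    Per-CpG calls are Bernoulli(``p_methylation``); a fraction
    ``no_call_rate`` of calls is replaced by N; the number of unconverted
    non-CpG cytosines is Binomial(``noncpg_sites``,
    ``conversion_failure_rate``).
    """
    for name, val in [
        ("p_methylation", p_methylation),
        ("conversion_failure_rate", conversion_failure_rate),
        ("no_call_rate", no_call_rate),
    ]:
        if not 0.0 <= val <= 1.0:
            raise ValueError(f"{name} must be in [0, 1]")
    rng = np.random.default_rng(seed)
    clones = []
    for ci in range(n_clones):
        meth = rng.random(n_cpgs) < p_methylation
        nocall = rng.random(n_cpgs) < no_call_rate
        calls = "".join(
            "N" if nc else ("M" if m else "U") for m, nc in zip(meth, nocall)
        )
        unconverted = int(rng.binomial(noncpg_sites, conversion_failure_rate))
        clones.append(
            BisulfiteClone(
                f"clone{ci:03d}", amplicon, allele, calls, noncpg_sites, unconverted
            )
        )
    truth = {
        "seed": seed,
        "n_clones": n_clones,
        "n_cpgs": n_cpgs,
        "p_methylation": p_methylation,
        "conversion_failure_rate": conversion_failure_rate,
        "no_call_rate": no_call_rate,
        "allele": allele,
    }
    return clones, truth


def write_clone_table(clones: Sequence[BisulfiteClone], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write(
            "clone_id\tamplicon\tallele\tcpg_calls\tnonCpG_total\tnonCpG_unconverted\n"
        )
        for c in clones:
            fh.write(
                f"{c.clone_id}\t{c.amplicon}\t{c.allele}\t{c.cpg_calls}\t"
                f"{c.noncpg_total}\t{c.noncpg_unconverted}\n"
            )


# ---------------------------------------------------------------------------
# Allele-specific qPCR and litter generators
# ---------------------------------------------------------------------------

def gen_allelic_series(
    conditions: Sequence[tuple[str, float]],
    n_replicates: int = 3,
    ct_noise_sd: float = 0.15,
    efficiency: float = 2.0,
    base_ct: float = 24.0,
    seed: int = 0,
) -> tuple[pd.DataFrame, dict]:
    """Allele-specific qPCR Ct table for a differentiation series.

    ``conditions`` maps sample labels to true maternal:paternal expression
    ratios (paternal quantity fixed at 1).  Ct values follow
    ``base_ct - log_eff(quantity)`` plus Gaussian noise, so at zero noise
    the ratio is recovered exactly from ``efficiency**(ct_pat - ct_mat)``.
    """
    rng = np.random.default_rng(seed)
    rows = []
    for label, ratio in conditions:
        if ratio <= 0:
            raise ValueError("true ratios must be positive")
        for assay, qty in (("maternal", ratio), ("paternal", 1.0)):
            ct_clean = base_ct - np.log(qty) / np.log(efficiency)
            for rep in range(n_replicates):
                rows.append(
                    {
                        "sample": label,
                        "assay": assay,
                        "replicate": rep,
                        "ct": float(ct_clean + rng.normal(0.0, ct_noise_sd)),
                    }
                )
    truth = {
        "seed": seed,
        "conditions": {label: ratio for label, ratio in conditions},
        "n_replicates": n_replicates,
        "ct_noise_sd": ct_noise_sd,
        "efficiency": efficiency,
    }
    return pd.DataFrame(rows), truth


def recover_allelic_ratios(qpcr: pd.DataFrame, efficiency: float = 2.0) -> dict[str, float]:
    """Mean mat:pat quantity ratio per sample from a Ct table."""
    out: dict[str, float] = {}
    for label, grp in qpcr.groupby("sample", sort=False):
        ct_mat = grp.loc[grp["assay"] == "maternal", "ct"].mean()
        ct_pat = grp.loc[grp["assay"] == "paternal", "ct"].mean()
        out[str(label)] = float(efficiency ** (ct_pat - ct_mat))
    return out


def gen_litter(
    n: int = 65,
    weights: Sequence[float] = (1.0, 2.0, 1.0),
    labels: Sequence[str] = ("wildtype", "heterozygote", "homozygote"),
    seed: int = 0,
) -> tuple[GenotypeCounts, dict]:
    """Multinomial litter genotype counts under Mendelian class weights."""
    w = np.asarray(weights, dtype=float)
    if np.any(w <= 0):
        raise ValueError("weights must be positive")
    rng = np.random.default_rng(seed)
    counts = rng.multinomial(n, w / w.sum())
    gc = GenotypeCounts(tuple(labels), tuple(int(c) for c in counts), tuple(w))
    truth = {"seed": seed, "n": n, "weights": list(map(float, w)), "labels": list(labels)}
    return gc, truth
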