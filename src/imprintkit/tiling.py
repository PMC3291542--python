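"""Tiling-array relative intensity, transcript-extent calling, and
strand-specific read-ratio windows.

The array design is ~50 bp probes spaced every 100 bp of single-copy
sequence; a cDNA channel is co-hybridised with a genomic-DNA channel.  The
per-probe cDNA/gDNA ratio is Tukey-biweight centred in log space and
rescaled so the mean over the analysis region is 1 ("relative signal
intensity").  Overlapping windows of 9 probes are averaged, and each
displayed point summarises 20 consecutive window means (mean and sample
SD).  A transcript-extent call compares a mutant profile to a wildtype
one: a sustained fractional reduction marks where the transcript starts to
be lost, and a fall to background marks where it is absent.

Positions throughout are *oriented*: bp downstream of the designated
transcript TSS (negative positions are upstream of it).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .intervals import STRAND_MINUS, STRAND_PLUS, GenomeInterval


@dataclass(frozen=True)
class TilingProbe:
    interval: GenomeInterval
    cdna_signal: float
    gdna_signal: float

    def __post_init__(self) -> None:
        if self.cdna_signal < 0 or self.gdna_signal < 0:
            raise ValueError("probe signals must be non-negative")


def read_probe_table(path: str | Path) -> list[TilingProbe]:
    """Probe TSV with columns chrom, start, end, cdna, gdna."""
    df = pd.read_csv(path, sep="\t", comment="#")
    probes = []
    for row in df.itertuples(index=False):
        probes.append(
            TilingProbe(
                GenomeInterval(str(row.chrom), int(row.start), int(row.end)),
                float(row.cdna),
                float(row.gdna),
            )
        )
    return probes


def write_probe_table(probes: Iterable[TilingProbe], path: str | Path,
                      header_comment: str = "") -> None:
    with open(path, "w") as fh:
        if header_comment:
            fh.write(f"# {header_comment}\n")
        fh.write("chrom\tstart\tend\tcdna\tgdna\n")
        for p in probes:
            fh.write(
                f"{p.interval.chrom}\t{p.interval.start}\t{p.interval.end}\t"
                f"{p.cdna_signal:.6g}\t{p.gdna_signal:.6g}\n"
            )


def drop_zero_gdna(probes: Sequence[TilingProbe]) -> list[TilingProbe]:
    """QC: probes with no genomic-DNA signal carry no usable ratio."""
    kept = [p for p in probes if p.gdna_signal > 0]
    n_dropped = len(probes) - len(kept)
    if n_dropped:
        warnings.warn(f"dropped {n_dropped} probes with zero gDNA signal")
    return kept


def apply_masks(probes: Sequence[TilingProbe],
                masks: Sequence[GenomeInterval]) -> list[TilingProbe]:
    """Remove probes overlapping any mask interval (e.g. pseudogenes)."""
    kept = [
        p for p in probes if not any(p.interval.overlaps(m) for m in masks)
    ]
    n_removed = len(probes) - len(kept)
    if n_removed == len(probes) and probes:
        warnings.warn("masks removed every probe")
    return kept


def tukey_biweight_location(values, c: float = 5.0, eps: float = 1e-4) -> float:
    """One-step Tukey biweight location estimate.

    Values are centred on their median and scaled by ``c * MAD + eps``
    (MAD = median absolute deviation, unscaled); weights ``(1 - u^2)^2``
    vanish beyond ``|u| >= 1`` so a single arbitrarily large outlier has
    bounded influence.  Degenerate scale (MAD = 0) returns the median.
    """
    x = np.asarray(values, dtype=float)
    if x.size == 0:
        raise ValueError("tukey_biweight_location: empty input")
    med = float(np.median(x))
    mad = float(np.median(np.abs(x - med)))
    if mad == 0.0:
        return med
    u = (x - med) / (c * mad + eps)
    w = np.where(np.abs(u) < 1.0, (1.0 - u**2) ** 2, 0.0)
    return float(np.sum(w * x) / np.sum(w))


def relative_intensity(probes: Sequence[TilingProbe],
                       region: GenomeInterval | None = None,
                       c: float = 5.0, eps: float = 1e-4) -> np.ndarray:
    """Per-probe relative signal intensities with region mean 1.

    The cDNA/gDNA ratio vector is centred on its Tukey biweight location in
    log2 space (array ratios are conventionally treated on the log scale),
    back-transformed, and divided by its arithmetic mean so the mean over
    the region is exactly 1.  All-zero cDNA yields all zeros with a warning.
    """
    if region is not None:
        probes = [p for p in probes if p.interval.overlaps(region)]
    if not probes:
        raise ValueError("no probes in region")
    cdna = np.array([p.cdna_signal for p in probes], dtype=float)
    gdna = np.array([p.gdna_signal for p in probes], dtype=float)
    if np.any(gdna <= 0):
        raise ValueError("probes with zero gDNA must be dropped before use")
    ratio = cdna / gdna
    if not np.any(ratio > 0):
        warnings.warn("all cDNA signals are zero over the region")
        return np.zeros_like(ratio)
    pos = ratio > 0
    center = tukey_biweight_location(np.log2(ratio[pos]), c=c, eps=eps)
    centred = ratio / 2.0**center
    return centred / centred.mean()


@dataclass(frozen=True)
class ProfilePoint:
    oriented_position: float
    mean: float
    sd: float
    n_windows: int
    partial: bool = False


@dataclass
class RelativeIntensityProfile:
    """Smoothed relative-intensity points (strictly increasing positions)."""

    points: list[ProfilePoint]

    def __post_init__(self) -> None:
        pos = self.positions
        if np.any(np.diff(pos) <= 0):
            raise ValueError("profile positions must be strictly increasing")

    @property
    def positions(self) -> np.ndarray:
        return np.array([p.oriented_position for p in self.points])

    @property
    def means(self) -> np.ndarray:
        return np.array([p.mean for p in self.points])

    @property
    def sds(self) -> np.ndarray:
        return np.array([p.sd for p in self.points])

    def restrict(self, start: float, end: float) -> "RelativeIntensityProfile":
        kept = [p for p in self.points if start <= p.oriented_position < end]
        return RelativeIntensityProfile(kept)


def smooth_profile(positions, values, tiles_per_window: int = 9,
                   windows_per_point: int = 20) -> RelativeIntensityProfile:
    """Overlapping 9-probe window means grouped into disjoint 20-window points.

    Windows advance one probe at a time; consecutive disjoint blocks of 20
    window means give each displayed point its mean and sample SD.  A
    trailing block with fewer windows is emitted flagged as partial, never
    silently averaged as if full.  The point position is the central probe
    position of the block.
    """
    pos = np.asarray(positions, dtype=float)
    vals = np.asarray(values, dtype=float)
    if pos.size != vals.size:
        raise ValueError("positions and values must have equal length")
    if pos.size < tiles_per_window:
        raise ValueError(
            f"need >= {tiles_per_window} probes, got {pos.size}"
        )
    if np.any(np.diff(pos) <= 0):
        raise ValueError("probes must be sorted by position")

    kernel = np.full(tiles_per_window, 1.0 / tiles_per_window)
    window_means = np.convolve(vals, kernel, mode="valid")
    n_windows = window_means.size

    points: list[ProfilePoint] = []
    for block_start in range(0, n_windows, windows_per_point):
        block = window_means[block_start : block_start + windows_per_point]
        nw = block.size
        partial = nw < windows_per_point
        # probes spanned by this block: indices block_start .. block_start+nw+tiles-2
        central = block_start + (nw + tiles_per_window - 2) // 2
        sd = float(np.std(block, ddof=1)) if nw > 1 else float("nan")
        points.append(
            ProfilePoint(float(pos[central]), float(block.mean()), sd, nw, partial)
        )
    return RelativeIntensityProfile(points)


@dataclass(frozen=True)
class RegionSegmentation:
    """Three adjacent tiles of the display region in oriented coordinates.

    The sense-gene-specific tile runs from the sense gene's 3' end (the most
    5' oriented position displayed) to the TSS at 0; the sense/antisense
    overlap runs from 0 to ``overlap_end``; the transcript-specific tile
    runs from there to the transcript 3' end.  The first tile may be empty
    when the display starts at the TSS.
    """

    igf2r_specific: tuple[float, float]
    overlap: tuple[float, float]
    transcript_specific: tuple[float, float]


def segment_region(igf2r_end_oriented: float, overlap_end_oriented: float,
                   transcript_end_oriented: float) -> RegionSegmentation:
    if not (0 < overlap_end_oriented < transcript_end_oriented):
        raise ValueError(
            "require 0 < overlap_end < transcript_end, got "
            f"{overlap_end_oriented}, {transcript_end_oriented}"
        )
    if igf2r_end_oriented > 0:
        raise ValueError("sense-specific segment must end at or before the TSS")
    return RegionSegmentation(
        (igf2r_end_oriented, 0.0),
        (0.0, overlap_end_oriented),
        (overlap_end_oriented, transcript_end_oriented),
    )


@dataclass(frozen=True)
class Background:
    mean: float
    sd: float


@dataclass(frozen=True)
class ExtentCall:
    reduction_start: float | None
    absence_start: float | None
    criterion_params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if (
            self.reduction_start is not None
            and self.absence_start is not None
            and self.reduction_start > self.absence_start
        ):
            raise ValueError("reduction_start must be <= absence_start")


def estimate_background(profile: RelativeIntensityProfile,
                        n_tail: int = 5) -> Background:
    """Background from the last ``n_tail`` profile points (3' tail).

    Only meaningful when the profile's 3' tail lies beyond the transcribed
    region (true for a truncated mutant over a display region that extends
    past the wildtype 3' end); otherwise supply a Background measured from
    an untranscribed region directly.  The background mean is the average of the tail point means; the
    background sd is the average of the tail points' own SDs — the
    window-level variability that the profile's error bars display, which
    is the scale on which a single point must clear the background to
    count as signal.
    """
    means = profile.means[-n_tail:]
    sds = profile.sds[-n_tail:]
    sd = float(np.nanmean(sds)) if np.any(np.isfinite(sds)) else 0.0
    return Background(float(means.mean()), sd)


def _first_k_run(condition: np.ndarray, k: int) -> int | None:
    run = 0
    for i, ok in enumerate(condition):
        run = run + 1 if ok else 0
        if run == k:
            return i - k + 1
    return None


def _refine_onset(positions: np.ndarray, ratio: np.ndarray, i0: int) -> float:
    """Back-extrapolate the decline flank to its onset.

    The first point of the sustained-reduction run lies partway down a
    gradual decline (the run criterion only fires once the reduction
    exceeds delta).  The onset is recovered by fitting a least-squares line
    to the declining flank of the mutant/wildtype ratio and solving for
    where it regains the pre-decline baseline, snapped to the point grid.
    """
    baseline = float(np.median(ratio[: max(i0, 1)]))
    if baseline <= 0:
        return float(positions[i0])
    lo, hi = 0.15 * baseline, 0.95 * baseline
    j_end = i0
    while j_end + 1 < ratio.size and ratio[j_end + 1] >= lo:
        j_end += 1
    j_start = i0
    while j_start > 0 and lo <= ratio[j_start - 1] <= hi:
        j_start -= 1
    flank = [j for j in range(j_start, j_end + 1) if lo <= ratio[j] <= hi]
    if len(flank) < 2:
        return float(positions[i0])
    x, y = positions[flank], ratio[flank]
    slope, intercept = np.polyfit(x, y, 1)
    if slope >= 0:
        return float(positions[i0])
    onset = (baseline - intercept) / slope
    onset = min(onset, positions[i0])
    nearest = int(np.argmin(np.abs(positions - onset)))
    return float(positions[min(nearest, i0)])


def call_extent(mutant: RelativeIntensityProfile,
                wildtype: RelativeIntensityProfile,
                background: Background,
                delta: float = 0.25, k: int = 3, z: float = 2.0,
                segment: tuple[float, float] | None = None,
                refine_onset: bool = True) -> ExtentCall:
    """Call where a mutant transcript is reduced and where it is absent.

    ``reduction_start``: detection requires ``k`` consecutive points with
    mutant mean below ``(1 - delta)`` times the wildtype mean; the reported
    position is the estimated decline onset (see ``refine_onset``), or the
    raw run start when ``refine_onset=False``.  ``absence_start``: first
    point of a ``k``-run with mutant mean at or below
    ``background.mean + z * background.sd``.  Either field is None when no
    such run exists.  Point grids must match exactly; no resampling.
    """
    if segment is not None:
        mutant = mutant.restrict(*segment)
        wildtype = wildtype.restrict(*segment)
    mpos, wpos = mutant.positions, wildtype.positions
    if mpos.size != wpos.size or not np.allclose(mpos, wpos):
        raise ValueError("mutant and wildtype profiles are on different point grids")
    if mpos.size == 0:
        raise ValueError("no profile points in segment")

    mmean, wmean = mutant.means, wildtype.means
    params = {"delta": delta, "k": k, "z": z}

    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(wmean > 0, mmean / np.where(wmean > 0, wmean, 1.0), np.nan)

    reduced = mmean < (1.0 - delta) * wmean
    i_red = _first_k_run(reduced, k)
    reduction_start = None
    if i_red is not None:
        if refine_onset:
            reduction_start = _refine_onset(mpos, np.nan_to_num(ratio, nan=0.0), i_red)
        else:
            reduction_start = float(mpos[i_red])

    # Two-threshold (hysteresis) absence detection: a k-run below the
    # confident threshold establishes that the signal has reached
    # background; the absent stretch is then extended backward over points
    # still consistent with background at a weaker bound, so a single
    # noise blip cannot postpone the call by whole points.
    threshold = background.mean + z * background.sd
    extend_threshold = background.mean + 2.0 * z * background.sd
    absent = mmean <= threshold
    i_abs = _first_k_run(absent, k)
    if i_abs is None:
        absence_start = None
    else:
        j = i_abs
        while j > 0 and mmean[j - 1] <= extend_threshold:
            j -= 1
        absence_start = float(mpos[j])

    if reduction_start is not None and absence_start is not None:
        reduction_start = min(reduction_start, absence_start)
    return ExtentCall(reduction_start, absence_start, params)


# ---------------------------------------------------------------------------
# Strand-specific read-count windows
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class StrandWindowRatio:
    window: GenomeInterval
    fwd_count: int
    rev_count: int
    log2_ratio: float | None
    masked: bool


def strand_log_ratio(reads: Iterable[tuple[str, int, str]],
                     region: GenomeInterval,
                     window_size: int = 3200,
                     masks: Sequence[GenomeInterval] = (),
                     alpha: float = 1.0) -> list[StrandWindowRatio]:
    """Non-overlapping window log2(fwd/rev) read-count ratios over a region.

    Windows tile the region left to right (the last may be short).  A
    window overlapping any mask is flagged masked and carries no ratio, as
    does a window with zero reads on both strands.  The pseudocount
    ``alpha`` (default 1) guards against empty single strands; with
    ``alpha = 0`` a window with a zero count on either strand carries no
    ratio.
    """
    if window_size <= 0:
        raise ValueError("window_size must be positive")

    starts = np.arange(region.start, region.end, window_size)
    n_win = starts.size
    fwd = np.zeros(n_win, dtype=int)
    rev = np.zeros(n_win, dtype=int)
    for chrom, pos, strand in reads:
        if chrom != region.chrom or not (region.start <= pos < region.end):
            continue
        idx = (pos - region.start) // window_size
        if strand == STRAND_PLUS:
            fwd[idx] += 1
        elif strand == STRAND_MINUS:
            rev[idx] += 1

    out: list[StrandWindowRatio] = []
    for i, ws in enumerate(starts):
        we = min(int(ws) + window_size, region.end)
        win = GenomeInterval(region.chrom, int(ws), we)
        masked = any(win.overlaps(m) for m in masks)
        ratio: float | None = None
        if not masked and not (fwd[i] == 0 and rev[i] == 0):
            num, den = fwd[i] + alpha, rev[i] + alpha
            if num > 0 and den > 0:
                ratio = float(np.log2(num / den))
        out.append(StrandWindowRatio(win, int(fwd[i]), int(rev[i]), ratio, masked))
    return out


def unmasked_ratios(windows: Iterable[StrandWindowRatio]) -> list[StrandWindowRatio]:
    return [w for w in windows if not w.masked and w.log2_ratio is not None]
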