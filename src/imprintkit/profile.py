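"""CGI/TSS metagene profiling.

For each gene, its transcription start site (TSS) is associated to a CpG
island (CGI) if it falls inside an *extended window*: the CGI body plus a
flank of half the CGI length on either side.  The position within the
window is expressed as an oriented relative coordinate in ``[0, 1)`` (the
window is mirrored for minus-strand genes so "upstream" always means 5' of
the gene), binned into 100 equal parts, and bins are summed over all CGIs
to give a metagene profile of TSS positions relative to CGIs.

Relative-coordinate bands map to relation classes::

    [0.00, 0.25)  upstream_flank
    [0.25, 0.75)  inside (the CGI body)
    [0.75, 1.00)  downstream_flank
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .intervals import (
    STRAND_MINUS,
    STRAND_PLUS,
    AnnotationSet,
    GenomeInterval,
    TranscriptionStartSite,
)

N_BINS = 100

RELATION_INSIDE = "inside"
RELATION_UPSTREAM = "upstream_flank"
RELATION_DOWNSTREAM = "downstream_flank"
RELATION_UNASSOCIATED = "unassociated"


@dataclass(frozen=True)
class ExtendedWindow:
    """A CGI body plus half-length flanks, possibly clipped at position 0.

    ``virtual_start`` is the unclipped 5' edge (may be negative); relative
    coordinates are always computed against the unclipped 2L-long window so
    that the band <-> relation correspondence is exact even when clipped.
    """

    cgi: GenomeInterval
    virtual_start: int
    virtual_end: int
    clipped: bool

    @property
    def window(self) -> GenomeInterval:
        return GenomeInterval(
            self.cgi.chrom, max(0, self.virtual_start), self.virtual_end
        )

    @property
    def length(self) -> int:
        return self.virtual_end - self.virtual_start

    def contains(self, pos: int) -> bool:
        return max(0, self.virtual_start) <= pos < self.virtual_end


def extended_window(cgi: GenomeInterval) -> ExtendedWindow:
    """The CGI plus 50%-of-length flanks on both sides.

    Odd lengths split floor/ceil (upstream flank gets the floor) so the
    unclipped window length is exactly ``2 * len(cgi)``.
    """
    length = len(cgi)
    vstart = cgi.start - length // 2
    vend = cgi.end + (length + 1) // 2
    return ExtendedWindow(cgi, vstart, vend, clipped=vstart < 0)


@dataclass(frozen=True)
class CgiAssociation:
    gene_id: str
    cgi: GenomeInterval | None
    relation: str
    relative_coord: float | None
    bin_index: int | None
    window_clipped: bool = False


def _relative_coord(pos: int, win: ExtendedWindow, strand: str) -> float:
    if strand == STRAND_MINUS:
        return (win.virtual_end - 1 - pos) / win.length
    return (pos - win.virtual_start) / win.length


def _relation_for(rel: float) -> str:
    if rel < 0.25:
        return RELATION_UPSTREAM
    if rel < 0.75:
        return RELATION_INSIDE
    return RELATION_DOWNSTREAM


class CgiIndex:
    """Per-chromosome sorted CGI lookup for window-containment queries.

    An extended window spans at most one CGI length on either side of the
    body, so only CGIs whose start lies within ``2 * max_length`` of the
    query position can contain it; those are found by bisection.
    """

    def __init__(self, cgis: Sequence[GenomeInterval]):
        self._by_chrom: dict[str, tuple[list[GenomeInterval], np.ndarray, int]] = {}
        grouped: dict[str, list[GenomeInterval]] = {}
        for cgi in cgis:
            grouped.setdefault(cgi.chrom, []).append(cgi)
        for chrom, items in grouped.items():
            items.sort(key=lambda iv: iv.start)
            starts = np.array([iv.start for iv in items])
            max_len = max(len(iv) for iv in items)
            self._by_chrom[chrom] = (items, starts, max_len)

    def candidates(self, chrom: str, pos: int) -> list[GenomeInterval]:
        entry = self._by_chrom.get(chrom)
        if entry is None:
            return []
        items, starts, max_len = entry
        lo = int(np.searchsorted(starts, pos - 2 * max_len, side="left"))
        hi = int(np.searchsorted(starts, pos + max_len, side="right"))
        return items[lo:hi]


def associate_tss(
    tss: TranscriptionStartSite,
    cgis: Sequence[GenomeInterval] | AnnotationSet | CgiIndex,
    orient_by_strand: bool = True,
) -> CgiAssociation:
    """Associate one TSS to the nearest containing CGI window.

    When the TSS lies in several extended windows, the CGI whose body
    midpoint is nearest wins; ties break to the lower start coordinate.
    """
    if isinstance(cgis, CgiIndex):
        index = cgis
    elif isinstance(cgis, AnnotationSet):
        index = CgiIndex(cgis.cgis)
    else:
        index = CgiIndex(list(cgis))
    candidates = index.candidates(tss.chrom, tss.pos)

    best: ExtendedWindow | None = None
    best_key: tuple[float, int] | None = None
    for cgi in candidates:
        win = extended_window(cgi)
        if not win.contains(tss.pos):
            continue
        key = (abs(tss.pos - cgi.midpoint), cgi.start)
        if best_key is None or key < best_key:
            best, best_key = win, key

    if best is None:
        return CgiAssociation(tss.gene_id, None, RELATION_UNASSOCIATED, None, None)

    strand = tss.strand if orient_by_strand else STRAND_PLUS
    rel = _relative_coord(tss.pos, best, strand)
    bin_index = min(int(rel * N_BINS), N_BINS - 1)
    return CgiAssociation(
        tss.gene_id,
        best.cgi,
        _relation_for(rel),
        rel,
        bin_index,
        window_clipped=best.clipped,
    )


@dataclass
class MetageneProfile:
    """100-bin TSS count profile over extended CGI windows plus fractions.

    ``fractions['associated']`` is a percentage of all genes; the
    inside/upstream/downstream entries are percentages of associated genes.
    Fractions are ``None`` when their denominator is zero.
    """

    bins: np.ndarray
    n_genes_total: int
    n_associated: int
    fractions: dict[str, float | None]

    def counts_by_relation(self) -> dict[str, int]:
        up = int(self.bins[: N_BINS // 4].sum())
        inside = int(self.bins[N_BINS // 4 : 3 * N_BINS // 4].sum())
        down = int(self.bins[3 * N_BINS // 4 :].sum())
        return {
            RELATION_UPSTREAM: up,
            RELATION_INSIDE: inside,
            RELATION_DOWNSTREAM: down,
        }


def build_profile(
    genes: Iterable[TranscriptionStartSite] | AnnotationSet,
    cgis: Sequence[GenomeInterval] | AnnotationSet | None = None,
    orient_by_strand: bool = True,
) -> tuple[MetageneProfile, list[CgiAssociation]]:
    """Accumulate the metagene profile; also return per-gene audit records.

    If ``genes`` is an AnnotationSet, one designated TSS per gene (the
    5'-most in transcript orientation) is used and, unless ``cgis`` is
    given, the set's own CGIs.
    """
    if isinstance(genes, AnnotationSet):
        if cgis is None:
            cgis = genes
        gene_list = genes.designated_tss()
    else:
        gene_list = list(genes)
        if cgis is None:
            raise ValueError("cgis required when genes is not an AnnotationSet")

    if isinstance(cgis, AnnotationSet):
        index = CgiIndex(cgis.cgis)
    elif isinstance(cgis, CgiIndex):
        index = cgis
    else:
        index = CgiIndex(list(cgis))

    bins = np.zeros(N_BINS, dtype=int)
    records: list[CgiAssociation] = []
    n_assoc = 0
    for tss in gene_list:
        assoc = associate_tss(tss, index, orient_by_strand=orient_by_strand)
        records.append(assoc)
        if assoc.bin_index is not None:
            bins[assoc.bin_index] += 1
            n_assoc += 1

    n_total = len(gene_list)
    fractions: dict[str, float | None]
    if n_total == 0:
        fractions = {k: None for k in ("associated", "inside", "upstream", "downstream")}
    else:
        fractions = {"associated": 100.0 * n_assoc / n_total}
        if n_assoc == 0:
            fractions.update(inside=None, upstream=None, downstream=None)
        else:
            by_rel = {
                RELATION_INSIDE: 0,
                RELATION_UPSTREAM: 0,
                RELATION_DOWNSTREAM: 0,
            }
            for rec in records:
                if rec.relation in by_rel:
                    by_rel[rec.relation] += 1
            fractions["inside"] = 100.0 * by_rel[RELATION_INSIDE] / n_assoc
            fractions["upstream"] = 100.0 * by_rel[RELATION_UPSTREAM] / n_assoc
            fractions["downstream"] = 100.0 * by_rel[RELATION_DOWNSTREAM] / n_assoc

    profile = MetageneProfile(bins, n_total, n_assoc, fractions)
    return profile, records


def write_profile_tsv(profile: MetageneProfile, path) -> None:
    """100 (bin_index, count) rows preceded by a header block of fractions."""
    with open(path, "w") as fh:
        fh.write(f"# n_genes_total\t{profile.n_genes_total}\n")
        fh.write(f"# n_associated\t{profile.n_associated}\n")
        for key in ("associated", "inside", "upstream", "downstream"):
            val = profile.fractions.get(key)
            fh.write(f"# pct_{key}\t{'NA' if val is None else f'{val:.4f}'}\n")
        fh.write("bin_index\tcount\n")
        for i, c in enumerate(profile.bins):
            fh.write(f"{i}\t{int(c)}\n")


def write_audit_tsv(records: Iterable[CgiAssociation], path) -> None:
    with open(path, "w") as fh:
        fh.write("gene_id\trelation\trelative_coord\tbin_index\tcgi\tclipped\n")
        for r in records:
            cgi = (
                f"{r.cgi.chrom}:{r.cgi.start}-{r.cgi.end}" if r.cgi is not None else "NA"
            )
            rel = "NA" if r.relative_coord is None else f"{r.relative_coord:.6f}"
            idx = "NA" if r.bin_index is None else str(r.bin_index)
            fh.write(f"{r.gene_id}\t{r.relation}\t{rel}\t{idx}\t{cgi}\t{int(r.window_clipped)}\n")
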