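"""Genomic coordinate primitives and annotation I/O.

All coordinates are 0-based, half-open ``[start, end)`` — the BED convention.
A printed locus string ``chrN:A-B`` is interpreted so that its length is
``B - A``; both plain hyphens and typographic en-dashes are accepted, and
internal whitespace and thousands separators are ignored.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

STRAND_PLUS = "+"
STRAND_MINUS = "-"
STRAND_NONE = "."

_MINUS_ALIASES = {"-", "−", "–"}  # hyphen, minus sign, en-dash


class ParseError(ValueError):
    """Raised when a text record cannot be parsed; names the offending token."""


def _normalize_strand(strand: str) -> str:
    if strand in (STRAND_PLUS,):
        return STRAND_PLUS
    if strand in _MINUS_ALIASES:
        return STRAND_MINUS
    if strand in (STRAND_NONE, "", None):
        return STRAND_NONE
    raise ValueError(f"invalid strand {strand!r}")


@dataclass(frozen=True, order=True)
class GenomeInterval:
    """Half-open stranded interval ``[start, end)`` on a chromosome."""

    chrom: str
    start: int
    end: int
    strand: str = STRAND_NONE

    def __post_init__(self) -> None:
        object.__setattr__(self, "strand", _normalize_strand(self.strand))
        if self.start < 0:
            raise ValueError(f"start must be >= 0, got {self.start}")
        if self.start >= self.end:
            raise ValueError(
                f"zero- or negative-length interval [{self.start},{self.end})"
            )

    def __len__(self) -> int:
        return self.end - self.start

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def midpoint(self) -> float:
        return (self.start + self.end) / 2.0

    def overlaps(self, other: "GenomeInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )

    def contains(self, pos: int) -> bool:
        return self.start <= pos < self.end


@dataclass(frozen=True)
class TranscriptionStartSite:
    """A single TSS: a stranded 0-based point position."""

    gene_id: str
    chrom: str
    pos: int
    strand: str

    def __post_init__(self) -> None:
        strand = _normalize_strand(self.strand)
        if strand == STRAND_NONE:
            raise ValueError("TSS strand is mandatory")
        object.__setattr__(self, "strand", strand)
        if self.pos < 0:
            raise ValueError(f"pos must be >= 0, got {self.pos}")


_LOCUS_RE = re.compile(r"^(?P<chrom>[^:]+):(?P<rest>.+)$")


def parse_locus(text: str) -> GenomeInterval:
    """Parse ``"chrN:A-B"`` (hyphen or en-dash) into a GenomeInterval.

    The returned interval has length ``B - A``: the printed range is read
    under the end-minus-start convention.
    """
    cleaned = text.strip()
    m = _LOCUS_RE.match(cleaned)
    if m is None:
        raise ParseError(f"malformed locus string: {text!r}")
    chrom = m.group("chrom").strip()
    rest = m.group("rest")
    for dash in _MINUS_ALIASES:
        rest = rest.replace(dash, "-")
    parts = rest.split("-")
    if len(parts) != 2:
        raise ParseError(f"expected one range separator in {rest!r}")
    coords = []
    for token in parts:
        digits = re.sub(r"[\s,]", "", token)
        if not digits.isdigit():
            raise ParseError(f"non-numeric coordinate token {token!r} in {text!r}")
        coords.append(int(digits))
    a, b = coords
    if a >= b:
        raise ValueError(f"locus start {a} must be < end {b} in {text!r}")
    return GenomeInterval(chrom, a, b)


def oriented_offset(pos: int, anchor: GenomeInterval, strand: str, chrom: str | None = None) -> int:
    """Signed offset of ``pos`` from the anchor's oriented 5' edge.

    Positive offsets point downstream in transcript orientation: for ``+``
    the 5' edge is ``anchor.start``; for ``-`` it is the last base
    ``anchor.end - 1`` and the axis is mirrored.
    """
    if chrom is not None and chrom != anchor.chrom:
        raise ValueError(
            f"chromosome mismatch: point on {chrom}, anchor on {anchor.chrom}"
        )
    strand = _normalize_strand(strand)
    if strand == STRAND_PLUS:
        return pos - anchor.start
    if strand == STRAND_MINUS:
        return anchor.end - 1 - pos
    raise ValueError("oriented_offset requires a stranded anchor")


@dataclass
class AnnotationSet:
    """Sorted annotation collections with per-chromosome lookup.

    Lookups on an unknown chromosome return empty results rather than
    raising, so that downstream iteration is total.
    """

    cgis: list[GenomeInterval] = field(default_factory=list)
    genes: list[TranscriptionStartSite] = field(default_factory=list)
    masks: list[GenomeInterval] = field(default_factory=list)
    provenance: str = ""

    def __post_init__(self) -> None:
        self.cgis = sorted(self.cgis, key=lambda iv: (iv.chrom, iv.start))
        self.genes = sorted(self.genes, key=lambda t: (t.chrom, t.pos))
        self.masks = sorted(self.masks, key=lambda iv: (iv.chrom, iv.start))

    def cgis_on(self, chrom: str) -> list[GenomeInterval]:
        return [iv for iv in self.cgis if iv.chrom == chrom]

    def masks_on(self, chrom: str) -> list[GenomeInterval]:
        return [iv for iv in self.masks if iv.chrom == chrom]

    def designated_tss(self) -> list[TranscriptionStartSite]:
        """One TSS per gene: the 5'-most in transcript orientation.

        For a plus-strand gene that is the smallest position; for a
        minus-strand gene the largest.
        """
        by_gene: dict[str, TranscriptionStartSite] = {}
        for tss in self.genes:
            cur = by_gene.get(tss.gene_id)
            if cur is None:
                by_gene[tss.gene_id] = tss
                continue
            if tss.strand == STRAND_PLUS:
                if tss.pos < cur.pos:
                    by_gene[tss.gene_id] = tss
            else:
                if tss.pos > cur.pos:
                    by_gene[tss.gene_id] = tss
        return sorted(by_gene.values(), key=lambda t: (t.chrom, t.pos))


# ---------------------------------------------------------------------------
# BED I/O
# ---------------------------------------------------------------------------

def _parse_bed_line(line: str, lineno: int, n_fields: int) -> list[str]:
    fields = line.rstrip("\n").split("\t")
    if len(fields) < n_fields:
        raise ParseError(
            f"line {lineno}: expected >= {n_fields} tab-separated fields, "
            f"got {len(fields)}"
        )
    return fields


def _parse_coords(fields: Sequence[str], lineno: int) -> tuple[str, int, int]:
    chrom = fields[0]
    try:
        start, end = int(fields[1]), int(fields[2])
    except ValueError as exc:
        raise ParseError(f"line {lineno}: non-integer coordinate: {exc}") from None
    if start < 0 or start >= end:
        raise ParseError(f"line {lineno}: invalid interval [{start},{end})")
    return chrom, start, end


def read_bed3(path: str | Path) -> list[GenomeInterval]:
    """Read a BED3 file (comment lines starting with ``#`` are skipped)."""
    out = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            fields = _parse_bed_line(line, lineno, 3)
            chrom, start, end = _parse_coords(fields, lineno)
            out.append(GenomeInterval(chrom, start, end))
    return out


def read_bed6_tss(path: str | Path) -> list[TranscriptionStartSite]:
    """Read TSS records from BED6; the TSS is the strand-appropriate 5' end.

    For ``+`` features that is ``start``; for ``-`` features ``end - 1``.
    """
    out = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            fields = _parse_bed_line(line, lineno, 6)
            chrom, start, end = _parse_coords(fields, lineno)
            name, strand = fields[3], fields[5]
            try:
                strand = _normalize_strand(strand)
            except ValueError:
                raise ParseError(f"line {lineno}: invalid strand {strand!r}") from None
            if strand == STRAND_NONE:
                raise ParseError(f"line {lineno}: missing strand in BED6 TSS mode")
            pos = start if strand == STRAND_PLUS else end - 1
            out.append(TranscriptionStartSite(name, chrom, pos, strand))
    return out


def read_bed6_reads(path: str | Path) -> list[tuple[str, int, str]]:
    """Read stranded reads from BED6 as (chrom, 5'-position, strand) tuples."""
    reads = []
    for tss in read_bed6_tss(path):
        reads.append((tss.chrom, tss.pos, tss.strand))
    return reads


_HEADER = "# imprintkit BED (0-based half-open){extra}\n"


def write_bed3(intervals: Iterable[GenomeInterval], path: str | Path,
               provenance: str = "") -> None:
    extra = f"; provenance: {provenance}" if provenance else ""
    with open(path, "w") as fh:
        fh.write(_HEADER.format(extra=extra))
        for iv in sorted(intervals, key=lambda iv: (iv.chrom, iv.start)):
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\n")


def write_bed6_tss(tss_records: Iterable[TranscriptionStartSite],
                   path: str | Path, provenance: str = "") -> None:
    """Write TSSs as 1-bp BED6 features whose 5' end is the TSS position."""
    extra = f"; provenance: {provenance}" if provenance else ""
    with open(path, "w") as fh:
        fh.write(_HEADER.format(extra=extra))
        for t in sorted(tss_records, key=lambda t: (t.chrom, t.pos)):
            fh.write(f"{t.chrom}\t{t.pos}\t{t.pos + 1}\t{t.gene_id}\t0\t{t.strand}\n")


def read_annotation_set(cgi_path: str | Path | None = None,
                        tss_path: str | Path | None = None,
                        mask_path: str | Path | None = None,
                        provenance: str = "") -> AnnotationSet:
    return AnnotationSet(
        cgis=read_bed3(cgi_path) if cgi_path else [],
        genes=read_bed6_tss(tss_path) if tss_path else [],
        masks=read_bed3(mask_path) if mask_path else [],
        provenance=provenance,
    )
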