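"""Genome annotation model and GFF3 I/O.

Internally all intervals are 0-based half-open; GFF3 (1-based closed) is
converted at the parser/writer boundary.  Only gene / mRNA / exon / CDS
features are interpreted; other feature types are ignored.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, TextIO

log = logging.getLogger(__name__)

__all__ = [
    "Interval",
    "CdsSegment",
    "Transcript",
    "Gene",
    "GenomeAnnotation",
    "Gff3Error",
    "parse_gff3",
    "write_gff3",
    "select_longest_isoform",
]


class Gff3Error(ValueError):
    """Raised for malformed GFF3 input, naming the offending line."""


@dataclass(frozen=True)
class Interval:
    """0-based half-open genomic interval."""

    start: int
    end: int

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError(f"empty or inverted interval [{self.start}, {self.end})")

    def __len__(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class CdsSegment:
    start: int
    end: int
    phase: int

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError(f"empty or inverted CDS [{self.start}, {self.end})")
        if self.phase not in (0, 1, 2):
            raise ValueError(f"invalid CDS phase {self.phase!r}")


@dataclass
class Transcript:
    transcript_id: str
    gene_id: str
    strand: str
    exons: list[Interval] = field(default_factory=list)
    cds: list[CdsSegment] = field(default_factory=list)

    @property
    def span(self) -> Interval:
        return Interval(min(e.start for e in self.exons), max(e.end for e in self.exons))

    @property
    def span_length(self) -> int:
        """Pre-mRNA span length (first exon start to last exon end)."""
        return len(self.span)

    @property
    def cds_length(self) -> int:
        return sum(s.end - s.start for s in self.cds)

    def validate(self) -> None:
        if not self.exons:
            raise ValueError(f"transcript {self.transcript_id} has no exons")
        if self.strand not in ("+", "-"):
            raise ValueError(f"transcript {self.transcript_id}: strand must be + or -")
        if self.cds:
            first = self.cds[0] if self.strand == "+" else self.cds[-1]
            if (self.cds_length - first.phase) % 3 != 0:
                raise ValueError(
                    f"transcript {self.transcript_id}: CDS length {self.cds_length} "
                    f"(phase {first.phase}) is not a whole number of codons"
                )


@dataclass
class Gene:
    gene_id: str
    chromosome: str
    strand: str
    start: int
    end: int
    transcripts: list[Transcript] = field(default_factory=list)

    @property
    def n_exons(self) -> int:
        """Maximum exon count over isoforms (single-exon genes have 1)."""
        return max((len(t.exons) for t in self.transcripts), default=0)

    @property
    def midpoint(self) -> float:
        return 0.5 * (self.start + self.end)


@dataclass
class GenomeAnnotation:
    genes: dict[str, Gene]
    chromosome_lengths: dict[str, int] = field(default_factory=dict)

    def validate(self) -> None:
        for g in self.genes.values():
            for t in g.transcripts:
                t.validate()
                span = t.span
                if span.start < g.start or span.end > g.end:
                    raise ValueError(
                        f"transcript {t.transcript_id} exceeds gene span of {g.gene_id}"
                    )


def _parse_attributes(col: str) -> dict[str, str]:
    out: dict[str, str] = {}
    for part in col.strip().split(";"):
        part = part.strip()
        if not part:
            continue
        if "=" in part:
            k, v = part.split("=", 1)
            out[k.strip()] = v.strip()
    return out


def parse_gff3(path: str | TextIO) -> GenomeAnnotation:
    """Parse a GFF3 file into a hierarchical :class:`GenomeAnnotation`.

    gene / mRNA / exon / CDS records are linked via ID/Parent attributes;
    unknown feature types are ignored.  ``##sequence-region`` pragmas
    populate chromosome lengths.  Coordinates are converted from 1-based
    closed to internal 0-based half-open.
    """
    close = False
    if isinstance(path, str):
        fh: TextIO = open(path)
        close = True
    else:
        fh = path
    genes: dict[str, Gene] = {}
    transcripts: dict[str, Transcript] = {}
    chrom_lengths: dict[str, int] = {}
    try:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if line.startswith("##sequence-region"):
                parts = line.split()
                if len(parts) >= 4:
                    chrom_lengths[parts[1]] = int(parts[3])
                continue
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) != 9:
                raise Gff3Error(f"line {lineno}: expected 9 tab-delimited columns, got {len(cols)}")
            chrom, _src, ftype, start_s, end_s, _score, strand, phase_s, attr_s = cols
            try:
                start1, end1 = int(start_s), int(end_s)
            except ValueError as exc:
                raise Gff3Error(f"line {lineno}: non-integer coordinates") from exc
            if end1 < start1:
                raise Gff3Error(f"line {lineno}: end {end1} < start {start1}")
            start, end = start1 - 1, end1  # 0-based half-open
            attrs = _parse_attributes(attr_s)
            if ftype == "gene":
                gid = attrs.get("ID")
                if gid is None:
                    raise Gff3Error(f"line {lineno}: gene without ID attribute")
                genes[gid] = Gene(gid, chrom, strand, start, end)
            elif ftype in ("mRNA", "transcript"):
                tid, parent = attrs.get("ID"), attrs.get("Parent")
                if tid is None or parent is None:
                    raise Gff3Error(f"line {lineno}: mRNA needs ID and Parent attributes")
                tr = Transcript(tid, parent, strand)
                transcripts[tid] = tr
                if parent in genes:
                    genes[parent].transcripts.append(tr)
                else:
                    raise Gff3Error(f"line {lineno}: mRNA parent {parent!r} not seen")
            elif ftype == "exon":
                parent = attrs.get("Parent")
                if parent is None or parent not in transcripts:
                    raise Gff3Error(f"line {lineno}: exon parent {attrs.get('Parent')!r} not seen")
                transcripts[parent].exons.append(Interval(start, end))
            elif ftype == "CDS":
                parent = attrs.get("Parent")
                if parent is None or parent not in transcripts:
                    raise Gff3Error(f"line {lineno}: CDS parent {attrs.get('Parent')!r} not seen")
                try:
                    phase = int(phase_s)
                except ValueError as exc:
                    raise Gff3Error(f"line {lineno}: CDS with invalid phase {phase_s!r}") from exc
                transcripts[parent].cds.append(CdsSegment(start, end, phase))
            # other feature types silently ignored
    finally:
        if close:
            fh.close()
    ann = GenomeAnnotation(genes, chrom_lengths)
    for t in transcripts.values():
        t.exons.sort(key=lambda e: e.start)
        t.cds.sort(key=lambda c: c.start)
        t.validate()
    return ann


def write_gff3(ann: GenomeAnnotation, path: str) -> None:
    """Write an annotation back out as GFF3 (1-based closed coordinates)."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for chrom, length in sorted(ann.chromosome_lengths.items()):
            fh.write(f"##sequence-region {chrom} 1 {length}\n")
        for g in sorted(ann.genes.values(), key=lambda g: (g.chromosome, g.start)):
            fh.write(
                f"{g.chromosome}\tdiapop\tgene\t{g.start + 1}\t{g.end}\t.\t{g.strand}\t.\tID={g.gene_id}\n"
            )
            for t in g.transcripts:
                span = t.span
                fh.write(
                    f"{g.chromosome}\tdiapop\tmRNA\t{span.start + 1}\t{span.end}\t.\t"
                    f"{t.strand}\t.\tID={t.transcript_id};Parent={g.gene_id}\n"
                )
                for e in t.exons:
                    fh.write(
                        f"{g.chromosome}\tdiapop\texon\t{e.start + 1}\t{e.end}\t.\t"
                        f"{t.strand}\t.\tParent={t.transcript_id}\n"
                    )
                for c in t.cds:
                    fh.write(
                        f"{g.chromosome}\tdiapop\tCDS\t{c.start + 1}\t{c.end}\t.\t"
                        f"{t.strand}\t{c.phase}\tParent={t.transcript_id}\n"
                    )


def select_longest_isoform(ann: GenomeAnnotation) -> dict[str, Transcript]:
    """Pick, per gene, the transcript with the longest pre-mRNA span.

    Ties go to the first-listed transcript (file order), so the selection is
    deterministic and idempotent.  A gene with no transcripts is an error.
    """
    out: dict[str, Transcript] = {}
    for gid, gene in ann.genes.items():
        if not gene.transcripts:
            raise ValueError(f"gene {gid} has no transcripts")
        best = gene.transcripts[0]
        for t in gene.transcripts[1:]:
            if t.span_length > best.span_length:
                best = t
        out[gid] = best
    return out
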