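"""samtools mpileup (text) and PoPoolation2 sync parsing/writing.

Positions are 1-based in both formats and kept 1-based on the records
(these formats never enter interval arithmetic directly; conversion to the
package's 0-based convention happens where sites are matched to genes).
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Iterator, TextIO

__all__ = [
    "PileupSite",
    "SyncSite",
    "PileupError",
    "SyncError",
    "parse_pileup",
    "parse_sync",
    "write_sync",
]

# sync column order is A:T:C:G:N:del
SYNC_ALLELES = ("A", "T", "C", "G", "N", "del")

_INDEL_RE = re.compile(r"[+-](\d+)")


class PileupError(ValueError):
    pass


class SyncError(ValueError):
    pass


@dataclass
class PileupSite:
    chromosome: str
    position: int  # 1-based
    ref_base: str
    depth: int
    base_counts: dict[str, int]  # keys A,C,G,T,N,del; quality-filtered
    has_indel: bool = False


@dataclass(frozen=True)
class SyncSite:
    chromosome: str
    position: int  # 1-based
    ref_base: str
    counts: tuple[tuple[int, ...], ...]  # one (A,T,C,G,N,del) sextuple per pool


def _decode_bases(bases: str, quals: str, ref: str, min_qual: int) -> tuple[dict[str, int], bool]:
    """Resolve an mpileup base string against its quality string.

    ``^``+mapq and ``$`` markers and ``+n``/``-n`` indel tags are stripped
    (indel tags set the indel flag); ``.``/``,`` resolve to the reference
    base; ``*`` counts toward the del slot.  Each counted symbol consumes
    one quality character; bases below ``min_qual`` are excluded from the
    counts (but still consume their quality character).
    """
    counts = {b: 0 for b in ("A", "C", "G", "T", "N", "del")}
    has_indel = False
    i = 0  # index into bases
    qi = 0  # index into quals
    n = len(bases)
    while i < n:
        c = bases[i]
        if c == "^":
            i += 2  # '^' is followed by the read's mapping quality
            continue
        if c == "$":
            i += 1
            continue
        if c in "+-":
            m = _INDEL_RE.match(bases, i)
            if m is None:
                raise PileupError(f"malformed indel tag at offset {i} in {bases!r}")
            has_indel = True
            i = m.end() + int(m.group(1))
            continue
        if qi >= len(quals):
            raise PileupError("base string longer than quality string")
        qual = ord(quals[qi]) - 33
        qi += 1
        if c in ".,":
            base = ref.upper()
        elif c == "*":
            base = "del"
        elif c in "><":
            base = "N"  # reference skip
        else:
            base = c.upper()
            if base not in "ACGTN":
                raise PileupError(f"unexpected pileup symbol {c!r}")
        if qual >= min_qual:
            counts[base] += 1
        i += 1
    if qi != len(quals):
        raise PileupError("base/quality length mismatch after tag stripping")
    return counts, has_indel


def parse_pileup(path: str | TextIO, min_base_quality: int = 20) -> Iterator[PileupSite]:
    """Stream :class:`PileupSite` records from single-pool mpileup text."""
    close = False
    if isinstance(path, str):
        fh: TextIO = open(path)
        close = True
    else:
        fh = path
    try:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line:
                continue
            cols = line.split("\t")
            if len(cols) < 6:
                raise PileupError(f"line {lineno}: expected >=6 columns, got {len(cols)}")
            chrom, pos_s, ref, depth_s, bases, quals = cols[:6]
            try:
                pos, depth = int(pos_s), int(depth_s)
            except ValueError as exc:
                raise PileupError(f"line {lineno}: non-integer position/depth") from exc
            if pos < 1:
                raise PileupError(f"line {lineno}: position must be >= 1")
            if depth == 0:
                yield PileupSite(chrom, pos, ref.upper(), 0, {b: 0 for b in ("A", "C", "G", "T", "N", "del")})
                continue
            try:
                counts, has_indel = _decode_bases(bases, quals, ref, min_base_quality)
            except PileupError as exc:
                raise PileupError(f"line {lineno}: {exc}") from exc
            yield PileupSite(chrom, pos, ref.upper(), depth, counts, has_indel)
    finally:
        if close:
            fh.close()


def parse_sync(path: str | TextIO) -> Iterator[SyncSite]:
    """Stream :class:`SyncSite` records; counts are A:T:C:G:N:del per pool."""
    close = False
    if isinstance(path, str):
        fh: TextIO = open(path)
        close = True
    else:
        fh = path
    try:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line:
                continue
            cols = line.split()
            if len(cols) < 4:
                raise SyncError(f"line {lineno}: expected chrom, pos, ref and >=1 pool column")
            chrom, pos_s, ref = cols[0], cols[1], cols[2]
            try:
                pos = int(pos_s)
            except ValueError as exc:
                raise SyncError(f"line {lineno}: non-integer position") from exc
            pools = []
            for col in cols[3:]:
                parts = col.split(":")
                if len(parts) != 6:
                    raise SyncError(f"line {lineno}: pool column {col!r} has {len(parts)} fields, expected 6")
                try:
                    sextuple = tuple(int(x) for x in parts)
                except ValueError as exc:
                    raise SyncError(f"line {lineno}: non-integer count in {col!r}") from exc
                if any(x < 0 for x in sextuple):
                    raise SyncError(f"line {lineno}: negative count in {col!r}")
                pools.append(sextuple)
            yield SyncSite(chrom, pos, ref.upper(), tuple(pools))
    finally:
        if close:
            fh.close()


def write_sync(sites, path: str | TextIO) -> None:
    """Write SyncSite records; ``parse_sync(write_sync(x)) == x``."""
    close = False
    if isinstance(path, str):
        fh: TextIO = open(path, "w")
        close = True
    else:
        fh = path
    try:
        for s in sites:
            pools = "\t".join(":".join(str(c) for c in pool) for pool in s.counts)
            fh.write(f"{s.chromosome}\t{s.position}\t{s.ref_base}\t{pools}\n")
    finally:
        if close:
            fh.close()
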