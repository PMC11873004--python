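"""CIGAR parsing, micro-indel smoothing, and query-coordinate geometry.

A chimeric (split) read is represented by several alignment records, each
covering a different stretch of the same sequenced molecule.  To reason about
the split we must place every alignment back onto the read: the CIGAR string
of each record tells us how many query bases are clipped (S soft / H hard)
on either side of the mapped block, and the record's strand tells us whether
those coordinates are expressed on the as-sequenced read or its reverse
complement.  This module converts each record into an
:class:`AlignedSegment` carrying both its reference interval and its query
interval *in as-sequenced read orientation*, and orders the segments of one
read along the query.

Conventions
-----------
* All reference coordinates are SAM-style 1-based inclusive.
* Query coordinates are 1-based inclusive positions on the as-sequenced read.
* Hard clips are treated as query-consuming placeholders when reconstructing
  query coordinates (aligners emit H on supplementary records for the very
  bases that are soft-clipped on the primary record).
* ``=``/``X`` fold into ``M``; ``P`` is dropped; ``N`` (splice gap, from
  non-BWA aligners) is kept as a reference-consuming gap that terminates an
  M run and is never smoothed.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

CigarOp = tuple[str, int]

_CIGAR_TOKEN = re.compile(r"(\d+)([MIDNSHP=X])")

QUERY_OPS = frozenset("MIS")
REF_OPS = frozenset("MDN")
CLIP_OPS = frozenset("SH")


def parse_cigar(cigar: str) -> list[CigarOp]:
    """Parse a CIGAR string into an ordered list of ``(op, length)`` pairs.

    ``=`` and ``X`` are folded into ``M`` (adjacent runs merged); ``P`` is
    discarded.  Raises ``ValueError`` on anything unparsable.
    """
    ops: list[CigarOp] = []
    pos = 0
    for m in _CIGAR_TOKEN.finditer(cigar):
        if m.start() != pos:
            raise ValueError(f"unparsable CIGAR token in {cigar!r} at offset {pos}")
        pos = m.end()
        length = int(m.group(1))
        op = m.group(2)
        if length <= 0:
            raise ValueError(f"zero-length op in CIGAR {cigar!r}")
        if op in "=X":
            op = "M"
        elif op == "P":
            continue
        if ops and ops[-1][0] == op:
            ops[-1] = (op, ops[-1][1] + length)
        else:
            ops.append((op, length))
    if pos != len(cigar) or not ops:
        raise ValueError(f"unparsable CIGAR {cigar!r}")
    return ops


def reference_span(ops: list[CigarOp]) -> int:
    """Reference bases consumed (M + D + N)."""
    return sum(n for op, n in ops if op in REF_OPS)


def query_span(ops: list[CigarOp], include_clips: bool = True) -> int:
    """Query bases consumed; with clips this equals the full read length."""
    total = sum(n for op, n in ops if op in QUERY_OPS)
    if include_clips:
        total += sum(n for op, n in ops if op == "H")
    return total


def smooth_small_indels(ops: list[CigarOp], max_len: int = 1) -> list[CigarOp]:
    """Absorb micro-indels (length <= ``max_len``) into their flanking M runs.

    Sequencing and alignment noise produces spurious 1-base insertions and
    deletions inside what is really one continuous mapped block; these would
    otherwise fragment the block.  An absorbed deletion keeps its base on the
    reference (use :func:`reference_span` on the *original* ops for the
    reference extent); an absorbed insertion adds its bases to the merged M
    query length.  Applied left-to-right, repeated to fixpoint, so chains
    like ``M 1D M 1D M`` collapse fully.  Indels longer than ``max_len`` are
    left intact.
    """
    ops = list(ops)
    changed = True
    while changed:
        changed = False
        for i in range(1, len(ops) - 1):
            op, n = ops[i]
            if op in "ID" and n <= max_len and ops[i - 1][0] == "M" and ops[i + 1][0] == "M":
                merged_q = ops[i - 1][1] + ops[i + 1][1] + (n if op == "I" else 0)
                ops[i - 1 : i + 2] = [("M", merged_q)]
                changed = True
                break
    return ops


def _leading_clip(ops: list[CigarOp]) -> int:
    total = 0
    for op, n in ops:
        if op in CLIP_OPS:
            total += n
        else:
            break
    return total


def _trailing_clip(ops: list[CigarOp]) -> int:
    return _leading_clip(ops[::-1])


def query_interval(ops: list[CigarOp], strand: str, read_length: int) -> tuple[int, int]:
    """Query interval (1-based inclusive, as-sequenced orientation) of the
    mapped block of one alignment record.

    On the plus strand the record's coordinates already refer to the
    as-sequenced read.  On the minus strand the record describes the reverse
    complement, so the interval is reflected: position ``p`` on the record
    corresponds to ``read_length - p + 1`` on the read.
    """
    leading = _leading_clip(ops)
    trailing = _trailing_clip(ops)
    mapped_q = sum(n for op, n in ops if op in "MI")
    if leading + mapped_q + trailing != read_length:
        raise ValueError(
            f"CIGAR consumes {leading + mapped_q + trailing} query bases, "
            f"read length is {read_length}"
        )
    qs, qe = leading + 1, leading + mapped_q
    if strand == "-":
        qs, qe = read_length - qe + 1, read_length - qs + 1
    return qs, qe


@dataclass
class AlignedSegment:
    """One alignment (primary or supplementary) of a read.

    ``query_start``/``query_end`` are in as-sequenced read orientation;
    ``ref_start``/``ref_end`` are 1-based inclusive reference coordinates.
    """

    read_id: str
    chrom: str
    ref_start: int
    ref_end: int
    strand: str
    mapq: int
    query_start: int
    query_end: int
    is_primary: bool = False
    cigar: str = ""
    remapped: bool = False

    @property
    def mapped_len(self) -> int:
        return self.query_end - self.query_start + 1


def segment_from_alignment(
    read_id: str,
    chrom: str,
    pos: int,
    strand: str,
    cigar: str,
    mapq: int,
    read_length: int,
    is_primary: bool = False,
    max_smoothed_indel: int = 1,
) -> AlignedSegment:
    """Build an :class:`AlignedSegment` from raw SAM-style alignment fields."""
    raw_ops = parse_cigar(cigar)
    ops = smooth_small_indels(raw_ops, max_smoothed_indel)
    qs, qe = query_interval(ops, strand, read_length)
    return AlignedSegment(
        read_id=read_id,
        chrom=chrom,
        ref_start=pos,
        ref_end=pos + reference_span(raw_ops) - 1,
        strand=strand,
        mapq=mapq,
        query_start=qs,
        query_end=qe,
        is_primary=is_primary,
        cigar=cigar,
    )


@dataclass
class SplitReadLayout:
    """All segments of one read, ordered along the query."""

    read_id: str
    umi: str
    ls: object  # LigationSite; untyped here to avoid a circular import
    segments: list[AlignedSegment] = field(default_factory=list)
    read_length: int = 0
    is_read1: bool = True
    sequence: str = ""
    qualities: str = ""


def order_segments(
    segments: list[AlignedSegment],
    read_id: str = "",
    umi: str = "",
    ls=None,
    read_length: int = 0,
    is_read1: bool = True,
    sequence: str = "",
    qualities: str = "",
) -> SplitReadLayout:
    """Sort segments by query start (ties by reference coordinate) into a layout."""
    ordered = sorted(segments, key=lambda s: (s.query_start, s.chrom, s.ref_start))
    if not read_id and ordered:
        read_id = ordered[0].read_id
    if not read_length and ordered:
        read_length = max(s.query_end for s in ordered)
    return SplitReadLayout(
        read_id=read_id,
        umi=umi,
        ls=ls,
        segments=ordered,
        read_length=read_length,
        is_read1=is_read1,
        sequence=sequence,
        qualities=qualities,
    )
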