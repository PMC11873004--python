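"""SAM/BAM ingestion, UMI parsing, ligation-site adjustment, and duplicate
consolidation.

Anchored multiplex PCR libraries tag every source molecule with a unique
molecular identifier (UMI, carried in the read name) and ligate a common
adapter at a random fragment end — the ligation site (LS).  Two reads with
the same UMI *and* the same (soft-clip-adjusted) LS are PCR/optical copies
of one molecule and are collapsed to a single representative before fusion
calling; the number of distinct LS values per junction ("partner ends") is
the key evidence count downstream.

Only the first 10 standard SAM fields plus the SA (supplementary) and XA
(alternative) tags are required, so any aligner that emits split reads in
this form can feed the pipeline (kickstart contract).
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field

import pysam

from .split_transform import (
    AlignedSegment,
    _leading_clip,
    _trailing_clip,
    parse_cigar,
    query_span,
    reference_span,
    segment_from_alignment,
)

log = logging.getLogger(__name__)

DEFAULT_UMI_REGEX = r"(?:_|:)UMI[:_]?([ACGTN]+)$"


@dataclass(frozen=True)
class LigationSite:
    """Soft-clip-adjusted genomic coordinate of the ligated fragment end."""

    chrom: str
    pos: int
    strand: str


@dataclass
class RawRecord:
    """One read's primary alignment with its SA/XA expansions still packed."""

    read_id: str
    umi: str
    flag_strand: str
    chrom: str
    pos: int
    mapq: int
    cigar: str
    sa_entries: list[tuple] = field(default_factory=list)  # (chrom,pos,strand,cigar,mapq)
    xa_entries: list[tuple] = field(default_factory=list)  # (chrom,pos,strand,cigar)
    read_length: int = 0
    is_read1: bool = True
    sequence: str = ""
    qualities: str = ""
    ls: LigationSite | None = None
    # XA tags seen on any of this read's rows, keyed by that row's
    # (chrom, pos) so a MAPQ-0 supplementary segment can be matched with
    # its own alternative placements during repeat rescue
    xa_by_locus: dict = field(default_factory=dict)


def parse_read_meta(read_name: str, umi_regex: str = DEFAULT_UMI_REGEX) -> tuple[str, str]:
    """Split a read name into (base read id, UMI).

    The default dialect expects the UMI as a ``_UMI:XXXX`` / ``:UMI:XXXX``
    suffix.  Names without a parsable UMI return ``umi=""`` and are treated
    as each unique (no duplicate collapse), which is the correct behaviour
    for plain RNA-seq read names.
    """
    if not read_name:
        raise ValueError("empty read name")
    m = re.search(umi_regex, read_name)
    if m is None:
        return read_name, ""
    return read_name[: m.start()], m.group(1)


def compute_ligation_site(rec: RawRecord) -> LigationSite:
    """Soft-clip-adjusted LS of the ligation-end alignment.

    The few bases at the ligated fragment end are often too short or too
    noisy to map and end up soft-clipped; projecting them back through the
    clip recovers the true fragment-end coordinate, so that reads from the
    same molecule agree on their LS regardless of how much of the end
    mapped.  Plus strand: alignment start minus the leading clip.  Minus
    strand: alignment end plus the trailing clip (the read start lies at
    the reference-rightmost side of a reverse alignment).
    """
    ops = parse_cigar(rec.cigar)
    if rec.flag_strand == "+":
        pos = rec.pos - _leading_clip(ops)
    else:
        ref_end = rec.pos + reference_span(ops) - 1
        pos = ref_end + _trailing_clip(ops)
    return LigationSite(chrom=rec.chrom, pos=max(1, pos), strand=rec.flag_strand)


def parse_sa_tag(sa: str) -> list[tuple]:
    """Parse an ``SA:Z`` tag into (chrom, pos, strand, cigar, mapq) tuples.

    Entries with a field count other than 6 invalidate the whole tag
    (callers skip the record with a warning).
    """
    entries = []
    for chunk in sa.rstrip(";").split(";"):
        if not chunk:
            continue
        fields = chunk.split(",")
        if len(fields) != 6:
            raise ValueError(f"SA entry has {len(fields)} fields, expected 6: {chunk!r}")
        chrom, pos, strand, cigar, mapq, _nm = fields
        entries.append((chrom, int(pos), strand, cigar, int(mapq)))
    return entries


def parse_xa_tag(xa: str) -> list[tuple]:
    """Parse an ``XA:Z`` tag into (chrom, pos, strand, cigar) tuples.

    XA encodes strand as a sign prefix on the position.
    """
    entries = []
    for chunk in xa.rstrip(";").split(";"):
        if not chunk:
            continue
        fields = chunk.split(",")
        if len(fields) != 4:
            continue
        chrom, signed_pos, cigar, _nm = fields
        strand = "-" if signed_pos.startswith("-") else "+"
        entries.append((chrom, int(signed_pos.lstrip("+-")), strand, cigar))
    return entries


def read_sam(
    path: str,
    umi_regex: str = DEFAULT_UMI_REGEX,
    ligation_end: str = "read1_start",
) -> list[RawRecord]:
    """Load primary alignments (with their SA/XA tags) from a SAM/BAM file.

    Secondary and supplementary rows are skipped: the SA tag on the primary
    row is the authoritative description of the split.  For paired data the
    ligation-end mate (read 1 by default) defines the record; the other
    mate's rows are ignored for junction calling.
    """
    want_read1 = ligation_end == "read1_start"
    records: list[RawRecord] = []
    supp_xa: dict[str, dict] = {}
    with pysam.AlignmentFile(path, check_sq=False) as fh:
        for aln in fh:
            if aln.is_unmapped or aln.is_secondary:
                continue
            if aln.is_supplementary:
                if aln.has_tag("XA"):
                    read_id, _ = parse_read_meta(aln.query_name, umi_regex)
                    supp_xa.setdefault(read_id, {})[
                        (aln.reference_name, aln.reference_start + 1)
                    ] = parse_xa_tag(aln.get_tag("XA"))
                continue
            if aln.is_paired and (aln.is_read1 != want_read1):
                continue
            read_id, umi = parse_read_meta(aln.query_name, umi_regex)
            try:
                sa = parse_sa_tag(aln.get_tag("SA")) if aln.has_tag("SA") else []
            except ValueError as exc:
                log.warning("skipping %s: %s", aln.query_name, exc)
                continue
            xa = parse_xa_tag(aln.get_tag("XA")) if aln.has_tag("XA") else []
            cigar = aln.cigarstring
            rec = RawRecord(
                read_id=read_id,
                umi=umi,
                flag_strand="-" if aln.is_reverse else "+",
                chrom=aln.reference_name,
                pos=aln.reference_start + 1,
                mapq=aln.mapping_quality,
                cigar=cigar,
                sa_entries=sa,
                xa_entries=xa,
                read_length=query_span(parse_cigar(cigar)),
                is_read1=(not aln.is_paired) or aln.is_read1,
                sequence=aln.query_sequence or "",
                qualities=aln.qual or "",
            )
            rec.ls = compute_ligation_site(rec)
            if rec.xa_entries:
                rec.xa_by_locus[(rec.chrom, rec.pos)] = rec.xa_entries
            records.append(rec)
    for rec in records:
        rec.xa_by_locus.update(supp_xa.get(rec.read_id, {}))
    return records


def _dedup_key(rec: RawRecord, mode: str):
    ls = rec.ls if rec.ls is not None else compute_ligation_site(rec)
    ls_key = (ls.chrom, ls.pos, ls.strand)
    if mode == "ls":
        return ls_key
    if rec.umi == "":
        # UMI-less reads are each unique under umi_ls: collapsing by
        # position alone would destroy depth in amplicon-free data.
        return ("__noumi__", rec.read_id)
    return (rec.umi, ls_key)


def dedup_by_umi_ls(records: list[RawRecord], mode: str = "umi_ls") -> list[RawRecord]:
    """Collapse duplicate reads to one representative per UMI-LS key.

    The representative is the read with the highest primary mapping quality
    (ties broken by lexicographically smallest read id) so the best-mapped
    evidence survives.  ``mode``: ``umi_ls`` (default), ``ls`` (position
    only), or ``off``.  Idempotent by construction.
    """
    if mode == "off":
        return list(records)
    best: dict = {}
    for rec in records:
        key = _dedup_key(rec, mode)
        prev = best.get(key)
        if prev is None or (-rec.mapq, rec.read_id) < (-prev.mapq, prev.read_id):
            best[key] = rec
    return sorted(best.values(), key=lambda r: r.read_id)


def expand_alignments(rec: RawRecord, max_smoothed_indel: int = 1) -> list[AlignedSegment]:
    """Expand a primary record and its SA entries into aligned segments.

    Reads with no supplementary alignment have no split and return an empty
    list — they carry no fusion evidence.
    """
    if not rec.sa_entries:
        return []
    segments = [
        segment_from_alignment(
            rec.read_id,
            rec.chrom,
            rec.pos,
            rec.flag_strand,
            rec.cigar,
            rec.mapq,
            rec.read_length,
            is_primary=True,
            max_smoothed_indel=max_smoothed_indel,
        )
    ]
    for chrom, pos, strand, cigar, mapq in rec.sa_entries:
        segments.append(
            segment_from_alignment(
                rec.read_id,
                chrom,
                pos,
                strand,
                cigar,
                mapq,
                rec.read_length,
                is_primary=False,
                max_smoothed_indel=max_smoothed_indel,
            )
        )
    return segments
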