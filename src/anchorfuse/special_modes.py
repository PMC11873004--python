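"""Pseudogene/repeat rescue, targeted-event reporting, and blacklisting.

Repeat rescue: aligners give multi-mapping reads a mapping quality of 0 and
record the alternative placements in the XA tag.  For clinically relevant
repeat families (e.g. the DUX4 repeat array) the user supplies a BED file of
regions of interest; a MAPQ-0 alignment whose primary or alternative
placement falls inside such a region is re-anchored to that region, so
fusions into the repeat are not lost to mapping ambiguity.

Target mode: intragenic events (exon skipping, exon deletion, cryptic-exon
splicing such as AR-V7) live *below* the intron-distance rule and would
never surface as fusion candidates; a whitelist of named junction patterns
re-enables them, and a panel BED restricts reporting to junctions touching
the genes of interest.  A blacklist of recurring artifact junctions is
applied last.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import pandas as pd

from .annotator import AnnotatedCall, GeneModelIndex, annotate_group
from .junction_core import (
    JunctionCandidate,
    _make_candidate,
    group_precalls,
    is_partner_pair,
)
from .split_transform import AlignedSegment, SplitReadLayout, segment_from_alignment

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class RepeatRegion:
    chrom: str
    start: int  # 1-based inclusive
    end: int
    label: str = ""

    def contains(self, chrom: str, pos: int) -> bool:
        return chrom == self.chrom and self.start <= pos <= self.end

    def overlaps(self, chrom: str, start: int, end: int) -> bool:
        return chrom == self.chrom and start <= self.end and end >= self.start


def load_bed(path: str) -> list[RepeatRegion]:
    """Load a BED file into 1-based inclusive regions."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    regions = []
    for row in df.itertuples(index=False):
        label = str(row[3]) if len(row) > 3 else ""
        regions.append(RepeatRegion(str(row[0]), int(row[1]) + 1, int(row[2]), label))
    return regions


def pseudogene_remap(
    seg: AlignedSegment,
    xa_entries: list[tuple],
    regions: list[RepeatRegion],
    read_length: int,
    max_smoothed_indel: int = 1,
) -> AlignedSegment:
    """Re-anchor a MAPQ-0 segment into a designated repeat region.

    Priority: the primary placement if it already overlaps a region, else
    the first XA entry (file order) that overlaps.  Segments with MAPQ > 0
    are never touched.
    """
    if seg.mapq != 0 or not regions:
        return seg
    if any(r.overlaps(seg.chrom, seg.ref_start, seg.ref_end) for r in regions):
        seg.remapped = True
        return seg
    for chrom, pos, strand, cigar, *_ in xa_entries:
        if any(r.contains(chrom, pos) for r in regions):
            new = segment_from_alignment(
                seg.read_id, chrom, pos, strand, cigar, 0, read_length,
                is_primary=seg.is_primary, max_smoothed_indel=max_smoothed_indel,
            )
            new.remapped = True
            return new
    return seg


# ---------------------------------------------------------------------------
# Target mode


@dataclass
class TargetEvent:
    """A whitelisted intragenic event.

    ``kind`` is ``exon_pair`` (junction from the donor of exon ``exon5`` to
    the acceptor of exon ``exon3`` of ``gene``; exact boundary match) or
    ``coords`` (explicit junction coordinates matched within
    ``+-target_window`` bases, for cryptic exons absent from models).
    """

    name: str
    gene: str
    kind: str
    exon5: int = 0
    exon3: int = 0
    chrom5: str = ""
    pos5: int = 0
    chrom3: str = ""
    pos3: int = 0
    min_partner_ends: int = 3


def parse_target_pattern(name: str, gene: str, pattern: str, min_pe: int = 3) -> TargetEvent:
    """Parse a pattern string: ``exon:<n5>-<n3>`` or
    ``coord:<chrom>:<pos5>|<chrom>:<pos3>``."""
    if pattern.startswith("exon:"):
        n5, n3 = pattern[5:].split("-")
        return TargetEvent(name, gene, "exon_pair", exon5=int(n5), exon3=int(n3),
                           min_partner_ends=min_pe)
    if pattern.startswith("coord:"):
        left, right = pattern[6:].split("|")
        c5, p5 = left.rsplit(":", 1)
        c3, p3 = right.rsplit(":", 1)
        return TargetEvent(name, gene, "coords", chrom5=c5, pos5=int(p5),
                           chrom3=c3, pos3=int(p3), min_partner_ends=min_pe)
    raise ValueError(f"unparsable target pattern {pattern!r} for event {name}")


def load_targets(path: str, index: GeneModelIndex | None = None) -> list[TargetEvent]:
    """Load a targets TSV: columns name, gene, pattern[, min_partner_ends]."""
    df = pd.read_csv(path, sep="\t", comment="#")
    events = []
    for row in df.itertuples(index=False):
        min_pe = int(getattr(row, "min_partner_ends", 3)) if hasattr(row, "min_partner_ends") else 3
        ev = parse_target_pattern(str(row.name), str(row.gene), str(row.pattern), min_pe)
        if index is not None and ev.kind == "exon_pair" and ev.gene not in index.by_gene:
            raise ValueError(f"target event {ev.name} references unknown gene {ev.gene}")
        events.append(ev)
    return events


def _event_matches(
    ev: TargetEvent, cand: JunctionCandidate, index: GeneModelIndex, window: int
) -> bool:
    if ev.kind == "coords":
        return (
            cand.bp_left.chrom == ev.chrom5
            and abs(cand.bp_left.pos - ev.pos5) <= window
            and cand.bp_right.chrom == ev.chrom3
            and abs(cand.bp_right.pos - ev.pos3) <= window
        )
    for t in index.by_gene.get(ev.gene, []):
        if t.chrom != cand.bp_left.chrom or t.chrom != cand.bp_right.chrom:
            continue
        if ev.exon5 > t.n_exons or ev.exon3 > t.n_exons:
            continue
        if (
            cand.bp_left.pos == t.donor_of_exon(ev.exon5)
            and cand.bp_right.pos == t.acceptor_of_exon(ev.exon3)
        ):
            return True
    return False


def detect_target_events(
    layouts: list[SplitReadLayout],
    events: list[TargetEvent],
    index: GeneModelIndex,
    cfg,
) -> list[AnnotatedCall]:
    """Scan splits that fail the fusion distance rule for whitelisted events.

    Neighboring same-chromosome, same-strand, sub-threshold splits (normal
    splice geometry) are matched against the event patterns; matching
    junctions are aggregated like fusions and called at the event's own
    partner-end threshold, labelled with the event name.
    """
    per_event: dict[str, list[JunctionCandidate]] = {ev.name: [] for ev in events}
    for layout in layouts:
        segs = layout.segments
        for i in range(len(segs) - 1):
            if is_partner_pair(segs[i], segs[i + 1], cfg.max_intron_distance,
                               cfg.allow_inversion):
                continue  # already handled by the default fusion path
            cand = _make_candidate(layout, segs[i], segs[i + 1], [])
            for ev in events:
                if _event_matches(ev, cand, index, cfg.target_window):
                    per_event[ev.name].append(cand)
    calls = []
    for ev in events:
        for key, group in sorted(group_precalls(per_event[ev.name]).items()):
            call = annotate_group(group, index, cfg)
            if call.n_partner_ends >= ev.min_partner_ends:
                call.event_name = ev.name
                call.mode_flags.append("targeted")
                calls.append(call)
    return calls


def panel_restrict(
    calls: list[AnnotatedCall], panel: list[RepeatRegion]
) -> list[AnnotatedCall]:
    """Keep only calls with at least one breakpoint inside the panel."""
    if not panel:
        return calls
    kept = []
    for c in calls:
        if any(
            r.contains(c.bp5.chrom, c.bp5.pos) or r.contains(c.bp3.chrom, c.bp3.pos)
            for r in panel
        ):
            kept.append(c)
    return kept


# ---------------------------------------------------------------------------
# Blacklist


@dataclass(frozen=True)
class BlacklistEntry:
    gene_a: str
    gene_b: str
    chrom_a: str = ""
    pos_a: int = 0
    chrom_b: str = ""
    pos_b: int = 0

    @property
    def has_coords(self) -> bool:
        return bool(self.chrom_a)


def load_blacklist(path: str) -> list[BlacklistEntry]:
    """Load a blacklist TSV: geneA, geneB[, chromA, posA, chromB, posB]."""
    df = pd.read_csv(path, sep="\t", comment="#")
    entries = []
    for row in df.itertuples(index=False):
        vals = list(row)
        if len(vals) >= 6 and pd.notna(vals[2]):
            entries.append(
                BlacklistEntry(str(vals[0]), str(vals[1]), str(vals[2]),
                               int(vals[3]), str(vals[4]), int(vals[5]))
            )
        else:
            entries.append(BlacklistEntry(str(vals[0]), str(vals[1])))
    return entries


def apply_blacklist(
    calls: list[AnnotatedCall], blacklist: list[BlacklistEntry]
) -> list[AnnotatedCall]:
    """Drop calls matching a blacklist entry (gene pair, or exact junction
    when coordinates are given)."""
    if not blacklist:
        return calls
    kept = []
    for c in calls:
        hit = False
        for e in blacklist:
            if (e.gene_a, e.gene_b) != (c.ann5.gene, c.ann3.gene):
                continue
            if e.has_coords:
                if (e.chrom_a, e.pos_a, e.chrom_b, e.pos_b) == (
                    c.bp5.chrom, c.bp5.pos, c.bp3.chrom, c.bp3.pos
                ):
                    hit = True
                    break
            else:
                hit = True
                break
        if hit:
            log.info("blacklist suppressed %s %s", c.fusion_name, c.junction)
            c.mode_flags.append("blacklist-suppressed")
        else:
            kept.append(c)
    return kept
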