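"""Candidate fusion junction detection and initial filtering.

Two neighboring alignments of one read are candidate fusion partners when
they cannot be explained by normal splicing: different chromosomes, the
same chromosome at a distance greater than the largest plausible intron
(750 kb by default), or opposite strands (an inversion cannot be a splice).
The breakpoint pair is read off the junction-adjacent segment termini,
strand-aware.  Split alignments frequently share a few identical bases at
the junction (micro-homology from seed extension at canonical splice
sequences); those shared bases are attributed to the 5' side and the 3'
breakpoint advanced past them, so every read supporting the same fusion
reports the same exact junction.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

from .split_transform import AlignedSegment, SplitReadLayout


@dataclass(frozen=True)
class Breakpoint:
    chrom: str
    pos: int
    side: str  # "5prime_end" | "3prime_start"
    strand: str


@dataclass
class JunctionCandidate:
    """A putative fusion breakpoint pair supported by one read."""

    read_id: str
    umi: str
    ls: object
    left: AlignedSegment
    right: AlignedSegment
    bp_left: Breakpoint
    bp_right: Breakpoint
    overlap_len: int = 0
    gap_len: int = 0
    mid_segments: list[AlignedSegment] = field(default_factory=list)
    ligation_end_len: int = 0
    anchored_end_len: int = 0
    roles_mode: str = "anchored"
    targeted: bool = False


def compute_overlap_gap(left: AlignedSegment, right: AlignedSegment) -> tuple[int, int]:
    """Query-coordinate overlap and gap between two ordered segments.

    Mutually exclusive by construction: a positive overlap forces gap 0 and
    vice versa.
    """
    overlap = max(0, left.query_end - right.query_start + 1)
    gap = max(0, right.query_start - left.query_end - 1)
    return overlap, gap


def _bp_left_of(seg: AlignedSegment) -> Breakpoint:
    """Reference coordinate of a segment's query-3' terminus."""
    pos = seg.ref_end if seg.strand == "+" else seg.ref_start
    return Breakpoint(seg.chrom, pos, "5prime_end", seg.strand)


def _bp_right_of(seg: AlignedSegment) -> Breakpoint:
    """Reference coordinate of a segment's query-5' terminus."""
    pos = seg.ref_start if seg.strand == "+" else seg.ref_end
    return Breakpoint(seg.chrom, pos, "3prime_start", seg.strand)


def advance_breakpoint(bp: Breakpoint, bases: int) -> Breakpoint:
    """Move a breakpoint ``bases`` further along the read direction."""
    if bases == 0:
        return bp
    delta = bases if bp.strand == "+" else -bases
    return replace(bp, pos=bp.pos + delta)


def is_partner_pair(
    left: AlignedSegment,
    right: AlignedSegment,
    max_intron_distance: int = 750_000,
    allow_inversion: bool = True,
) -> bool:
    """Can this pair of alignments NOT be normal splicing?"""
    if left.chrom != right.chrom:
        return True
    if allow_inversion and left.strand != right.strand:
        return True
    return abs(right.ref_start - left.ref_end) > max_intron_distance


def _make_candidate(
    layout: SplitReadLayout,
    jleft: AlignedSegment,
    jright: AlignedSegment,
    mids: list[AlignedSegment],
) -> JunctionCandidate:
    overlap, gap = compute_overlap_gap(jleft, jright)
    bp_l = _bp_left_of(jleft)
    # micro-homology bases belong to the 5' side; push the 3' breakpoint
    # past them so all reads of one fusion agree on the junction
    bp_r = advance_breakpoint(_bp_right_of(jright), overlap)
    return JunctionCandidate(
        read_id=layout.read_id,
        umi=layout.umi,
        ls=layout.ls,
        left=jleft,
        right=jright,
        bp_left=bp_l,
        bp_right=bp_r,
        overlap_len=overlap,
        gap_len=gap,
        mid_segments=mids,
    )


def detect_candidates(
    layout: SplitReadLayout,
    max_intron_distance: int = 750_000,
    allow_inversion: bool = True,
) -> list[JunctionCandidate]:
    """Emit junction candidates from one ordered split-read layout.

    One candidate per qualifying neighboring split; interior segments of
    multi-part layouts (e.g. the partner gene's neighboring exon between
    the outer alignments) go to ``mid_segments`` for separate annotation.
    If no neighboring pair qualifies but the outermost pair does (two
    sub-threshold steps adding up), the outermost pair forms the candidate.
    """
    segs = layout.segments
    if len(segs) < 2:
        return []
    interior = segs[1:-1]
    cands: list[JunctionCandidate] = []
    for i in range(len(segs) - 1):
        if is_partner_pair(segs[i], segs[i + 1], max_intron_distance, allow_inversion):
            mids = [s for s in interior if s is not segs[i] and s is not segs[i + 1]]
            cands.append(_make_candidate(layout, segs[i], segs[i + 1], mids))
    if not cands and len(segs) >= 3 and is_partner_pair(
        segs[0], segs[-1], max_intron_distance, allow_inversion
    ):
        cands.append(_make_candidate(layout, segs[0], segs[-1], list(interior)))
    return cands


def assign_end_roles(
    cand: JunctionCandidate, layout: SplitReadLayout, mode: str = "anchored"
) -> JunctionCandidate:
    """Attach ligation-end / anchored-end mapped lengths to a candidate.

    In anchored libraries read 1 starts at the ligated (partner-gene) end
    and finishes toward the gene-specific primer, so the segment containing
    query base 1 is the ligation end and the segment containing the final
    base is the anchored end; the two carry different minimum-length
    cutoffs.  Plain RNA-seq has no such asymmetry ("symmetric" roles).
    """
    first = layout.segments[0]
    last = layout.segments[-1]
    if mode == "anchored" and not layout.is_read1:
        first, last = last, first  # read 2 runs the other way along the fragment
    cand.ligation_end_len = first.mapped_len
    cand.anchored_end_len = last.mapped_len
    cand.roles_mode = mode if mode == "anchored" else "plain"
    return cand


def initial_filter(cands: list[JunctionCandidate], cfg) -> list[JunctionCandidate]:
    """Apply overlap/gap and end-length filters to per-read candidates.

    ``cfg`` needs: max_overlap, max_gap, min_map_len_ligation,
    min_map_len_anchored, min_map_len_plain, min_exclusive_len.
    """
    kept = []
    for c in cands:
        if c.overlap_len > cfg.max_overlap or c.gap_len > cfg.max_gap:
            continue
        if c.roles_mode == "anchored":
            if c.ligation_end_len < cfg.min_map_len_ligation:
                continue
            if c.anchored_end_len < cfg.min_map_len_anchored:
                continue
        else:
            if min(c.ligation_end_len, c.anchored_end_len) < cfg.min_map_len_plain:
                continue
        excl_left = c.left.mapped_len - c.overlap_len
        excl_right = c.right.mapped_len - c.overlap_len
        if min(excl_left, excl_right) < cfg.min_exclusive_len:
            continue
        kept.append(c)
    return kept


def junction_key(cand: JunctionCandidate) -> tuple:
    bl, br = cand.bp_left, cand.bp_right
    return (bl.chrom, bl.pos, bl.strand, br.chrom, br.pos, br.strand)


def group_precalls(cands: list[JunctionCandidate]) -> dict[tuple, list[JunctionCandidate]]:
    """Group surviving per-read candidates by exact breakpoint pair.

    Exact-junction grouping (no fuzz window) is deliberate: subclone
    analysis distinguishes fusions by their exact junction.
    """
    groups: dict[tuple, list[JunctionCandidate]] = {}
    for c in cands:
        groups.setdefault(junction_key(c), []).append(c)
    return groups
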