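"""Gene-model loading, breakpoint annotation, exon-boundary and frame calls.

The annotation layer turns an exact genomic breakpoint pair into a
clinically interpretable call: which genes are fused, at which exon and
cDNA position, whether each junction coincides with an annotated exon
terminus (fusions generated by genomic rearrangement plus normal splicing
land exactly on exon boundaries), and whether the fused coding sequences
stay in one reading frame.

Exon-boundary status drives the evidence threshold: a fusion with both
junctions on exon boundaries is called from a single partner end (distinct
ligation site), while a single-boundary fusion requires three — boundary
concordance is itself strong evidence, so demanding deep read support
would only cost sensitivity.

Frame status is pure phase arithmetic: with ``c5`` coding bases of the 5'
transcript retained (CDS start through the last retained base) and ``c3``
coding bases of the 3' transcript removed (CDS start up to, excluding, the
first retained base), the fusion is in frame iff ``c5 == c3 (mod 3)``.
It is defined only when both junction-adjacent bases lie inside their
transcripts' CDS; 5'UTR, intronic, and non-coding partners yield NA.
"""

from __future__ import annotations

import bisect
import logging
from dataclasses import dataclass, field

from intervaltree import IntervalTree

from .junction_core import Breakpoint, JunctionCandidate

log = logging.getLogger(__name__)


@dataclass
class TranscriptModel:
    """One transcript: strand, ordered exons, and CDS bounds.

    ``exons`` are genomic-ascending 1-based inclusive intervals;
    ``cds_start <= cds_end`` are genomic bounds (stop codon included) or
    ``None`` for non-coding transcripts.
    """

    transcript_id: str
    gene_name: str
    chrom: str
    strand: str
    exons: list[tuple[int, int]]
    cds_start: int | None = None
    cds_end: int | None = None

    def __post_init__(self):
        self.exons = sorted(self.exons)
        for (s1, e1), (s2, e2) in zip(self.exons, self.exons[1:]):
            if s2 <= e1:
                raise ValueError(f"overlapping exons in {self.transcript_id}")

    # -- basic geometry -------------------------------------------------
    @property
    def tx_start(self) -> int:
        return self.exons[0][0]

    @property
    def tx_end(self) -> int:
        return self.exons[-1][1]

    @property
    def n_exons(self) -> int:
        return len(self.exons)

    @property
    def cds_len(self) -> int:
        if self.cds_start is None:
            return 0
        return sum(
            max(0, min(e, self.cds_end) - max(s, self.cds_start) + 1) for s, e in self.exons
        )

    @property
    def total_exon_len(self) -> int:
        return sum(e - s + 1 for s, e in self.exons)

    def exon_number(self, genomic_pos: int) -> int | None:
        """1-based exon ordinal in transcript orientation, or None if intronic."""
        for i, (s, e) in enumerate(self.exons):
            if s <= genomic_pos <= e:
                return i + 1 if self.strand == "+" else self.n_exons - i
        return None

    def intron_number(self, genomic_pos: int) -> int | None:
        """Ordinal of the intron containing the position (intron N follows exon N)."""
        for i in range(self.n_exons - 1):
            if self.exons[i][1] < genomic_pos < self.exons[i + 1][0]:
                return i + 1 if self.strand == "+" else self.n_exons - 1 - i
        return None

    def cdna_pos(self, genomic_pos: int) -> int | None:
        """Spliced 1-based position from the transcript 5' end, or None if intronic."""
        offset = 0
        if self.strand == "+":
            for s, e in self.exons:
                if s <= genomic_pos <= e:
                    return offset + genomic_pos - s + 1
                offset += e - s + 1
        else:
            for s, e in reversed(self.exons):
                if s <= genomic_pos <= e:
                    return offset + e - genomic_pos + 1
                offset += e - s + 1
        return None

    def genomic_pos(self, cdna_pos: int) -> int:
        """Genomic coordinate of a spliced transcript position (inverse of
        :meth:`cdna_pos`)."""
        if cdna_pos < 1 or cdna_pos > self.total_exon_len:
            raise ValueError(f"cDNA position {cdna_pos} outside transcript")
        offset = 0
        exon_iter = self.exons if self.strand == "+" else list(reversed(self.exons))
        for s, e in exon_iter:
            length = e - s + 1
            if cdna_pos <= offset + length:
                within = cdna_pos - offset
                return s + within - 1 if self.strand == "+" else e - within + 1
            offset += length
        raise AssertionError("unreachable")

    def cdna_cds_start(self) -> int | None:
        if self.cds_start is None:
            return None
        g = self.cds_start if self.strand == "+" else self.cds_end
        return self.cdna_pos(g)

    def cdna_cds_end(self) -> int | None:
        if self.cds_start is None:
            return None
        g = self.cds_end if self.strand == "+" else self.cds_start
        return self.cdna_pos(g)

    def donor_positions(self) -> set[int]:
        """Genomic coordinates of exon 3' termini in transcript orientation."""
        if self.strand == "+":
            return {e for _, e in self.exons}
        return {s for s, _ in self.exons}

    def acceptor_positions(self) -> set[int]:
        """Genomic coordinates of exon 5' termini in transcript orientation."""
        if self.strand == "+":
            return {s for s, _ in self.exons}
        return {e for _, e in self.exons}

    def exon_bounds(self, exon_no: int) -> tuple[int, int]:
        """Genomic interval of exon ``exon_no`` (transcript-ordinal, 1-based)."""
        idx = exon_no - 1 if self.strand == "+" else self.n_exons - exon_no
        return self.exons[idx]

    def donor_of_exon(self, exon_no: int) -> int:
        s, e = self.exon_bounds(exon_no)
        return e if self.strand == "+" else s

    def acceptor_of_exon(self, exon_no: int) -> int:
        s, e = self.exon_bounds(exon_no)
        return s if self.strand == "+" else e


class GeneModelIndex:
    """All transcripts with a per-gene canonical choice and interval lookup.

    Canonical transcript per gene: longest CDS, ties broken by longest
    total exon length, then smallest transcript id.
    """

    def __init__(self, transcripts: list[TranscriptModel]):
        if not transcripts:
            raise ValueError("no transcripts loaded")
        self.transcripts = {t.transcript_id: t for t in transcripts}
        self.by_gene: dict[str, list[TranscriptModel]] = {}
        for t in transcripts:
            self.by_gene.setdefault(t.gene_name, []).append(t)
        self.canonical: dict[str, TranscriptModel] = {
            g: min(ts, key=lambda t: (-t.cds_len, -t.total_exon_len, t.transcript_id))
            for g, ts in self.by_gene.items()
        }
        self._tree: dict[str, IntervalTree] = {}
        for t in transcripts:
            tree = self._tree.setdefault(t.chrom, IntervalTree())
            tree.addi(t.tx_start, t.tx_end + 1, t.transcript_id)

    def genes_at(self, chrom: str, pos: int) -> list[str]:
        tree = self._tree.get(chrom)
        if tree is None:
            return []
        genes = {self.transcripts[iv.data].gene_name for iv in tree.at(pos)}
        return sorted(genes)

    def canonical_at(self, chrom: str, pos: int) -> TranscriptModel | None:
        genes = self.genes_at(chrom, pos)
        if not genes:
            return None
        return self.canonical[genes[0]]


# ---------------------------------------------------------------------------
# loaders


def load_refflat(path: str) -> list[TranscriptModel]:
    """Load UCSC refFlat (0-based half-open converted to 1-based inclusive)."""
    models = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 11:
                log.warning("refFlat line %d malformed (%d fields); skipped", lineno, len(fields))
                continue
            gene, tx_id, chrom, strand = fields[0], fields[1], fields[2], fields[3]
            cds_s, cds_e = int(fields[6]), int(fields[7])
            starts = [int(x) for x in fields[9].rstrip(",").split(",")]
            ends = [int(x) for x in fields[10].rstrip(",").split(",")]
            exons = [(s + 1, e) for s, e in zip(starts, ends)]
            coding = cds_e > cds_s
            models.append(
                TranscriptModel(
                    transcript_id=tx_id,
                    gene_name=gene,
                    chrom=chrom,
                    strand=strand,
                    exons=exons,
                    cds_start=cds_s + 1 if coding else None,
                    cds_end=cds_e if coding else None,
                )
            )
    return models


def load_gtf(path: str) -> list[TranscriptModel]:
    """Load transcript models from a GTF (exon + CDS features)."""
    import gffutils

    db = gffutils.create_db(
        path, dbfn=":memory:", force=True, keep_order=True,
        disable_infer_genes=True, disable_infer_transcripts=True,
    )
    exons: dict[str, list] = {}
    cds: dict[str, list] = {}
    meta: dict[str, tuple] = {}
    for feat in db.all_features():
        if feat.featuretype not in ("exon", "CDS"):
            continue
        tx_id = feat.attributes["transcript_id"][0]
        gene = feat.attributes.get("gene_name", feat.attributes.get("gene_id", ["NA"]))[0]
        meta[tx_id] = (gene, feat.seqid, feat.strand)
        target = exons if feat.featuretype == "exon" else cds
        target.setdefault(tx_id, []).append((feat.start, feat.end))
    models = []
    for tx_id, ex in exons.items():
        gene, chrom, strand = meta[tx_id]
        cds_iv = cds.get(tx_id)
        models.append(
            TranscriptModel(
                transcript_id=tx_id,
                gene_name=gene,
                chrom=chrom,
                strand=strand,
                exons=ex,
                cds_start=min(s for s, _ in cds_iv) if cds_iv else None,
                cds_end=max(e for _, e in cds_iv) if cds_iv else None,
            )
        )
    return models


def load_models(path: str) -> GeneModelIndex:
    """Load gene models from refFlat or GTF (sniffed by extension)."""
    lower = str(path).lower()
    if lower.endswith((".gtf", ".gff", ".gff3")):
        models = load_gtf(path)
    else:
        models = load_refflat(path)
    return GeneModelIndex(models)


# ---------------------------------------------------------------------------
# per-breakpoint annotation


@dataclass
class BreakpointAnnotation:
    gene: str = "NA"
    transcript_id: str = "NA"
    exon_number: int | None = None
    region: str = "intergenic"  # "exon<N>" | "intron<N>" | "intergenic"
    cdna_pos: int | None = None
    on_boundary: bool = False


def _shifted_lookup_pos(bp: Breakpoint, shift: int) -> int:
    """Shift a breakpoint ``shift`` bases inward, into its own alignment.

    Junction micro-homology can drag the raw coordinate a few bases into
    the partner gene's territory; looking up the gene a few bases inside
    the segment's own mapped block is robust to that.
    """
    if bp.side == "5prime_end":
        delta = -shift if bp.strand == "+" else shift
    else:
        delta = shift if bp.strand == "+" else -shift
    return max(1, bp.pos + delta)


def annotate_breakpoint(
    bp: Breakpoint, index: GeneModelIndex, shift: int = 6
) -> BreakpointAnnotation:
    """Annotate one breakpoint with gene / exon / cDNA position.

    The gene and transcript are selected at the inward-shifted position;
    the exon/intron label and cDNA position are then computed at the raw
    junction coordinate within that transcript, which is the coordinate
    reported downstream.
    """
    tx = index.canonical_at(bp.chrom, _shifted_lookup_pos(bp, shift))
    if tx is None:
        tx = index.canonical_at(bp.chrom, bp.pos)
    if tx is None:
        return BreakpointAnnotation()
    exon_no = tx.exon_number(bp.pos)
    if exon_no is not None:
        region = f"exon{exon_no}"
    else:
        intron_no = tx.intron_number(bp.pos)
        region = f"intron{intron_no}" if intron_no is not None else "near_gene"
    return BreakpointAnnotation(
        gene=tx.gene_name,
        transcript_id=tx.transcript_id,
        exon_number=exon_no,
        region=region,
        cdna_pos=tx.cdna_pos(bp.pos),
    )


def boundary_status(
    bp5: Breakpoint,
    bp3: Breakpoint,
    ann5: BreakpointAnnotation,
    ann3: BreakpointAnnotation,
    index: GeneModelIndex,
    tolerance: int = 0,
) -> str:
    """Judge whether each junction lies on a known exon terminus.

    The 5' junction must equal an exon 3' terminus (donor side) and the 3'
    junction an exon 5' terminus (acceptor side) of *any* transcript of its
    gene.  Returns "both" / "one" / "none" and sets the per-side flags on
    the annotations.
    """

    def _on(gene: str, pos: int, donor: bool) -> bool:
        if gene == "NA":
            return False
        for t in index.by_gene.get(gene, []):
            sites = t.donor_positions() if donor else t.acceptor_positions()
            if tolerance == 0:
                if pos in sites:
                    return True
            elif any(abs(pos - s) <= tolerance for s in sites):
                return True
        return False

    ann5.on_boundary = _on(ann5.gene, bp5.pos, donor=True)
    ann3.on_boundary = _on(ann3.gene, bp3.pos, donor=False)
    n = int(ann5.on_boundary) + int(ann3.on_boundary)
    return {2: "both", 1: "one", 0: "none"}[n]


def _frame_for_pair(
    t5: TranscriptModel, bp5_pos: int, t3: TranscriptModel, bp3_pos: int
) -> str:
    """Frame call for one transcript pair; "NA" unless both junction-adjacent
    bases are coding."""
    if t5.cds_start is None or t3.cds_start is None:
        return "NA"
    c5_cdna = t5.cdna_pos(bp5_pos)
    c3_cdna = t3.cdna_pos(bp3_pos)
    if c5_cdna is None or c3_cdna is None:
        return "NA"
    s5, e5 = t5.cdna_cds_start(), t5.cdna_cds_end()
    s3, e3 = t3.cdna_cds_start(), t3.cdna_cds_end()
    if not (s5 <= c5_cdna <= e5) or not (s3 <= c3_cdna <= e3):
        return "NA"
    c5 = c5_cdna - s5 + 1  # coding bases retained from the 5' CDS
    c3 = c3_cdna - s3      # coding bases removed from the 3' CDS
    return "in-frame" if c5 % 3 == c3 % 3 else "out-of-frame"


def frame_status(
    bp5: Breakpoint,
    bp3: Breakpoint,
    ann5: BreakpointAnnotation,
    ann3: BreakpointAnnotation,
    index: GeneModelIndex,
) -> tuple[str, bool]:
    """Frame call on canonical transcripts, with isoform rescue.

    If the canonical pair is NA but some other isoform pair is in frame,
    that isoform's call is reported (flagged) — a fusion transcribed from a
    minor isoform is still clinically actionable.  Returns
    ``(status, isoform_rescued)``.
    """
    if ann5.gene == "NA" or ann3.gene == "NA":
        return "NA", False
    t5 = index.transcripts.get(ann5.transcript_id)
    t3 = index.transcripts.get(ann3.transcript_id)
    if t5 is None or t3 is None:
        return "NA", False
    status = _frame_for_pair(t5, bp5.pos, t3, bp3.pos)
    if status != "NA":
        return status, False
    for alt5 in index.by_gene[ann5.gene]:
        for alt3 in index.by_gene[ann3.gene]:
            if alt5 is t5 and alt3 is t3:
                continue
            if _frame_for_pair(alt5, bp5.pos, alt3, bp3.pos) == "in-frame":
                return "in-frame", True
    return "NA", False


# ---------------------------------------------------------------------------
# aggregation


@dataclass
class AnnotatedCall:
    """A junction aggregated over its supporting reads, fully annotated."""

    bp5: Breakpoint
    bp3: Breakpoint
    ann5: BreakpointAnnotation
    ann3: BreakpointAnnotation
    frame_status: str
    boundary_status: str
    n_umi_reads: int
    n_partner_ends: int
    supporting_read_ids: list[str] = field(default_factory=list)
    mid_annotations: list[str] = field(default_factory=list)
    isoform_rescued: bool = False
    event_name: str = ""
    mode_flags: list[str] = field(default_factory=list)

    @property
    def fusion_name(self) -> str:
        if self.event_name:
            return self.event_name
        return f"{self.ann5.gene}::{self.ann3.gene}"

    @property
    def junction(self) -> str:
        return f"{self.bp5.chrom}:{self.bp5.pos}_{self.bp3.chrom}:{self.bp3.pos}"


def _evidence_counts(cands: list[JunctionCandidate]) -> tuple[int, int, list[str]]:
    umis = set()
    no_umi = 0
    ls_set = set()
    read_ids = []
    for c in cands:
        read_ids.append(c.read_id)
        if c.umi:
            umis.add(c.umi)
        else:
            no_umi += 1
        if c.ls is not None:
            ls_set.add((c.ls.chrom, c.ls.pos, c.ls.strand))
    n_umi = len(umis) + no_umi
    n_pe = len(ls_set) if ls_set else n_umi
    return n_umi, min(n_pe, n_umi), sorted(set(read_ids))


def annotate_group(
    cands: list[JunctionCandidate], index: GeneModelIndex, cfg
) -> AnnotatedCall:
    """Annotate one exact-junction group of per-read candidates."""
    rep = cands[0]
    ann5 = annotate_breakpoint(rep.bp_left, index, cfg.annotation_shift)
    ann3 = annotate_breakpoint(rep.bp_right, index, cfg.annotation_shift)
    bstat = boundary_status(
        rep.bp_left, rep.bp_right, ann5, ann3, index, cfg.boundary_tolerance
    )
    fstat, rescued = frame_status(rep.bp_left, rep.bp_right, ann5, ann3, index)
    n_umi, n_pe, read_ids = _evidence_counts(cands)
    mids = sorted(
        {
            f"{a.gene}:{a.region}"
            for c in cands
            for a in (
                annotate_breakpoint(
                    Breakpoint(m.chrom, m.ref_start, "3prime_start", m.strand),
                    index,
                    0,
                )
                for m in c.mid_segments
            )
        }
    )
    return AnnotatedCall(
        bp5=rep.bp_left,
        bp3=rep.bp_right,
        ann5=ann5,
        ann3=ann3,
        frame_status=fstat,
        boundary_status=bstat,
        n_umi_reads=n_umi,
        n_partner_ends=n_pe,
        supporting_read_ids=read_ids,
        mid_annotations=mids,
        isoform_rescued=rescued,
    )


def aggregate_and_threshold(
    groups: dict[tuple, list[JunctionCandidate]], index: GeneModelIndex, cfg
) -> list[AnnotatedCall]:
    """Annotate junction groups and apply the boundary-aware evidence rule.

    both boundaries -> >= ``minPartnerEnds_BothExonJunction`` (default 1)
    one boundary    -> >= ``minPartnerEnds_OneExonJunction`` (default 3)
    no boundary     -> rejected here (only whitelisted targeted events pass)
    """
    calls = []
    for key in sorted(groups):
        call = annotate_group(groups[key], index, cfg)
        if call.boundary_status == "both":
            if call.n_partner_ends >= cfg.minPartnerEnds_BothExonJunction:
                calls.append(call)
        elif call.boundary_status == "one":
            if call.n_partner_ends >= cfg.minPartnerEnds_OneExonJunction:
                calls.append(call)
    return calls
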