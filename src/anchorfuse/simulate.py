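"""Seeded synthetic data: genomes, transcript models, split reads, truth.

The generator emulates the geometry of anchored multiplex PCR (AMP)
libraries aligned to a genome: each fusion-crossing read starts at a
ligated fragment end inside the partner gene (read base 1 = ligation site),
crosses the fusion junction, and finishes in the panel gene where the
gene-specific primers sit.  It emits aligned SAM records directly — a
primary record mapping the ligation side with the anchored side
soft-clipped, plus a reciprocal hard-clipped supplementary record and a
consistent SA tag, exactly the contract of a BWA-MEM-style split aligner —
so the whole pipeline is testable without running an aligner.  Every output
is a pure function of the seed, and each scenario ships a truth table
sufficient to score pipeline output without re-deriving anything from
sequence.

Coding sequences are synthesized from T-free codons (alphabet {A,C,G})
between an ATG start and a TAA stop.  No stop codon can then arise by
chance at a fusion junction or in a shifted frame inside the CDS, which
makes reading-frame phase arithmetic *provably* equivalent to direct
translation on these fixtures; real transcripts do not have this property,
so agreement here validates the arithmetic, not stop-codon robustness.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
from Bio.Seq import Seq

from .annotator import TranscriptModel

BASES = np.array(list("ACGT"))
TFREE_CODONS = [a + b + c for a in "ACG" for b in "ACG" for c in "ACG"]


def _rand_seq(rng: np.random.Generator, n: int) -> str:
    return "".join(BASES[rng.integers(0, 4, n)])


def _revcomp(s: str) -> str:
    return str(Seq(s).reverse_complement())


@dataclass
class GeneSpec:
    """Blueprint for one synthetic gene."""

    name: str
    n_exons: int = 5
    exon_len: int = 150
    intron_len: int = 400
    strand: str = "+"
    utr5: int = 30
    utr3: int = 30
    coding: bool = True
    transcript_id: str = ""

    def __post_init__(self):
        if not self.transcript_id:
            self.transcript_id = f"TX_{self.name}"


@dataclass
class SimulatedGene:
    """A placed synthetic gene: model (contig coordinates) plus sequences."""

    spec: GeneSpec
    model: TranscriptModel
    cdna: str
    cds_cdna_start: int | None  # 1-based cDNA position of the A of ATG
    cds_cdna_end: int | None    # last base of the TAA stop
    contig: str
    gene_seq: str               # transcript-orientation genomic sequence

    @property
    def protein(self) -> str:
        if self.cds_cdna_start is None:
            return ""
        cds = self.cdna[self.cds_cdna_start - 1 : self.cds_cdna_end]
        return str(Seq(cds).translate(to_stop=True))


def make_gene(rng: np.random.Generator, spec: GeneSpec, contig: str, offset: int) -> SimulatedGene:
    """Build a gene at 1-based contig ``offset`` (gene occupies
    [offset, offset + span - 1] on the forward strand)."""
    cdna_len = spec.n_exons * spec.exon_len
    if spec.coding:
        cds_len = cdna_len - spec.utr5 - spec.utr3
        cds_len -= cds_len % 3
        if cds_len < 9:
            raise ValueError(f"gene {spec.name}: exons too short for a CDS")
        body = "".join(
            TFREE_CODONS[i] for i in rng.integers(0, len(TFREE_CODONS), cds_len // 3 - 2)
        )
        cds = "ATG" + body + "TAA"
        utr3_len = cdna_len - spec.utr5 - cds_len
        cdna = _rand_seq(rng, spec.utr5) + cds + _rand_seq(rng, utr3_len)
        cds_s, cds_e = spec.utr5 + 1, spec.utr5 + cds_len
    else:
        cdna = _rand_seq(rng, cdna_len)
        cds_s = cds_e = None

    # transcript-orientation genomic sequence and local exon intervals
    parts = []
    local_exons = []  # 1-based inclusive, transcript orientation
    cursor = 0
    for i in range(spec.n_exons):
        ex = cdna[i * spec.exon_len : (i + 1) * spec.exon_len]
        local_exons.append((cursor + 1, cursor + spec.exon_len))
        parts.append(ex)
        cursor += spec.exon_len
        if i < spec.n_exons - 1:
            intron = "GT" + _rand_seq(rng, spec.intron_len - 4) + "AG"
            parts.append(intron)
            cursor += spec.intron_len
    gene_seq = "".join(parts)
    span = len(gene_seq)

    def to_genomic(local: int) -> int:
        if spec.strand == "+":
            return offset + local - 1
        return offset + span - local

    exons = sorted(tuple(sorted((to_genomic(s), to_genomic(e)))) for s, e in local_exons)
    if cds_s is not None:
        # map CDS cDNA bounds through exons to genomic bounds
        def cdna_to_local(p: int) -> int:
            exon_idx = (p - 1) // spec.exon_len
            within = (p - 1) % spec.exon_len
            return local_exons[exon_idx][0] + within

        g1 = to_genomic(cdna_to_local(cds_s))
        g2 = to_genomic(cdna_to_local(cds_e))
        cds_lo, cds_hi = min(g1, g2), max(g1, g2)
    else:
        cds_lo = cds_hi = None
    model = TranscriptModel(
        transcript_id=spec.transcript_id,
        gene_name=spec.name,
        chrom=contig,
        strand=spec.strand,
        exons=exons,
        cds_start=cds_lo,
        cds_end=cds_hi,
    )
    return SimulatedGene(
        spec=spec,
        model=model,
        cdna=cdna,
        cds_cdna_start=cds_s,
        cds_cdna_end=cds_e,
        contig=contig,
        gene_seq=gene_seq,
    )


# ---------------------------------------------------------------------------
# junction specification


@dataclass
class JunctionSpec:
    """Where the fusion junction sits in each partner.

    ``exon5``/``exon3`` are transcript-ordinal exon numbers.  ``offset5``
    moves the 5' junction upstream (into the exon) from the donor terminus;
    ``intron_offset5`` instead places it that many bases *into* the intron
    following ``exon5`` (cryptic, genomically contiguous with the exon).
    ``offset3`` moves the 3' junction downstream into its exon from the
    acceptor terminus.
    """

    exon5: int = 2
    exon3: int = 2
    offset5: int = 0
    offset3: int = 0
    intron_offset5: int = 0


@dataclass
class ResolvedJunction:
    bp5: int            # genomic, last retained base of the 5' side
    bp3: int            # genomic, first retained base of the 3' side
    cdna5_end: int | None
    cdna3_start: int | None
    boundary5: bool = False
    boundary3: bool = False


def resolve_junction(gene5: SimulatedGene, gene3: SimulatedGene, js: JunctionSpec) -> ResolvedJunction:
    m5, m3 = gene5.model, gene3.model
    if js.intron_offset5:
        donor = m5.donor_of_exon(js.exon5)
        bp5 = donor + js.intron_offset5 if m5.strand == "+" else donor - js.intron_offset5
        cdna5 = None
        b5 = False
    else:
        cdna5 = m5.cdna_pos(m5.donor_of_exon(js.exon5)) - js.offset5
        bp5 = m5.genomic_pos(cdna5)
        b5 = js.offset5 == 0
    cdna3 = m3.cdna_pos(m3.acceptor_of_exon(js.exon3)) + js.offset3
    bp3 = m3.genomic_pos(cdna3)
    return ResolvedJunction(
        bp5=bp5,
        bp3=bp3,
        cdna5_end=cdna5,
        cdna3_start=cdna3,
        boundary5=b5,
        boundary3=js.offset3 == 0,
    )


# ---------------------------------------------------------------------------
# the translation oracle


def translate_oracle(
    gene5: SimulatedGene, cdna5_end: int | None, gene3: SimulatedGene, cdna3_start: int | None
) -> bool | None:
    """Direct-translation frame oracle, independent of phase arithmetic.

    Builds the fused mRNA (5' transcript through ``cdna5_end`` + 3'
    transcript from ``cdna3_start``), translates from the 5' gene's start
    codon, and declares the fusion in frame iff translation terminates and
    the product ends with the 3' gene's C-terminal peptide.  Abstains
    (returns None) when either junction-adjacent base lies outside its
    gene's CDS — UTR, intronic, and non-coding junctions have no defined
    fusion frame.
    """
    if cdna5_end is None or cdna3_start is None:
        return None
    if gene5.cds_cdna_start is None or gene3.cds_cdna_start is None:
        return None
    if not (gene5.cds_cdna_start <= cdna5_end <= gene5.cds_cdna_end):
        return None
    if not (gene3.cds_cdna_start <= cdna3_start <= gene3.cds_cdna_end):
        return None
    fused = gene5.cdna[:cdna5_end] + gene3.cdna[cdna3_start - 1 :]
    coding_region = fused[gene5.cds_cdna_start - 1 :]
    coding_region = coding_region[: len(coding_region) - len(coding_region) % 3]
    prot = str(Seq(coding_region).translate())
    terminated = "*" in prot
    product = prot.split("*")[0]
    tail_len = min(8, len(gene3.protein))
    tail = gene3.protein[-tail_len:] if tail_len else ""
    return terminated and tail_len > 0 and product.endswith(tail)


# ---------------------------------------------------------------------------
# reference assembly


@dataclass
class SimulatedReference:
    contigs: dict[str, str] = field(default_factory=dict)
    genes: dict[str, SimulatedGene] = field(default_factory=dict)
    truth: dict = field(default_factory=dict)
    decoys: list[tuple] = field(default_factory=list)  # (contig, start, end, source_gene)

    def write_fasta(self, path: str) -> str:
        with open(path, "w") as fh:
            for name in sorted(self.contigs):
                fh.write(f">{name}\n")
                seq = self.contigs[name]
                for i in range(0, len(seq), 70):
                    fh.write(seq[i : i + 70] + "\n")
        return str(path)

    def write_refflat(self, path: str) -> str:
        with open(path, "w") as fh:
            for name in sorted(self.genes):
                m = self.genes[name].model
                starts = ",".join(str(s - 1) for s, _ in m.exons) + ","
                ends = ",".join(str(e) for _, e in m.exons) + ","
                cds_s = m.cds_start - 1 if m.cds_start else m.tx_start - 1
                cds_e = m.cds_end if m.cds_end else m.tx_start - 1
                fh.write(
                    "\t".join(
                        [
                            m.gene_name, m.transcript_id, m.chrom, m.strand,
                            str(m.tx_start - 1), str(m.tx_end),
                            str(cds_s), str(cds_e),
                            str(m.n_exons), starts, ends,
                        ]
                    )
                    + "\n"
                )
        return str(path)

    def write_gtf(self, path: str) -> str:
        with open(path, "w") as fh:
            for name in sorted(self.genes):
                m = self.genes[name].model
                attrs = (
                    f'gene_id "{m.gene_name}"; transcript_id "{m.transcript_id}"; '
                    f'gene_name "{m.gene_name}";'
                )
                for s, e in m.exons:
                    fh.write(
                        f"{m.chrom}\tsim\texon\t{s}\t{e}\t.\t{m.strand}\t.\t{attrs}\n"
                    )
                    if m.cds_start is not None:
                        cs, ce = max(s, m.cds_start), min(e, m.cds_end)
                        if cs <= ce:
                            fh.write(
                                f"{m.chrom}\tsim\tCDS\t{cs}\t{ce}\t.\t{m.strand}\t.\t{attrs}\n"
                            )
        return str(path)

    def truth_json(self, path: str) -> str:
        with open(path, "w") as fh:
            json.dump(self.truth, fh, indent=1, sort_keys=True, default=str)
        return str(path)


PAD = 2000


def build_reference(
    gene_specs: list[tuple[GeneSpec, str]],
    seed: int,
    gaps: dict[str, int] | None = None,
    repeat_of: dict[str, int] | None = None,
) -> SimulatedReference:
    """Assemble contigs containing the given genes.

    ``gene_specs`` is a list of (spec, contig) pairs; genes on one contig
    are laid out in order with ``PAD`` of random padding between them, or a
    caller-specified exact ``gaps[gene_name]`` to the previous gene's end
    (used to probe the intron-distance rule).  ``repeat_of[gene_name] = k``
    appends k decoy copies of that gene's genomic span, spaced far apart,
    to force ambiguous (MAPQ-0) mapping scenarios.
    """
    rng = np.random.default_rng(seed)
    gaps = gaps or {}
    repeat_of = repeat_of or {}
    ref = SimulatedReference()
    pieces: dict[str, list[str]] = {}
    cursor: dict[str, int] = {}
    for spec, contig in gene_specs:
        pieces.setdefault(contig, [_rand_seq(rng, PAD)])
        cursor.setdefault(contig, PAD)
        gap = gaps.get(spec.name, PAD)
        if cursor[contig] > PAD or gap != PAD:
            pieces[contig].append(_rand_seq(rng, gap))
            cursor[contig] += gap
        gene = make_gene(rng, spec, contig, cursor[contig] + 1)
        placed = gene.gene_seq if spec.strand == "+" else _revcomp(gene.gene_seq)
        pieces[contig].append(placed)
        cursor[contig] += len(gene.gene_seq)
        ref.genes[spec.name] = gene
        for _ in range(repeat_of.get(spec.name, 0)):
            pieces[contig].append(_rand_seq(rng, 5 * PAD))
            cursor[contig] += 5 * PAD
            seq = gene.gene_seq if spec.strand == "+" else _revcomp(gene.gene_seq)
            start = cursor[contig] + 1
            pieces[contig].append(seq)
            cursor[contig] += len(seq)
            ref.decoys.append((contig, start, cursor[contig], spec.name))
    for contig in pieces:
        pieces[contig].append(_rand_seq(rng, PAD))
        ref.contigs[contig] = "".join(pieces[contig])
    return ref


# ---------------------------------------------------------------------------
# read emission


@dataclass
class FusionScenario:
    """A planted fusion with planned read/molecule/partner-end counts."""

    name: str
    gene5: str
    gene3: str
    junction: JunctionSpec = field(default_factory=JunctionSpec)
    n_reads: int = 20
    n_umis: int = 12
    n_partner_ends: int = 5
    read_length: int = 100
    error_rate: float = 0.0
    anchored: bool = True
    min_split: int = 30  # smallest ligation-side part length emitted
    decoy_supplementary: bool = False  # map the anchored side to a decoy copy

    def __post_init__(self):
        if not (self.n_partner_ends <= self.n_umis <= self.n_reads):
            raise ValueError("need partner_ends <= umis <= reads")


@dataclass
class SamRecord:
    """A minimal alignment row (SAM columns + tags) the writer serializes."""

    name: str
    flag: int
    chrom: str
    pos: int
    mapq: int
    cigar: str
    seq: str
    tags: dict = field(default_factory=dict)


def _upstream_flank(ref: SimulatedReference, gene: SimulatedGene, bp5: int, k: int) -> str:
    contig = ref.contigs[gene.contig]
    if gene.model.strand == "+":
        return contig[bp5 - k : bp5]
    return _revcomp(contig[bp5 - 1 : bp5 - 1 + k])


def _downstream_flank(ref: SimulatedReference, gene: SimulatedGene, bp3: int, k: int) -> str:
    contig = ref.contigs[gene.contig]
    if gene.model.strand == "+":
        return contig[bp3 - 1 : bp3 - 1 + k]
    return _revcomp(contig[bp3 - k : bp3])


def _apply_errors(rng: np.random.Generator, seq: str, rate: float) -> str:
    if rate <= 0:
        return seq
    out = list(seq)
    for i in range(len(out)):
        if rng.random() < rate:
            out[i] = "ACGT"[(("ACGT".index(out[i])) + int(rng.integers(1, 4))) % 4]
    return "".join(out)


def emit_reads(
    scenario: FusionScenario, ref: SimulatedReference, seed: int
) -> tuple[list[SamRecord], dict]:
    """Emit aligned split-read records for one fusion scenario plus truth.

    Molecules are planned first: ``n_partner_ends`` distinct split points
    (distinct ligation sites), ``n_umis`` distinct molecules cycling over
    them, then ``n_reads`` reads cycling over the molecules so surplus
    reads are exact UMI-LS duplicates.
    """
    rng = np.random.default_rng(seed)
    g5, g3 = ref.genes[scenario.gene5], ref.genes[scenario.gene3]
    rj = resolve_junction(g5, g3, scenario.junction)
    L = scenario.read_length
    splits = [scenario.min_split + i for i in range(scenario.n_partner_ends)]

    def _umi(i: int) -> str:  # base-4 encoding: distinct for i < 4**8
        return "".join("ACGT"[(i >> (2 * j)) & 3] for j in range(8))

    molecules = [(_umi(i), splits[i % len(splits)]) for i in range(scenario.n_umis)]
    records: list[SamRecord] = []
    truth_reads = []
    supp_chrom, supp_map = g3.contig, None
    if scenario.decoy_supplementary:
        decoys = [d for d in ref.decoys if d[3] == scenario.gene3]
        if not decoys:
            raise ValueError("decoy_supplementary requires repeat copies of gene3")
        supp_map = decoys  # anchored side reported at the first decoy, XA lists the rest

    for i in range(scenario.n_reads):
        umi, s = molecules[i % len(molecules)]
        k = L - s
        read_seq = _upstream_flank(ref, g5, rj.bp5, s) + _downstream_flank(ref, g3, rj.bp3, k)
        read_seq = _apply_errors(rng, read_seq, scenario.error_rate)
        base_name = f"{scenario.name}R{i:04d}"
        name = base_name + (f"_UMI:{umi}" if scenario.anchored else "")
        # primary: ligation (5' gene) side mapped, anchored side soft-clipped
        if g5.model.strand == "+":
            p_pos, p_flag, p_cigar = rj.bp5 - s + 1, 0, f"{s}M{k}S"
            p_seq = read_seq
        else:
            p_pos, p_flag, p_cigar = rj.bp5, 16, f"{k}S{s}M"
            p_seq = _revcomp(read_seq)
        # supplementary: anchored (3' gene) side
        g3_strand = g3.model.strand
        if scenario.decoy_supplementary:
            d_contig, d_start, d_end, _ = supp_map[0]
            gene_lo = g3.model.tx_start
            true_pos_plus = rj.bp3
            offset_in_gene = (true_pos_plus - gene_lo) if g3_strand == "+" else (
                g3.model.tx_end - rj.bp3
            )
            s_chrom = d_contig
            s_pos = d_start + offset_in_gene
            s_mapq = 0
        else:
            s_chrom = g3.contig
            s_pos = rj.bp3 if g3_strand == "+" else rj.bp3 - k + 1
            s_mapq = 60
        if g3_strand == "+":
            s_flag_strand, s_cigar_s, s_cigar_h = "+", f"{s}S{k}M", f"{s}H{k}M"
            s_seq = read_seq[s:]  # hard-clipped rows carry only the mapped part
        else:
            if scenario.decoy_supplementary:
                raise ValueError("decoy copies of minus-strand panel genes not supported")
            s_flag_strand, s_cigar_s, s_cigar_h = "-", f"{k}M{s}S", f"{k}M{s}H"
            s_seq = _revcomp(read_seq)[:k]
        p_tags = {"SA": f"{s_chrom},{s_pos},{s_flag_strand},{s_cigar_s},{s_mapq},0;"}
        s_flag = 2048 | (16 if s_flag_strand == "-" else 0)
        s_tags = {
            "SA": f"{g5.contig},{p_pos},{'-' if p_flag & 16 else '+'},{p_cigar},60,0;"
        }
        if scenario.decoy_supplementary:
            # alternatives: the true locus plus the remaining decoys
            true_pos = rj.bp3 if g3_strand == "+" else rj.bp3 - k + 1
            alts = [f"{g3.contig},{'+' if g3_strand == '+' else '-'}{true_pos},{s_cigar_s},0"]
            for d_contig, d_start, _, _ in supp_map[1:]:
                alts.append(f"{d_contig},+{d_start + (s_pos - supp_map[0][1])},{s_cigar_s},1")
            s_tags["XA"] = ";".join(alts) + ";"
        records.append(SamRecord(name, p_flag, g5.contig, p_pos, 60, p_cigar, p_seq, p_tags))
        records.append(SamRecord(name, s_flag, s_chrom, s_pos, s_mapq, s_cigar_h, s_seq, s_tags))
        ls_pos = rj.bp5 - s + 1 if g5.model.strand == "+" else rj.bp5 + s - 1
        truth_reads.append({"name": base_name, "umi": umi, "split": s, "ls": ls_pos})

    oracle = translate_oracle(g5, rj.cdna5_end, g3, rj.cdna3_start)
    truth = {
        "scenario": scenario.name,
        "gene5": scenario.gene5,
        "gene3": scenario.gene3,
        "junction": {
            "chrom5": g5.contig, "bp5": rj.bp5, "chrom3": g3.contig, "bp3": rj.bp3,
        },
        "boundary_status": {2: "both", 1: "one", 0: "none"}[
            int(rj.boundary5) + int(rj.boundary3)
        ],
        "frame_oracle": oracle,
        "n_reads": scenario.n_reads,
        "n_distinct_umi_ls": len({(u, s) for u, s in molecules}),
        "n_partner_ends": len({s for _, s in molecules}),
        "reads": truth_reads,
    }
    return records, truth


def write_sam(records: list[SamRecord], ref: SimulatedReference, path: str) -> str:
    """Serialize records as name-grouped text SAM with proper @SQ lines."""
    with open(path, "w") as fh:
        fh.write("@HD\tVN:1.6\tSO:queryname\n")
        for name in sorted(ref.contigs):
            fh.write(f"@SQ\tSN:{name}\tLN:{len(ref.contigs[name])}\n")
        for r in sorted(records, key=lambda r: (r.name, r.flag)):
            tags = "".join(f"\t{k}:Z:{v}" for k, v in sorted(r.tags.items()))
            qual = "I" * len(r.seq)
            fh.write(
                f"{r.name}\t{r.flag}\t{r.chrom}\t{r.pos}\t{r.mapq}\t{r.cigar}"
                f"\t*\t0\t0\t{r.seq}\t{qual}{tags}\n"
            )
    return str(path)


def write_fastq(records: list[SamRecord], path: str) -> str:
    with open(path, "w") as fh:
        for r in sorted(records, key=lambda r: r.name):
            if r.flag & 2048:
                continue
            seq = r.seq if not (r.flag & 16) else _revcomp(r.seq)
            fh.write(f"@{r.name}\n{seq}\n+\n{'I' * len(seq)}\n")
    return str(path)


# ---------------------------------------------------------------------------
# model-level trials for the reading-frame property


def random_frame_trial(seed: int) -> dict:
    """One random fusion scenario at the transcript-model level.

    Draws two random genes (exon counts, exon/intron/UTR lengths, strands)
    and a junction of a random kind — exon boundary, intra-exon, intronic
    5' side, 5'UTR 3' side, or non-coding partner — and returns the models,
    the genomic breakpoints, and the translation-oracle verdict
    (True / False / None), with no reads involved.  Used to validate frame
    phase arithmetic against direct translation over many scenarios.
    """
    rng = np.random.default_rng(seed)

    def draw_spec(name: str, coding: bool = True) -> GeneSpec:
        return GeneSpec(
            name,
            n_exons=int(rng.integers(3, 7)),
            exon_len=int(rng.integers(30, 71)) * 3,
            intron_len=int(rng.integers(25, 80)) * 4,
            strand="+" if rng.random() < 0.5 else "-",
            utr5=int(rng.integers(10, 41)),
            utr3=int(rng.integers(10, 41)),
            coding=coding,
        )

    kind = ["boundary", "exonic", "intron5", "utr3prime_partner", "noncoding"][
        int(rng.integers(0, 5))
    ]
    s5 = draw_spec("F5")
    s3 = draw_spec("F3", coding=kind != "noncoding")
    g5 = make_gene(rng, s5, "ctg5", 1001)
    g3 = make_gene(rng, s3, "ctg3", 1001)
    if kind == "boundary":
        js = JunctionSpec(
            exon5=int(rng.integers(1, s5.n_exons)), exon3=int(rng.integers(1, s3.n_exons))
        )
    elif kind == "exonic":
        js = JunctionSpec(
            exon5=int(rng.integers(2, s5.n_exons)),
            exon3=int(rng.integers(2, s3.n_exons)),
            offset5=int(rng.integers(1, s5.exon_len - 1)),
            offset3=int(rng.integers(1, s3.exon_len // 2)),
        )
    elif kind == "intron5":
        js = JunctionSpec(
            exon5=int(rng.integers(1, s5.n_exons)),
            exon3=int(rng.integers(2, s3.n_exons)),
            intron_offset5=int(rng.integers(1, s5.intron_len - 2)),
        )
    elif kind == "utr3prime_partner":
        js = JunctionSpec(
            exon5=int(rng.integers(1, s5.n_exons)),
            exon3=1,
            offset3=int(rng.integers(0, s3.utr5)),
        )
    else:  # noncoding partner
        js = JunctionSpec(
            exon5=int(rng.integers(1, s5.n_exons)), exon3=int(rng.integers(1, s3.n_exons))
        )
    rj = resolve_junction(g5, g3, js)
    return {
        "kind": kind,
        "gene5": g5,
        "gene3": g3,
        "junction": rj,
        "oracle": translate_oracle(g5, rj.cdna5_end, g3, rj.cdna3_start),
    }


# ---------------------------------------------------------------------------
# convenience: a standard two-gene fusion world used across tests/examples


def standard_world(seed: int = 7, **scenario_kwargs):
    """A partner gene and a panel gene on different contigs with a planted
    exon-boundary fusion; returns (reference, records, truth)."""
    specs = [
        (GeneSpec("GENE5P", n_exons=6, exon_len=150, intron_len=400), "chrA"),
        (GeneSpec("GENE3P", n_exons=6, exon_len=150, intron_len=400), "chrB"),
    ]
    ref = build_reference(specs, seed)
    scenario = FusionScenario(
        name="std", gene5="GENE5P", gene3="GENE3P", **scenario_kwargs
    )
    records, truth = emit_reads(scenario, ref, seed + 1)
    ref.truth[scenario.name] = truth
    return ref, records, truth
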