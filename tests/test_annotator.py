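"""Gene models, breakpoint annotation, boundary status, frame inference."""

import numpy as np
import pytest

from anchorfuse import RunConfig
from anchorfuse.annotator import (
    GeneModelIndex,
    TranscriptModel,
    aggregate_and_threshold,
    annotate_breakpoint,
    boundary_status,
    frame_status,
    load_models,
)
from anchorfuse.junction_core import Breakpoint
from anchorfuse import simulate as sim


@pytest.fixture(scope="module")
def two_gene_index(tmp_path_factory):
    d = tmp_path_factory.mktemp("models")
    specs = [
        (sim.GeneSpec("ALKG", n_exons=5, exon_len=120, intron_len=300), "cA"),
        (sim.GeneSpec("EMLG", n_exons=5, exon_len=120, intron_len=300, strand="-"), "cB"),
    ]
    ref = sim.build_reference(specs, 3)
    refflat = ref.write_refflat(d / "m.refflat")
    gtf = ref.write_gtf(d / "m.gtf")
    return {"ref": ref, "refflat": str(refflat), "gtf": str(gtf)}


class TestTranscriptModel:
    def test_cdna_and_genomic_roundtrip_both_strands(self, two_gene_index):
        for gene in ("ALKG", "EMLG"):
            m = two_gene_index["ref"].genes[gene].model
            for cp in (1, 60, 121, 333, m.total_exon_len):
                assert m.cdna_pos(m.genomic_pos(cp)) == cp

    def test_exon_numbering_transcript_oriented(self, two_gene_index):
        m = two_gene_index["ref"].genes["EMLG"].model  # minus strand
        assert m.exon_number(m.tx_end) == 1  # transcript 5' end = genomic right
        assert m.exon_number(m.tx_start) == m.n_exons

    def test_overlapping_exons_rejected(self):
        with pytest.raises(ValueError):
            TranscriptModel("t", "g", "c", "+", [(1, 100), (50, 200)])


class TestLoaders:
    def test_refflat_and_gtf_encode_identical_models(self, two_gene_index):
        a = load_models(two_gene_index["refflat"])
        b = load_models(two_gene_index["gtf"])
        assert set(a.transcripts) == set(b.transcripts)
        for tx_id, ta in a.transcripts.items():
            tb = b.transcripts[tx_id]
            assert (ta.exons, ta.cds_start, ta.cds_end, ta.strand, ta.gene_name) == (
                tb.exons, tb.cds_start, tb.cds_end, tb.strand, tb.gene_name
            )

    def test_canonical_picks_longest_cds_then_longest_transcript(self):
        mk = lambda tid, exons, cs, ce: TranscriptModel(tid, "G", "c", "+", exons, cs, ce)
        short = mk("t1", [(1, 400)], 101, 400)          # CDS 300
        long_a = mk("t2", [(1, 1000)], 101, 1000)       # CDS 900
        long_b = mk("t3", [(1, 1200)], 301, 1200)       # CDS 900, longer transcript
        idx = GeneModelIndex([short, long_a, long_b])
        assert idx.canonical["G"].transcript_id == "t3"

    def test_empty_model_set_is_hard_error(self):
        with pytest.raises(ValueError):
            GeneModelIndex([])


class TestAnnotateBreakpoint:
    def test_boundary_breakpoint_annotated_in_its_exon(self, two_gene_index):
        m = two_gene_index["ref"].genes["ALKG"].model
        bp = Breakpoint(m.chrom, m.donor_of_exon(2), "5prime_end", "+")
        ann = annotate_breakpoint(bp, load_models(two_gene_index["refflat"]), shift=6)
        assert (ann.gene, ann.region) == ("ALKG", "exon2")
        assert ann.cdna_pos == 240

    def test_slightly_intronic_breakpoint_reports_intron(self, two_gene_index):
        """3 bases past the donor: the shifted lookup stays in the gene but
        the reported region is the raw coordinate's intron."""
        m = two_gene_index["ref"].genes["ALKG"].model
        bp = Breakpoint(m.chrom, m.donor_of_exon(2) + 3, "5prime_end", "+")
        ann = annotate_breakpoint(bp, load_models(two_gene_index["refflat"]), shift=6)
        assert (ann.gene, ann.region) == ("ALKG", "intron2")
        assert ann.cdna_pos is None

    def test_intergenic_breakpoint_is_na(self, two_gene_index):
        idx = load_models(two_gene_index["refflat"])
        ann = annotate_breakpoint(Breakpoint("cA", 10, "5prime_end", "+"), idx)
        assert (ann.gene, ann.cdna_pos) == ("NA", None)


class TestBoundaryStatus:
    def _status(self, index, ref, pos5, pos3):
        bp5 = Breakpoint("cA", pos5, "5prime_end", "+")
        bp3 = Breakpoint("cB", pos3, "3prime_start", "-")
        a5 = annotate_breakpoint(bp5, index)
        a3 = annotate_breakpoint(bp3, index)
        return boundary_status(bp5, bp3, a5, a3, index)

    def test_both_one_none(self, two_gene_index):
        idx = load_models(two_gene_index["refflat"])
        ref = two_gene_index["ref"]
        donor = ref.genes["ALKG"].model.donor_of_exon(2)
        acceptor = ref.genes["EMLG"].model.acceptor_of_exon(3)
        assert self._status(idx, ref, donor, acceptor) == "both"
        assert self._status(idx, ref, donor - 7, acceptor) == "one"  # cryptic donor
        assert self._status(idx, ref, donor + 3, acceptor + 40) == "none"

    def test_boundary_invariant_to_annotation_shift(self, two_gene_index):
        idx = load_models(two_gene_index["refflat"])
        ref = two_gene_index["ref"]
        donor = ref.genes["ALKG"].model.donor_of_exon(2)
        acceptor = ref.genes["EMLG"].model.acceptor_of_exon(3)
        bp5 = Breakpoint("cA", donor, "5prime_end", "+")
        bp3 = Breakpoint("cB", acceptor, "3prime_start", "-")
        for shift in (0, 3, 6, 12):
            a5 = annotate_breakpoint(bp5, idx, shift)
            a3 = annotate_breakpoint(bp3, idx, shift)
            assert boundary_status(bp5, bp3, a5, a3, idx) == "both"


class TestFrameStatus:
    def test_phase_arithmetic_examples(self):
        # single-exon coding genes make the phase arithmetic transparent
        t5 = TranscriptModel("t5", "G5", "c5", "+", [(1, 5000)], 101, 4000)
        t3 = TranscriptModel("t3", "G3", "c3", "+", [(1, 5000)], 201, 4500)
        idx = GeneModelIndex([t5, t3])

        def call(c5, c3):
            bp5 = Breakpoint("c5", 100 + c5, "5prime_end", "+")
            bp3 = Breakpoint("c3", 200 + c3 + 1, "3prime_start", "+")
            a5 = annotate_breakpoint(bp5, idx)
            a3 = annotate_breakpoint(bp3, idx)
            return frame_status(bp5, bp3, a5, a3, idx)[0]

        assert call(1203, 2157) == "in-frame"      # both = 0 mod 3
        assert call(1204, 2158) == "in-frame"      # 1 vs 1
        assert call(1204, 2159) == "out-of-frame"  # 1 vs 2

    def test_utr_partner_is_na(self):
        t5 = TranscriptModel("t5", "G5", "c5", "+", [(1, 5000)], 101, 4000)
        t3 = TranscriptModel("t3", "G3", "c3", "+", [(1, 5000)], 201, 4500)
        idx = GeneModelIndex([t5, t3])
        bp5 = Breakpoint("c5", 1000, "5prime_end", "+")
        bp3 = Breakpoint("c3", 150, "3prime_start", "+")  # inside 5'UTR
        a5 = annotate_breakpoint(bp5, idx)
        a3 = annotate_breakpoint(bp3, idx)
        assert frame_status(bp5, bp3, a5, a3, idx)[0] == "NA"

    def test_isoform_rescue_reports_inframe_minor_isoform(self):
        # canonical isoform lacks the junction exon (junction intronic, NA),
        # a minor isoform contains it in frame
        canon = TranscriptModel("tA", "G3", "c3", "+", [(1, 300), (1001, 1900)], 101, 1800)
        minor = TranscriptModel("tB", "G3", "c3", "+", [(1, 300), (501, 599), (1001, 1300)],
                                101, 1200)
        t5 = TranscriptModel("t5", "G5", "c5", "+", [(1, 3000)], 1, 2700)
        idx = GeneModelIndex([t5, canon, minor])
        assert idx.canonical["G3"].transcript_id == "tA"
        bp5 = Breakpoint("c5", 300, "5prime_end", "+")       # c5 = 300 = 0 mod 3
        bp3 = Breakpoint("c3", 502, "3prime_start", "+")     # minor-isoform c3 = 201 = 0 mod 3
        a5 = annotate_breakpoint(bp5, idx)
        a3 = annotate_breakpoint(bp3, idx)
        status, rescued = frame_status(bp5, bp3, a5, a3, idx)
        assert (status, rescued) == ("in-frame", True)

    @pytest.mark.parametrize("n_trials", [200])
    def test_frame_matches_translation_oracle(self, n_trials):
        """Phase arithmetic equals direct translation of the fused mRNA on
        random synthetic gene pairs, and returns NA exactly when the oracle
        abstains (UTR / intronic / non-coding junctions)."""
        verdicts = {"in-frame": 0, "out-of-frame": 0, "NA": 0}
        for seed in range(n_trials):
            trial = sim.random_frame_trial(seed)
            g5, g3, rj = trial["gene5"], trial["gene3"], trial["junction"]
            idx = GeneModelIndex([g5.model, g3.model])
            bp5 = Breakpoint(g5.contig, rj.bp5, "5prime_end", g5.model.strand)
            bp3 = Breakpoint(g3.contig, rj.bp3, "3prime_start", g3.model.strand)
            a5 = annotate_breakpoint(bp5, idx, 6)
            a3 = annotate_breakpoint(bp3, idx, 6)
            status, _ = frame_status(bp5, bp3, a5, a3, idx)
            expected = {None: "NA", True: "in-frame", False: "out-of-frame"}[trial["oracle"]]
            assert status == expected, (seed, trial["kind"], status, expected)
            verdicts[status] += 1
        assert min(verdicts.values()) >= 10  # all three outcomes exercised


class TestAggregateThreshold:
    def _world_calls(self, tmp_path, junction, n_pe, n_umis=None, n_reads=None):
        n_umis = n_umis or max(n_pe, 3)
        n_reads = n_reads or n_umis
        specs = [(sim.GeneSpec("P5", n_exons=6), "wA"), (sim.GeneSpec("P3", n_exons=6), "wB")]
        ref = sim.build_reference(specs, 17)
        sc = sim.FusionScenario(
            name="t", gene5="P5", gene3="P3", junction=junction,
            n_reads=n_reads, n_umis=n_umis, n_partner_ends=n_pe,
        )
        records, truth = sim.emit_reads(sc, ref, 18)
        sam = sim.write_sam(records, ref, tmp_path / "t.sam")
        refflat = ref.write_refflat(tmp_path / "t.refflat")
        from conftest import run_world

        calls, _, _ = run_world(str(sam), str(refflat))
        return calls, truth

    @pytest.mark.parametrize("n_pe,called", [(1, True)])
    def test_both_boundary_called_from_single_partner_end(self, tmp_path, n_pe, called):
        calls, truth = self._world_calls(
            tmp_path, sim.JunctionSpec(exon5=2, exon3=2), n_pe, n_umis=1, n_reads=1
        )
        assert truth["boundary_status"] == "both"
        assert bool(calls) is called

    @pytest.mark.parametrize("n_pe,called", [(2, False), (3, True)])
    def test_one_boundary_needs_three_partner_ends(self, tmp_path, n_pe, called):
        calls, truth = self._world_calls(
            tmp_path, sim.JunctionSpec(exon5=2, exon3=2, offset5=9), n_pe
        )
        assert truth["boundary_status"] == "one"
        assert bool(calls) is called

    def test_no_boundary_rejected_without_whitelist(self, tmp_path):
        calls, truth = self._world_calls(
            tmp_path, sim.JunctionSpec(exon5=2, exon3=2, offset5=9, offset3=8), 10,
            n_umis=10, n_reads=10,
        )
        assert truth["boundary_status"] == "none"
        assert calls == []
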