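"""Repeat rescue, targeted intragenic events, panel restriction, blacklist."""

import pytest

from anchorfuse import RunConfig
from anchorfuse import simulate as sim
from anchorfuse.annotator import load_models
from anchorfuse.io_dedup import dedup_by_umi_ls, read_sam
from anchorfuse.pipeline import build_layouts, call_fusions
from anchorfuse.special_modes import (
    BlacklistEntry,
    RepeatRegion,
    apply_blacklist,
    load_bed,
    parse_target_pattern,
    pseudogene_remap,
)
from anchorfuse.split_transform import AlignedSegment

from conftest import run_world


def seg(mapq=0, chrom="c1", rs=1000, re_=1099):
    return AlignedSegment("r", chrom, rs, re_, "+", mapq, 1, 100, cigar="100M")


class TestPseudogeneRemap:
    REGION = [RepeatRegion("cR", 5000, 9000, "DUX4_like")]

    def test_mapq0_with_xa_hit_remapped_into_region(self):
        xa = [("cX", 100, "+", "100M"), ("cR", 6000, "+", "100M")]
        out = pseudogene_remap(seg(mapq=0), xa, self.REGION, 100)
        assert (out.chrom, out.ref_start, out.remapped) == ("cR", 6000, True)

    def test_mapq0_no_overlap_unchanged(self):
        out = pseudogene_remap(seg(mapq=0), [("cX", 100, "+", "100M")], self.REGION, 100)
        assert (out.chrom, out.remapped) == ("c1", False)

    def test_high_mapq_inside_region_untouched(self):
        out = pseudogene_remap(seg(mapq=60, chrom="cR", rs=6000, re_=6099), [], self.REGION, 100)
        assert not out.remapped

    def test_primary_overlap_takes_priority_over_xa(self):
        s = seg(mapq=0, chrom="cR", rs=5500, re_=5599)
        out = pseudogene_remap(s, [("cR", 8000, "+", "100M")], self.REGION, 100)
        assert (out.ref_start, out.remapped) == (5500, True)


@pytest.fixture(scope="module")
def repeat_world(tmp_path_factory):
    """A partner gene fused into a gene whose cassette exists in 3 decoy
    copies; the anchored side maps MAPQ-0 to a decoy with XA alternatives."""
    d = tmp_path_factory.mktemp("repeat_world")
    specs = [(sim.GeneSpec("PART"), "chrA"), (sim.GeneSpec("RPT"), "chrB")]
    ref = sim.build_reference(specs, 21, repeat_of={"RPT": 3})
    sc = sim.FusionScenario(name="pg", gene5="PART", gene3="RPT", decoy_supplementary=True)
    records, truth = sim.emit_reads(sc, ref, 22)
    sam = sim.write_sam(records, ref, d / "a.sam")
    refflat = ref.write_refflat(d / "m.refflat")
    m = ref.genes["RPT"].model
    bed = d / "pseudogene.bed"
    bed.write_text(f"{m.chrom}\t{m.tx_start - 1}\t{m.tx_end}\tRPT_region\n")
    return {"sam": str(sam), "refflat": str(refflat), "bed": str(bed), "truth": truth}


class TestPseudogeneMode:
    def _junctions(self, world, enabled):
        calls, _, _ = run_world(
            world["sam"], world["refflat"],
            pseudogene_mode=enabled, pseudogene_bed=world["bed"] if enabled else "",
        )
        return {(c.fusion_name, c.junction) for c in calls}

    def test_planted_fusion_only_with_mode_enabled(self, repeat_world):
        t = repeat_world["truth"]["junction"]
        planted = ("PART::RPT", f"{t['chrom5']}:{t['bp5']}_{t['chrom3']}:{t['bp3']}")
        assert planted not in self._junctions(repeat_world, False)
        assert planted in self._junctions(repeat_world, True)

    def test_mode_is_noop_on_repeat_free_fixture(self, std_world):
        base, _, _ = run_world(std_world["sam"], std_world["refflat"])
        bed = std_world["dir"] / "empty_far.bed"
        bed.write_text("chrZ\t0\t1000\tunused\n")
        with_mode, _, _ = run_world(
            std_world["sam"], std_world["refflat"],
            pseudogene_mode=True, pseudogene_bed=str(bed),
        )
        assert [(c.fusion_name, c.junction) for c in base] == [
            (c.fusion_name, c.junction) for c in with_mode
        ]


@pytest.fixture(scope="module")
def target_world(tmp_path_factory):
    """One 8-exon panel gene with two planted intragenic events:
    an exon-skip junction (donor ex13-like) and a multi-exon deletion."""
    d = tmp_path_factory.mktemp("target_world")
    specs = [(sim.GeneSpec("PANEL1", n_exons=8), "chrT")]
    ref = sim.build_reference(specs, 31)
    records = []
    skip = sim.FusionScenario(  # exon 3 skipped: donor ex2 -> acceptor ex4
        name="sk", gene5="PANEL1", gene3="PANEL1",
        junction=sim.JunctionSpec(exon5=2, exon3=4),
    )
    deletion = sim.FusionScenario(  # exons 2-5 deleted: donor ex1 -> acceptor ex6
        name="dl", gene5="PANEL1", gene3="PANEL1",
        junction=sim.JunctionSpec(exon5=1, exon3=6), min_split=40,
    )
    truths = {}
    for i, sc in enumerate((skip, deletion)):
        recs, truth = sim.emit_reads(sc, ref, 32 + i)
        records.extend(recs)
        truths[sc.name] = truth
    sam = sim.write_sam(records, ref, d / "a.sam")
    refflat = ref.write_refflat(d / "m.refflat")
    targets = d / "targets.tsv"
    targets.write_text(
        "name\tgene\tpattern\tmin_partner_ends\n"
        "EX3_SKIP\tPANEL1\texon:2-4\t3\n"
        "EX2_5_DEL\tPANEL1\texon:1-6\t3\n"
    )
    return {"sam": str(sam), "refflat": str(refflat), "targets": str(targets),
            "truths": truths}


class TestTargetMode:
    def test_events_reported_only_in_target_mode_with_names(self, target_world):
        off, _, _ = run_world(target_world["sam"], target_world["refflat"])
        assert off == []  # same-gene sub-threshold junctions: silent by default
        on, _, _ = run_world(
            target_world["sam"], target_world["refflat"],
            target_mode=True, targets_path=target_world["targets"],
        )
        assert {c.fusion_name for c in on} == {"EX3_SKIP", "EX2_5_DEL"}
        assert all("targeted" in c.mode_flags for c in on)
        for c in on:
            name = {"EX3_SKIP": "sk", "EX2_5_DEL": "dl"}[c.fusion_name]
            t = target_world["truths"][name]["junction"]
            assert c.junction == f"{t['chrom5']}:{t['bp5']}_{t['chrom3']}:{t['bp3']}"

    def test_event_below_partner_end_threshold_not_called(self, tmp_path):
        specs = [(sim.GeneSpec("PANEL1", n_exons=8), "chrT")]
        ref = sim.build_reference(specs, 31)
        sc = sim.FusionScenario(
            name="sk", gene5="PANEL1", gene3="PANEL1",
            junction=sim.JunctionSpec(exon5=2, exon3=4),
            n_reads=2, n_umis=2, n_partner_ends=2,
        )
        records, _ = sim.emit_reads(sc, ref, 33)
        sam = sim.write_sam(records, ref, tmp_path / "a.sam")
        refflat = ref.write_refflat(tmp_path / "m.refflat")
        targets = tmp_path / "targets.tsv"
        targets.write_text("name\tgene\tpattern\nEX3_SKIP\tPANEL1\texon:2-4\n")
        calls, _, _ = run_world(
            str(sam), str(refflat), target_mode=True, targets_path=str(targets)
        )
        assert calls == []

    def test_unknown_gene_in_pattern_is_hard_error(self, target_world):
        from anchorfuse.special_modes import load_targets

        idx = load_models(target_world["refflat"])
        bad = target_world["targets"].replace("targets.tsv", "bad.tsv")
        with open(bad, "w") as fh:
            fh.write("name\tgene\tpattern\nX\tNOSUCH\texon:1-2\n")
        with pytest.raises(ValueError):
            load_targets(bad, idx)


class TestPanelRestriction:
    def test_panel_keeps_only_touching_calls(self, std_world):
        m = load_models(std_world["refflat"]).canonical["GENE3P"]
        panel = std_world["dir"] / "panel.bed"
        panel.write_text(f"{m.chrom}\t{m.tx_start - 1}\t{m.tx_end}\tGENE3P\n")
        calls, _, _ = run_world(
            std_world["sam"], std_world["refflat"],
            target_mode=True, panel_bed=str(panel),
        )
        assert len(calls) == 1  # the planted fusion touches the panel gene
        off_panel = std_world["dir"] / "panel_off.bed"
        off_panel.write_text("chrZ\t0\t100\tOTHER\n")
        calls2, _, _ = run_world(
            std_world["sam"], std_world["refflat"],
            target_mode=True, panel_bed=str(off_panel),
        )
        assert calls2 == []


class TestBlacklist:
    def test_gene_pair_entry_removes_call(self, std_calls):
        calls = std_calls["calls"]
        out = apply_blacklist(list(calls), [BlacklistEntry("GENE5P", "GENE3P")])
        assert out == []

    def test_coordinate_entry_matches_exact_junction_only(self, std_calls):
        (call,) = std_calls["calls"]
        exact = BlacklistEntry("GENE5P", "GENE3P", call.bp5.chrom, call.bp5.pos,
                               call.bp3.chrom, call.bp3.pos)
        other = BlacklistEntry("GENE5P", "GENE3P", call.bp5.chrom, call.bp5.pos + 1,
                               call.bp3.chrom, call.bp3.pos)
        assert apply_blacklist([call], [other]) == [call]
        assert apply_blacklist([call], [exact]) == []

    def test_empty_blacklist_is_identity(self, std_calls):
        assert apply_blacklist(std_calls["calls"], []) == std_calls["calls"]


class TestBedLoading:
    def test_bed_converted_to_one_based_inclusive(self, tmp_path):
        p = tmp_path / "r.bed"
        p.write_text("chr1\t999\t2000\tregionA\nchr2\t0\t10\n")
        regions = load_bed(str(p))
        assert (regions[0].start, regions[0].end, regions[0].label) == (1000, 2000, "regionA")
        assert (regions[1].start, regions[1].end) == (1, 10)
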