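"""Shared fixtures: small synthetic fusion worlds built fresh per session."""

from __future__ import annotations

import pytest

from anchorfuse import RunConfig
from anchorfuse import simulate as sim
from anchorfuse.annotator import load_models
from anchorfuse.io_dedup import dedup_by_umi_ls, read_sam
from anchorfuse.pipeline import build_layouts, call_fusions


@pytest.fixture(scope="session")
def std_world(tmp_path_factory):
    """Two genes on separate contigs with a planted exon-boundary fusion:
    20 reads, 12 molecules, 5 partner ends."""
    d = tmp_path_factory.mktemp("std_world")
    ref, records, truth = sim.standard_world(7)
    sam = sim.write_sam(records, ref, d / "aligned.sam")
    refflat = ref.write_refflat(d / "models.refflat")
    gtf = ref.write_gtf(d / "models.gtf")
    fasta = ref.write_fasta(d / "genome.fa")
    return {
        "dir": d,
        "ref": ref,
        "records": records,
        "truth": truth,
        "sam": str(sam),
        "refflat": str(refflat),
        "gtf": str(gtf),
        "fasta": str(fasta),
    }


@pytest.fixture(scope="session")
def std_index(std_world):
    return load_models(std_world["refflat"])


def run_world(sam, models_path, **cfg_kwargs):
    """Helper: ingest a SAM and call fusions with the given config."""
    from anchorfuse.special_modes import load_bed, load_blacklist, load_targets

    cfg = RunConfig(models_path=models_path, **cfg_kwargs)
    index = load_models(models_path)
    records = read_sam(sam, cfg.umi_regex, cfg.ligation_end)
    consolidated = dedup_by_umi_ls(records, cfg.dedup)
    repeat_regions = load_bed(cfg.pseudogene_bed) if cfg.pseudogene_bed else []
    layouts = build_layouts(consolidated, cfg, repeat_regions)
    calls, kept = call_fusions(
        layouts,
        index,
        cfg,
        targets=load_targets(cfg.targets_path, index) if cfg.targets_path else None,
        panel=load_bed(cfg.panel_bed) if cfg.panel_bed else None,
        blacklist=load_blacklist(cfg.blacklist_path) if cfg.blacklist_path else None,
    )
    return calls, kept, consolidated


@pytest.fixture(scope="session")
def std_calls(std_world):
    calls, kept, consolidated = run_world(std_world["sam"], std_world["refflat"])
    return {"calls": calls, "kept": kept, "consolidated": consolidated}
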