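"""End-to-end orchestration: aligned SAM/BAM in, fusion summary out.

Stage order: ingest + dedup -> segment expansion (+ repeat rescue) ->
layout ordering -> candidate detection -> end-role assignment + initial
filters -> exact-junction grouping -> annotation + boundary-aware
thresholds -> target-mode additions / panel restriction -> blacklist ->
summary, supporting-read extraction, run metadata.  Starting from an
already-aligned file is the normal ("kickstart") entry point; running the
aligner is out of scope.
"""

from __future__ import annotations

import json
import logging
import time
from pathlib import Path

import pandas as pd

from . import __version__
from .annotator import AnnotatedCall, GeneModelIndex, aggregate_and_threshold, load_models
from .config import RunConfig
from .io_dedup import RawRecord, dedup_by_umi_ls, expand_alignments, read_sam
from .junction_core import (
    assign_end_roles,
    detect_candidates,
    group_precalls,
    initial_filter,
)
from .reporting import extract_supporting_reads, write_summary
from .special_modes import (
    apply_blacklist,
    detect_target_events,
    load_bed,
    load_blacklist,
    load_targets,
    panel_restrict,
    pseudogene_remap,
)
from .split_transform import SplitReadLayout, order_segments

log = logging.getLogger(__name__)


def build_layouts(
    records: list[RawRecord], cfg: RunConfig, repeat_regions=None
) -> list[SplitReadLayout]:
    """Expand consolidated records into ordered split-read layouts."""
    layouts = []
    for rec in records:
        segments = expand_alignments(rec, cfg.max_smoothed_indel)
        if len(segments) < 2:
            continue
        if cfg.pseudogene_mode and repeat_regions:
            segments = [
                pseudogene_remap(
                    seg,
                    rec.xa_by_locus.get((seg.chrom, seg.ref_start), rec.xa_entries),
                    repeat_regions,
                    rec.read_length,
                    cfg.max_smoothed_indel,
                )
                for seg in segments
            ]
        layouts.append(
            order_segments(
                segments,
                read_id=rec.read_id,
                umi=rec.umi,
                ls=rec.ls,
                read_length=rec.read_length,
                is_read1=rec.is_read1,
                sequence=rec.sequence,
                qualities=rec.qualities,
            )
        )
    return layouts


def call_fusions(
    layouts: list[SplitReadLayout],
    index: GeneModelIndex,
    cfg: RunConfig,
    targets=None,
    panel=None,
    blacklist=None,
) -> tuple[list[AnnotatedCall], list]:
    """Core calling on prepared layouts; returns (calls, surviving candidates)."""
    mode = "anchored" if cfg.anchored else "plain"
    cands = []
    for layout in layouts:
        for cand in detect_candidates(layout, cfg.max_intron_distance, cfg.allow_inversion):
            cands.append(assign_end_roles(cand, layout, mode))
    kept = initial_filter(cands, cfg)
    calls = aggregate_and_threshold(group_precalls(kept), index, cfg)
    if cfg.target_mode:
        if targets:
            calls.extend(detect_target_events(layouts, targets, index, cfg))
        if panel:
            calls = panel_restrict(calls, panel)
    calls = apply_blacklist(calls, blacklist or [])
    return calls, kept


def _channel_frames(kept) -> dict[str, pd.DataFrame]:
    """Materialize the left / right / mid intermediate channels."""
    left_rows, right_rows, mid_rows = [], [], []
    for c in kept:
        base = {"read_id": c.read_id, "umi": c.umi}
        left_rows.append(
            {**base, "chrom": c.left.chrom, "ref_start": c.left.ref_start,
             "ref_end": c.left.ref_end, "strand": c.left.strand,
             "query_start": c.left.query_start, "query_end": c.left.query_end,
             "bp": c.bp_left.pos}
        )
        right_rows.append(
            {**base, "chrom": c.right.chrom, "ref_start": c.right.ref_start,
             "ref_end": c.right.ref_end, "strand": c.right.strand,
             "query_start": c.right.query_start, "query_end": c.right.query_end,
             "bp": c.bp_right.pos}
        )
        for m in c.mid_segments:
            mid_rows.append(
                {**base, "chrom": m.chrom, "ref_start": m.ref_start,
                 "ref_end": m.ref_end, "strand": m.strand,
                 "query_start": m.query_start, "query_end": m.query_end}
            )
    cols_lr = ["read_id", "umi", "chrom", "ref_start", "ref_end", "strand",
               "query_start", "query_end", "bp"]
    cols_mid = cols_lr[:-1]
    return {
        "left": pd.DataFrame(left_rows, columns=cols_lr),
        "right": pd.DataFrame(right_rows, columns=cols_lr),
        "mid": pd.DataFrame(mid_rows, columns=cols_mid),
    }


def run(input_path: str, cfg: RunConfig, outdir: str) -> list[AnnotatedCall]:
    """Run the full pipeline and write the output directory.

    Writes summary.tsv, left/right/mid.tsv, supporting_reads/*, and
    run_meta.json.  Succeeds (and writes a header-only summary) on inputs
    with zero split reads.
    """
    t0 = time.time()
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    index = load_models(cfg.models_path)
    repeat_regions = load_bed(cfg.pseudogene_bed) if cfg.pseudogene_bed else []
    panel = load_bed(cfg.panel_bed) if cfg.panel_bed else []
    targets = load_targets(cfg.targets_path, index) if cfg.targets_path else []
    blacklist = load_blacklist(cfg.blacklist_path) if cfg.blacklist_path else []

    records = read_sam(input_path, cfg.umi_regex, cfg.ligation_end)
    log.info("loaded %d primary records", len(records))
    consolidated = dedup_by_umi_ls(records, cfg.dedup)
    log.info("consolidated to %d UMI-LS representatives", len(consolidated))
    layouts = build_layouts(consolidated, cfg, repeat_regions)
    log.info("%d split-read layouts", len(layouts))
    calls, kept = call_fusions(layouts, index, cfg, targets, panel, blacklist)
    log.info("%d fusion calls", len(calls))

    for name, df in _channel_frames(kept).items():
        df.sort_values(list(df.columns), kind="mergesort").to_csv(
            out / f"{name}.tsv", sep="\t", index=False
        )
    summary = write_summary(calls, out / "summary.tsv", cfg.sample_id)

    by_id = {r.read_id: r for r in consolidated}
    reads_dir = out / "supporting_reads"
    reads_dir.mkdir(exist_ok=True)
    for i, call in enumerate(calls):
        prefix = reads_dir / f"{call.fusion_name.replace('::', '_')}_{i}"
        extract_supporting_reads(call, by_id, str(prefix), cfg.n_extract_reads, cfg.seed)

    meta = {
        "version": __version__,
        "config": cfg.to_dict(),
        "input": str(input_path),
        "n_input_records": len(records),
        "n_consolidated": len(consolidated),
        "n_layouts": len(layouts),
        "n_calls": len(calls),
        "runtime_s": round(time.time() - t0, 3),
    }
    with open(out / "run_meta.json", "w") as fh:
        json.dump(meta, fh, indent=1, sort_keys=True)
    return calls
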