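"""Final fusion summary, supporting-read extraction, subclone counting, and
the exact test used for heterogeneity comparisons.

A "fusion-junction-defined subclone" is a tumor subpopulation distinguished
by a distinct exact junction for the same gene pair: because junctions are
grouped without any fuzz window, each distinct junction string in the
summary is one subclone.  Comparing how often tumors of two variant classes
carry multiple subclones is a 2x2 contingency problem, handled by a
two-sided Fisher's exact test computed with exact rational arithmetic (the
two-sided p is the sum of hypergeometric probabilities of all tables with
the same margins that are no more probable than the observed one).
"""

from __future__ import annotations

import random
import zlib
from dataclasses import dataclass
from fractions import Fraction
from math import comb
from pathlib import Path

import pandas as pd
import pysam

from .annotator import AnnotatedCall
from .io_dedup import RawRecord

SUMMARY_COLUMNS = [
    "sample_id",
    "fusion_name",
    "junction",
    "n_umi_reads",
    "n_partner_ends",
    "frame_status",
    "boundary_status",
    "transcript5",
    "exon5",
    "cdna5",
    "transcript3",
    "exon3",
    "cdna3",
    "mode_flags",
]


@dataclass(frozen=True)
class ContingencyTable2x2:
    a: int
    b: int
    c: int
    d: int

    def __post_init__(self):
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("contingency cells must be non-negative")


def fisher_exact_two_sided(t: ContingencyTable2x2) -> float:
    """Two-sided Fisher's exact p via exact hypergeometric enumeration.

    All tables with the observed margins are enumerated; tables whose exact
    rational probability is <= that of the observed table contribute to p.
    Rational arithmetic makes the <= comparison exact (no float ties).
    """
    r1, r2 = t.a + t.b, t.c + t.d
    c1 = t.a + t.c
    n = r1 + r2
    denom = comb(n, c1)

    def prob(x: int) -> Fraction:
        return Fraction(comb(r1, x) * comb(r2, c1 - x), denom)

    p_obs = prob(t.a)
    lo, hi = max(0, c1 - r2), min(r1, c1)
    p = sum(prob(x) for x in range(lo, hi + 1) if prob(x) <= p_obs)
    return float(p)


def calls_to_frame(calls: list[AnnotatedCall], sample_id: str) -> pd.DataFrame:
    rows = []
    for c in calls:
        rows.append(
            {
                "sample_id": sample_id,
                "fusion_name": c.fusion_name,
                "junction": c.junction,
                "n_umi_reads": c.n_umi_reads,
                "n_partner_ends": c.n_partner_ends,
                "frame_status": c.frame_status,
                "boundary_status": c.boundary_status,
                "transcript5": c.ann5.transcript_id,
                "exon5": c.ann5.region,
                "cdna5": c.ann5.cdna_pos if c.ann5.cdna_pos is not None else "NA",
                "transcript3": c.ann3.transcript_id,
                "exon3": c.ann3.region,
                "cdna3": c.ann3.cdna_pos if c.ann3.cdna_pos is not None else "NA",
                "mode_flags": ";".join(c.mode_flags) or ".",
            }
        )
    df = pd.DataFrame(rows, columns=SUMMARY_COLUMNS)
    if len(df):
        df = df.sort_values(
            ["fusion_name", "n_umi_reads", "junction"],
            ascending=[True, False, True],
            kind="mergesort",
        ).reset_index(drop=True)
    return df


def write_summary(calls: list[AnnotatedCall], path: str, sample_id: str = "sample") -> pd.DataFrame:
    """Write the final fusion summary TSV (deterministic order; header always)."""
    df = calls_to_frame(calls, sample_id)
    df.to_csv(path, sep="\t", index=False)
    return df


def count_subclones(summary: pd.DataFrame, sample_id: str, fusion_name: str) -> int:
    """Number of distinct exact junctions for one gene pair in one sample."""
    sel = summary[
        (summary["sample_id"] == sample_id) & (summary["fusion_name"] == fusion_name)
    ]
    return sel["junction"].nunique()


def extract_supporting_reads(
    call: AnnotatedCall,
    records: dict[str, RawRecord],
    out_prefix: str,
    n: int = 10,
    seed: int = 0,
) -> list[str]:
    """Randomly sample up to ``n`` supporting reads; write FASTQ + mini-SAM.

    Sampling is without replacement from the sorted supporting-read ids
    with a run-seed-derived generator, so repeated runs extract the same
    reads.  The mini-SAM is genome-browser-loadable evidence for manual
    review.
    """
    ids = sorted(call.supporting_read_ids)
    # per-junction stream derived stably from the run seed (str hash is
    # process-salted, so use crc32 instead)
    rng = random.Random((seed * 2654435761 + zlib.crc32(call.junction.encode())) & 0x7FFFFFFF)
    chosen = sorted(rng.sample(ids, min(n, len(ids))))
    out_prefix = str(out_prefix)
    chrom_max: dict[str, int] = {}
    recs = [records[i] for i in chosen if i in records]
    for r in recs:
        chrom_max[r.chrom] = max(chrom_max.get(r.chrom, 0), r.pos + len(r.sequence) + 1000)
        for chrom, pos, *_ in r.sa_entries:
            chrom_max[chrom] = max(chrom_max.get(chrom, 0), pos + len(r.sequence) + 1000)
    with open(out_prefix + ".fastq", "w") as fq:
        for r in recs:
            qual = r.qualities or "I" * len(r.sequence)
            fq.write(f"@{r.read_id}\n{r.sequence}\n+\n{qual}\n")
    header = {
        "HD": {"VN": "1.6", "SO": "unsorted"},
        "SQ": [{"SN": c, "LN": ln} for c, ln in sorted(chrom_max.items())],
        "CO": [f"anchorfuse supporting reads; seed={seed}; junction={call.junction}"],
    }
    with pysam.AlignmentFile(out_prefix + ".sam", "w", header=header) as out:
        for r in recs:
            a = pysam.AlignedSegment(out.header)
            a.query_name = r.read_id
            a.flag = 16 if r.flag_strand == "-" else 0
            a.reference_name = r.chrom
            a.reference_start = r.pos - 1
            a.mapping_quality = r.mapq
            a.cigarstring = r.cigar
            a.query_sequence = r.sequence or None
            if r.sa_entries:
                a.set_tag(
                    "SA",
                    "".join(
                        f"{c},{p},{s},{cg},{mq},0;" for c, p, s, cg, mq in r.sa_entries
                    ),
                )
            out.write(a)
    return chosen
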