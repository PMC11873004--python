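"""Run configuration: filter thresholds, mode flags, and resource paths."""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import yaml


@dataclass
class RunConfig:
    """All tunable parameters of a fusion-calling run.

    Length/count parameters are in bases/reads; ``max_intron_distance`` is
    the largest same-chromosome separation still attributable to normal
    splicing (the largest known intron is just under 750 kb).
    """

    # junction detection
    max_intron_distance: int = 750_000
    allow_inversion: bool = True
    # initial filters
    min_map_len_ligation: int = 25
    min_map_len_anchored: int = 18
    min_map_len_plain: int = 18
    max_overlap: int = 6
    max_gap: int = 5
    min_exclusive_len: int = 15
    # annotation
    annotation_shift: int = 6
    boundary_tolerance: int = 0
    minPartnerEnds_BothExonJunction: int = 1
    minPartnerEnds_OneExonJunction: int = 3
    # CIGAR handling
    max_smoothed_indel: int = 1
    # dedup
    dedup: str = "umi_ls"  # umi_ls | ls | off
    umi_regex: str = r"(?:_|:)UMI[:_]?([ACGTN]+)$"
    ligation_end: str = "read1_start"
    # modes
    anchored: bool = True
    target_mode: bool = False
    pseudogene_mode: bool = False
    target_window: int = 5
    # reporting
    n_extract_reads: int = 10
    seed: int = 0
    sample_id: str = "sample"
    # resources
    models_path: str = ""
    panel_bed: str = ""
    pseudogene_bed: str = ""
    blacklist_path: str = ""
    targets_path: str = ""

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_yaml(cls, path: str, **overrides) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        data.update({k: v for k, v in overrides.items() if v is not None})
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)
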