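"""Pipeline configuration.

Every tunable of both branches lives in one dataclass so that a run manifest
can snapshot it and a YAML file or CLI flags can override any field.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict, replace
from pathlib import Path

import yaml


@dataclass
class SearchParams:
    """Thresholds of the built-in seed-and-extend search engine.

    Significance is a raw score plus identity floor, not an E-value: the
    engine is meant to be deterministic and input-size independent.
    """

    nt_seed_len: int = 11
    aa_seed_len: int = 4
    aa_seed_self_score_min: int = 12  # BLOSUM62 self-score floor for aa seeds
    aa_two_hit: bool = True          # require >=2 seeds on a diagonal run (aa modes)
    band: int = 31                   # adaptive band width for gapped extension
    xdrop_ungapped_nt: int = 20
    xdrop_ungapped_aa: int = 16
    xdrop_gapped_nt: int = 30
    xdrop_gapped_aa: int = 24
    ungapped_trigger_nt: int = 22
    ungapped_trigger_aa: int = 20
    nt_match: int = 1
    nt_mismatch: int = -2
    nt_gap_open: int = -5
    nt_gap_extend: int = -2
    aa_gap_open: int = -11
    aa_gap_extend: int = -1
    min_score_nt: int = 40
    min_score_aa: int = 50
    min_identity_nt: float = 60.0
    min_identity_aa: float = 30.0
    min_aln_len: int = 1


@dataclass
class PipelineConfig:
    """All shipped defaults of the two-branch pipeline."""

    # Branch A step 1
    extension_bp: int = 2000          # option -X
    merge_gap_bp: int = 5000          # loci separated by <= this are merged
    # Branch A step 2
    hsp_min: int = 5                  # option -hsp: min member spans per group
    group_cap: int = 20               # max members aligned per consensus
    subgenome_identity_pct: float = 85.0
    subgenome_min_hsp_len: int = 100
    # Branch A step 3
    cluster_S_pct: float = 90.0       # option -S
    cluster_L_frac: float = 0.9       # option -L
    cluster_L_mode: str = "both"      # both|either coverage condition
    filter_chimeras: bool = True      # option -ch
    blastclust_supplementation: bool = False  # option -bl
    concatemer_min_len: int = 2000
    concatemer_min_hit: int = 1000
    concatemer_min_identity: float = 90.0
    # Branch A step 4
    mask_min_identity: float = 70.0
    mask_min_len: int = 80
    # Branch B
    rt_flank_bp: int = 120
    min_protein_aa: int = 200
    rt_cluster_identity_pct: float = 80.0
    trim_rounds_initial: int = 2
    trim_rounds_final: int = 4
    support_threshold: float = 70.0
    bootstrap_replicates: int = 100
    # Phylo / alignment machinery
    trim_col_gap_max: float = 0.8
    trim_seq_occupancy_min: float = 0.5
    block_min_len: int = 5
    block_col_gap_max: float = 0.5
    block_col_conservation_min: float = 0.5
    # Global
    seed: int = 1
    search: SearchParams = field(default_factory=SearchParams)

    # option-name aliases mirroring the tool's published flags
    _ALIASES = {
        "X": "extension_bp",
        "hsp": "hsp_min",
        "S": "cluster_S_pct",
        "L": "cluster_L_frac",
        "ch": "filter_chimeras",
        "bl": "blastclust_supplementation",
    }

    def to_dict(self) -> dict:
        return asdict(self)

    def with_overrides(self, **kwargs) -> "PipelineConfig":
        search_kwargs = {}
        own = {}
        for key, val in kwargs.items():
            key = self._ALIASES.get(key, key)
            if hasattr(SearchParams, key) and not hasattr(type(self), key):
                search_kwargs[key] = val
            else:
                own[key] = val
        cfg = replace(self, **own)
        if search_kwargs:
            cfg.search = replace(cfg.search, **search_kwargs)
        return cfg

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        search = SearchParams(**data.pop("search", {}))
        cfg = cls(**data)
        cfg.search = search
        return cfg
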