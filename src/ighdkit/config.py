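"""Run configuration: YAML file plus flag overrides, strictly validated."""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml


@dataclass
class RunConfig:
    input: str | None = None
    format: str = "fasta"
    gene_table: str | None = None
    out_dir: str = "out"
    log_level: str = "INFO"
    seed: int = 0
    scan: dict = field(default_factory=dict)  # max_heptamer_mm, max_nonamer_mm
    calling: dict = field(default_factory=dict)  # min/max_coding, max_intergene_gap
    align: dict = field(default_factory=dict)  # match, mismatch, gap_open, gap_extend
    fusion: dict = field(default_factory=dict)  # weights, terminus_slack, ...
    repeats: dict = field(default_factory=dict)  # min_unit, max_unit, max_mm_per_copy
    sim: dict = field(default_factory=dict)  # SimParams overrides

    _ALLOWED_SUBKEYS = {
        "scan": {"max_heptamer_mm", "max_nonamer_mm"},
        "calling": {"min_coding", "max_coding", "max_intergene_gap", "first_cluster_id"},
        "align": {"match", "mismatch", "gap_open", "gap_extend"},
        "fusion": {"weights", "terminus_slack", "breakpoint_pad"},
        "repeats": {"min_unit", "max_unit", "max_mm_per_copy"},
        "sim": {
            "n_genes",
            "n_clusters",
            "mu",
            "expansion_geom_p",
            "junction_in_repeat_p",
            "protect_rss",
            "seed",
        },
    }

    def __post_init__(self) -> None:
        for section, allowed in self._ALLOWED_SUBKEYS.items():
            extra = set(getattr(self, section)) - allowed
            if extra:
                raise ValueError(f"unknown keys in {section!r}: {sorted(extra)}")
        if self.format not in ("fasta", "genbank"):
            raise ValueError(f"unsupported input format {self.format!r}")

    def validate_paths(self) -> None:
        for attr in ("input", "gene_table"):
            p = getattr(self, attr)
            if p is not None and not Path(p).exists():
                raise FileNotFoundError(f"{attr} path does not exist: {p}")

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        if not isinstance(data, dict):
            raise ValueError(f"config file {path} must contain a mapping")
        known = set(cls.__dataclass_fields__) - {"_ALLOWED_SUBKEYS"}
        extra = set(data) - known
        if extra:
            raise ValueError(f"unknown config keys: {sorted(extra)}")
        data.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**data)

    def digest(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha1(payload.encode()).hexdigest()[:12]
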