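"""Pipeline configuration: defaults, YAML loading and validation."""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path

import yaml


@dataclass
class PipelineConfig:
    # input paths (None disables the dependent stage)
    fragments: str = None
    genes: str = None
    cres: str = None
    tads: str = None
    blacklist: str = None
    sv_table: str = None
    cn_table: str = None
    gene_sets: str = None
    clone_table: str = None
    ne_labels: str = None
    # thresholds
    mapq_min: int = 10
    fdr: float = 0.1
    ne_threshold: float = 0.9
    cf_mode_switch: float = 0.1
    scan_radius: int = 1_000_000
    window: int = 50_000
    step: int = 10_000
    n_perm: int = 1_000
    min_fragments_state: int = 20
    bin_size: int = 10
    seed: int = 0
    out: str = "scnova_out"

    def validate(self) -> list:
        errors = []
        if self.mapq_min < 0:
            errors.append("mapq_min: must be >= 0")
        for name in ("fdr", "ne_threshold", "cf_mode_switch"):
            v = getattr(self, name)
            if not (0.0 < v <= 1.0):
                errors.append(f"{name}: must lie in (0, 1], got {v}")
        for name in ("scan_radius", "window", "step", "n_perm", "min_fragments_state", "bin_size"):
            if getattr(self, name) < 1:
                errors.append(f"{name}: must be >= 1")
        if self.window < self.step:
            errors.append("window: must be >= step")
        for name in ("fragments", "genes", "cres", "tads", "blacklist", "sv_table", "cn_table", "gene_sets", "clone_table", "ne_labels"):
            p = getattr(self, name)
            if p is not None and not Path(p).exists():
                errors.append(f"{name}: path does not exist: {p}")
        return errors

    def to_dict(self) -> dict:
        return asdict(self)


def validate_config(path) -> PipelineConfig:
    """Load and validate a YAML pipeline config; raise with all violations listed.

    Unknown keys are warned about and ignored; an empty file yields the full
    default configuration.
    """
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise ValueError(f"{path}: config must be a mapping")
    known = set(PipelineConfig.__dataclass_fields__)
    unknown = sorted(set(raw) - known)
    if unknown:
        warnings.warn(f"{path}: unknown config keys ignored: {unknown}")
    cfg = PipelineConfig(**{k: v for k, v in raw.items() if k in known})
    errors = cfg.validate()
    if errors:
        raise ValueError(f"{path}: invalid configuration:\n  " + "\n  ".join(errors))
    return cfg
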