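"""Run configuration: a flat key-value file with CLI override precedence.

Every default below is echoed into the run manifest, so a finished run
records exactly which thresholds produced it.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from pathlib import Path

import yaml


@dataclass
class PipelineConfig:
    # motif discovery
    max_motifs: int = 10
    min_width: int = 6
    max_width: int = 14
    sig_threshold: float = 0.05
    n_shuffles: int = 20
    max_seed_candidates: int = 1000
    n_refine: int = 50
    uniform_background: bool = False
    # hit extension / alignment
    flank: int = 5
    occupancy: float = 0.8
    # profile HMM iteration
    match_threshold: float = 0.5
    iter_evalue: float = 1.0
    final_evalue: float = 1.0
    max_iter: int = 20
    n_calibrate: int = 200
    extend_each_iteration: bool = False
    # coevolution
    k_clusters: int = 2
    min_hits: int = 1
    include_unduplicated: bool = False
    # global
    seed: int = 1

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def load_config(path: str | Path | None = None, **overrides) -> PipelineConfig:
    """Config from an optional flat YAML file, then keyword overrides."""
    values: dict = {}
    if path is not None:
        loaded = yaml.safe_load(Path(path).read_text()) or {}
        if not isinstance(loaded, dict):
            raise ValueError("config file must be a flat key-value mapping")
        values.update(loaded)
    values.update({k: v for k, v in overrides.items() if v is not None})
    known = {f.name for f in dataclasses.fields(PipelineConfig)}
    unknown = set(values) - known
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    return PipelineConfig(**values)
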