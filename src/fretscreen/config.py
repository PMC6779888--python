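"""Validated run configuration for simulation and analysis commands.

A single JSON (or YAML) document describes the whole screen: the library block
(clone diversity, insert length, spikes), the simulation block (MOI model,
co-culture gate probabilities, sequencer), the pipeline block (merge / QC /
cluster parameters) and the enrichment block (k·σ rule).  Unknown keys are
rejected; the seed is mandatory because every simulation command must be
reproducible.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Literal, Optional, Union

import yaml
from pydantic import BaseModel, ConfigDict, Field, ValidationError

from .simulate import DEFAULT_FLANK3, DEFAULT_FLANK5

__all__ = ["ScreenConfig", "LibraryConfig", "SpikeConfig", "SimulationConfig",
           "PipelineConfigBlock", "EnrichmentConfig", "load_config",
           "ConfigError", "DataError"]


class ConfigError(Exception):
    """Invalid configuration (CLI exit code 2)."""


class DataError(Exception):
    """Invalid or empty input data (CLI exit code 3)."""


class _Block(BaseModel):
    model_config = ConfigDict(extra="forbid")


class SpikeConfig(_Block):
    id: str = "spike"
    fraction: float = Field(gt=0, lt=1)
    mode: Literal["cell", "dna"] = "cell"
    epitope: str = "SIINFEKL"
    total_len_aa: int = 16
    position: int = 4
    nt_seq: Optional[str] = None   # explicit insert overrides epitope encoding


class LibraryConfig(_Block):
    n_clones: int = Field(ge=1)
    length_nt: int = 48
    spikes: list[SpikeConfig] = []


class SimulationConfig(_Block):
    total_cells: int = Field(ge=1)
    moi_lambda: float = 0.1
    condition_on_transduced: bool = True
    purity_sorted: bool = True
    p_hit: float = 0.6
    p_fp: float = 1e-4
    f_reactive: float = 1.0
    et_ratio: float = 1.0
    gate_capacity: Optional[int] = None
    reads_per_gate: int = 500_000
    read_len: int = 250
    sub_error_rate: float = 0.002
    amp_lognorm_sigma: float = 0.5
    qual_mean: float = 32.0
    qual_sd: float = 3.0
    flank5: str = DEFAULT_FLANK5
    flank3: str = DEFAULT_FLANK3


class PipelineConfigBlock(_Block):
    min_overlap: int = 10
    max_overlap: int = 304
    max_mismatch_ratio: float = 0.25
    allow_outies: bool = True
    min_q: int = 20
    min_fraction: float = 0.9
    max_flank_mismatches: int = 3
    cluster_max_dist: int = 3
    blacklist: list[str] = []


class EnrichmentConfig(_Block):
    k: float = 10.0
    background: Union[Literal["all"], int] = "all"


class ScreenConfig(_Block):
    library: LibraryConfig
    simulation: SimulationConfig
    pipeline: PipelineConfigBlock = PipelineConfigBlock()
    enrichment: EnrichmentConfig = EnrichmentConfig()
    seed: int


def load_config(path) -> ScreenConfig:
    """Load and validate a JSON/YAML config; raises :class:`ConfigError` with
    the schema path of the first failure."""
    path = Path(path)
    try:
        text = path.read_text()
    except OSError as e:
        raise ConfigError(f"cannot read config {path}: {e}") from e
    try:
        raw = yaml.safe_load(text) if path.suffix in (".yml", ".yaml") else json.loads(text)
    except Exception as e:
        raise ConfigError(f"cannot parse config {path}: {e}") from e
    try:
        return ScreenConfig.model_validate(raw)
    except ValidationError as e:
        first = e.errors()[0]
        loc = ".".join(str(p) for p in first["loc"])
        raise ConfigError(f"invalid config {path}: {loc}: {first['msg']}") from e
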