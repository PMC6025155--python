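"""Run configuration: one YAML file, every CLI flag overrides it."""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import yaml

from .text_pipeline import PipelineConfig


class ConfigError(ValueError):
    """Invalid run configuration."""


@dataclass
class RunConfig:
    corpus_path: str = ""
    corpus_format: str = "csv"
    field_map: dict[str, str] = field(default_factory=dict)
    kb_path: str = ""
    kb_format: str = "toy"  # "toy" or "rrf"
    rel_path: str = ""  # relation file for the rrf dialect
    pipeline: PipelineConfig = field(default_factory=PipelineConfig)
    m: int = 1
    alpha: float = 0.1
    beta: float = 0.01
    iterations: int = 200
    seed: int = 0
    top_terms: int = 5
    lkr_mode: str = "reachable"
    lkr_ms: list[int] = field(default_factory=lambda: [1, 2, 3])
    kcr_hop_radius: int = 1
    expansion_scope: str = "hierarchy"
    out_dir: str = "kitm_out"

    def validate(self) -> None:
        if not self.corpus_path or not os.path.exists(self.corpus_path):
            raise ConfigError(f"corpus path does not exist: {self.corpus_path!r}")
        if not self.kb_path or not os.path.exists(self.kb_path):
            raise ConfigError(f"knowledge base path does not exist: {self.kb_path!r}")
        if self.kb_format == "rrf" and not os.path.exists(self.rel_path):
            raise ConfigError(f"relation file does not exist: {self.rel_path!r}")
        if self.m < 0:
            raise ConfigError("m must be >= 0")
        if self.iterations < 0:
            raise ConfigError("iterations must be >= 0")


def load_run_config(path: str, overrides: dict | None = None) -> RunConfig:
    with open(path, encoding="utf-8") as fh:
        payload = yaml.safe_load(fh) or {}
    payload.update({k: v for k, v in (overrides or {}).items() if v is not None})
    pipeline_payload = payload.pop("pipeline", {}) or {}
    config = RunConfig(**payload)
    config.pipeline = PipelineConfig(**pipeline_payload)
    return config
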