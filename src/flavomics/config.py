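"""Pipeline configuration: a single declarative YAML file with CLI overrides.

Every run writes a resolved copy of its configuration next to the outputs,
and output tables carry the configuration hash and seed in comment headers.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

__all__ = ["PipelineConfig", "load_config"]

SCENARIOS = ("default", "paper-like", "null")


@dataclass
class PipelineConfig:
    library: str = "packaged"  # or a path to a compound TSV
    spectra_path: str | None = None
    spectra_format: str | None = None  # mgf | csv | mzml (None: from suffix)
    intensity_path: str | None = None
    metadata_path: str | None = None

    ms1_tol_ppm: float = 10.0
    frag_tol_mda: float = 5.0
    rt_window: float | None = None

    p_cutoff: float = 0.05
    fc_up: float = 2.5
    fc_down: float = 0.4
    equal_var: bool = False  # Student instead of Welch when True
    average_injections: bool = True
    fdr: bool = False

    scenario: str = "paper-like"
    seed: int = 0
    ppm_jitter: float = 0.0
    frag_dropout: float = 0.0

    out_dir: str = "flavomics_out"

    def __post_init__(self) -> None:
        for name in ("ms1_tol_ppm", "frag_tol_mda", "p_cutoff", "fc_up", "fc_down"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.scenario not in SCENARIOS:
            raise ValueError(
                f"unknown scenario {self.scenario!r}; choose from {SCENARIOS}"
            )

    def sha256(self) -> str:
        payload = asdict(self)
        payload.pop("out_dir")  # output location is not analytic configuration
        return hashlib.sha256(
            json.dumps(payload, sort_keys=True).encode()
        ).hexdigest()[:12]

    def header_lines(self) -> list[str]:
        return [f"flavomics config_sha256={self.sha256()} seed={self.seed}"]

    def write_resolved(self, out_dir: Path) -> Path:
        out_dir.mkdir(parents=True, exist_ok=True)
        path = out_dir / "config.resolved.yaml"
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=True)
        return path


def load_config(path: str | Path | None = None, **overrides) -> PipelineConfig:
    """Load YAML config (if given) and apply keyword overrides on top."""
    data: dict = {}
    if path is not None:
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        unknown = set(data) - set(PipelineConfig.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
    data.update({k: v for k, v in overrides.items() if v is not None})
    return PipelineConfig(**data)
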