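"""Run configuration: one auditable record of every stage parameter.

Defaults follow the study design the pipeline reproduces: 100 randomization
reps, ten 70%/30% train-test splits, TSS acceptance cutoff 0.4, a 97%
variance target for component selection, and a 16 km² minimum remnant-patch
area. Configs load from YAML with strict validation — unknown keys are
rejected, so typos cannot silently fall back to defaults.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .errors import ArgumentError, SchemaError
from .synthetic import SCENARIO_NAMES

__all__ = ["RunConfig"]


@dataclass
class RunConfig:
    # input mode: a generated scenario, or file paths
    mode: str = "scenario"  # "scenario" | "files"
    scenario: str = "divergent_allopatric"
    n_per_species: int = 50
    n_rows: int = 48
    n_cols: int = 48
    n_layers: int = 5
    smoothness: float = 0.15
    correlation: float = 0.6
    separation: float = 3.0
    niche_sd_factor: float = 0.35
    # file mode
    rasters: str | None = None
    occurrences: str | None = None
    backgrounds: dict = field(default_factory=dict)  # species -> mask .asc path
    pairs: list = field(default_factory=list)  # [[sp1, sp2], ...]
    # environmental space / PCA
    pca_target_fraction: float = 0.97
    env_space_resolution: int = 100
    availability_floor: float = 1e-6
    bandwidth: tuple | None = None  # per-axis override; None = Silverman
    # overlap tests
    reps: int = 100
    equivalency_alternative: str = "lower"
    similarity_alternative: str = "greater"
    # ensemble
    algorithms: tuple = ("envelope", "mahalanobis")
    n_splits: int = 10
    train_fraction: float = 0.7
    tss_cutoff: float = 0.4
    # survey gap
    consensus_cut: float = 0.5
    min_patch_km2: float = 16.0
    connectivity: int = 8
    fine_factor: int = 2
    remnant_coverage: float = 0.3
    remnant_patchiness: float = 2.0
    # run
    seed: int = 0
    out_dir: str = "nichecmp_out"

    def validate(self) -> None:
        if self.mode not in ("scenario", "files"):
            raise ArgumentError(f"mode must be 'scenario' or 'files', got {self.mode!r}")
        if self.mode == "scenario" and self.scenario not in SCENARIO_NAMES:
            raise ArgumentError(f"unknown scenario {self.scenario!r}")
        if self.mode == "files":
            if not self.rasters or not self.occurrences:
                raise ArgumentError("file mode needs 'rasters' and 'occurrences' paths")
            if not self.pairs:
                raise ArgumentError("file mode needs at least one species pair")
        if self.reps < 1:
            raise ArgumentError("reps must be >= 1")
        if self.n_splits < 1:
            raise ArgumentError("n_splits must be >= 1")
        if not 0.0 < self.train_fraction < 1.0:
            raise ArgumentError("train_fraction must be in (0, 1)")
        if not 0.0 < self.pca_target_fraction <= 1.0:
            raise ArgumentError("pca_target_fraction must be in (0, 1]")
        if self.env_space_resolution < 2:
            raise ArgumentError("env_space_resolution must be >= 2")
        if not 0.0 < self.remnant_coverage <= 1.0:
            raise ArgumentError("remnant_coverage must be in (0, 1]")
        if self.connectivity not in (4, 8):
            raise ArgumentError("connectivity must be 4 or 8")
        if self.fine_factor < 1:
            raise ArgumentError("fine_factor must be >= 1")

    @classmethod
    def from_dict(cls, data: dict) -> "RunConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise SchemaError(f"unknown config key(s): {sorted(unknown)}")
        cfg = cls(**data)
        if cfg.bandwidth is not None:
            cfg.bandwidth = tuple(cfg.bandwidth)
        cfg.algorithms = tuple(cfg.algorithms)
        return cfg

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        if not isinstance(data, dict):
            raise SchemaError(f"config {path} must be a YAML mapping")
        return cls.from_dict(data)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["algorithms"] = list(self.algorithms)
        d["bandwidth"] = list(self.bandwidth) if self.bandwidth is not None else None
        return d

    def parameter_hash(self) -> str:
        """Stable digest of the analysis parameters (manifest key).

        The output directory is excluded: two runs of the same analysis into
        different folders are the same computation.
        """
        d = self.to_dict()
        d.pop("out_dir")
        return hashlib.sha256(
            json.dumps(d, sort_keys=True).encode()
        ).hexdigest()[:16]
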