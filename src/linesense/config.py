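"""Configuration objects for simulation and pipeline runs.

``SimConfig`` holds every knob of the synthetic inbred-panel generator; its
defaults describe the study design the package targets: 126 inbred lines,
30 individuals per line x age x treatment cell, two ages, two treatments,
blocks nested within age, body mass as a nuisance covariate, and a global
gene-interaction graph carrying a planted, internally dense module.

``AnalysisConfig`` holds the analysis-side thresholds (candidate cutoff,
network gene cutoff, annotation window, permutation count) plus the master
seed from which every stage derives its own random stream.
"""

from __future__ import annotations

import dataclasses
import json
import zlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import yaml

from .errors import ConfigurationError


def stage_seed(master_seed: int, stage: str) -> np.random.SeedSequence:
    """Derive a per-stage seed stream from a master seed.

    Uses a CRC32 of the stage name as a second entropy word so stages get
    independent, collision-free streams while staying reproducible.
    """
    return np.random.SeedSequence([int(master_seed) % (2**31), zlib.crc32(stage.encode())])


def stage_rng(master_seed: int, stage: str) -> np.random.Generator:
    return np.random.default_rng(stage_seed(master_seed, stage))


@dataclass
class SimConfig:
    """Parameters of the synthetic inbred-panel data generator.

    Variance components are in squared trait units; masses in mg; fixed
    effects and causal effect sizes in trait units (per allele for the
    latter).  ``ages`` and ``treatments`` are opaque labels; the first entry
    of each is the baseline (young / control).
    """

    n_lines: int = 126
    n_flies_per_cell: int = 30
    n_variants: int = 10_000
    maf_range: tuple[float, float] = (0.05, 0.5)
    ages: tuple[str, ...] = ("young", "old")
    treatments: tuple[str, ...] = ("control", "treated")
    n_blocks_per_age: int = 3

    # random genetic (co)variance structure, squared trait units.  The
    # three-way term dominates so background cross-treatment and cross-age
    # line-effect correlations sit near 0.25 and 0.15: age- and
    # treatment-specific allelic effects outweigh shared ones.
    var_line: float = 0.010
    var_line_by_age: float = 0.025
    var_line_by_treatment: float = 0.011
    var_line_by_age_by_treatment: float = 0.094
    var_block: float = 0.01
    var_error: float = 0.25

    # body-mass covariate
    mass_mean: float = 0.8
    mass_sd: float = 0.08
    mass_line_sd: float = 0.0
    mass_slope: float = 0.3

    # fixed design effects (per step away from the baseline level)
    constant: float = 1.54
    age_effect: float = -0.77
    treatment_effect: float = 0.10

    # planted causal architecture
    n_causal_trait: int = 4
    n_causal_sensitivity: int = 4
    causal_effect_size: float = 0.6
    causal_module_preference: float = 0.9

    # interaction-network generator
    network_n_genes: int = 2000
    network_attach_m: int = 2
    planted_module_size: int = 15
    module_extra_edges: int = 15
    plant_module_edges: bool = True

    trait: str = "speed"
    seed: int = 0

    def validate(self) -> "SimConfig":
        if self.n_lines < 1 or self.n_flies_per_cell < 1 or self.n_variants < 1:
            raise ConfigurationError("n_lines, n_flies_per_cell and n_variants must be positive")
        lo, hi = self.maf_range
        if not (0.0 < lo <= hi <= 0.5):
            raise ConfigurationError(f"maf_range must lie within (0, 0.5], got {self.maf_range}")
        for name in (
            "var_line",
            "var_line_by_age",
            "var_line_by_treatment",
            "var_line_by_age_by_treatment",
            "var_block",
            "var_error",
        ):
            v = getattr(self, name)
            if v is None or not np.isfinite(v) or v < 0:
                raise ConfigurationError(f"variance component {name} must be a finite number >= 0")
        if len(self.ages) < 1 or len(self.treatments) < 1:
            raise ConfigurationError("need at least one age and one treatment label")
        if self.n_blocks_per_age < 1:
            raise ConfigurationError("n_blocks_per_age must be >= 1")
        if self.planted_module_size < 2:
            raise ConfigurationError("planted_module_size must be >= 2")
        if self.planted_module_size > self.network_n_genes:
            raise ConfigurationError("planted_module_size cannot exceed network_n_genes")
        if self.n_causal_trait > self.n_variants or self.n_causal_sensitivity > self.n_variants:
            raise ConfigurationError("n_causal_* cannot exceed n_variants")
        if self.network_attach_m < 1 or self.network_n_genes <= self.network_attach_m:
            raise ConfigurationError("network_attach_m must satisfy 1 <= m < network_n_genes")
        return self

    def replace(self, **kw) -> "SimConfig":
        return dataclasses.replace(self, **kw)


@dataclass
class AnalysisConfig:
    """End-to-end pipeline configuration."""

    sim: SimConfig = field(default_factory=SimConfig)
    candidate_threshold: float = 1e-5
    network_gene_threshold: float = 1e-6
    annotation_window: int = 5000
    n_permutations: int = 1000
    min_class_count: int = 4
    sensitivity_on: str = "lsmeans"  # or "raw"
    run_sensitivity: bool = True
    run_full_anova: bool = True
    seed: int = 0
    outdir: str = "linesense_out"

    def validate(self) -> "AnalysisConfig":
        self.sim.validate()
        for name in ("candidate_threshold", "network_gene_threshold"):
            v = getattr(self, name)
            if not (0.0 < v < 1.0):
                raise ConfigurationError(f"{name} must be in (0,1), got {v}")
        if self.annotation_window < 0:
            raise ConfigurationError("annotation_window must be >= 0")
        if self.n_permutations < 1:
            raise ConfigurationError("n_permutations must be >= 1")
        if self.sensitivity_on not in ("lsmeans", "raw"):
            raise ConfigurationError("sensitivity_on must be 'lsmeans' or 'raw'")
        return self

    # -- serialization ----------------------------------------------------
    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "AnalysisConfig":
        d = dict(d)
        sim = d.pop("sim", {})
        if isinstance(sim, dict):
            sim = {
                **sim,
                **{
                    k: tuple(v)
                    for k, v in sim.items()
                    if k in ("maf_range", "ages", "treatments") and isinstance(v, (list, tuple))
                },
            }
            sim = SimConfig(**sim)
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ConfigurationError(f"unknown config keys: {sorted(unknown)}")
        return cls(sim=sim, **d)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))

    @classmethod
    def from_file(cls, path: str | Path) -> "AnalysisConfig":
        text = Path(path).read_text()
        if str(path).endswith(".json"):
            d = json.loads(text)
        else:
            d = yaml.safe_load(text)
        return cls.from_dict(d).validate()
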