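"""Scenario configuration with YAML round-trip.

A :class:`SimConfig` fixes everything about one simulated breeding
program except the seed: genome and trait architecture, the product
development (PD) stage pipeline, phenotyping precision per stage, the
training-set policy and the within-simulation optimiser settings.

Two presets are provided.  ``desk_scale`` is the default used throughout
the test-bench: a 10-chromosome genome with 100 causal and 100 marker
loci per chromosome and a PD pipeline small enough that a full
multi-scenario comparison runs on a single CPU in minutes.
``full_scale`` mirrors a full-size wheat program (preliminary trials of
1000 lines plus advanced/elite stages feeding 1040 training records per
year, i.e. 3120 over a three-year window) and is intended for
cluster-scale validation runs.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import yaml

from .ocs import DEConfig

__all__ = ["SimConfig", "load_config", "dump_config"]

STAGES = ("f1", "dh", "headrow", "preliminary", "advanced", "elite")


@dataclass
class SimConfig:
    # genome
    n_chromosomes: int = 10
    n_causal_per_chrom: int = 100
    n_markers_per_chrom: int = 100
    chrom_length_m: float = 1.0
    n_founders: int = 100
    maf_floor: float = 0.05
    founder_mating_generations: int = 10
    # trait
    genic_variance_init: float = 1.0
    trait_intercept: float = 0.0
    # product development pipeline (per year)
    pd_crosses: int = 16
    dh_per_cross: int = 20
    n_preliminary: int = 50
    n_advanced: int = 12
    n_elite: int = 4
    # narrow-sense precision of the phenotype taken at each stage
    stage_h2: dict = field(
        default_factory=lambda: {
            "headrow": 0.1,
            "preliminary": 0.2,
            "advanced": 0.4,
            "elite": 0.5,
        }
    )
    # effective replication per stage -> residual-variance weight
    stage_weights: dict = field(
        default_factory=lambda: {
            "headrow": 1.0,
            "preliminary": 2.0,
            "advanced": 4.0,
            "elite": 8.0,
        }
    )
    training_stages: tuple = ("headrow", "preliminary", "advanced", "elite")
    # conventional program
    conv_n_parents: int = 20
    burnin_years: int = 20
    burnin_training_years: int = 3
    # two-part population improvement
    pi_metric_dh: int = 100
    ocs_degrees: float = 45.0
    ocs_de: DEConfig = field(
        default_factory=lambda: DEConfig(
            pop_size=20, generations=120, stall=30, penalty_multiplier=10.0
        )
    )

    @classmethod
    def desk_scale(cls) -> "SimConfig":
        """Default desk-scale study conditions (see the methods note)."""
        return cls()

    @classmethod
    def full_scale(cls) -> "SimConfig":
        """Full-size program: 1040 training lines per year (3120 over the
        three-year initiation window), preliminary trials of 1000 lines."""
        return cls(
            n_founders=400,
            pd_crosses=100,
            dh_per_cross=100,
            n_preliminary=1000,
            n_advanced=30,
            n_elite=10,
            conv_n_parents=50,
            training_stages=("preliminary", "advanced", "elite"),
            pi_metric_dh=500,
        )

    def training_lines_per_year(self) -> int:
        """Number of genotype+phenotype records added to the training set
        per simulated year under this configuration."""
        sizes = {
            "headrow": self.pd_crosses * self.dh_per_cross,
            "preliminary": self.n_preliminary,
            "advanced": self.n_advanced,
            "elite": self.n_elite,
        }
        return sum(sizes[s] for s in self.training_stages)

    def residual_variance(self, stage: str) -> float:
        """Phenotype error variance at a stage from its heritability,
        anchored at the initial genic variance."""
        h2 = self.stage_h2[stage]
        return self.genic_variance_init * (1.0 - h2) / h2

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["training_stages"] = list(self.training_stages)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SimConfig":
        d = dict(d)
        if "ocs_de" in d and isinstance(d["ocs_de"], dict):
            d["ocs_de"] = DEConfig(**d["ocs_de"])
        if "training_stages" in d:
            d["training_stages"] = tuple(d["training_stages"])
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise KeyError(f"unknown configuration keys: {sorted(unknown)}")
        return cls(**d)


def load_config(path) -> SimConfig:
    with open(path) as fh:
        d = yaml.safe_load(fh)
    if not isinstance(d, dict):
        raise KeyError("configuration file must hold a mapping")
    return SimConfig.from_dict(d)


def dump_config(cfg: SimConfig, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(cfg.to_dict(), fh, sort_keys=False)
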