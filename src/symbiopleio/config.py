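"""Configuration objects for simulation and pipeline runs.

All stochastic behaviour in the package is driven by the integer ``seed``
carried here; identical configs (including the seed) reproduce byte-identical
outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Any

import yaml

HOSTS = ("DZA", "A17")

#: single-strain traits measured per replicate plant
SINGLE_STRAIN_TRAITS = ("shoot_biomass", "chlorophyll_a", "nodule_number", "nodule_weight")

#: the multi-strain trait derived from pooled sequencing
RELATIVE_FITNESS_TRAIT = "relative_fitness"

ALL_TRAITS = SINGLE_STRAIN_TRAITS + (RELATIVE_FITNESS_TRAIT,)

#: symbiont-side fitness proxies (nodulation success and competitive fitness)
RHIZOBIUM_TRAITS = frozenset({"nodule_number", "nodule_weight", RELATIVE_FITNESS_TRAIT})
#: host-side fitness proxies
PLANT_TRAITS = frozenset({"shoot_biomass", "chlorophyll_a"})

REPLICONS = ("chromosome", "pSymA", "pSymB")
#: site share per replicon, proportional to the ~3.7/1.4/1.7 Mbp genome parts
REPLICON_WEIGHTS = (0.54, 0.21, 0.25)


class ConfigError(ValueError):
    """Raised when a configuration fails validation."""


@dataclass
class SimConfig:
    """Parameters of the synthetic study.

    Defaults describe a compact panel (100 strains, 5000 sites) structured
    like the real one: a handful of subpopulations with moderate
    differentiation, causal variant pairs planted with concordant or
    discordant cross-trait signs, greenhouse rack effects on replicate-level
    measurements, and a select-and-resequence pooled experiment in which
    strain frequencies shift with competitive fitness.
    """

    n_strains: int = 100
    n_sites: int = 5000
    n_subpops: int = 4
    fst: float = 0.1
    gene_size_mean: float = 10.0
    n_concordant_pairs: int = 3
    n_discordant_pairs: int = 3
    effect_size: float = 3.0
    h2_polygenic: float = 0.3
    noise_sd: float = 0.5
    n_racks: int = 3
    reps_per_strain: int = 4
    n_pools: int = 6
    mean_depth: float = 200.0
    selection_gradient: float = 1.0
    seed: int = 0
    # plumbing knobs beyond the headline design
    missing_rate: float = 0.02
    rack_sd: float = 1.0
    symbiotic_fraction: float = 0.5
    host_shared_fraction: float = 0.5
    dirichlet_init: float | None = None  # None -> equal initial pool frequencies

    def validate(self) -> None:
        if self.n_subpops > self.n_strains:
            raise ConfigError("n_subpops may not exceed n_strains")
        if not (0.0 < self.fst < 1.0):
            raise ConfigError("fst must lie strictly inside (0, 1)")
        if not (0.0 <= self.h2_polygenic < 1.0):
            raise ConfigError("h2_polygenic must lie in [0, 1)")
        n_causal = 2 * (self.n_concordant_pairs + self.n_discordant_pairs)
        if n_causal > self.n_sites:
            raise ConfigError(
                f"{n_causal} causal sites requested but only {self.n_sites} sites simulated"
            )
        if not (0.0 <= self.missing_rate < 1.0):
            raise ConfigError("missing_rate must lie in [0, 1)")
        for name in ("n_strains", "n_sites", "n_subpops", "n_racks", "reps_per_strain", "n_pools"):
            if getattr(self, name) < 1:
                raise ConfigError(f"{name} must be >= 1")

    def to_dict(self) -> dict[str, Any]:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict[str, Any]) -> "SimConfig":
        cfg = cls(**d)
        cfg.validate()
        return cfg


@dataclass
class RunConfig:
    """Full pipeline configuration: a simulation block plus per-stage knobs."""

    sim: SimConfig = field(default_factory=SimConfig)
    outdir: str = "results/run"
    hosts: tuple[str, ...] = HOSTS
    maf_min: float = 0.05
    miss_max: float = 0.2
    permutations: int = 1000
    alpha: float = 0.05
    selection_reps: int = 1000
    pseudo_frequency: float | None = None  # None -> depth-derived default
    log_chlorophyll: bool = False

    def validate(self) -> None:
        self.sim.validate()
        if not (0.0 <= self.maf_min <= 0.5):
            raise ConfigError("maf_min must lie in [0, 0.5]")
        if not (0.0 <= self.miss_max <= 1.0):
            raise ConfigError("miss_max must lie in [0, 1]")
        if self.permutations < 100:
            raise ConfigError("permutations must be >= 100")
        if not (0.0 < self.alpha <= 1.0):
            raise ConfigError("alpha must lie in (0, 1]")
        for h in self.hosts:
            if h not in HOSTS:
                raise ConfigError(f"unknown host line {h!r}")

    def to_dict(self) -> dict[str, Any]:
        d = asdict(self)
        d["hosts"] = list(self.hosts)
        return d

    @classmethod
    def from_dict(cls, d: dict[str, Any]) -> "RunConfig":
        d = dict(d)
        sim = SimConfig(**d.pop("sim", {}))
        hosts = tuple(d.pop("hosts", HOSTS))
        cfg = cls(sim=sim, hosts=hosts, **d)
        cfg.validate()
        return cfg


def load_run_config(path: str | Path) -> RunConfig:
    with open(path) as fh:
        return RunConfig.from_dict(yaml.safe_load(fh) or {})


def save_run_config(cfg: RunConfig, path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(cfg.to_dict(), fh, sort_keys=True)
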