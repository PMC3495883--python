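"""Configuration objects for the synthetic population, the recruitment
simulator, and the end-to-end pipeline, with YAML (de)serialisation."""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import yaml


class ConfigurationError(ValueError):
    """Raised for infeasible or inconsistent configuration values."""


@dataclass
class TraitSpec:
    """A categorical individual attribute carried on the network.

    ``homophily`` in [0, 1] controls how strongly network ties prefer
    same-category endpoints: 0 means edges ignore the trait, 1 means
    cross-category edges are (almost) never accepted during rewiring.
    """

    name: str
    categories: list
    probabilities: list
    homophily: float = 0.0

    def __post_init__(self) -> None:
        if len(self.categories) != len(self.probabilities):
            raise ConfigurationError(
                f"trait {self.name!r}: {len(self.categories)} categories but "
                f"{len(self.probabilities)} probabilities"
            )
        total = float(sum(self.probabilities))
        if abs(total - 1.0) > 1e-9:
            raise ConfigurationError(
                f"trait {self.name!r}: marginal probabilities sum to {total}, not 1"
            )
        if not 0.0 <= self.homophily <= 1.0:
            raise ConfigurationError(
                f"trait {self.name!r}: homophily {self.homophily} outside [0, 1]"
            )


@dataclass
class PopulationConfig:
    """Synthetic population: network model plus individual attributes.

    ``degree_model`` is one of ``poisson`` (parameter ``mean``), ``powerlaw``
    (parameter ``exponent``, degrees are zipf-distributed and truncated at
    n - 1) or ``regular`` (parameter ``degree``).
    """

    n_individuals: int = 5000
    degree_model: str = "poisson"
    degree_params: dict = field(default_factory=lambda: {"mean": 8.0})
    trait_specs: list = field(default_factory=list)
    province_distribution: dict = field(
        default_factory=lambda: {"hanoi": 0.45, "hcmc": 0.37, "other": 0.18}
    )
    province_homophily: float = 0.0
    age_range: tuple = (18, 40)
    age_mode: int = 22

    def __post_init__(self) -> None:
        if self.n_individuals < 2:
            raise ConfigurationError("n_individuals must be at least 2")
        if self.degree_model not in ("poisson", "powerlaw", "regular"):
            raise ConfigurationError(f"unknown degree model {self.degree_model!r}")
        total = float(sum(self.province_distribution.values()))
        if abs(total - 1.0) > 1e-9:
            raise ConfigurationError(
                f"province probabilities sum to {total}, not 1"
            )
        if not 0.0 <= self.province_homophily <= 1.0:
            raise ConfigurationError("province_homophily outside [0, 1]")
        self.trait_specs = [
            t if isinstance(t, TraitSpec) else TraitSpec(**t) for t in self.trait_specs
        ]


@dataclass
class InvalidInjection:
    """Rates at which known-invalid records are injected into submissions."""

    underage_rate: float = 0.0
    duplicate_token_rate: float = 0.0
    shared_ip_rate: float = 0.0
    fast_completion_rate: float = 0.0

    def __post_init__(self) -> None:
        for name in (
            "underage_rate",
            "duplicate_token_rate",
            "shared_ip_rate",
            "fast_completion_rate",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigurationError(f"{name}={v} outside [0, 1]")


@dataclass
class SimulationConfig:
    """Recruitment dynamics and submission fabrication parameters.

    Defaults follow the study design: 20 seeds, up to 4 electronic
    invitations per participant, recruitment without replacement, and
    voluntary participation.
    """

    n_seeds: int = 20
    seed_selection: str = "uniform"
    seed_trait: tuple | None = None  # (trait name, category) for by_trait
    coupons_per_participant: int = 4
    participation_probability: float = 0.25
    with_replacement: bool = False
    max_waves: int | None = None
    rng_seed: int = 0
    invalid_injection: InvalidInjection = field(default_factory=InvalidInjection)
    network_size_missing_rate: float = 0.0
    network_size_fraction: float = 0.7  # internet-using share of contacts

    def __post_init__(self) -> None:
        if self.n_seeds < 1:
            raise ConfigurationError("n_seeds must be at least 1")
        if self.coupons_per_participant < 0:
            raise ConfigurationError("coupons_per_participant must be >= 0")
        if not 0.0 <= self.participation_probability <= 1.0:
            raise ConfigurationError("participation_probability outside [0, 1]")
        if not 0.0 <= self.network_size_missing_rate <= 1.0:
            raise ConfigurationError("network_size_missing_rate outside [0, 1]")
        if self.seed_selection not in ("uniform", "by_trait"):
            raise ConfigurationError(f"unknown seed_selection {self.seed_selection!r}")
        if self.seed_selection == "by_trait" and self.seed_trait is None:
            raise ConfigurationError("seed_selection='by_trait' requires seed_trait")
        if isinstance(self.invalid_injection, dict):
            self.invalid_injection = InvalidInjection(**self.invalid_injection)


@dataclass
class PipelineConfig:
    """Everything the end-to-end pipeline needs, under one RNG seed."""

    population: PopulationConfig = field(default_factory=PopulationConfig)
    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    inclusion_level: str = "L1"
    variables: list = field(default_factory=list)  # empty -> auto-detect
    numeric_variables: list = field(
        default_factory=lambda: ["stated_age", "partners_6mo", "reported_network_size"]
    )
    last_k: int = 200
    equilibrium_tolerance: float = 0.02
    composition_step: int = 25
    wave_threshold: int = 5
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if isinstance(self.population, dict):
            self.population = PopulationConfig(**self.population)
        if isinstance(self.simulation, dict):
            self.simulation = SimulationConfig(**self.simulation)
        if not 0.0 < self.equilibrium_tolerance < 1.0:
            raise ConfigurationError("equilibrium_tolerance must lie in (0, 1)")
        if self.inclusion_level not in ("L0", "L1", "L2", "L3"):
            raise ConfigurationError(f"unknown inclusion level {self.inclusion_level!r}")


def _asdict(obj):
    d = dataclasses.asdict(obj)

    def clean(x):
        if isinstance(x, dict):
            return {k: clean(v) for k, v in x.items()}
        if isinstance(x, (list, tuple)):
            return [clean(v) for v in x]
        return x

    return clean(d)


def to_yaml(config, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(_asdict(config), fh, sort_keys=True)


def pipeline_config_from_yaml(path) -> PipelineConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    return PipelineConfig(**raw)
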