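"""Agent population data model, scenario configuration and initialization.

The simulated system is a single-locus autosomal recessive trait (deafness,
DFNB1A-like) in a closed population with non-overlapping generations.  An
agent carries two binary alleles (1 = recessive mutant, 0 = normal dominant),
a sex, a deafness phenotype (genetic — recessive homozygote — or
environmental), a sign-language flag that mediates assortative mate choice,
and a "social position" score threshold used by the marriage market.

Populations are stored columnar (one numpy array per attribute), which keeps
a generation step vectorized end to end.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields, replace
from typing import Optional

import numpy as np

__all__ = [
    "AgentPopulation",
    "MatingWeights",
    "ScenarioConfig",
    "PopulationStats",
    "ExtinctPopulationError",
    "init_population",
    "compute_stats",
]


class ExtinctPopulationError(Exception):
    """Raised when statistics are requested for an empty (extinct) population."""


@dataclass(frozen=True)
class MatingWeights:
    """Weights of the mutual-evaluation score for candidate couples.

    ``w_pheno_h``/``w_pheno_d`` reward phenotype similarity for hearing and
    deaf candidates respectively; ``w_sign_h``/``w_sign_d`` reward shared
    sign-language knowledge.  ``random_mating`` bypasses scoring entirely
    (every male-female pair is equally acceptable).

    ``mixed_rule`` selects the deaf-hearing both-signing branch of the score:
    ``"prose"`` adds W^H_S + W^D_S, ``"equation"`` adds W^D_P + W^D_S (the two
    published variants).  ``threshold_rule`` selects whether a score must
    exceed the larger (``"max"``) or the smaller (``"min"``) of the two
    candidates' social-position thresholds.
    """

    w_pheno_h: float = 1.0
    w_pheno_d: float = 1.0
    w_sign_h: float = 0.0
    w_sign_d: float = 0.0
    random_mating: bool = False
    mixed_rule: str = "prose"
    threshold_rule: str = "max"

    def __post_init__(self) -> None:
        for name in ("w_pheno_h", "w_pheno_d", "w_sign_h", "w_sign_d"):
            v = getattr(self, name)
            if not np.isfinite(v) or v < 0:
                raise ValueError(f"weight {name} must be finite and >= 0, got {v!r}")
        if self.mixed_rule not in ("prose", "equation"):
            raise ValueError(f"mixed_rule must be 'prose' or 'equation', got {self.mixed_rule!r}")
        if self.threshold_rule not in ("max", "min"):
            raise ValueError(f"threshold_rule must be 'max' or 'min', got {self.threshold_rule!r}")


@dataclass
class AgentPopulation:
    """Columnar store of all living agents.

    Invariants: all arrays share one length; ``genetic_deaf`` is derived as
    ``allele1 & allele2`` and ``deaf`` as ``genetic_deaf | env_deaf``.
    """

    male: np.ndarray          # bool; True = male
    allele1: np.ndarray       # uint8 in {0, 1}; 1 = recessive mutant
    allele2: np.ndarray       # uint8 in {0, 1}
    env_deaf: np.ndarray      # bool; deaf for non-genetic reasons
    knows_sign: np.ndarray    # bool
    social_position: np.ndarray  # float; per-agent score threshold

    def __post_init__(self) -> None:
        n = len(self.male)
        for f in fields(self):
            arr = getattr(self, f.name)
            if len(arr) != n:
                raise ValueError("all per-agent arrays must have identical length")

    @property
    def size(self) -> int:
        return len(self.male)

    @property
    def genetic_deaf(self) -> np.ndarray:
        return (self.allele1 & self.allele2).astype(bool)

    @property
    def deaf(self) -> np.ndarray:
        return self.genetic_deaf | self.env_deaf

    @classmethod
    def empty(cls) -> "AgentPopulation":
        return cls(
            male=np.zeros(0, dtype=bool),
            allele1=np.zeros(0, dtype=np.uint8),
            allele2=np.zeros(0, dtype=np.uint8),
            env_deaf=np.zeros(0, dtype=bool),
            knows_sign=np.zeros(0, dtype=bool),
            social_position=np.zeros(0, dtype=float),
        )


@dataclass(frozen=True)
class ScenarioConfig:
    """Full parameter set for one simulation experiment.

    Proportions are fractions of the initial population: ``prop_hom``
    recessive homozygotes, ``prop_het`` heterozygous carriers,
    ``prop_env_deaf`` the per-agent probability of non-genetic deafness
    (applied to every newborn as well).  ``prop_sign_deaf`` /
    ``prop_sign_hearing`` give the probability that a deaf / hearing agent
    knows sign language.  ``birthrate_DD/DH/HH`` are mean numbers of children
    per couple by couple phenotype class (both deaf / mixed / both hearing);
    per-couple counts are drawn from a scaled beta distribution with support
    [0, max_children] and concentration alpha+beta = ``beta_concentration``,
    stochastically rounded so the mean is exact.
    """

    initial_size: int = 200_000
    prop_hom: float = 0.0025
    prop_het: float = 0.10
    prop_env_deaf: float = 0.0025
    prop_sign_deaf: float = 0.0
    prop_sign_hearing: float = 0.0
    weights: MatingWeights = field(default_factory=MatingWeights)
    social_position_default: float = 0.0
    birthrate_DD: float = 1.78
    birthrate_DH: float = 1.70
    birthrate_HH: float = 2.24
    max_children: int = 10
    beta_concentration: float = 4.0
    n_generations: int = 20
    n_runs: int = 1000
    ci_level: float = 0.99
    seed: int = 0
    name: Optional[str] = None

    def __post_init__(self) -> None:
        if not float(self.initial_size).is_integer() or self.initial_size < 0:
            raise ValueError(f"initial_size must be a non-negative integer, got {self.initial_size!r}")
        object.__setattr__(self, "initial_size", int(self.initial_size))
        for name in ("prop_hom", "prop_het", "prop_env_deaf", "prop_sign_deaf", "prop_sign_hearing"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v!r}")
        if self.prop_hom + self.prop_het > 1.0:
            raise ValueError(
                f"prop_hom + prop_het must be <= 1, got {self.prop_hom + self.prop_het}"
            )
        if self.max_children < 1:
            raise ValueError("max_children must be >= 1")
        for name in ("birthrate_DD", "birthrate_DH", "birthrate_HH"):
            v = getattr(self, name)
            if not 0.0 <= v <= self.max_children:
                raise ValueError(f"{name} must be in [0, max_children], got {v!r}")
        if self.beta_concentration <= 0:
            raise ValueError("beta_concentration must be > 0")
        if self.n_generations < 0:
            raise ValueError("n_generations must be >= 0")
        if self.n_runs < 1:
            raise ValueError("n_runs must be >= 1")
        if not 0.0 < self.ci_level < 1.0:
            raise ValueError("ci_level must be in (0, 1)")
        if isinstance(self.weights, dict):
            object.__setattr__(self, "weights", MatingWeights(**self.weights))

    def with_overrides(self, **kwargs) -> "ScenarioConfig":
        """Return a copy with the given fields replaced (re-validated)."""
        if "weights" in kwargs and isinstance(kwargs["weights"], dict):
            kwargs["weights"] = replace(self.weights, **kwargs["weights"])
        return replace(self, **kwargs)

    def birthrate(self, couple_class: str) -> float:
        return {"DD": self.birthrate_DD, "DH": self.birthrate_DH, "HH": self.birthrate_HH}[couple_class]


@dataclass(frozen=True)
class PopulationStats:
    """Summary statistics of one population snapshot."""

    size: int
    n_deaf_total: int
    n_hom: int
    n_het: int
    prop_hom: float
    allele_freq: float


def _assign_sign_flags(deaf: np.ndarray, config: ScenarioConfig, rng: np.random.Generator) -> np.ndarray:
    p = np.where(deaf, config.prop_sign_deaf, config.prop_sign_hearing)
    return rng.random(len(deaf)) < p


def init_population(config: ScenarioConfig, rng: np.random.Generator) -> AgentPopulation:
    """Create the generation-0 population.

    Genotype counts are deterministic rounded targets (``round(N * prop)``)
    assigned to agents in random order, so generation-0 allele frequency is
    exact given the configuration; sex, environmental deafness and sign
    language are sampled per agent.
    """
    n = config.initial_size
    n_hom = int(np.rint(n * config.prop_hom))
    n_het = int(np.rint(n * config.prop_het))
    if n_hom + n_het > n:
        raise ValueError("rounded genotype counts exceed population size")

    allele1 = np.zeros(n, dtype=np.uint8)
    allele2 = np.zeros(n, dtype=np.uint8)
    allele1[:n_hom] = 1
    allele2[:n_hom] = 1
    allele1[n_hom:n_hom + n_het] = 1
    order = rng.permutation(n)
    allele1 = allele1[order]
    allele2 = allele2[order]

    male = rng.random(n) < 0.5
    env_deaf = rng.random(n) < config.prop_env_deaf
    deaf = ((allele1 & allele2) == 1) | env_deaf
    knows_sign = _assign_sign_flags(deaf, config, rng)
    social_position = np.full(n, config.social_position_default, dtype=float)

    return AgentPopulation(
        male=male,
        allele1=allele1,
        allele2=allele2,
        env_deaf=env_deaf,
        knows_sign=knows_sign,
        social_position=social_position,
    )


def compute_stats(pop: AgentPopulation) -> PopulationStats:
    """Compute the tracked per-generation statistics.

    Raises :class:`ExtinctPopulationError` for an empty population rather than
    dividing by zero.
    """
    n = pop.size
    if n == 0:
        raise ExtinctPopulationError("population is extinct (size 0)")
    mutant = pop.allele1.astype(np.int64) + pop.allele2.astype(np.int64)
    n_hom = int(np.count_nonzero(mutant == 2))
    n_het = int(np.count_nonzero(mutant == 1))
    return PopulationStats(
        size=n,
        n_deaf_total=int(np.count_nonzero(pop.deaf)),
        n_hom=n_hom,
        n_het=n_het,
        prop_hom=n_hom / n,
        allele_freq=(2 * n_hom + n_het) / (2 * n),
    )
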