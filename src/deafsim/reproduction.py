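"""Offspring generation: fertility by couple class and Mendelian inheritance.

Each couple draws its number of children from a beta distribution scaled to
``[0, max_children]`` whose mean equals the couple class's configured
birthrate, with the concentration alpha + beta fixed; the scaled draw is
stochastically rounded (floor plus a Bernoulli on the fractional part) so the
expected integer count equals the configured mean exactly.  Children inherit
one uniformly chosen allele from each parent (no de novo mutants), are male
or female with equal probability, and receive environmental deafness and
sign-language flags by the same rules as the initial population.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .model_core import AgentPopulation, ScenarioConfig, _assign_sign_flags

__all__ = [
    "BirthrateModel",
    "sample_offspring_count",
    "sample_offspring_counts",
    "inherit_genotype",
    "make_next_generation",
]


@dataclass(frozen=True)
class BirthrateModel:
    """Mean children per couple phenotype class plus the count-distribution shape."""

    mean_DD: float = 1.78
    mean_DH: float = 1.70
    mean_HH: float = 2.24
    max_children: int = 10
    beta_concentration: float = 4.0

    def __post_init__(self) -> None:
        for name in ("mean_DD", "mean_DH", "mean_HH"):
            v = getattr(self, name)
            if not 0.0 <= v <= self.max_children:
                raise ValueError(f"{name} must be in [0, max_children], got {v!r}")
        if self.beta_concentration <= 0:
            raise ValueError("beta_concentration must be > 0")

    @classmethod
    def from_config(cls, config: ScenarioConfig) -> "BirthrateModel":
        return cls(
            mean_DD=config.birthrate_DD,
            mean_DH=config.birthrate_DH,
            mean_HH=config.birthrate_HH,
            max_children=config.max_children,
            beta_concentration=config.beta_concentration,
        )

    def mean(self, couple_class: str) -> float:
        return {"DD": self.mean_DD, "DH": self.mean_DH, "HH": self.mean_HH}[couple_class]


def _beta_counts(
    means: np.ndarray, model: BirthrateModel, rng: np.random.Generator
) -> np.ndarray:
    """Vector of integer offspring counts with exact expected value ``means``."""
    nu = model.beta_concentration
    cmax = model.max_children
    alpha = nu * means / cmax
    beta = nu - alpha
    x = np.zeros(len(means), dtype=float)
    inner = (alpha > 0) & (beta > 0)
    if inner.any():
        x[inner] = cmax * rng.beta(alpha[inner], beta[inner])
    x[beta <= 0] = cmax  # mean == max_children: degenerate at the upper bound
    # alpha <= 0 (mean 0) stays at 0
    lo = np.floor(x)
    counts = lo + (rng.random(len(x)) < (x - lo))
    return counts.astype(np.int64)


def sample_offspring_count(
    couple_class: str, model: BirthrateModel, rng: np.random.Generator
) -> int:
    """Number of children for one couple of the given phenotype class."""
    return int(_beta_counts(np.array([model.mean(couple_class)]), model, rng)[0])


def sample_offspring_counts(
    couple_classes: np.ndarray, model: BirthrateModel, rng: np.random.Generator
) -> np.ndarray:
    """Vectorized offspring counts for an array of 'DD'/'DH'/'HH' labels."""
    means = np.empty(len(couple_classes), dtype=float)
    for label in ("DD", "DH", "HH"):
        means[couple_classes == label] = model.mean(label)
    return _beta_counts(means, model, rng)


def inherit_genotype(
    mother: tuple, father: tuple, rng: np.random.Generator
) -> tuple:
    """Child genotype: one uniformly chosen allele from each parent."""
    return (
        mother[rng.integers(2)],
        father[rng.integers(2)],
    )


def make_next_generation(
    couples,
    pop: AgentPopulation,
    config: ScenarioConfig,
    rng: np.random.Generator,
) -> AgentPopulation:
    """Build the full replacement generation from the couple set.

    Generations are non-overlapping: the returned population consists solely
    of the couples' children; unmatched agents and all parents leave no
    further trace.  Zero couples (or zero total children) yields an empty
    population, i.e. extinction.
    """
    if couples.n_couples == 0:
        return AgentPopulation.empty()

    model = BirthrateModel.from_config(config)
    classes = couples.couple_classes(pop)
    counts = sample_offspring_counts(classes, model, rng)
    total = int(counts.sum())
    if total == 0:
        return AgentPopulation.empty()

    fathers = np.repeat(couples.male_idx, counts)
    mothers = np.repeat(couples.female_idx, counts)

    from_a1 = rng.random(total) < 0.5
    pat = np.where(from_a1, pop.allele1[fathers], pop.allele2[fathers])
    from_a1 = rng.random(total) < 0.5
    mat = np.where(from_a1, pop.allele1[mothers], pop.allele2[mothers])

    male = rng.random(total) < 0.5
    env_deaf = rng.random(total) < config.prop_env_deaf
    deaf = ((pat & mat) == 1) | env_deaf
    knows_sign = _assign_sign_flags(deaf, config, rng)

    return AgentPopulation(
        male=male,
        allele1=pat.astype(np.uint8),
        allele2=mat.astype(np.uint8),
        env_deaf=env_deaf,
        knows_sign=knows_sign,
        social_position=np.full(total, config.social_position_default, dtype=float),
    )
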