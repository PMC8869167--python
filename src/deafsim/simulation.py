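"""Generational loop for a single replicate.

One cycle = one non-overlapping generation (nominally 20 years): form couples
among the living agents, generate their children, replace the population,
record statistics.  A trajectory is a tidy table with one row per generation;
row ``g`` carries the statistics of generation ``g`` together with the number
of couples formed *among* generation ``g``'s agents and the realized
assortment of that matching (NaN where undefined or never computed).
"""

from __future__ import annotations

from typing import Optional, Tuple

import numpy as np
import pandas as pd

from .mating import (
    UndefinedAssortmentError,
    form_couples_fast,
    realized_assortment,
)
from .model_core import (
    AgentPopulation,
    ExtinctPopulationError,
    PopulationStats,
    ScenarioConfig,
    compute_stats,
    init_population,
)
from .reproduction import make_next_generation

__all__ = ["GENERATION_YEARS", "TRAJECTORY_COLUMNS", "step_generation", "run_simulation"]

GENERATION_YEARS = 20  # metadata only; dynamics are per generation

TRAJECTORY_COLUMNS = [
    "generation",
    "year",
    "pop_size",
    "n_deaf",
    "n_hom",
    "prop_hom",
    "allele_freq",
    "n_couples",
    "assortment",
]


def _stats_row(generation: int, stats: PopulationStats) -> dict:
    return {
        "generation": generation,
        "year": generation * GENERATION_YEARS,
        "pop_size": stats.size,
        "n_deaf": stats.n_deaf_total,
        "n_hom": stats.n_hom,
        "prop_hom": stats.prop_hom,
        "allele_freq": stats.allele_freq,
        "n_couples": np.nan,
        "assortment": np.nan,
    }


def step_generation(
    pop: AgentPopulation,
    config: ScenarioConfig,
    rng: np.random.Generator,
) -> Tuple[AgentPopulation, dict]:
    """Advance one generation; returns the new population and a record of the step.

    The record holds the matching characteristics of the *parental* generation
    (couples formed, realized assortment) plus the statistics of the offspring
    generation; an extinct offspring generation is reported with size 0 rather
    than raised.
    """
    if pop.size == 0:
        raise ExtinctPopulationError("cannot step an extinct population")
    couples = form_couples_fast(pop, config.weights, rng)
    try:
        assortment = realized_assortment(couples, pop)
    except UndefinedAssortmentError:
        assortment = np.nan
    next_pop = make_next_generation(couples, pop, config, rng)
    record = {"n_couples": couples.n_couples, "assortment": assortment}
    try:
        stats = compute_stats(next_pop)
    except ExtinctPopulationError:
        stats = None
    record["stats"] = stats
    return next_pop, record


def run_simulation(
    config: ScenarioConfig,
    rng: Optional[np.random.Generator] = None,
    run_id: int = 0,
) -> pd.DataFrame:
    """Run one replicate; returns the per-generation trajectory table.

    Deterministic given ``(config, seed)``: when ``rng`` is omitted, a fresh
    generator is created from ``config.seed``.  Extinction terminates the
    trajectory early; the table's ``attrs["extinct"]`` flag records it.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    pop = init_population(config, rng)
    rows = [_stats_row(0, compute_stats(pop))]
    extinct = False
    for gen in range(1, config.n_generations + 1):
        pop, record = step_generation(pop, config, rng)
        rows[-1]["n_couples"] = record["n_couples"]
        rows[-1]["assortment"] = record["assortment"]
        if record["stats"] is None:
            extinct = True
            break
        rows.append(_stats_row(gen, record["stats"]))
    table = pd.DataFrame(rows, columns=TRAJECTORY_COLUMNS)
    table.insert(0, "run_id", run_id)
    table.attrs["extinct"] = extinct
    return table
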