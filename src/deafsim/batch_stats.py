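"""Replicated execution and cross-run summary statistics.

A batch runs ``n_runs`` independent replicates with per-run seeds derived
from a root seed by a counter-based spawn scheme (any replicate can be re-run
in isolation), then aggregates each tracked statistic per generation into a
mean and a normal-approximation confidence-interval half-width
``z(level) * sd / sqrt(n)``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .model_core import ScenarioConfig
from .simulation import GENERATION_YEARS, run_simulation

__all__ = ["BatchSummary", "confidence_interval", "replicate_rng", "run_batch"]

SUMMARIZED_STATS = ["pop_size", "n_deaf", "n_hom", "prop_hom", "allele_freq", "n_couples", "assortment"]


@dataclass
class BatchSummary:
    """Per-generation means and CI half-widths across replicates."""

    summary: pd.DataFrame            # generation, year, <stat>_mean, <stat>_ci, n
    n_runs: int
    ci_level: float
    scenario: Optional[str]
    root_seed: int
    n_extinct: int
    trajectories: Optional[pd.DataFrame] = None  # concatenated per-run tables

    def mean(self, stat: str, generation: int) -> float:
        s = self.summary
        return float(s.loc[s["generation"] == generation, f"{stat}_mean"].iloc[0])

    def ci(self, stat: str, generation: int) -> float:
        s = self.summary
        return float(s.loc[s["generation"] == generation, f"{stat}_ci"].iloc[0])


def confidence_interval(values: Sequence[float], level: float) -> tuple:
    """Normal-approximation CI: returns (mean, half-width) at the given level."""
    arr = np.asarray(values, dtype=float)
    if arr.size < 2:
        raise ValueError("confidence interval requires at least 2 values")
    if not 0.0 < level < 1.0:
        raise ValueError("level must be in (0, 1)")
    z = sps.norm.ppf(0.5 + level / 2.0)
    return float(arr.mean()), float(z * arr.std(ddof=1) / np.sqrt(arr.size))


def replicate_rng(root_seed: int, run_index: int) -> np.random.Generator:
    """Independent generator for one replicate (counter-based derivation)."""
    return np.random.default_rng(
        np.random.SeedSequence(entropy=root_seed, spawn_key=(run_index,))
    )


def run_batch(
    config: ScenarioConfig,
    n_runs: Optional[int] = None,
    root_seed: Optional[int] = None,
    keep_trajectories: bool = False,
) -> BatchSummary:
    """Run replicates and summarize each statistic per generation.

    Replicates that go extinct simply contribute rows only up to their last
    generation (the per-generation ``n`` column reflects this); extinction is
    counted, never fatal.
    """
    n_runs = config.n_runs if n_runs is None else n_runs
    root_seed = config.seed if root_seed is None else root_seed
    if n_runs < 2:
        raise ValueError("run_batch requires n_runs >= 2")

    tables: List[pd.DataFrame] = []
    n_extinct = 0
    for i in range(n_runs):
        t = run_simulation(config, rng=replicate_rng(root_seed, i), run_id=i)
        n_extinct += int(t.attrs.get("extinct", False))
        tables.append(t)
    stacked = pd.concat(tables, ignore_index=True)

    z = sps.norm.ppf(0.5 + config.ci_level / 2.0)
    grouped = stacked.groupby("generation")
    out = pd.DataFrame({"generation": sorted(stacked["generation"].unique())})
    out["year"] = out["generation"] * GENERATION_YEARS
    for stat in SUMMARIZED_STATS:
        agg = grouped[stat].agg(["mean", "std", "count"])
        out[f"{stat}_mean"] = agg["mean"].to_numpy()
        with np.errstate(invalid="ignore"):
            out[f"{stat}_ci"] = (z * agg["std"] / np.sqrt(agg["count"])).to_numpy()
    out["n"] = grouped["run_id"].count().to_numpy()

    return BatchSummary(
        summary=out,
        n_runs=n_runs,
        ci_level=config.ci_level,
        scenario=config.name,
        root_seed=root_seed,
        n_extinct=n_extinct,
        trajectories=stacked if keep_trajectories else None,
    )
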