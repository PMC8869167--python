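"""Scenario presets and configuration file handling.

Presets encode the published study conditions:

* ``no_deaf_mating`` — purifying selection: nobody signs, deaf-involving
  pairs score 0 and the social threshold 0 makes them ineligible, so deaf
  agents never marry.  Yakut-like composition (0.25% homozygotes, 10%
  carriers, 0.25% environmental deafness), class birthrates 1.78/1.70/2.24.
* ``assortative`` — relaxed selection: all deaf sign and a small calibrated
  fraction of hearing agents sign; the weights make deaf x deaf and
  deaf x hearing-signer scores tie at the top of the marriage market, so the
  greedy tie-break dilutes deaf-deaf pairing to a realized assortment of
  ~77.1% among married deaf.
* ``random_mating`` — neutral selection: scoring bypassed, uniform pairing,
  equal fitness (birthrate 2.24 for every couple class).
* ``usa_validation`` — historical-USA check: 0.2% homozygotes, environmental
  deafness 0.8% (homozygotes are 20% of the deaf at init), ~76% assortment,
  equal fitness at 2.1 children, 10 generations, 95% CIs.
* ``yakut_census`` — demographic check only: census-1897 population size,
  no mutant alleles, uniform birthrate 2.24, 5 generations.

Config files are YAML or JSON documents whose keys exactly match
:class:`~deafsim.model_core.ScenarioConfig` fields (``weights`` as a nested
mapping); unknown keys are rejected with a message listing them.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Dict, Optional, Union

import yaml

from .model_core import MatingWeights, ScenarioConfig

__all__ = ["PRESETS", "get_preset", "load_config", "write_config", "config_to_dict"]

# Calibrated fractions of hearing agents knowing sign language.  With the
# tie-at-the-top weight layout below, the realized assortment among married
# deaf equals the target when the signing-hearing pool K and deaf pool D
# satisfy K * (1 - exp(-D/K)) = (1 - target) * D (fluid limit of the
# tie-break urn process); values verified by simulation.
KAPPA_YAKUT = 0.00122   # realized assortment ~ 0.771 at 0.4994% deaf
KAPPA_USA = 0.002536    # realized assortment ~ 0.76 at 0.998% deaf

# Deaf x deaf (both sign): 2*(w_pheno_d + w_sign_d) = 4
# Deaf x hearing (both sign): w_sign_h + w_sign_d = 4  (tie)
# Hearing x hearing: 2*w_pheno_h = 2
_ASSORTATIVE_WEIGHTS = MatingWeights(
    w_pheno_h=1.0, w_pheno_d=1.0, w_sign_h=3.0, w_sign_d=1.0
)


def _build_presets() -> Dict[str, ScenarioConfig]:
    yakut = dict(
        initial_size=200_000,
        prop_hom=0.0025,
        prop_het=0.10,
        prop_env_deaf=0.0025,
        birthrate_DD=1.78,
        birthrate_DH=1.70,
        birthrate_HH=2.24,
        n_generations=20,
        n_runs=1000,
        ci_level=0.99,
    )
    return {
        "no_deaf_mating": ScenarioConfig(
            name="no_deaf_mating",
            prop_sign_deaf=0.0,
            prop_sign_hearing=0.0,
            weights=MatingWeights(w_pheno_h=1.0, w_pheno_d=0.0),
            **yakut,
        ),
        "assortative": ScenarioConfig(
            name="assortative",
            prop_sign_deaf=1.0,
            prop_sign_hearing=KAPPA_YAKUT,
            weights=_ASSORTATIVE_WEIGHTS,
            **yakut,
        ),
        "random_mating": ScenarioConfig(
            name="random_mating",
            initial_size=200_000,
            prop_hom=0.0025,
            prop_het=0.10,
            prop_env_deaf=0.0025,
            prop_sign_deaf=0.0,
            prop_sign_hearing=0.0,
            weights=MatingWeights(random_mating=True),
            birthrate_DD=2.24,
            birthrate_DH=2.24,
            birthrate_HH=2.24,
            n_generations=20,
            n_runs=1000,
            ci_level=0.99,
        ),
        "usa_validation": ScenarioConfig(
            name="usa_validation",
            initial_size=200_000,
            prop_hom=0.002,
            # Carrier proportion is not published for this preset.  A
            # Hardy-Weinberg-consistent 8.5% caps the assortative homozygote
            # excess near 0.26% (mean-field recursion), short of the
            # documented ~1.9x rise; 10% carriers (q0 ~ 5.2%) is the value a
            # mean-field treatment of this model needs to hit that rise, and
            # is adopted as the reconstruction.
            prop_het=0.10,
            prop_env_deaf=0.008,
            prop_sign_deaf=1.0,
            prop_sign_hearing=KAPPA_USA,
            weights=_ASSORTATIVE_WEIGHTS,
            birthrate_DD=2.1,
            birthrate_DH=2.1,
            birthrate_HH=2.1,
            n_generations=10,
            n_runs=1000,
            ci_level=0.95,
        ),
        "yakut_census": ScenarioConfig(
            name="yakut_census",
            initial_size=227_384,
            prop_hom=0.0,
            prop_het=0.0,
            prop_env_deaf=0.0,
            prop_sign_deaf=0.0,
            prop_sign_hearing=0.0,
            weights=MatingWeights(w_pheno_h=1.0),
            birthrate_DD=2.24,
            birthrate_DH=2.24,
            birthrate_HH=2.24,
            n_generations=5,
            n_runs=1000,
            ci_level=0.99,
        ),
    }


PRESETS: Dict[str, ScenarioConfig] = _build_presets()


def get_preset(name: str) -> ScenarioConfig:
    try:
        return PRESETS[name]
    except KeyError:
        raise KeyError(
            f"unknown preset {name!r}; available: {', '.join(sorted(PRESETS))}"
        ) from None


def config_to_dict(config: ScenarioConfig) -> dict:
    d = dataclasses.asdict(config)
    if d.get("name") is None:
        d.pop("name")
    return d


_CONFIG_FIELDS = {f.name for f in dataclasses.fields(ScenarioConfig)}
_WEIGHT_FIELDS = {f.name for f in dataclasses.fields(MatingWeights)}


def _config_from_dict(data: dict, source: str) -> ScenarioConfig:
    if not isinstance(data, dict):
        raise ValueError(f"{source}: config document must be a mapping")
    unknown = sorted(set(data) - _CONFIG_FIELDS)
    if unknown:
        raise ValueError(f"{source}: unknown configuration keys: {', '.join(unknown)}")
    weights = data.get("weights")
    if isinstance(weights, dict):
        unknown_w = sorted(set(weights) - _WEIGHT_FIELDS)
        if unknown_w:
            raise ValueError(f"{source}: unknown weight keys: {', '.join(unknown_w)}")
        data = {**data, "weights": MatingWeights(**weights)}
    return ScenarioConfig(**data)


def load_config(
    source: Union[str, Path],
    overrides: Optional[dict] = None,
) -> ScenarioConfig:
    """Load a scenario from a preset name or a YAML/JSON file, then apply overrides."""
    source = str(source)
    if source in PRESETS:
        config = PRESETS[source]
    else:
        path = Path(source)
        if not path.exists():
            raise FileNotFoundError(
                f"{source!r} is neither a preset ({', '.join(sorted(PRESETS))}) "
                "nor an existing config file"
            )
        with open(path, "r", encoding="utf-8") as fh:
            data = yaml.safe_load(fh)  # YAML is a superset of JSON
        config = _config_from_dict(data, source)
    if overrides:
        unknown = sorted(set(overrides) - _CONFIG_FIELDS)
        if unknown:
            raise ValueError(f"unknown override keys: {', '.join(unknown)}")
        config = config.with_overrides(**overrides)
    return config


def write_config(config: ScenarioConfig, path: Union[str, Path]) -> None:
    """Serialize a scenario to YAML (or JSON when the suffix is .json)."""
    path = Path(path)
    d = config_to_dict(config)
    with open(path, "w", encoding="utf-8") as fh:
        if path.suffix.lower() == ".json":
            json.dump(d, fh, indent=2)
            fh.write("\n")
        else:
            yaml.safe_dump(d, fh, sort_keys=False)
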