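"""Scenario configuration IO, synthetic scenario generation, and reporting.

A scenario document (YAML) binds a set of regional parameter blocks to a
species and optional model settings::

    species: inachis_io            # default species for all scenarios
    illustrative: true             # provenance flag for packaged fixtures
    stochastic:                    # optional Monte-Carlo settings
      variance: 0.175
      replicates: 1000
      seed: 1
    scenarios:
      - region: Bonn
        species: inachis_io        # optional per-scenario override
        x: 0.4
        a: 0.5
        z: 0.1
        v: 0.8
        y: 0.23
        e: 0.0
        f: 0.5
        C: 10.0
        D: 2.0
        q: 0.1

Schema violations are reported with the offending key path.  Results are
written as CSV with three-significant-figure scientific notation.

The packaged 11-region fixture is *illustrative*: the regional parameter
values behind the published regional estimates were expert-elicited and never
published individually, so the fixture samples plausible values within the
published ranges and is not a reproduction of any published table.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .population import RegionScenario, RiskEstimate
from .stochastic import StochasticSettings

__all__ = [
    "ScenarioCase",
    "ScenarioSet",
    "read_config",
    "write_config",
    "write_results",
    "generate_synthetic_scenarios",
    "zero_host_plant_scenario",
    "load_illustrative_scenarios",
    "PARAMETER_RANGES",
]

_SPECIES = ("inachis_io", "vanessa_atalanta", "plutella_xylostella")
_SCENARIO_FIELDS = ("x", "a", "z", "v", "y", "e", "f", "C", "D", "q")

#: Published per-parameter (min, max) ranges across the 11 regions.  z, v, C
#: and D are generic across species; x, a, y, e, f are species-specific.
#: q has no published range; (0, 0.5) is the generator default.
PARAMETER_RANGES: dict[str, dict[str, tuple[float, float]]] = {
    "inachis_io": {
        "x": (0.2, 0.8), "a": (0.01, 0.6), "y": (0.1, 0.5),
        "e": (0.0, 0.01), "f": (0.0, 10.0),
    },
    "vanessa_atalanta": {
        "x": (0.1, 0.7), "a": (0.01, 0.6), "y": (0.1, 0.5),
        "e": (0.0, 0.01), "f": (0.0, 10.0),
    },
    "plutella_xylostella": {
        "x": (0.1, 0.8), "a": (0.1, 0.8), "y": (0.1, 0.8),
        "e": (0.0, 0.5), "f": (0.0, 15.0),
    },
}
_GENERIC_RANGES: dict[str, tuple[float, float]] = {
    "z": (0.024, 0.7),
    "C": (1.1, 58.0),
    "D": (1.0, 4.5),
    "q": (0.0, 0.5),
}
#: Worst-case MON810 uptake outside Spain (insect-resistance-management cap).
WORST_CASE_V = 0.8


@dataclass(frozen=True)
class ScenarioCase:
    """One region x species scenario."""

    species: str
    scenario: RegionScenario


@dataclass(frozen=True)
class ScenarioSet:
    """A set of scenarios plus shared stochastic settings and provenance."""

    cases: tuple[ScenarioCase, ...]
    stochastic: StochasticSettings | None = None
    illustrative: bool = False

    def __post_init__(self) -> None:
        keys = [(c.scenario.region, c.species) for c in self.cases]
        if len(keys) != len(set(keys)):
            raise ValueError("region/species pairs must be unique")
        for c in self.cases:
            if c.species not in _SPECIES:
                raise ValueError(f"unknown species {c.species!r}")

    def __len__(self) -> int:
        return len(self.cases)


class ConfigError(ValueError):
    """A configuration schema violation, naming the offending key path."""


def _require(mapping: dict, key: str, path: str):
    if key not in mapping:
        raise ConfigError(f"{path}.{key}: missing required key")
    return mapping[key]


def _parse_scenario(block: dict, idx: int, default_species: str | None) -> ScenarioCase:
    path = f"scenarios[{idx}]"
    if not isinstance(block, dict):
        raise ConfigError(f"{path}: expected a mapping")
    region = _require(block, "region", path)
    species = block.get("species", default_species)
    if species is None:
        raise ConfigError(f"{path}.species: no species given and no document default")
    if species not in _SPECIES:
        raise ConfigError(f"{path}.species: unknown species {species!r}")
    kwargs = {}
    for name in _SCENARIO_FIELDS:
        if name == "q" and name not in block:
            continue
        val = _require(block, name, path)
        if not isinstance(val, (int, float)) or isinstance(val, bool):
            raise ConfigError(f"{path}.{name}: expected a number, got {val!r}")
        kwargs[name] = float(val)
    try:
        scen = RegionScenario(region=str(region), **kwargs)
    except ValueError as err:
        raise ConfigError(f"{path}: {err}") from None
    return ScenarioCase(species=species, scenario=scen)


def read_config(path: str | Path) -> ScenarioSet:
    """Read a scenario document from YAML; schema errors name the key path."""
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    return parse_config(doc)


def parse_config(doc) -> ScenarioSet:
    """Parse an already-loaded scenario document (mapping) into a ScenarioSet."""
    if not isinstance(doc, dict):
        raise ConfigError("document root: expected a mapping")
    default_species = doc.get("species")
    blocks = _require(doc, "scenarios", "document root")
    if not isinstance(blocks, list):
        raise ConfigError("scenarios: expected a list")
    cases = tuple(
        _parse_scenario(b, i, default_species) for i, b in enumerate(blocks)
    )
    stoch = None
    if "stochastic" in doc and doc["stochastic"] is not None:
        sb = doc["stochastic"]
        if not isinstance(sb, dict):
            raise ConfigError("stochastic: expected a mapping")
        try:
            stoch = StochasticSettings(
                variance=float(sb.get("variance", 0.175)),
                replicates=int(sb.get("replicates", 1000)),
                seed=int(sb.get("seed", 0)),
            )
        except ValueError as err:
            raise ConfigError(f"stochastic: {err}") from None
    return ScenarioSet(
        cases=cases, stochastic=stoch, illustrative=bool(doc.get("illustrative", False))
    )


def write_config(scenario_set: ScenarioSet, path: str | Path) -> None:
    """Write a ScenarioSet back to YAML (read-write-read is the identity)."""
    doc: dict = {"illustrative": scenario_set.illustrative, "scenarios": []}
    if scenario_set.stochastic is not None:
        s = scenario_set.stochastic
        doc["stochastic"] = {
            "variance": s.variance, "replicates": s.replicates, "seed": s.seed,
        }
    for case in scenario_set.cases:
        block = {"region": case.scenario.region, "species": case.species}
        block.update({k: getattr(case.scenario, k) for k in _SCENARIO_FIELDS})
        doc["scenarios"].append(block)
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)


def write_results(estimates: list[RiskEstimate], path: str | Path) -> pd.DataFrame:
    """Write risk estimates to CSV (3 significant figures, scientific notation).

    Returns the unrounded DataFrame.  Column order is fixed: region, species,
    h, mu, adjusted crop/margin individual rates, population mortality and
    sublethality.
    """
    df = pd.DataFrame(
        {
            "region": [r.region for r in estimates],
            "species": [r.species for r in estimates],
            "h": [r.worst_case_within_crop for r in estimates],
            "mu": [r.worst_case_margin_avg for r in estimates],
            "adjusted_crop": [r.adjusted_individual_crop for r in estimates],
            "adjusted_margin": [r.adjusted_individual_margin for r in estimates],
            "mortality": [r.population_mortality for r in estimates],
            "sublethality": [r.population_sublethality for r in estimates],
        }
    )
    df.to_csv(path, index=False, float_format="%.2e")
    return df


def generate_synthetic_scenarios(
    n: int,
    seed: int,
    species: str = "inachis_io",
    ranges: dict[str, tuple[float, float]] | None = None,
) -> ScenarioSet:
    """Draw ``n`` synthetic regional scenarios uniformly within parameter ranges.

    Defaults reproduce the published per-species ranges; ``v`` is fixed at the
    worst-case uptake 0.8 (the rule applied to all regions outside Spain)
    rather than sampled.  Scenarios that would expose no host plants at all
    (e = 0 and f*D = 0, a measure-zero event under continuous sampling) are
    nudged to a tiny margin density.
    """
    if species not in _SPECIES:
        raise ValueError(f"unknown species {species!r}")
    rng = np.random.default_rng(seed)
    bounds = dict(_GENERIC_RANGES)
    bounds.update(PARAMETER_RANGES[species])
    if ranges:
        bounds.update(ranges)
    cases = []
    for i in range(n):
        params = {
            name: float(rng.uniform(lo, hi)) for name, (lo, hi) in bounds.items()
        }
        if params["e"] == 0.0 and params["f"] * params["D"] == 0.0:
            params["f"] = 1e-6
        scen = RegionScenario(region=f"synthetic-{i}", v=WORST_CASE_V, **params)
        cases.append(ScenarioCase(species=species, scenario=scen))
    return ScenarioSet(cases=tuple(cases), illustrative=True)


def zero_host_plant_scenario(region: str = "Madrid") -> RegionScenario:
    """A Spain-style scenario with essentially no exposed host plants.

    Weed control and irrigation suppress margin vegetation in the Spanish
    regions, so there are almost no host plants: encoded as e = 0 with a tiny
    margin density and y = 0, which drives population mortality to exactly
    zero through the multiplicative chain.
    """
    return RegionScenario(
        region=region, x=0.2, a=0.1, z=0.024, v=0.035, y=0.0,
        e=0.0, f=1e-3, C=20.0, D=1.0, q=0.5,
    )


def load_illustrative_scenarios() -> ScenarioSet:
    """Load the packaged 11-region illustrative fixture (all three species)."""
    ref = resources.files("lepirisk.data").joinpath("regions_illustrative.yaml")
    with resources.as_file(ref) as path:
        return read_config(path)
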