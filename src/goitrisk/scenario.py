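"""Scenario definition: agents, potency weights, RfD approaches, age groups.

A :class:`Scenario` bundles everything the Monte Carlo engine needs for a
cumulative (multi-agent) and aggregate (multi-route) goitrogen exposure
assessment:

* the three risk agents — perchlorate, nitrate, thiocyanate — with their
  perchlorate-equivalence (PEC) potency divisors on two bases,
* truncated-lognormal concentration distributions per agent and route
  (water in ug/L, food in ug/kg effective food-basket concentration),
* age groups with water and food exposure-factor (EF) distributions
  (L/kg-day and kg/kg-day — intake and body mass are folded into one
  factor because they are correlated),
* an optional food-basket composition and a deterministic endogenous
  nitrate production coefficient.

PEC weighting expresses each agent's intake in perchlorate-potency units
by *dividing* by the agent's divisor.  The serum-concentration basis uses
potency ratios 1 : 8.8 : 150 (perchlorate : thiocyanate : nitrate) and
the serum-half-life-corrected ingested-mass basis 1 : 0.5 : 240, so the
same physical intakes weight thiocyanate 17.6x more heavily under the
half-life basis.
"""

from __future__ import annotations

import importlib.resources
import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import yaml

from .distributions import TruncatedLognormal
from .errors import SchemaError

__all__ = [
    "Agent", "RfDApproach", "AgeGroup", "Scenario", "GeneratorSpec",
    "default_constants", "default_agents", "default_approaches",
    "default_age_groups", "synthetic_scenario", "load_scenario",
    "save_scenario", "load_reference_table",
    "AGENT_NAMES", "ROUTES", "BASES", "PERCENTILE_GRID",
    "ROUTE_WATER_SHARES", "COMPONENT_NAMES",
]

AGENT_NAMES = ("perchlorate", "nitrate", "thiocyanate")
ROUTES = ("water", "food")
BASES = ("serum", "halflife")
PERCENTILE_GRID = (1, 5, 10, 30, 50, 70, 90, 95, 99)

#: Fraction of each agent's mean intake arriving via drinking water in the
#: U.S. assessment: 4% for perchlorate, 6% for nitrate, and none for
#: thiocyanate (negligible waterborne concentrations).
ROUTE_WATER_SHARES = {"perchlorate": 0.04, "nitrate": 0.06, "thiocyanate": 0.0}

COMPONENT_NAMES = tuple(f"{a}_{r}" for r in ROUTES for a in AGENT_NAMES)


@dataclass(frozen=True)
class Agent:
    """A goitrogenic risk agent with its PEC potency divisors.

    ``pec_divisor_serum`` / ``pec_divisor_halflife`` are the masses of the
    agent toxicologically equivalent to one mass unit of perchlorate, so
    PEC intake = raw intake / divisor.  Perchlorate itself has divisor 1
    on both bases.
    """

    name: str
    pec_divisor_serum: float
    pec_divisor_halflife: float

    def divisor(self, basis: str) -> float:
        if basis == "serum":
            return self.pec_divisor_serum
        if basis == "halflife":
            return self.pec_divisor_halflife
        raise KeyError(f"unknown basis {basis!r}; expected one of {BASES}")


@dataclass(frozen=True)
class RfDApproach:
    """A reference-dose choice, in ug/kg-day PEC, under both bases.

    A3 derives the RfD from a no-observed-effect level including the
    study population's background goitrogen intake; A4 from an
    exposure-response curve with a 50% iodide-uptake-inhibition
    threshold; A4b from the same curve with a 0-5% threshold.
    """

    name: str
    rfd_no_correction: float
    rfd_with_correction: float

    def rfd(self, basis: str) -> float:
        if basis == "serum":
            return self.rfd_no_correction
        if basis == "halflife":
            return self.rfd_with_correction
        raise KeyError(f"unknown basis {basis!r}; expected one of {BASES}")


@dataclass(frozen=True)
class AgeGroup:
    """An exposure cohort with its water and food exposure factors."""

    name: str
    ef_water: TruncatedLognormal  # L water per kg body mass per day
    ef_food: TruncatedLognormal   # kg food per kg body mass per day


def default_agents() -> tuple[Agent, ...]:
    return (
        Agent("perchlorate", 1.0, 1.0),
        Agent("nitrate", 150.0, 240.0),
        Agent("thiocyanate", 8.8, 0.5),
    )


def default_approaches() -> tuple[RfDApproach, ...]:
    return (
        RfDApproach("A3", 13.5, 22.9),
        RfDApproach("A4", 29.5, 38.9),
        RfDApproach("A4b", 14.5, 23.9),
    )


# Default EF medians (L/kg-day water; kg/kg-day food) are representative
# per-body-mass intake rates by age: infants drink and eat far more per
# kilogram than adults.  Spreads default to GSD 1.3 (water) / 1.25 (food).
_DEFAULT_EF = {
    "1-3 months": (0.130, 0.100),
    "2-3 years": (0.035, 0.080),
    "6-11 years": (0.025, 0.050),
    "18-21 years": (0.015, 0.030),
    ">21 years": (0.016, 0.030),
    "pregnant women": (0.018, 0.033),
}


def default_age_groups(
    gsd_water: float = 1.3, gsd_food: float = 1.25, trunc: float = 3.0
) -> tuple[AgeGroup, ...]:
    return tuple(
        AgeGroup(
            name,
            ef_water=TruncatedLognormal(mw, gsd_water, trunc),
            ef_food=TruncatedLognormal(mf, gsd_food, trunc),
        )
        for name, (mw, mf) in _DEFAULT_EF.items()
    )


def default_constants():
    """Return (agents, approaches, percentile grid) with published defaults."""
    return default_agents(), default_approaches(), list(PERCENTILE_GRID)


@dataclass(frozen=True)
class Scenario:
    """Full input specification for one Monte Carlo assessment."""

    agents: tuple[Agent, ...]
    age_groups: tuple[AgeGroup, ...]
    conc_water: dict[str, TruncatedLognormal]  # agent name -> ug/L
    conc_food: dict[str, TruncatedLognormal]   # agent name -> ug/kg (effective basket)
    basket_shares: dict[str, float] | None = None
    endo_nitrate_coeff: float = 0.0

    def __post_init__(self):
        names = [a.name for a in self.agents]
        if len(set(names)) != len(names) or not names:
            raise SchemaError("agents: must be a non-empty set of unique agents")
        if not self.age_groups:
            raise SchemaError("age_groups: must be non-empty")
        for key, m in (("conc_water", self.conc_water), ("conc_food", self.conc_food)):
            for agent in names:
                if agent not in m:
                    raise SchemaError(f"{key}: missing entry for agent {agent!r}")
        if self.basket_shares is not None:
            total = sum(self.basket_shares.values())
            if abs(total - 1.0) > 1e-9:
                raise SchemaError(f"basket_shares: fractions sum to {total}, not 1")
        if not (self.endo_nitrate_coeff >= 0):
            raise SchemaError(
                f"endo_nitrate_coeff: must be >= 0, got {self.endo_nitrate_coeff}")

    # -- lookups -------------------------------------------------------
    def agent(self, name: str) -> Agent:
        for a in self.agents:
            if a.name == name:
                return a
        raise KeyError(f"unknown agent {name!r}")

    def age_group(self, name: str) -> AgeGroup:
        for g in self.age_groups:
            if g.name == name:
                return g
        raise KeyError(
            f"unknown age group {name!r}; "
            f"available: {[g.name for g in self.age_groups]}")

    def concentration(self, agent: str, route: str) -> TruncatedLognormal:
        if route == "water":
            return self.conc_water[agent]
        if route == "food":
            return self.conc_food[agent]
        raise KeyError(f"unknown route {route!r}; expected one of {ROUTES}")


# ----------------------------------------------------------------------
# Synthetic scenario generation
# ----------------------------------------------------------------------

@dataclass(frozen=True)
class GeneratorSpec:
    """Parameters of the synthetic scenario generator.

    Medians are drawn log-uniformly within ``(lo, hi)`` ranges centred on
    realistic U.S. exposure levels: roughly 1 ug/L perchlorate and a few
    mg/L nitrate in drinking water; food concentrations sized so that
    water carries only a few percent of each agent's intake and nitrate
    dominates the serum-basis PEC total, with thiocyanate food
    concentrations at the hundreds of ug/kg typical of vegetables.
    Concentration GSDs default to 1.5 and all truncations to 3 GSDs.
    """

    conc_median_ranges: dict = field(default_factory=lambda: {
        ("perchlorate", "water"): (0.5, 2.0),        # ug/L
        ("perchlorate", "food"): (8.0, 20.0),        # ug/kg
        ("nitrate", "water"): (2500.0, 8000.0),      # ug/L
        ("nitrate", "food"): (30000.0, 60000.0),     # ug/kg
        ("thiocyanate", "water"): (0.0, 0.0),        # negligible
        ("thiocyanate", "food"): (150.0, 400.0),     # ug/kg
    })
    conc_gsd: float = 1.5
    trunc: float = 3.0
    ef_gsd_water: float = 1.3
    ef_gsd_food: float = 1.25
    endo_nitrate_coeff: float = 0.0
    basket: dict = field(default_factory=lambda: {
        "fruits": 0.15, "vegetables": 0.25, "grains": 0.25,
        "meats": 0.15, "dairy": 0.15, "seafood": 0.05,
    })
    #: log-space jitter of per-category concentrations around the agent median
    basket_category_spread: float = 0.3
    agent_names: tuple = AGENT_NAMES
    age_group_names: tuple = tuple(_DEFAULT_EF)


def synthetic_scenario(seed: int, spec: GeneratorSpec | None = None) -> Scenario:
    """Generate a fully populated, reproducible synthetic :class:`Scenario`.

    Per-category food concentrations are drawn around each agent's base
    median and collapsed through the fixed basket composition into one
    effective food concentration per agent (every individual eats the
    same category mix; only total mass varies, via the food EF).
    """
    spec = spec or GeneratorSpec()
    if not spec.agent_names:
        raise SchemaError("generator spec: empty agent roster")
    if not spec.age_group_names:
        raise SchemaError("generator spec: empty age-group roster")
    rng = np.random.default_rng([int(seed), 0x5C3A])

    def draw_median(lo, hi):
        if hi <= 0:
            return 0.0
        return float(np.exp(rng.uniform(np.log(lo), np.log(hi))))

    conc_water, conc_food = {}, {}
    for agent in spec.agent_names:
        lo, hi = spec.conc_median_ranges[(agent, "water")]
        m = draw_median(lo, hi)
        conc_water[agent] = TruncatedLognormal(m, spec.conc_gsd, spec.trunc)

        lo, hi = spec.conc_median_ranges[(agent, "food")]
        base = draw_median(lo, hi)
        if base == 0:
            conc_food[agent] = TruncatedLognormal(0.0)
            continue
        # per-category medians jittered around the base, then collapsed
        cats = np.array(list(spec.basket.values()))
        jitter = np.exp(rng.normal(0.0, spec.basket_category_spread, len(cats)))
        effective = float(np.sum(cats * base * jitter))
        conc_food[agent] = TruncatedLognormal(effective, spec.conc_gsd, spec.trunc)

    groups = tuple(
        g for g in default_age_groups(spec.ef_gsd_water, spec.ef_gsd_food, spec.trunc)
        if g.name in spec.age_group_names
    )
    return Scenario(
        agents=tuple(a for a in default_agents() if a.name in spec.agent_names),
        age_groups=groups,
        conc_water=conc_water,
        conc_food=conc_food,
        basket_shares=dict(spec.basket),
        endo_nitrate_coeff=spec.endo_nitrate_coeff,
    )


# ----------------------------------------------------------------------
# Config I/O (YAML)
# ----------------------------------------------------------------------

_TOP_KEYS = {"agents", "age_groups", "conc_water", "conc_food",
             "basket_shares", "endo_nitrate_coeff"}


def _dist_to_dict(d: TruncatedLognormal) -> dict:
    return d.to_dict()


def _dist_from_dict(d, key: str) -> TruncatedLognormal:
    if not isinstance(d, dict) or "median" not in d:
        raise SchemaError(f"{key}: expected a mapping with a 'median' field")
    extra = set(d) - {"median", "gsd", "trunc"}
    if extra:
        raise SchemaError(f"{key}: unknown keys {sorted(extra)}")
    try:
        return TruncatedLognormal.from_dict(d)
    except Exception as exc:  # invalid median/gsd/trunc
        raise SchemaError(f"{key}: {exc}") from exc


def save_scenario(scenario: Scenario, path) -> None:
    """Serialise a scenario to YAML; stable (sorted-key) output so two
    saves of the same scenario are byte-identical."""
    doc = {
        "agents": [
            {"name": a.name,
             "pec_divisor_serum": a.pec_divisor_serum,
             "pec_divisor_halflife": a.pec_divisor_halflife}
            for a in scenario.agents
        ],
        "age_groups": [
            {"name": g.name,
             "ef_water": _dist_to_dict(g.ef_water),
             "ef_food": _dist_to_dict(g.ef_food)}
            for g in scenario.age_groups
        ],
        "conc_water": {k: _dist_to_dict(v) for k, v in scenario.conc_water.items()},
        "conc_food": {k: _dist_to_dict(v) for k, v in scenario.conc_food.items()},
        "endo_nitrate_coeff": float(scenario.endo_nitrate_coeff),
    }
    if scenario.basket_shares is not None:
        doc["basket_shares"] = {k: float(v) for k, v in scenario.basket_shares.items()}
    text = yaml.safe_dump(doc, sort_keys=True, default_flow_style=False)
    with open(path, "w") as fh:
        fh.write(text)


def load_scenario(path) -> Scenario:
    """Load a scenario config, validating the schema.

    An agent missing from ``conc_water``/``conc_food`` is filled with the
    degenerate zero distribution (the documented default for negligible
    pathways such as thiocyanate in water).
    """
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    if not isinstance(doc, dict):
        raise SchemaError("scenario config: top level must be a mapping")
    unknown = set(doc) - _TOP_KEYS
    if unknown:
        raise SchemaError(f"scenario config: unknown keys {sorted(unknown)}")
    for req in ("agents", "age_groups", "conc_water", "conc_food"):
        if req not in doc:
            raise SchemaError(f"scenario config: missing required key {req!r}")

    agents = []
    for i, a in enumerate(doc["agents"]):
        extra = set(a) - {"name", "pec_divisor_serum", "pec_divisor_halflife"}
        if extra:
            raise SchemaError(f"agents[{i}]: unknown keys {sorted(extra)}")
        try:
            agents.append(Agent(a["name"], float(a["pec_divisor_serum"]),
                                float(a["pec_divisor_halflife"])))
        except KeyError as exc:
            raise SchemaError(f"agents[{i}]: missing field {exc}") from exc

    groups = []
    for i, g in enumerate(doc["age_groups"]):
        extra = set(g) - {"name", "ef_water", "ef_food"}
        if extra:
            raise SchemaError(f"age_groups[{i}]: unknown keys {sorted(extra)}")
        try:
            groups.append(AgeGroup(
                g["name"],
                _dist_from_dict(g["ef_water"], f"age_groups[{i}].ef_water"),
                _dist_from_dict(g["ef_food"], f"age_groups[{i}].ef_food"),
            ))
        except KeyError as exc:
            raise SchemaError(f"age_groups[{i}]: missing field {exc}") from exc

    agent_names = [a.name for a in agents]

    def conc_map(key):
        out = {}
        raw = doc[key]
        unknown_agents = set(raw) - set(agent_names)
        if unknown_agents:
            raise SchemaError(f"{key}: entries for unknown agents {sorted(unknown_agents)}")
        for agent in agent_names:
            if agent in raw:
                out[agent] = _dist_from_dict(raw[agent], f"{key}.{agent}")
            else:
                out[agent] = TruncatedLognormal(0.0)
        return out

    shares = doc.get("basket_shares")
    if shares is not None:
        shares = {str(k): float(v) for k, v in shares.items()}

    return Scenario(
        agents=tuple(agents),
        age_groups=tuple(groups),
        conc_water=conc_map("conc_water"),
        conc_food=conc_map("conc_food"),
        basket_shares=shares,
        endo_nitrate_coeff=float(doc.get("endo_nitrate_coeff", 0.0)),
    )


# ----------------------------------------------------------------------
# Packaged reference tables (published U.S. assessment results)
# ----------------------------------------------------------------------

_TABLE_FILES = {
    "adri_percentiles": "adri_percentiles.csv",
    "hi_exceedance": "hi_exceedance.csv",
    "cv_shares": "cv_shares.csv",
    "attribution": "attribution.csv",
}


def load_reference_table(name: str) -> pd.DataFrame:
    """Load one of the packaged published reference tables.

    ``name`` is one of ``adri_percentiles`` (composite PEC-ADRI
    percentile rows per age group and basis), ``hi_exceedance``
    (percentage of the population with HI > 1 per RfD approach),
    ``cv_shares`` (contribution-to-variance shares), ``attribution``
    (per-goitrogen exceedance attribution).
    """
    try:
        fname = _TABLE_FILES[name]
    except KeyError:
        raise KeyError(f"unknown table {name!r}; available: {sorted(_TABLE_FILES)}")
    ref = importlib.resources.files("goitrisk.data").joinpath(fname)
    with importlib.resources.as_file(ref) as p:
        return pd.read_csv(p)
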