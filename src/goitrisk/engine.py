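"""Monte Carlo core: per-individual sampling and hazard-index summaries.

Each simulated individual draws one water exposure factor and one food
exposure factor (shared across agents — one person, one intake rate) and
six independent concentration values, one per agent x route.  The
average daily rate of intake (ADRI) for each component is

    ADRI = C x EF            [ug of agent / kg body mass / day]

converted to perchlorate-equivalent (PEC) units by dividing by the
agent's potency divisor on the chosen basis, and summed over the six
components into the composite PEC ADRI.  Dividing by a reference dose
common to the mode of action gives the Hazard Index

    HI = (ADRI_1 + ... + ADRI_k) / RfD

and the population risk metric is the percentage of individuals with
HI > 1.

Concentration draws are perfectly correlated across days within an
individual (a deliberately health-protective over-dispersion: day-to-day
averaging of food sources would narrow the inter-subject distribution,
but the temporal correlation needed to model it is not observable).

Random streams are derived deterministically from the root seed per
(age group, component), so any component's draws are reproducible
independently of evaluation order or of which other components exist.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field

import numpy as np

from .errors import EmptyInputError, NonConvergenceError, UndefinedShareError
from .scenario import (
    AGENT_NAMES,
    BASES,
    PERCENTILE_GRID,
    ROUTES,
    Scenario,
)

__all__ = [
    "ADRISampleSet", "simulate", "percentile_table", "exceedance_fraction",
    "attribute_exceedance", "stability_n", "route_shares", "component_rng",
]


def component_rng(seed: int, age_group: str, component: str) -> np.random.Generator:
    """Deterministic child stream for one (age group, component) pair.

    The stream depends only on the root seed and the two labels (via
    CRC32, stable across platforms and sessions), never on evaluation
    order.
    """
    key = f"{age_group}/{component}".encode()
    return np.random.default_rng([int(seed), zlib.crc32(key)])


@dataclass
class ADRISampleSet:
    """Per-individual draws and PEC-weighted totals for one age group.

    ``components`` holds the PEC-converted intake of each agent x route
    (ug/kg-day PEC); ``conc_draws`` the raw concentration draws (native
    units) and ``ef_draws`` the shared exposure-factor draws, retained so
    the contribution-to-variance decomposition can rank the raw input
    factors against the total.
    """

    age_group: str
    basis: str
    n: int
    components: dict[str, np.ndarray]
    ef_draws: dict[str, np.ndarray]
    conc_draws: dict[str, np.ndarray]
    total: np.ndarray
    seed: int

    def agent_contribution(self, agent: str) -> np.ndarray:
        """Summed water+food PEC contribution of one agent, per individual."""
        return sum(self.components[f"{agent}_{route}"] for route in ROUTES)

    @property
    def agent_names(self) -> tuple[str, ...]:
        seen = []
        for name in self.components:
            agent = name.rsplit("_", 1)[0]
            if agent not in seen:
                seen.append(agent)
        return tuple(seen)


def simulate(
    scenario: Scenario,
    age_group: str,
    basis: str,
    n: int,
    seed: int,
) -> ADRISampleSet:
    """Run the Monte Carlo sampling for one age group and PEC basis.

    For individual ``i`` one water-EF and one food-EF draw are shared
    across agents; agent ``g`` via route ``r`` contributes
    ``EF_r[i] * C_{g,r}[i] / divisor_basis(g)``, with the endogenous
    nitrate multiplier ``(1 + endo_nitrate_coeff)`` applied to nitrate
    intake before PEC conversion.  The basis affects only the divisors,
    so identical seeds give identical draws on both bases.
    """
    if n < 1:
        raise ValueError(f"n must be >= 1, got {n}")
    if basis not in BASES:
        raise KeyError(f"unknown basis {basis!r}; expected one of {BASES}")
    group = scenario.age_group(age_group)  # KeyError on unknown group

    ef_draws = {
        "water": group.ef_water.sample(n, component_rng(seed, age_group, "ef_water")),
        "food": group.ef_food.sample(n, component_rng(seed, age_group, "ef_food")),
    }

    components: dict[str, np.ndarray] = {}
    conc_draws: dict[str, np.ndarray] = {}
    for agent_obj in scenario.agents:
        agent = agent_obj.name
        divisor = agent_obj.divisor(basis)
        for route in ROUTES:
            name = f"{agent}_{route}"
            dist = scenario.concentration(agent, route)
            conc = dist.sample(n, component_rng(seed, age_group, f"conc_{name}"))
            conc_draws[name] = conc
            intake = conc * ef_draws[route]
            if agent == "nitrate":
                intake = intake * (1.0 + scenario.endo_nitrate_coeff)
            components[name] = intake / divisor

    total = sum(components.values())
    return ADRISampleSet(
        age_group=age_group, basis=basis, n=n, components=components,
        ef_draws=ef_draws, conc_draws=conc_draws, total=total, seed=int(seed),
    )


def percentile_table(samples: ADRISampleSet, grid=PERCENTILE_GRID) -> dict[float, float]:
    """Empirical quantiles of the composite PEC ADRI at the grid points.

    Uses the inclusive linear-interpolation definition (numpy's
    ``linear`` method), so e.g. the 50th percentile of 1..100 is 50.5.
    """
    if samples.n == 0 or samples.total.size == 0:
        raise EmptyInputError("cannot take percentiles of an empty sample set")
    values = np.percentile(samples.total, list(grid), method="linear")
    return {float(p): float(v) for p, v in zip(grid, values)}


def exceedance_fraction(samples: ADRISampleSet, rfd: float) -> float:
    """Percentage of individuals with HI = total/RfD strictly above 1."""
    if not (rfd > 0):
        raise ValueError(f"rfd must be > 0, got {rfd}")
    return float(100.0 * np.mean(samples.total / rfd > 1.0))


def attribute_exceedance(
    samples: ADRISampleSet, rfd: float, rule: str = "partition"
) -> dict[str, float]:
    """Split the HI > 1 percentage across agents.

    ``rule="partition"`` (default) assigns each exceeding individual to
    exactly one agent — the one with the largest summed water+food PEC
    contribution — so the per-agent percentages sum exactly to
    :func:`exceedance_fraction`.  ``rule="single"`` instead reports, for
    each agent, the percentage whose HI would exceed 1 from that agent
    alone (no partition property); it exists for sensitivity exploration
    only.
    """
    if not (rfd > 0):
        raise ValueError(f"rfd must be > 0, got {rfd}")
    agents = samples.agent_names
    contribs = np.vstack([samples.agent_contribution(a) for a in agents])
    if rule == "single":
        return {a: float(100.0 * np.mean(contribs[i] / rfd > 1.0))
                for i, a in enumerate(agents)}
    if rule != "partition":
        raise ValueError(f"unknown attribution rule {rule!r}")
    exceeding = samples.total / rfd > 1.0
    winner = np.argmax(contribs, axis=0)  # ties -> first agent (probability zero)
    out = {}
    for i, a in enumerate(agents):
        out[a] = float(100.0 * np.mean(exceeding & (winner == i)))
    return out


def route_shares(samples: ADRISampleSet, agent: str) -> tuple[float, float]:
    """(water %, food %) of the agent's mean PEC contribution; sums to 100."""
    water = float(np.mean(samples.components[f"{agent}_water"]))
    food = float(np.mean(samples.components[f"{agent}_food"]))
    total = water + food
    if total <= 0:
        raise UndefinedShareError(
            f"agent {agent!r} has zero total contribution; route shares undefined")
    return (100.0 * water / total, 100.0 * food / total)


def stability_n(
    scenario: Scenario,
    age_group: str,
    basis: str,
    start_n: int = 1000,
    seed: int = 0,
    rel_tol: float = 0.01,
    cap: int = 10**6,
) -> int:
    """Smallest n on a doubling schedule meeting the 95th-percentile
    stability rule.

    The sample size is doubled until the 95th-percentile estimate at the
    next stage differs from the current stage's by less than ``rel_tol``
    (default 1%) relative; the current stage's n is returned.  Raises
    :class:`NonConvergenceError` (carrying the (n, p95) trace) if the cap
    is reached first.
    """
    if start_n < 1:
        raise ValueError(f"start_n must be >= 1, got {start_n}")

    def p95(n, stage):
        s = simulate(scenario, age_group, basis, n, seed=int(seed) + stage)
        return float(np.percentile(s.total, 95, method="linear"))

    trace = []
    n = int(start_n)
    prev = p95(n, 0)
    trace.append((n, prev))
    stage = 1
    while n <= cap:
        nxt = p95(2 * n, stage)
        trace.append((2 * n, nxt))
        denom = abs(prev) if prev != 0 else 1.0
        if abs(nxt - prev) / denom < rel_tol:
            return n
        n *= 2
        prev = nxt
        stage += 1
    raise NonConvergenceError(
        f"95th percentile not stable within {rel_tol:.1%} below cap {cap}",
        trace=trace,
    )
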