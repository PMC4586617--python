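"""Contribution-to-variance (CV) sensitivity decomposition.

CV answers the risk-management question "which input factor drives the
spread of the hazard metric between individuals?"  Following the
convention of spreadsheet risk tools, each factor's share is the
normalised squared Spearman rank correlation between its draws and the
composite total:

    share(f) = 100 * rho_f^2 / sum_g rho_g^2

over the eight input factors — six concentration draws (agent x route)
and the two shared exposure factors.  Shares sum to 100 exactly before
rounding; a degenerate factor (e.g. thiocyanate in water) has share 0.

A first-order analytic variance-share estimator is provided as an
independent cross-check for the additive-in-components part of the
model; it is not the default.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .engine import ADRISampleSet
from .errors import InsufficientTraceError
from .scenario import AGENT_NAMES, ROUTES

__all__ = ["CVResult", "contribution_to_variance", "first_order_variance_shares",
           "FACTOR_NAMES"]

FACTOR_NAMES = tuple(
    [f"{a}_{r}_conc" for r in ROUTES for a in AGENT_NAMES] + ["water_EF", "food_EF"]
)


@dataclass(frozen=True)
class CVResult:
    """Percentage share of inter-subject variance per input factor."""

    shares: dict[str, float]

    @property
    def total(self) -> float:
        return float(sum(self.shares.values()))

    def dominant_factor(self) -> str:
        return max(self.shares, key=self.shares.get)


def _factor_draws(samples: ADRISampleSet) -> dict[str, np.ndarray]:
    draws = {}
    for route in ROUTES:
        for agent in samples.agent_names:
            name = f"{agent}_{route}"
            if name not in samples.conc_draws:
                raise InsufficientTraceError(
                    f"sample set lacks concentration draws for {name}")
            draws[f"{name}_conc"] = samples.conc_draws[name]
    for route in ROUTES:
        if route not in samples.ef_draws:
            raise InsufficientTraceError(f"sample set lacks {route} EF draws")
    draws["water_EF"] = samples.ef_draws["water"]
    draws["food_EF"] = samples.ef_draws["food"]
    return draws


def contribution_to_variance(samples: ADRISampleSet) -> CVResult:
    """Normalised squared rank-correlation shares of the composite ADRI.

    Requires the sample set to retain per-factor draws (concentration
    and EF); raises :class:`InsufficientTraceError` otherwise.
    """
    draws = _factor_draws(samples)
    total_rank = stats.rankdata(samples.total)
    rho2 = {}
    for name, x in draws.items():
        if np.all(x == x[0]):  # degenerate factor carries no variance
            rho2[name] = 0.0
            continue
        r = np.corrcoef(stats.rankdata(x), total_rank)[0, 1]
        rho2[name] = float(r * r)
    denom = sum(rho2.values())
    if denom == 0:
        # fully degenerate scenario: no factor varies
        return CVResult({name: 0.0 for name in rho2})
    return CVResult({name: 100.0 * v / denom for name, v in rho2.items()})


def first_order_variance_shares(samples: ADRISampleSet) -> CVResult:
    """Analytic first-order cross-check: Var of each component (for
    concentrations, holding EF at its conditional contribution) over the
    summed component variances.

    For the additive model ``total = sum_c EF_r(c) * K_c * C_c`` the
    first-order (main-effect) variance of factor f is
    ``Var(E[total | f])``, estimated here by Monte Carlo regression of
    the total on each factor's draws via binned conditional means.
    """
    draws = _factor_draws(samples)
    total = samples.total
    n = total.size
    nbins = max(10, min(200, n // 200))
    var_total = float(np.var(total))
    shares = {}
    for name, x in draws.items():
        if np.all(x == x[0]) or var_total == 0:
            shares[name] = 0.0
            continue
        order = np.argsort(x)
        splits = np.array_split(total[order], nbins)
        cond_means = np.array([s.mean() for s in splits])
        weights = np.array([s.size for s in splits], dtype=float) / n
        grand = float(np.sum(weights * cond_means))
        shares[name] = float(np.sum(weights * (cond_means - grand) ** 2))
    denom = sum(shares.values())
    if denom == 0:
        return CVResult({name: 0.0 for name in shares})
    return CVResult({name: 100.0 * v / denom for name, v in shares.items()})
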