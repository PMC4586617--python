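"""Truncated lognormal distributions for exposure modelling.

Concentrations of contaminants in environmental media and per-body-mass
intake rates are both well described by lognormal distributions, here
parameterised by a population *median* and a *geometric standard
deviation* (GSD).  Biological and environmental quantities are not
observed arbitrarily far into the tails, so the distribution is
truncated symmetrically in log space at ``±trunc`` GSDs from the median
(default 3) and the density renormalised.

Writing ``s = ln(gsd)``, a draw is ``median * exp(s * Z)`` where ``Z``
is a standard normal restricted to ``[-trunc, +trunc]``.  Sampling is by
inverse CDF on the restricted normal, which guarantees every draw lies
inside the support ``[median / gsd**trunc, median * gsd**trunc]``
without rejection loops.

``median == 0`` is accepted as the degenerate all-zero distribution
(used for pathways with negligible concentration, e.g. thiocyanate in
water); its ``gsd`` is ignored.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, special, stats

from .errors import (
    InconsistentTargetsError,
    InvalidDistributionError,
    UnderdeterminedError,
)

__all__ = ["TruncatedLognormal", "fit_from_percentiles"]


def _phi(z):
    """Standard normal CDF."""
    return special.ndtr(z)


def _phi_inv(p):
    """Standard normal quantile."""
    return special.ndtri(p)


@dataclass(frozen=True)
class TruncatedLognormal:
    """Lognormal distribution truncated at ``±trunc`` GSDs from the median.

    Parameters
    ----------
    median : float
        Population median, in the units of the quantity modelled.
        ``0`` denotes the degenerate all-zero distribution.
    gsd : float
        Geometric standard deviation, dimensionless, > 1.  For an
        untruncated lognormal, 68% of values lie within
        ``[median/gsd, median*gsd]``.
    trunc : float
        Truncation half-width in units of GSDs (log-space z units),
        > 0.  ``math.inf`` gives the untruncated lognormal.
    """

    median: float
    gsd: float = 1.5
    trunc: float = 3.0

    def __post_init__(self):
        m, g, t = self.median, self.gsd, self.trunc
        if not (np.isfinite(m) and m >= 0):
            raise InvalidDistributionError(f"median must be finite and >= 0, got {m}")
        if m == 0:
            return  # degenerate zero distribution; gsd/trunc irrelevant
        if not (np.isfinite(g) and g > 1):
            raise InvalidDistributionError(f"gsd must be finite and > 1, got {g}")
        if not (t > 0):
            raise InvalidDistributionError(f"trunc must be > 0, got {t}")

    # ------------------------------------------------------------------
    @property
    def is_zero(self) -> bool:
        """Whether this is the degenerate all-zero distribution."""
        return self.median == 0

    @property
    def support(self) -> tuple[float, float]:
        if self.is_zero:
            return (0.0, 0.0)
        if math.isinf(self.trunc):
            return (0.0, math.inf)
        half = self.gsd ** self.trunc
        return (self.median / half, self.median * half)

    @property
    def log_sd(self) -> float:
        """Standard deviation of log(X) before truncation, ln(gsd)."""
        return 0.0 if self.is_zero else math.log(self.gsd)

    # ------------------------------------------------------------------
    def _restricted_normal_ppf(self, p):
        """Quantile of a standard normal restricted to [-trunc, +trunc]."""
        t = self.trunc
        if math.isinf(t):
            return _phi_inv(p)
        lo = _phi(-t)
        hi = _phi(t)
        z = _phi_inv(lo + np.asarray(p) * (hi - lo))
        return np.clip(z, -t, t)

    def quantile(self, p):
        """Quantile function, ``median * gsd**z(p)`` with ``z`` the
        renormalised restricted-normal quantile.

        ``p`` may be a scalar or array in the open interval (0, 1);
        the endpoints map to the truncation bounds in the limit.
        """
        p_arr = np.asarray(p, dtype=float)
        if np.any(p_arr <= 0) or np.any(p_arr >= 1):
            raise ValueError(f"probability must lie in (0, 1), got {p}")
        if self.is_zero:
            return np.zeros_like(p_arr) if p_arr.ndim else 0.0
        z = self._restricted_normal_ppf(p_arr)
        out = self.median * np.exp(self.log_sd * z)
        return out if p_arr.ndim else float(out)

    def cdf(self, x):
        """P(X <= x) under the truncated distribution."""
        if self.is_zero:
            return np.where(np.asarray(x, dtype=float) >= 0, 1.0, 0.0)
        x_arr = np.asarray(x, dtype=float)
        with np.errstate(divide="ignore"):
            z = np.where(x_arr > 0, np.log(x_arr / self.median) / self.log_sd, -np.inf)
        t = self.trunc
        if math.isinf(t):
            out = _phi(z)
        else:
            lo, hi = _phi(-t), _phi(t)
            out = np.clip((_phi(np.clip(z, -t, t)) - lo) / (hi - lo), 0.0, 1.0)
            out = np.where(z < -t, 0.0, np.where(z > t, 1.0, out))
        return out if x_arr.ndim else float(out)

    def sf(self, x):
        """P(X > x), the tail probability."""
        return 1.0 - self.cdf(x)

    def mean(self) -> float:
        """Expected value.

        For the truncated form, ``E[exp(sZ)]`` over the restricted
        normal has the closed form
        ``exp(s^2/2) * (Phi(t - s) - Phi(-t - s)) / (Phi(t) - Phi(-t))``.
        """
        if self.is_zero:
            return 0.0
        s = self.log_sd
        t = self.trunc
        if math.isinf(t):
            return self.median * math.exp(s * s / 2)
        frac = (_phi(t - s) - _phi(-t - s)) / (_phi(t) - _phi(-t))
        return self.median * math.exp(s * s / 2) * frac

    def sample(self, n: int, rng: np.random.Generator) -> np.ndarray:
        """Draw ``n`` values via inverse CDF on uniforms from ``rng``."""
        if n < 1:
            raise ValueError(f"n must be >= 1, got {n}")
        if self.is_zero:
            rng.random(n)  # keep the stream advancing uniformly per component
            return np.zeros(n)
        u = rng.random(n)
        z = self._restricted_normal_ppf(u)
        return self.median * np.exp(self.log_sd * z)

    # ------------------------------------------------------------------
    def to_dict(self) -> dict:
        return {"median": float(self.median), "gsd": float(self.gsd),
                "trunc": float(self.trunc) if np.isfinite(self.trunc) else "inf"}

    @classmethod
    def from_dict(cls, d: dict) -> "TruncatedLognormal":
        trunc = d.get("trunc", 3.0)
        if trunc == "inf":
            trunc = math.inf
        return cls(median=float(d["median"]), gsd=float(d.get("gsd", 1.5)),
                   trunc=float(trunc))


def sample(dist: TruncatedLognormal, n: int, rng: np.random.Generator) -> np.ndarray:
    """Module-level alias for :meth:`TruncatedLognormal.sample`."""
    return dist.sample(n, rng)


def quantile(dist: TruncatedLognormal, p):
    """Module-level alias for :meth:`TruncatedLognormal.quantile`."""
    return dist.quantile(p)


def fit_from_percentiles(
    targets: dict[float, float],
    trunc: float = 3.0,
    fix_median: float | None = None,
) -> TruncatedLognormal:
    """Fit (median, gsd) so the distribution's quantiles match ``targets``.

    ``targets`` maps probabilities to strictly increasing positive
    values.  The fit minimises the sum of squared log-errors between
    model quantiles and targets.  With two targets and no truncation
    effect the two-point solution is exact:
    ``gsd = exp(ln(v2/v1) / (z2 - z1))``.

    Parameters
    ----------
    targets : dict
        {probability: value} pairs, at least two, or one plus ``fix_median``.
    trunc : float
        Truncation half-width in GSD units for the fitted distribution.
    fix_median : float, optional
        Hold the median fixed and fit only the GSD.
    """
    items = sorted(targets.items())
    ps = np.array([p for p, _ in items], dtype=float)
    vs = np.array([v for _, v in items], dtype=float)
    if np.any(ps <= 0) or np.any(ps >= 1):
        raise ValueError("target probabilities must lie in (0, 1)")
    if np.any(vs <= 0):
        raise InconsistentTargetsError("target values must be positive")
    if np.any(np.diff(vs) <= 0):
        raise InconsistentTargetsError(
            "target values must be strictly increasing with probability")
    if len(items) < 2 and fix_median is None:
        raise UnderdeterminedError(
            "a single percentile target cannot identify both median and gsd; "
            "supply fix_median or a second target")

    # Closed-form initial guess from untruncated z-scores.
    zs = _phi_inv(ps)
    if fix_median is not None:
        log_m0 = math.log(fix_median)
        nonzero = np.abs(zs) > 1e-12
        if not np.any(nonzero):
            raise UnderdeterminedError("targets at p=0.5 only cannot identify gsd")
        s0 = float(np.mean((np.log(vs[nonzero]) - log_m0) / zs[nonzero]))
    else:
        # least-squares line log(v) = log_m + s*z
        A = np.vstack([np.ones_like(zs), zs]).T
        coef, *_ = np.linalg.lstsq(A, np.log(vs), rcond=None)
        log_m0, s0 = float(coef[0]), float(coef[1])
    s0 = max(s0, 1e-6)

    if math.isinf(trunc):
        # closed form is already the exact least-squares solution
        median = fix_median if fix_median is not None else math.exp(log_m0)
        return TruncatedLognormal(median=median, gsd=math.exp(s0), trunc=trunc)

    lo_t, hi_t = _phi(-trunc), _phi(trunc)
    z_t = np.clip(_phi_inv(lo_t + ps * (hi_t - lo_t)), -trunc, trunc)

    def residuals(theta):
        if fix_median is not None:
            log_m, log_s = math.log(fix_median), theta[0]
        else:
            log_m, log_s = theta
        s = math.exp(log_s)
        return log_m + s * z_t - np.log(vs)

    x0 = [math.log(s0)] if fix_median is not None else [log_m0, math.log(s0)]
    sol = optimize.least_squares(residuals, x0, method="lm")
    if fix_median is not None:
        median, s = fix_median, math.exp(sol.x[0])
    else:
        median, s = math.exp(sol.x[0]), math.exp(sol.x[1])
    return TruncatedLognormal(median=median, gsd=math.exp(s), trunc=trunc)
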