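"""Stationary states, extinction/persistence thresholds, and the
confinement envelope.

Under constant therapy lam0 the equation has a positive stationary point
exactly when lam0 < sigma_inf - sigma_tilde; it solves

    p(u) = (sigma_tilde + lam0) / (3 sigma_inf),        x_s = u**3,

and every positive solution converges to it globally (or to 0 when the
inequality fails).  Under a genuinely periodic schedule the two constant
comparison equations built from gamma_max and gamma_min give states
x1 < x2, and every nonnegative solution eventually stays inside the
envelope [x1/2, 3*x2/2] when lam_max < sigma_inf - sigma_tilde; when
lam_min >= sigma_inf - sigma_tilde the tumor goes extinct.  Between those
inequalities the theory is silent (the conjecture is that
lam_bar < sigma_inf - sigma_tilde already suffices for a periodic orbit).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from enum import Enum

import numpy as np
from scipy.optimize import brentq

from . import kernels
from .model import ModelParams
from .therapy import TherapySchedule

__all__ = [
    "EquilibriumResult",
    "PersistenceBounds",
    "Regime",
    "RegimeResult",
    "stationary_state",
    "persistence_bounds",
    "classify",
    "equilibrium_curve",
    "invert_p",
]


def invert_p(c: float, tol: float = 1e-14) -> float:
    """Solve p(u) = c for u > 0, c in (0, 1/3).

    p is strictly decreasing, so a doubling bracket plus Brent's method is
    unconditionally safe.
    """
    if not 0.0 < c < 1.0 / 3.0:
        raise ValueError("c must lie in (0, 1/3)")
    lo = 1e-8
    if kernels.p(lo) <= c:
        # c within 1e-16 of 1/3; the root is essentially 0
        return lo
    hi = 1.0
    while kernels.p(hi) >= c:
        hi *= 2.0
        if hi > 1e12:  # pragma: no cover - c would have to underflow
            raise RuntimeError("bracket expansion failed")
    return brentq(lambda u: kernels.p(u) - c, lo, hi, xtol=tol, rtol=8.9e-16)


@dataclass(frozen=True)
class EquilibriumResult:
    """Constant-therapy stationary state (if it exists)."""

    exists: bool
    lam0: float
    threshold: float  # sigma_inf - sigma_tilde
    x_s: float | None = None
    R_s: float | None = None
    reason: str = ""

    def residual(self, params: ModelParams) -> float:
        """|3 sigma_inf f(x_s) - (sigma_tilde + lam0) x_s| at the root."""
        if not self.exists:
            return 0.0
        gam = params.sigma_tilde + self.lam0
        return abs(3.0 * params.sigma_inf * kernels.f(self.x_s)
                   - gam * self.x_s)


def stationary_state(params: ModelParams, lam0: float) -> EquilibriumResult:
    """Unique positive stationary point under constant therapy lam0.

    Exists iff lam0 < sigma_inf - sigma_tilde (equivalently the target
    ratio (sigma_tilde + lam0)/(3 sigma_inf) lies below 1/3); found by
    inverting the strictly decreasing kernel p.
    """
    if lam0 < 0:
        raise ValueError("lam0 must be nonnegative")
    thr = params.threshold
    c = (params.sigma_tilde + lam0) / (3.0 * params.sigma_inf)
    if c >= 1.0 / 3.0:
        return EquilibriumResult(False, lam0, thr,
                                 reason="lam0 >= sigma_inf - sigma_tilde: "
                                        "no positive stationary state")
    if c <= 0.0:
        return EquilibriumResult(False, lam0, thr,
                                 reason="no cell loss at all (sigma_tilde = "
                                        "lam0 = 0): growth is unbounded")
    u = invert_p(c)
    return EquilibriumResult(True, lam0, thr, x_s=u**3, R_s=u)


@dataclass(frozen=True)
class PersistenceBounds:
    """Comparison-equation states and the eventual confinement envelope."""

    exists: bool
    x1: float | None = None  # from gamma_max (strong-therapy comparison)
    x2: float | None = None  # from gamma_min (weak-therapy comparison)
    reason: str = ""

    @property
    def envelope(self) -> tuple[float, float] | None:
        if not self.exists:
            return None
        return (self.x1 / 2.0, 1.5 * self.x2)

    @property
    def width(self) -> float | None:
        if not self.exists:
            return None
        lo, hi = self.envelope
        return hi - lo


def persistence_bounds(params: ModelParams,
                       schedule: TherapySchedule) -> PersistenceBounds:
    """x1 < x2 from the constant comparison equations at the schedule's
    extremes; requires lam_max < sigma_inf - sigma_tilde."""
    if schedule.lam_max >= params.threshold:
        return PersistenceBounds(False, reason="lam_max >= sigma_inf - "
                                               "sigma_tilde: no positive roots")
    r1 = stationary_state(params, schedule.lam_max)
    r2 = stationary_state(params, schedule.lam_min)
    if not (r1.exists and r2.exists):
        # lam_min = sigma_tilde = 0: the weak comparison has no finite root
        return PersistenceBounds(False, reason=r2.reason or r1.reason)
    return PersistenceBounds(True, x1=r1.x_s, x2=r2.x_s)


class Regime(Enum):
    EXTINCT_NO_THERAPY_NEEDED = "extinct_no_therapy_needed"
    EXTINCT = "extinct"
    PERSISTENT_PERIODIC_EXISTS = "persistent_periodic_exists"
    INDETERMINATE = "indeterminate"


@dataclass(frozen=True)
class RegimeResult:
    regime: Regime
    certificate: dict = field(default_factory=dict)
    conjecture_periodic: bool = False

    @property
    def extinct(self) -> bool:
        return self.regime in (Regime.EXTINCT,
                               Regime.EXTINCT_NO_THERAPY_NEEDED)


def classify(params: ModelParams, schedule: TherapySchedule) -> RegimeResult:
    """Extinction/persistence classification with inequality certificates.

    - sigma_inf < sigma_tilde: the tumor dies even untreated.
    - lam_min >= sigma_inf - sigma_tilde: global extinction.
    - lam_max < sigma_inf - sigma_tilde: eventual confinement in the
      envelope and existence of a positive omega-periodic solution.
    - otherwise: not resolved by the theory; the conjecture flag is set
      when lam_bar < sigma_inf - sigma_tilde.
    """
    thr = params.threshold
    cert = {
        "sigma_inf": params.sigma_inf,
        "sigma_tilde": params.sigma_tilde,
        "threshold": thr,
        "lam_bar": schedule.lam_bar,
        "lam_max": schedule.lam_max,
        "lam_min": schedule.lam_min,
        "lam_min_positive": schedule.strictly_positive,
    }
    if params.sigma_inf < params.sigma_tilde:
        cert["inequality"] = "sigma_inf < sigma_tilde"
        return RegimeResult(Regime.EXTINCT_NO_THERAPY_NEEDED, cert)
    if schedule.lam_min >= thr:
        cert["inequality"] = "lam_min >= sigma_inf - sigma_tilde"
        return RegimeResult(Regime.EXTINCT, cert)
    if schedule.lam_max < thr:
        cert["inequality"] = "lam_max < sigma_inf - sigma_tilde"
        return RegimeResult(Regime.PERSISTENT_PERIODIC_EXISTS, cert)
    cert["inequality"] = "lam_min < sigma_inf - sigma_tilde <= lam_max"
    return RegimeResult(Regime.INDETERMINATE, cert,
                        conjecture_periodic=schedule.lam_bar < thr)


def equilibrium_curve(params: ModelParams, lam0_grid) -> list[EquilibriumResult]:
    """x_s(lam0) along a grid of constant therapy rates (strictly decreasing
    where it exists, -> 0 as lam0 approaches the threshold)."""
    return [stationary_state(params, float(l0)) for l0 in np.asarray(lam0_grid)]
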