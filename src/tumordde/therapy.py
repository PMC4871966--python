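"""Periodic therapy schedules lam(t) and the functionals the theory uses.

A schedule is a nonnegative omega-periodic apoptosis rate lam(t).  The
analysis depends on three functionals of one period,

    lam_bar = (1/omega) * int_0^omega lam,   lam_max = max lam,   lam_min = min lam,

on the combined death rate gamma(t) = sigma_tilde + lam(t), and on the cone
constant kappa = exp(-omega * (sigma_tilde + lam_bar)) that bounds positive
periodic solutions from below (x(t) >= kappa * sup x).

Three kinds are provided: constant, sinusoidal (mean + amplitude * cos),
and a periodic piecewise table (linear or left-constant interpolation).
Piecewise-constant pulsed dosing goes beyond the continuity assumption of
the underlying theory; the integrator aligns its steps to the table's
breakpoints so the discontinuities never sit inside a step.
"""

from __future__ import annotations

import math
from typing import NamedTuple

import numpy as np

__all__ = [
    "TherapySchedule",
    "ConstantTherapy",
    "SinusoidalTherapy",
    "PiecewiseTherapy",
    "LamStats",
    "lam_stats",
    "kappa",
    "schedule_from_dict",
]

TWO_PI = 2.0 * math.pi


class LamStats(NamedTuple):
    lam_bar: float
    lam_max: float
    lam_min: float


class TherapySchedule:
    """Base class: an omega-periodic nonnegative rate function."""

    kind = "abstract"

    def __init__(self, omega: float):
        if not omega > 0:
            raise ValueError("period omega must be positive")
        self.omega = float(omega)

    # -- subclass surface -------------------------------------------------
    def lam(self, t):
        raise NotImplementedError

    def _cum_in_period(self, tm):
        """int_0^tm lam for tm in [0, omega]."""
        raise NotImplementedError

    @property
    def lam_bar(self) -> float:
        return self._cum_in_period(self.omega) / self.omega

    @property
    def lam_max(self) -> float:
        raise NotImplementedError

    @property
    def lam_min(self) -> float:
        raise NotImplementedError

    def breakpoints(self):
        """Offsets in [0, omega) where lam is not smooth (empty by default)."""
        return np.empty(0)

    # -- shared machinery -------------------------------------------------
    @property
    def strictly_positive(self) -> bool:
        """Whether min lam > 0 — the hypothesis of the periodic-existence
        theory.  Schedules touching 0 are allowed but fall outside it."""
        return self.lam_min > 0

    def cum_lam(self, t) -> float:
        """int_0^t lam(u) du for any real t (periodic decomposition)."""
        t = float(t)
        per_period = self._cum_in_period(self.omega)
        k = math.floor(t / self.omega)
        tm = t - k * self.omega
        return k * per_period + self._cum_in_period(min(tm, self.omega))

    def lam_integral(self, a: float, b: float) -> float:
        """int_a^b lam(u) du."""
        return self.cum_lam(b) - self.cum_lam(a)

    def gamma(self, t, sigma_tilde: float):
        """Combined death rate sigma_tilde + lam(t)."""
        return sigma_tilde + self.lam(t)

    def gamma_integral(self, a: float, b: float, sigma_tilde: float) -> float:
        """int_a^b (sigma_tilde + lam(u)) du."""
        return sigma_tilde * (b - a) + self.lam_integral(a, b)

    def stats(self) -> LamStats:
        return LamStats(self.lam_bar, self.lam_max, self.lam_min)

    def to_dict(self) -> dict:
        raise NotImplementedError

    def __repr__(self):
        return f"{type(self).__name__}(omega={self.omega:g}, " \
               f"stats={tuple(round(v, 6) for v in self.stats())})"


class ConstantTherapy(TherapySchedule):
    """lam(t) = lam0.  Any period represents it; omega defaults to 2*pi."""

    kind = "constant"

    def __init__(self, lam0: float, omega: float = TWO_PI):
        super().__init__(omega)
        if lam0 < 0:
            raise ValueError("therapy rate must be nonnegative")
        self.lam0 = float(lam0)

    def lam(self, t):
        t = np.asarray(t, dtype=float)
        out = np.full_like(t, self.lam0)
        return float(out) if out.ndim == 0 else out

    def _cum_in_period(self, tm):
        return self.lam0 * tm

    @property
    def lam_bar(self):
        return self.lam0

    lam_max = lam_bar
    lam_min = lam_bar

    def to_dict(self):
        return {"kind": self.kind, "omega": self.omega, "lam0": self.lam0}


class SinusoidalTherapy(TherapySchedule):
    """lam(t) = mean + amplitude * cos(2*pi*t/omega + phase).

    Requires amplitude <= mean so the rate stays nonnegative.
    """

    kind = "sinusoidal"

    def __init__(self, mean: float, amplitude: float, omega: float = TWO_PI,
                 phase: float = 0.0):
        super().__init__(omega)
        if amplitude < 0:
            raise ValueError("amplitude must be nonnegative")
        if mean - amplitude < 0:
            raise ValueError("lam(t) would be negative: need amplitude <= mean")
        self.mean = float(mean)
        self.amplitude = float(amplitude)
        self.phase = float(phase)

    def _arg(self, t):
        return TWO_PI * np.asarray(t, dtype=float) / self.omega + self.phase

    def lam(self, t):
        out = self.mean + self.amplitude * np.cos(self._arg(t))
        return float(out) if np.ndim(out) == 0 else out

    def _cum_in_period(self, tm):
        w = TWO_PI / self.omega
        return self.mean * tm + self.amplitude / w * (
            math.sin(w * tm + self.phase) - math.sin(self.phase))

    @property
    def lam_bar(self):
        return self.mean

    @property
    def lam_max(self):
        return self.mean + self.amplitude

    @property
    def lam_min(self):
        return self.mean - self.amplitude

    def to_dict(self):
        return {"kind": self.kind, "omega": self.omega, "mean": self.mean,
                "amplitude": self.amplitude, "phase": self.phase}


class PiecewiseTherapy(TherapySchedule):
    """Periodic table of (time, rate) pairs on [0, omega].

    ``interp='linear'`` joins the nodes (continuous if the endpoint values
    match); ``interp='previous'`` holds each value until the next node
    (pulsed dosing).  Means and extrema are exact for both kinds; the
    cumulative integral is the exact trapezoid/rectangle sum.
    """

    kind = "piecewise"

    def __init__(self, times, values, omega: float, interp: str = "linear"):
        super().__init__(omega)
        times = np.asarray(times, dtype=float)
        values = np.asarray(values, dtype=float)
        if times.ndim != 1 or times.shape != values.shape or times.size < 2:
            raise ValueError("times and values must be matching 1-D arrays, n >= 2")
        if not (np.all(np.diff(times) > 0) and times[0] == 0.0
                and math.isclose(times[-1], omega)):
            raise ValueError("times must increase strictly from 0 to omega")
        if not np.all(np.isfinite(values)):
            raise ValueError("rates must be finite")
        if np.any(values < 0):
            raise ValueError("therapy rates must be nonnegative")
        if interp not in ("linear", "previous"):
            raise ValueError("interp must be 'linear' or 'previous'")
        self.times = times
        self.values = values
        self.interp = interp
        dt_cells = np.diff(times)
        if interp == "linear":
            cell = 0.5 * (values[:-1] + values[1:]) * dt_cells
        else:
            cell = values[:-1] * dt_cells
        self._cum_nodes = np.concatenate(([0.0], np.cumsum(cell)))

    def lam(self, t):
        tm = np.mod(np.asarray(t, dtype=float), self.omega)
        if self.interp == "linear":
            out = np.interp(tm, self.times, self.values)
        else:
            idx = np.clip(np.searchsorted(self.times, tm, side="right") - 1,
                          0, self.times.size - 2)
            out = self.values[idx]
        return float(out) if np.ndim(out) == 0 else out

    def _cum_in_period(self, tm):
        tm = float(np.clip(tm, 0.0, self.omega))
        i = int(np.clip(np.searchsorted(self.times, tm, side="right") - 1,
                        0, self.times.size - 2))
        h = tm - self.times[i]
        if self.interp == "linear":
            v0 = self.values[i]
            vt = float(np.interp(tm, self.times, self.values))
            part = 0.5 * (v0 + vt) * h
        else:
            part = self.values[i] * h
        return float(self._cum_nodes[i] + part)

    @property
    def lam_bar(self):
        return float(self._cum_nodes[-1]) / self.omega

    @property
    def lam_max(self):
        return float(np.max(self.values))

    @property
    def lam_min(self):
        vals = self.values if self.interp == "linear" else self.values[:-1]
        return float(np.min(vals))

    def breakpoints(self):
        return self.times[:-1].copy()

    def to_dict(self):
        return {"kind": self.kind, "omega": self.omega,
                "times": self.times.tolist(), "values": self.values.tolist(),
                "interp": self.interp}


def lam_stats(schedule: TherapySchedule) -> LamStats:
    """(lam_bar, lam_max, lam_min) of one period."""
    return schedule.stats()


def kappa(schedule: TherapySchedule, params) -> float:
    """Cone constant exp(-omega * (sigma_tilde + lam_bar)), in (0, 1).

    Positive omega-periodic solutions satisfy x(t) >= kappa * sup x.
    """
    expo = schedule.omega * (params.sigma_tilde + schedule.lam_bar)
    if not expo > 0:
        raise ValueError("kappa requires sigma_tilde + lam_bar > 0")
    return math.exp(-expo)


_KINDS = {
    "constant": ConstantTherapy,
    "sinusoidal": SinusoidalTherapy,
    "piecewise": PiecewiseTherapy,
}


def schedule_from_dict(d: dict) -> TherapySchedule:
    """Build a schedule from its config mapping {kind, omega, ...}."""
    d = dict(d)
    kind = d.pop("kind")
    try:
        cls = _KINDS[kind]
    except KeyError:
        raise ValueError(f"unknown schedule kind {kind!r}; "
                         f"choose from {sorted(_KINDS)}") from None
    return cls(**d)
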