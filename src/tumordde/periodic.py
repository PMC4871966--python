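"""Locating omega-periodic solutions by two independent routes.

An omega-periodic solution of the delay equation is exactly a fixed point of
the integral operator

    (A x)(t) = 3 sigma_inf * int_t^{t+omega} G(t,s) f(x(s - tau)) ds,

with the periodic Green's kernel G(t,s) = e^{int_t^s gamma} / (1/kappa - 1),
kappa = exp(-omega*(sigma_tilde + lam_bar)).  G is bounded between
kappa/(1-kappa) and 1/(1-kappa), which is what confines fixed points to the
cone {x : x(t) >= kappa * sup x}.

Route one iterates A (Picard) on a uniform period grid with Simpson
quadrature; the existence theory is non-constructive, so non-convergence of
the iteration is reported, not treated as a refutation.  Route two
simulates past the transient and reads off the period map: when successive
periods of the trajectory agree in sup norm, the last period is the orbit.
Agreement of the two routes is the package's strongest correctness check.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.interpolate import CubicSpline

from . import kernels
from .model import ModelParams
from .solver import HistoryFunction, integrate
from .therapy import TherapySchedule, kappa as cone_kappa

__all__ = [
    "PeriodicOrbit",
    "PeriodicSearchResult",
    "green_kernel",
    "apply_A",
    "find_periodic_operator",
    "find_periodic_poincare",
    "orbit_mismatch",
]

DEFAULT_GRID_N = 1024


@dataclass
class PeriodicOrbit:
    """One period of a located omega-periodic solution.

    ``grid`` covers [0, omega) uniformly (phase locked to the schedule's
    t = 0); ``x_path`` are the states there.  ``residual_A`` is the sup norm
    of x - A x, ``residual_P`` the sup-norm mismatch between the final two
    simulated periods; each route fills its own diagnostic.
    """

    grid: np.ndarray
    x_path: np.ndarray
    period: float
    method: str  # "operator_A" | "poincare"
    residual_A: float = math.nan
    residual_P: float = math.nan
    kappa: float = math.nan
    iterations: int = 0
    diagnostics: dict = field(default_factory=dict)

    @property
    def cone_ok(self) -> bool:
        """Cone membership: min x >= kappa * max x (and positivity)."""
        return bool(np.min(self.x_path) > 0
                    and np.min(self.x_path)
                    >= self.kappa * np.max(self.x_path) - 1e-12)

    def __call__(self, t):
        """Periodic interpolation of the orbit at any time."""
        spline = CubicSpline(np.append(self.grid, self.period),
                             np.append(self.x_path, self.x_path[0]),
                             bc_type="periodic")
        return spline(np.mod(t, self.period))

    def as_history(self) -> HistoryFunction:
        """The orbit's periodic extension as an initial history (feeding it
        back to the integrator should reproduce the orbit)."""
        return HistoryFunction(lambda t: float(self(t)))

    def to_csv(self, path) -> None:
        data = np.column_stack([self.grid, self.x_path, np.cbrt(self.x_path)])
        np.savetxt(path, data, delimiter=",", header="t,x,R", comments="")


@dataclass
class PeriodicSearchResult:
    """Outcome of a periodic-orbit search: converged / extinct / failed."""

    status: str
    orbit: PeriodicOrbit | None = None
    diagnostics: dict = field(default_factory=dict)

    @property
    def converged(self) -> bool:
        return self.status == "converged"


def green_kernel(t, s, schedule: TherapySchedule, params: ModelParams):
    """Periodic Green's kernel G(t, s) for s in [t, t + omega].

    Computed as exp(int_t^s gamma - omega*(sigma_tilde + lam_bar))/(1 - kappa)
    — the exponent is <= 0, so no overflow for strong therapy or long
    periods.  Satisfies kappa/(1-kappa) <= G <= 1/(1-kappa).
    """
    t = float(t)
    s_arr = np.asarray(s, dtype=float)
    if np.any(s_arr < t - 1e-12) or np.any(s_arr > t + schedule.omega + 1e-12):
        raise ValueError("s must lie in [t, t + omega]")
    kap = cone_kappa(schedule, params)
    log_kap = -schedule.omega * (params.sigma_tilde + schedule.lam_bar)
    expo = np.array([schedule.gamma_integral(t, float(si), params.sigma_tilde)
                     for si in np.atleast_1d(s_arr)]) + log_kap
    out = np.exp(np.minimum(expo, 0.0)) / (1.0 - kap)
    return float(out[0]) if s_arr.ndim == 0 else out


def _period_grid(schedule: TherapySchedule, n: int) -> np.ndarray:
    return np.arange(n) * (schedule.omega / n)


def _cum_gamma_nodes(schedule: TherapySchedule, params: ModelParams,
                     n: int) -> np.ndarray:
    """int_0^{t_k} gamma at the n+1 uniform nodes of one period."""
    om = schedule.omega
    return np.array([schedule.gamma_integral(0.0, k * om / n,
                                             params.sigma_tilde)
                     for k in range(n + 1)])


def apply_A(x_path: np.ndarray, schedule: TherapySchedule,
            params: ModelParams, _cum: np.ndarray | None = None) -> np.ndarray:
    """One application of the integral operator A on a uniform period grid.

    The delayed lookup x(s - tau) uses the periodic cubic-spline extension
    of the path; the integral uses composite Simpson over the n grid cells.
    The output is omega-periodic by construction.  ``_cum`` optionally
    supplies precomputed cumulative-gamma nodes (an iteration-loop cache).
    """
    x_path = np.asarray(x_path, dtype=float)
    if np.any(x_path < 0):
        raise ValueError("candidate path must be nonnegative")
    n = x_path.size
    if n % 2 or n < 8:
        raise ValueError("grid size must be even and >= 8")
    om = schedule.omega
    kap = cone_kappa(schedule, params)
    cum = _cum if _cum is not None else _cum_gamma_nodes(schedule, params, n)
    P = cum[-1]  # omega * (sigma_tilde + lam_bar)

    # periodic extension of cum gamma to 2n+1 nodes
    cum_ext = np.concatenate([cum, cum[1:] + P])

    # f(x(t_k - tau)) on the grid, via the periodic spline of the path
    spline = CubicSpline(np.append(_period_grid(schedule, n), om),
                         np.append(x_path, x_path[0]), bc_type="periodic")
    shifted = np.mod(_period_grid(schedule, n) - params.tau, om)
    q = kernels.f(np.maximum(spline(shifted), 0.0))

    idx = np.arange(n)[:, None] + np.arange(n + 1)[None, :]
    # G(t_i, t_i + u_j) * (1 - kappa) = exp(cum(t_{i+j}) - cum(t_i) - P)
    K = np.exp(cum_ext[idx] - cum[:n][:, None] - P)
    Q = q[idx % n]

    h = om / n
    w = np.full(n + 1, 2.0 * h / 3.0)
    w[1::2] = 4.0 * h / 3.0
    w[0] = w[-1] = h / 3.0
    return (3.0 * params.sigma_inf / (1.0 - kap)) * ((K * Q) @ w)


def find_periodic_operator(schedule: TherapySchedule, params: ModelParams,
                           init_path: np.ndarray | None = None,
                           tol: float = 1e-10, max_iter: int = 10_000,
                           grid_n: int = DEFAULT_GRID_N) -> PeriodicSearchResult:
    """Picard iteration of the operator A from a constant initial path.

    The default initial path is the upper persistence state x2 (the region
    where the existence theory places the orbit); convergence is declared
    when the sup-norm change drops below ``tol``.  The fixed-point theory
    guarantees existence, not contraction, so non-convergence returns a
    failure record rather than raising.
    """
    from .equilibria import persistence_bounds, stationary_state

    if init_path is None:
        pb = persistence_bounds(params, schedule)
        if pb.exists:
            level = pb.x2
        else:
            eq = stationary_state(params, schedule.lam_bar)
            level = eq.x_s if eq.exists else 1.0
        init_path = np.full(grid_n, level)
    x = np.asarray(init_path, dtype=float).copy()
    if x.size != grid_n:
        grid_n = x.size

    cum = _cum_gamma_nodes(schedule, params, grid_n)
    hist = []
    change = math.inf
    for it in range(1, max_iter + 1):
        x_new = apply_A(x, schedule, params, _cum=cum)
        change = float(np.max(np.abs(x_new - x)))
        hist.append(change)
        x = x_new
        if change <= tol:
            break
    kap = cone_kappa(schedule, params)
    residual = float(np.max(np.abs(apply_A(x, schedule, params, _cum=cum) - x)))
    orbit = PeriodicOrbit(_period_grid(schedule, grid_n), x, schedule.omega,
                          method="operator_A", residual_A=residual, kappa=kap,
                          iterations=len(hist),
                          diagnostics={"last_change": change})
    if np.max(x) < 1e-8:
        # the iteration collapsed to the trivial (tumor-free) solution
        return PeriodicSearchResult("extinct",
                                    diagnostics={"iterations": len(hist),
                                                 "last_change": change})
    if change <= tol and np.min(x) > 0:
        return PeriodicSearchResult("converged", orbit)
    status = "failed" if np.min(x) > 0 else "extinct"
    return PeriodicSearchResult(status, orbit if np.min(x) > 0 else None,
                                diagnostics={"iterations": len(hist),
                                             "last_change": change,
                                             "history_tail": hist[-10:]})


def find_periodic_poincare(schedule: TherapySchedule, params: ModelParams,
                           history: HistoryFunction,
                           n_transient: int = 50, tol: float = 1e-6,
                           dt: float | None = None,
                           grid_n: int = DEFAULT_GRID_N,
                           max_transient: int = 400) -> PeriodicSearchResult:
    """Periodic orbit as a fixed point of the period map on simulation.

    Integrates ``n_transient`` forcing periods, then compares the last two
    periods in sup norm on a uniform grid: mismatch <= ``tol`` yields the
    final period as the orbit; a vanished last period yields an extinction
    outcome; otherwise the transient is doubled up to ``max_transient``
    periods before giving up.
    """
    om = schedule.omega
    kap = cone_kappa(schedule, params)
    grid = _period_grid(schedule, grid_n)
    n = n_transient
    attempts = []
    while True:
        t_end = n * om
        traj = integrate(params, schedule, history, t_end, dt)
        last = traj(t_end - om + grid)
        prev = traj(t_end - 2 * om + grid)
        mismatch = float(np.max(np.abs(last - prev)))
        attempts.append({"n_transient": n, "mismatch": mismatch,
                         "max_last_period": float(np.max(last))})
        if np.max(last) <= 1e-6:
            return PeriodicSearchResult("extinct",
                                        diagnostics={"attempts": attempts})
        if mismatch <= tol:
            orbit = PeriodicOrbit(grid, last, om, method="poincare",
                                  residual_P=mismatch, kappa=kap,
                                  iterations=n,
                                  diagnostics={"attempts": attempts,
                                               "dt": traj.meta["dt"]})
            return PeriodicSearchResult("converged", orbit)
        if 2 * n > max_transient:
            return PeriodicSearchResult("failed",
                                        diagnostics={"attempts": attempts})
        n *= 2


def orbit_mismatch(a: PeriodicOrbit, b: PeriodicOrbit,
                   n_samples: int = 2048) -> float:
    """Sup-norm difference of two orbits with the same period and phase."""
    if not math.isclose(a.period, b.period, rel_tol=1e-9):
        raise ValueError("orbits have different periods")
    ts = np.linspace(0.0, a.period, n_samples, endpoint=False)
    return float(np.max(np.abs(a(ts) - b(ts))))
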