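"""Named simulation presets, the random-scenario generator, and the
scenario runner.

The eight presets are the canonical parameter sets used throughout the
package's validation: a stationary-state sweep (fig1), constant-therapy
convergence and extinction (fig2, fig3), periodic-therapy persistence and
extinction (fig4, fig5), a case in the gap of the theory where simulation
still finds a periodic orbit (fig6), and multi-history convergence probes
of the orbit-uniqueness conjecture (fig7, fig8).  All use sigma_inf = 5 and
a mitotic delay tau = 1; the sinusoidal schedules have period 2*pi.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .equilibria import (Regime, classify, equilibrium_curve,
                         persistence_bounds, stationary_state)
from .model import ModelParams
from .periodic import find_periodic_poincare, orbit_mismatch
from .solver import HistoryFunction, integrate
from .therapy import (ConstantTherapy, SinusoidalTherapy, TherapySchedule,
                      schedule_from_dict)

__all__ = [
    "ScenarioPreset",
    "PRESET_NAMES",
    "preset",
    "run_scenario",
    "random_scenario",
    "check_envelope_confinement",
]

TWO_PI = 2.0 * math.pi


@dataclass(frozen=True)
class ScenarioPreset:
    name: str
    params: ModelParams
    schedule: TherapySchedule
    histories: tuple  # constant x0 values
    expected: str  # extinct | converge_to_xs | periodic | envelope_confined
    #              | equilibrium_curve
    note: str = ""

    def to_dict(self) -> dict:
        return {"name": self.name, "params": self.params.to_dict(),
                "schedule": self.schedule.to_dict(),
                "histories": list(self.histories), "expected": self.expected}

    @classmethod
    def from_dict(cls, d: dict) -> "ScenarioPreset":
        return cls(name=d["name"], params=ModelParams.from_dict(d["params"]),
                   schedule=schedule_from_dict(d["schedule"]),
                   histories=tuple(d["histories"]), expected=d["expected"])


def _make_presets() -> dict:
    sig = 5.0
    tau = 1.0
    cos1 = lambda mean: SinusoidalTherapy(mean=mean, amplitude=1.0,
                                          omega=TWO_PI)
    return {
        # stationary-state sweep x_s(lam0) for sigma_inf=5, sigma_tilde=2
        "fig1": ScenarioPreset(
            "fig1", ModelParams(sig, 2.0, tau=tau), ConstantTherapy(0.0),
            (), "equilibrium_curve"),
        # combined death rate gamma = 4 (constant): converges to x_s
        "fig2": ScenarioPreset(
            "fig2", ModelParams(sig, 0.0, tau=tau), ConstantTherapy(4.0),
            (2.0,), "converge_to_xs",
            note="caption gives gamma(t)=4 without splitting; stored as "
                 "sigma_tilde=0, lam0=4 (only gamma enters the equation)"),
        # gamma = 5.5 > sigma_inf: extinction under constant therapy
        "fig3": ScenarioPreset(
            "fig3", ModelParams(sig, 0.0, tau=tau), ConstantTherapy(5.5),
            (2.0,), "extinct"),
        # lam = 1 + cos t: lam_max = 2 < 4, persistence + periodic orbit
        "fig4": ScenarioPreset(
            "fig4", ModelParams(sig, 1.0, tau=tau), cos1(1.0),
            (2.0,), "periodic",
            note="lam touches 0, outside the strict-positivity hypothesis"),
        # lam = 5 + cos t: lam_min = 4 >= 4, extinction
        "fig5": ScenarioPreset(
            "fig5", ModelParams(sig, 1.0, tau=tau), cos1(5.0),
            (2.0,), "extinct"),
        # theory gap: lam_min = 0.5 < 2 <= lam_max = 2.5, orbit found anyway
        "fig6": ScenarioPreset(
            "fig6", ModelParams(sig, 3.0, tau=tau), cos1(1.5),
            (2.6,), "periodic",
            note="indeterminate by the theorems; the conjecture case"),
        # uniqueness probe, well inside the persistence regime
        "fig7": ScenarioPreset(
            "fig7", ModelParams(sig, 1.5, tau=tau), cos1(1.5),
            (2.0, 20.0, 50.0), "periodic"),
        # uniqueness probe in the theory gap
        "fig8": ScenarioPreset(
            "fig8", ModelParams(sig, 3.0, tau=tau), cos1(1.5),
            (2.0, 3.0, 5.0), "periodic"),
    }


_PRESETS = _make_presets()
PRESET_NAMES = tuple(_PRESETS)


def preset(name: str) -> ScenarioPreset:
    """Named preset configuration (fig1 ... fig8)."""
    try:
        return _PRESETS[name]
    except KeyError:
        raise ValueError(f"unknown preset {name!r}; "
                         f"choose from {PRESET_NAMES}") from None


def check_envelope_confinement(params: ModelParams,
                               schedule: TherapySchedule, x0: float,
                               dt: float | None = None,
                               max_doublings: int = 2) -> dict:
    """Whether a trajectory eventually stays inside the persistence envelope.

    Operationalized as: over the last 20% of a horizon
    t_end = max(50*tau, 50*omega), the sampled range of x lies inside
    [x1/2, 3*x2/2]; the horizon is doubled (up to ``max_doublings`` times)
    if the check fails, since the theory's entry time T is not quantified.
    """
    pb = persistence_bounds(params, schedule)
    if not pb.exists:
        return {"confined": False, "reason": pb.reason, "bounds": None}
    lo, hi = pb.envelope
    t_end = max(50.0 * params.tau, 50.0 * schedule.omega)
    for attempt in range(max_doublings + 1):
        traj = integrate(params, schedule, HistoryFunction.constant(x0),
                         t_end, dt)
        ts = np.linspace(0.8 * t_end, t_end, 512)
        xs = traj(ts)
        x_min, x_max = float(np.min(xs)), float(np.max(xs))
        confined = lo <= x_min and x_max <= hi
        if confined or attempt == max_doublings:
            return {"confined": confined, "x_range": (x_min, x_max),
                    "bounds": (lo, hi), "t_end": t_end, "x1": pb.x1,
                    "x2": pb.x2}
        t_end *= 2.0


def run_scenario(sc: ScenarioPreset, t_end: float = 200.0,
                 dt: float | None = None, out_dir=None) -> dict:
    """Simulate a preset, run the applicable analyses, and check its
    expected qualitative outcome.  Returns a verdict report."""
    report = {"name": sc.name, "expected": sc.expected,
              "classification": classify(sc.params, sc.schedule).regime.value}
    passed = True

    if sc.expected == "equilibrium_curve":
        grid = np.linspace(0.0, sc.params.threshold, 61)[:-1]
        curve = equilibrium_curve(sc.params, grid)
        xs = np.array([r.x_s for r in curve])
        report["curve"] = {"lam0": grid.tolist(), "x_s": xs.tolist()}
        passed = bool(np.all(np.diff(xs) < 0))
    else:
        trajs = [integrate(sc.params, sc.schedule,
                           HistoryFunction.constant(x0), t_end, dt)
                 for x0 in sc.histories]
        finals = [t.final_value() for t in trajs]
        report["final_values"] = finals
        if out_dir is not None:
            for x0, tr in zip(sc.histories, trajs):
                tr.to_csv(f"{out_dir}/{sc.name}_x0_{x0:g}.csv")

        if sc.expected == "extinct":
            passed = all(v <= 1e-3 for v in finals)
        elif sc.expected == "converge_to_xs":
            eq = stationary_state(sc.params, sc.schedule.lam_bar)
            report["x_s"] = eq.x_s
            passed = eq.exists and all(abs(v - eq.x_s) <= 1e-4
                                       for v in finals)
        elif sc.expected in ("periodic", "envelope_confined"):
            results = [find_periodic_poincare(sc.schedule, sc.params,
                                              HistoryFunction.constant(x0),
                                              dt=dt)
                       for x0 in sc.histories]
            statuses = [r.status for r in results]
            report["poincare_status"] = statuses
            passed = all(s == "converged" for s in statuses)
            orbits = [r.orbit for r in results if r.converged]
            if len(orbits) > 1:
                pair = max(orbit_mismatch(a, b)
                           for i, a in enumerate(orbits)
                           for b in orbits[i + 1:])
                report["pairwise_orbit_mismatch"] = pair
                passed = passed and pair <= 1e-4
            if orbits and out_dir is not None:
                orbits[0].to_csv(f"{out_dir}/{sc.name}_orbit.csv")
            env = check_envelope_confinement(sc.params, sc.schedule,
                                             sc.histories[0], dt=dt)
            report["envelope"] = {k: env.get(k) for k in
                                  ("confined", "bounds", "x_range")}
            if classify(sc.params, sc.schedule).regime \
                    is Regime.PERSISTENT_PERIODIC_EXISTS:
                passed = passed and env["confined"]
        else:
            raise ValueError(f"unknown expected label {sc.expected!r}")

    report["passed"] = bool(passed)
    return report


def random_scenario(seed: int, regime: str) -> ScenarioPreset:
    """Seeded random admissible scenario in a requested regime.

    Draws sigma_inf in [1, 10], sigma_tilde in [0, sigma_inf), a sinusoidal
    schedule (mean in [0.05, 5], amplitude in [0, mean], period in [2, 10]),
    tau in [0.1, 2] and x0 in (0, 100], rejection-sampling the schedule until
    the regime's inequality holds.  Fully determined by the seed.
    """
    if regime not in ("extinct", "persistent", "indeterminate"):
        raise ValueError("regime must be extinct | persistent | indeterminate")
    rng = np.random.default_rng(seed)
    for _ in range(10_000):
        sigma_inf = rng.uniform(1.0, 10.0)
        sigma_tilde = rng.uniform(0.0, sigma_inf)
        thr = sigma_inf - sigma_tilde
        mean = rng.uniform(0.05, 5.0)
        amplitude = rng.uniform(0.0, mean)
        omega = rng.uniform(2.0, 10.0)
        phase = rng.uniform(0.0, TWO_PI)
        lam_min, lam_max = mean - amplitude, mean + amplitude
        ok = {"extinct": lam_min >= thr,
              "persistent": lam_max < thr,
              "indeterminate": lam_min < thr <= lam_max}[regime]
        if not ok:
            continue
        tau = rng.uniform(0.1, 2.0)
        x0 = rng.uniform(1e-6, 100.0)
        expected = {"extinct": "extinct", "persistent": "envelope_confined",
                    "indeterminate": "periodic"}[regime]
        return ScenarioPreset(
            name=f"random-{regime}-{seed}",
            params=ModelParams(sigma_inf, sigma_tilde, tau=tau),
            schedule=SinusoidalTherapy(mean, amplitude, omega, phase),
            histories=(x0,), expected=expected)
    raise RuntimeError(f"could not draw a {regime!r} scenario in 10000 tries")
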