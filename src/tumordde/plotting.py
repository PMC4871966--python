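"""Headless-safe plotting helpers (all verdicts derive from data files, not
from these figures)."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt  # noqa: E402
import numpy as np  # noqa: E402

__all__ = ["plot_trajectory", "plot_orbit", "plot_equilibrium_curve"]


def plot_trajectory(traj, path, variable="x"):
    fig, ax = plt.subplots(figsize=(6, 4))
    ts = np.linspace(0.0, traj.t_end, 2000)
    ys = traj.x(ts) if variable == "x" else traj.R(ts)
    ax.plot(ts, ys, lw=1.2)
    ax.set_xlabel("t")
    ax.set_ylabel("x(t) = R(t)^3" if variable == "x" else "R(t)")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_orbit(orbit, path):
    fig, ax = plt.subplots(figsize=(6, 4))
    ts = np.linspace(0.0, orbit.period, 1000)
    ax.plot(ts, orbit(ts), lw=1.4)
    ax.set_xlabel("t (one period)")
    ax.set_ylabel("x(t)")
    ax.set_title(f"{orbit.method}, period {orbit.period:g}")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_equilibrium_curve(lam0, x_s, path):
    fig, ax = plt.subplots(figsize=(6, 4))
    ax.plot(lam0, x_s, lw=1.4)
    ax.set_xlabel("constant therapy rate lam0")
    ax.set_ylabel("stationary state x_s")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
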