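"""Model parameters and the right-hand side of the reduced delay equation.

After rescaling space (consumption coefficient = 1) and solving the nutrient
balance in closed form, the free-boundary problem collapses to one scalar
delay differential equation for the cubed radius x = R**3:

    dx/dt = s * [ 3*sigma_inf * f(x(t - tau)) - gamma(t) * x(t) ],

with f(x) = x * p(x**(1/3)) and gamma(t) = sigma_tilde + lam(t), the sum of
the natural apoptosis rate and the periodic therapy-induced rate.  The
proliferation time constant s multiplies the whole field; s = 1 is the
conventional rescaling and all analysis thresholds are independent of s.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np

from . import kernels

__all__ = ["ModelParams", "rhs_x", "rhs_R"]


@dataclass(frozen=True)
class ModelParams:
    """Scalar parameters of the reduced model.

    Parameters
    ----------
    sigma_inf : float
        External nutrient concentration sigma_inf > 0 (dimensionless after
        rescaling).
    sigma_tilde : float
        Natural (therapy-free) apoptosis rate, >= 0.
    s : float, default 1.0
        Proliferation rate constant; 1 after the conventional rescaling.
    gamma_diff : float, default 1.0
        Nutrient consumption coefficient; 1 after rescaling space.
    tau : float, default 0.0
        Mitotic delay: the lag between nutrient uptake and completed cell
        division (time units), >= 0.
    """

    sigma_inf: float
    sigma_tilde: float = 0.0
    s: float = 1.0
    gamma_diff: float = 1.0
    tau: float = 0.0

    def __post_init__(self):
        if not self.sigma_inf > 0:
            raise ValueError("sigma_inf must be positive")
        if self.sigma_tilde < 0:
            raise ValueError("sigma_tilde must be nonnegative")
        if not self.s > 0:
            raise ValueError("s must be positive")
        if not self.gamma_diff > 0:
            raise ValueError("gamma_diff must be positive")
        if self.tau < 0:
            raise ValueError("tau must be nonnegative")

    @property
    def threshold(self) -> float:
        """sigma_inf - sigma_tilde: the therapy budget above which constant
        therapy (or min-rate therapy) forces extinction."""
        return self.sigma_inf - self.sigma_tilde

    @property
    def viable(self) -> bool:
        """Whether sigma_inf > sigma_tilde (the standing assumption of the
        persistence analysis; below it the tumor dies untreated)."""
        return self.sigma_inf > self.sigma_tilde

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "ModelParams":
        return cls(**d)


def rhs_x(x_now, x_delay, t, params: ModelParams, schedule) -> float:
    """dx/dt of the cubed-radius equation at time t.

    ``s * [3*sigma_inf*f(x_delay) - (sigma_tilde + lam(t)) * x_now]``.
    """
    if np.any(np.asarray(x_now) < 0) or np.any(np.asarray(x_delay) < 0):
        raise ValueError("states must be nonnegative")
    gam = params.sigma_tilde + schedule.lam(t)
    return params.s * (3.0 * params.sigma_inf * kernels.f(x_delay) - gam * x_now)


def rhs_R(R_now, R_delay, t, params: ModelParams, schedule) -> float:
    """dR/dt of the radius equation at time t.

    ``s * R * [sigma_inf * p(R_delay) * (R_delay/R)**3
               - sigma_tilde/3 - lam(t)/3]``,
    continuously extended by 0 at R = 0.  Algebraically equivalent to
    :func:`rhs_x` under x = R**3 (chain rule: dx/dt = 3 R**2 dR/dt).
    """
    R_now = float(R_now)
    R_delay = float(R_delay)
    if R_now < 0 or R_delay < 0:
        raise ValueError("radii must be nonnegative")
    if R_now == 0.0:
        return 0.0
    gam = params.sigma_tilde + schedule.lam(t)
    prolif = params.sigma_inf * kernels.p(R_delay) * (R_delay / R_now) ** 3
    return params.s * R_now * (prolif - gam / 3.0)
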