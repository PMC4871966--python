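"""Closed-form kernels of the reduced tumor-growth model.

The quasi-steady nutrient balance inside a nonnecrotic spherical tumor gives
the radial concentration profile ``sigma_inf * (R/sinh R) * (sinh r / r)``
(consumption coefficient rescaled to 1).  Integrating proliferation over the
sphere produces the kernel

    p(x) = (x coth x - 1) / x**2,

which is the volume-averaged nutrient fraction at radius ``x``; ``p`` is
strictly decreasing from 1/3 at 0 to 0 at infinity.  In the cubed-radius
variable ``x = R**3`` the proliferation term becomes ``f(x) = x * p(x**(1/3))``.

All functions accept scalars or numpy arrays and evaluate without
catastrophic cancellation (Maclaurin branch near 0) or overflow (asymptotic
branch for large arguments).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "KernelValue",
    "p",
    "p_prime",
    "f",
    "f_prime",
    "p_kernel",
    "f_kernel",
    "f_prime_kernel",
    "nutrient_profile",
    "SERIES_SWITCH",
]

#: below this argument p and p' are evaluated by their Maclaurin series;
#: both branches agree to ~1e-14 relative in a band around the switch.
SERIES_SWITCH = 0.2

# Maclaurin coefficients of p(x) = 1/3 - x^2/45 + 2x^4/945 - x^6/4725
#   + 2x^8/93555 - 1382x^10/638512875 + ...  (from the Bernoulli expansion
# of x coth x); truncation error below 1e-15 for x <= SERIES_SWITCH.
_P_COEF = (
    1.0 / 3.0,
    -1.0 / 45.0,
    2.0 / 945.0,
    -1.0 / 4725.0,
    2.0 / 93555.0,
    -1382.0 / 638512875.0,
)
# large-argument cutoff: tanh(x) == 1 in double precision for x >= 19.1,
# so the direct formula degrades gracefully; we switch exactly there to
# avoid evaluating sinh (overflow in p') for big x.
_ASYMPTOTIC_SWITCH = 19.0


@dataclass(frozen=True)
class KernelValue:
    """Scalar kernel evaluation together with the branch that produced it."""

    value: float
    branch: str  # "series" | "direct"


def _series_p(x):
    x2 = np.square(x)
    acc = np.full_like(x2, _P_COEF[-1])
    for c in _P_COEF[-2::-1]:
        acc = acc * x2 + c
    return acc


def _series_p_prime(x):
    # termwise derivative of the series above
    x2 = np.square(x)
    acc = np.zeros_like(x2)
    for k in range(len(_P_COEF) - 1, 0, -1):
        acc = acc * x2 + 2 * k * _P_COEF[k]
    return acc * x


def _direct_p(x):
    with np.errstate(invalid="ignore", divide="ignore"):
        out = (x / np.tanh(x) - 1.0) / np.square(x)
    return out


def _direct_p_prime(x):
    small = x < _ASYMPTOTIC_SWITCH
    xs = np.where(small, x, 1.0)  # keep sinh off the overflow range
    with np.errstate(invalid="ignore", divide="ignore"):
        core = (1.0 / np.tanh(xs) - xs / np.square(np.sinh(xs))) / np.square(xs) \
            - 2.0 * (xs / np.tanh(xs) - 1.0) / xs**3
        tail = -1.0 / np.square(x) + 2.0 / x**3
    return np.where(small, core, tail)


def _dispatch(x, series_fn, direct_fn, name):
    arr = np.asarray(x, dtype=float)
    if np.any(arr < 0):
        raise ValueError(f"{name} requires a nonnegative argument")
    use_series = arr <= SERIES_SWITCH
    out = np.where(use_series,
                   series_fn(np.where(use_series, arr, 0.0)),
                   direct_fn(np.where(use_series, 1.0, arr)))
    if np.isscalar(x) or arr.ndim == 0:
        return float(out)
    return out


def p(x):
    """Nutrient kernel ``(x coth x - 1) / x**2``, extended by p(0) = 1/3.

    Strictly decreasing on [0, inf) with range (0, 1/3].
    """
    return _dispatch(x, _series_p, _direct_p, "p")


def p_prime(x):
    """Derivative of :func:`p`; strictly negative for x > 0, p'(0) = 0."""
    return _dispatch(x, _series_p_prime, _direct_p_prime, "p'")


def f(x):
    """Proliferation kernel in the cubed-radius variable: ``x * p(x**(1/3))``.

    Strictly increasing, f(0) = 0, and f(x) <= x/3 because p < 1/3.
    """
    arr = np.asarray(x, dtype=float)
    if np.any(arr < 0):
        raise ValueError("f requires a nonnegative argument")
    out = arr * p(np.cbrt(arr))
    if np.isscalar(x) or arr.ndim == 0:
        return float(out)
    return out


def f_prime(x):
    """Derivative of :func:`f`: ``p(u) + (u/3) p'(u)`` with ``u = x**(1/3)``.

    Strictly positive for x > 0 (the proliferation term is monotone in the
    delayed state, which is what makes comparison arguments work).
    """
    arr = np.asarray(x, dtype=float)
    if np.any(arr <= 0):
        raise ValueError("f' requires a positive argument")
    u = np.cbrt(arr)
    out = p(u) + u * p_prime(u) / 3.0
    if np.isscalar(x) or arr.ndim == 0:
        return float(out)
    return out


def _branch_of(x: float) -> str:
    return "series" if x <= SERIES_SWITCH else "direct"


def p_kernel(x: float) -> KernelValue:
    """Scalar :func:`p` with branch provenance."""
    return KernelValue(p(float(x)), _branch_of(float(x)))


def f_kernel(x: float) -> KernelValue:
    """Scalar :func:`f` with branch provenance (branch of the inner p)."""
    xf = float(x)
    return KernelValue(f(xf), _branch_of(float(np.cbrt(xf))))


def f_prime_kernel(x: float) -> KernelValue:
    """Scalar :func:`f_prime` with branch provenance."""
    xf = float(x)
    return KernelValue(f_prime(xf), _branch_of(float(np.cbrt(xf))))


def nutrient_profile(r, R, sigma_inf):
    """Quasi-steady nutrient concentration at radius ``r`` inside a tumor of
    radius ``R``: ``sigma_inf * (R / sinh R) * (sinh r / r)``.

    Evaluated as ``sigma_inf * exp(r - R) * q(r) / q(R)`` with
    ``q(t) = (1 - exp(-2t)) / (2t)`` — an exact rewriting that cannot
    overflow for large radii.  Nondecreasing in r, equal to ``sigma_inf``
    at the boundary r = R.
    """
    r_arr = np.asarray(r, dtype=float)
    R_f = float(R)
    if R_f <= 0:
        raise ValueError("tumor radius R must be positive")
    if np.any(r_arr < 0) or np.any(r_arr > R_f * (1 + 1e-12)):
        raise ValueError("radius r must lie in [0, R]")

    def q(t):
        t = np.asarray(t, dtype=float)
        with np.errstate(invalid="ignore", divide="ignore"):
            val = -np.expm1(-2.0 * t) / (2.0 * t)
        return np.where(t == 0.0, 1.0, val)

    out = sigma_inf * np.exp(r_arr - R_f) * q(r_arr) / q(R_f)
    if np.isscalar(r) or r_arr.ndim == 0:
        return float(out)
    return out
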