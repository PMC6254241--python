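"""Bertalanffy-Putter growth dynamics.

The Bertalanffy-Putter model describes body mass ``m(t)`` (grams) at age
``t`` (years) through the differential equation

    dm/dt = p * m**a - q * m**b,        0 <= a < b,

with initial value ``m(0) = m0``.  The non-negative exponent pair ``(a, b)``
("metabolic scaling exponents") indexes a two-parameter family of growth
laws that contains the classical named models (von Bertalanffy, logistic,
Richards, West, ...) as special cases.  On the diagonal ``a == b`` the
right-hand side degenerates; its limit for ``b -> a`` is the generalized
Gompertz equation

    dm/dt = p * m**a - q * ln(m) * m**a,

whose special case ``a == 1`` is the classical Gompertz model.

This module defines the exponent-pair and parameter containers, a registry
of the named special cases, the growth rate, numerical mass-at-age solutions,
the elementary closed forms, and the asymptotic (equilibrium) mass
``m_max = (p/q)**(1/(b-a))`` (``exp(p/q)`` on the diagonal).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.integrate import odeint

__all__ = [
    "DIAGONAL_TOL",
    "MASS_FLOOR",
    "ExponentPair",
    "GrowthParameters",
    "NamedModel",
    "NAMED_MODELS",
    "Trajectory",
    "growth_rate",
    "solve_growth",
    "closed_form_mass",
    "asymptotic_mass",
]

#: Exponent pairs closer to the diagonal than this are treated as Gompertz.
#: The general equation is numerically unstable for b - a below this, and the
#: Gompertz form is its stated limit.
DIAGONAL_TOL = 1e-9

#: Trajectories dropping below this mass (grams) are flagged as failed;
#: fractional powers and the logarithm are undefined at non-positive mass.
MASS_FLOOR = 1e-12


@dataclass(frozen=True)
class ExponentPair:
    """The metabolic scaling exponents (a, b) with 0 <= a <= b.

    ``a`` scales anabolism (mass synthesis), ``b`` catabolism.  Pairs with
    ``|b - a| < DIAGONAL_TOL`` are interpreted as the Gompertz limit.
    """

    a: float
    b: float

    def __post_init__(self) -> None:
        if not (np.isfinite(self.a) and np.isfinite(self.b)):
            raise ValueError("exponents must be finite")
        if self.a < 0:
            raise ValueError(f"exponent a must be non-negative, got {self.a}")
        if self.b < self.a - DIAGONAL_TOL:
            raise ValueError(f"exponent b must satisfy b >= a, got {self!r}")

    @property
    def is_gompertz(self) -> bool:
        """True when the pair lies on the diagonal a == b (Gompertz limit)."""
        return abs(self.b - self.a) < DIAGONAL_TOL

    @classmethod
    def gompertz(cls, a: float) -> "ExponentPair":
        """Diagonal pair (a, a): the generalized Gompertz exponent."""
        return cls(a, a)

    def __iter__(self):
        return iter((self.a, self.b))


@dataclass(frozen=True)
class GrowthParameters:
    """Non-exponent model parameters: initial mass and rate constants.

    m0 : initial mass m(0) in grams (must be positive)
    p  : anabolic rate constant, grams^(1-a) per year
    q  : catabolic rate constant, grams^(1-b) per year
         (grams^(1-a) per year in the Gompertz limit)
    """

    m0: float
    p: float
    q: float

    def __post_init__(self) -> None:
        if not self.m0 > 0:
            raise ValueError(f"m0 must be positive, got {self.m0}")
        if self.p < 0 or self.q < 0:
            raise ValueError(f"p and q must be non-negative, got {self!r}")

    def __iter__(self):
        return iter((self.m0, self.p, self.q))


@dataclass(frozen=True)
class NamedModel:
    """A named special case of the growth family.

    ``pair`` is fixed for the fully specified models; for the one-free-exponent
    families (Richards, generalized Bertalanffy) the free exponent is recorded
    in ``free_exponent`` and ``pair`` holds the fixed one with the other set to
    ``nan`` conventions avoided -- instead the fixed value is stored and the
    free coordinate is named.
    """

    name: str
    a: float | None
    b: float | None
    free_exponent: str | None = None

    @property
    def pair(self) -> ExponentPair:
        if self.free_exponent is not None:
            raise ValueError(
                f"model {self.name!r} has free exponent {self.free_exponent!r}; "
                "no single exponent-pair"
            )
        return ExponentPair(self.a, self.b)


#: Registry of the named growth models, keyed by label.
NAMED_MODELS: dict[str, NamedModel] = {
    "von-bertalanffy-mass": NamedModel("von-bertalanffy-mass", 2.0 / 3.0, 1.0),
    "vbgf-length": NamedModel("vbgf-length", 0.0, 1.0),
    "west": NamedModel("west", 0.75, 1.0),
    "logistic": NamedModel("logistic", 1.0, 2.0),
    "gompertz": NamedModel("gompertz", 1.0, 1.0),
    "richards": NamedModel("richards", 1.0, None, free_exponent="b"),
    "generalized-bertalanffy": NamedModel(
        "generalized-bertalanffy", None, 1.0, free_exponent="a"
    ),
}


def growth_rate(
    pair: ExponentPair, params: GrowthParameters, m: float | np.ndarray
) -> float | np.ndarray:
    """Instantaneous growth rate dm/dt (grams/year) at mass ``m``.

    Evaluates ``p*m**a - q*m**b`` off the diagonal and the Gompertz limit
    ``p*m**a - q*ln(m)*m**a`` on it.  Raises ValueError for non-positive mass.
    """
    m = np.asarray(m, dtype=float)
    if np.any(m <= 0):
        raise ValueError("mass must be positive (fractional powers / log undefined)")
    a, b = pair.a, pair.b
    if pair.is_gompertz:
        rate = params.p * m**a - params.q * np.log(m) * m**a
    else:
        rate = params.p * m**a - params.q * m**b
    return rate if rate.ndim else float(rate)


@dataclass
class Trajectory:
    """Result of a numerical mass-at-age integration.

    ``success`` is False when the integrator failed or the trajectory left the
    admissible region (mass below :data:`MASS_FLOOR` or non-finite); callers
    fitting to data map that onto an infinite sum of squared errors.
    """

    times: np.ndarray
    masses: np.ndarray
    success: bool
    message: str = ""


def _rhs(pair: ExponentPair, params: GrowthParameters):
    a, b = pair.a, pair.b
    p, q = params.p, params.q
    if pair.is_gompertz:

        def f(y, t):
            m = y[0]
            if m <= MASS_FLOOR:
                return 0.0  # frozen outside the admissible region; flagged later
            return p * m**a - q * math.log(m) * m**a

    else:

        def f(y, t):
            m = y[0]
            if m <= MASS_FLOOR:
                return 0.0
            return p * m**a - q * m**b

    return f


def solve_growth(
    pair: ExponentPair,
    params: GrowthParameters,
    times: Sequence[float] | np.ndarray,
    rtol: float = 1e-9,
    atol: float = 1e-9,
) -> Trajectory:
    """Integrate the growth ODE from ``m(0) = m0`` and evaluate at ``times``.

    ``times`` must be non-negative and non-decreasing.  Uses adaptive
    high-precision integration (LSODA); a failed integration or a trajectory
    reaching non-positive mass yields ``success=False`` rather than raising,
    so that optimization loops can treat the point as infeasible.
    """
    t = np.asarray(times, dtype=float)
    if t.ndim != 1 or t.size == 0:
        raise ValueError("times must be a non-empty 1-D sequence")
    if np.any(t < 0):
        raise ValueError("ages must be non-negative")
    if np.any(np.diff(t) < 0):
        raise ValueError("ages must be sorted non-decreasing")

    prepend = t[0] > 0.0
    t_solve = np.concatenate([[0.0], t]) if prepend else t
    # odeint needs strictly advancing time for its internal steps; duplicated
    # output times are fine.
    f = _rhs(pair, params)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            out, info = odeint(
                f,
                params.m0,
                t_solve,
                rtol=rtol,
                atol=atol,
                full_output=True,
                mxstep=10000,
            )
        except Exception as exc:  # lsoda can raise on hard failures
            return Trajectory(t, np.full_like(t, np.nan), False, str(exc))
    m = out[:, 0]
    if prepend:
        m = m[1:]
    ok = info["message"] == "Integration successful."
    if not ok:
        return Trajectory(t, m, False, info["message"])
    if not np.all(np.isfinite(m)) or np.any(m <= MASS_FLOOR):
        return Trajectory(t, m, False, "trajectory left the admissible mass range")
    return Trajectory(t, m, True)


def closed_form_mass(
    pair: ExponentPair, params: GrowthParameters, t: float | np.ndarray
) -> float | np.ndarray:
    """Elementary mass-at-age solution for the classically solvable cases.

    Supported families (all with q > 0):

    * generalized von Bertalanffy, ``b == 1, a < 1``:
      ``m(t) = [p/q - (p/q - m0**(1-a)) * exp(-(1-a) q t)] ** (1/(1-a))``
    * Gompertz, ``a == b == 1``:
      ``m(t) = exp(p/q + (ln m0 - p/q) * exp(-q t))``
    * logistic, ``a == 1, b == 2``:
      ``m(t) = p / (q + (p/m0 - q) * exp(-p t))``

    Raises NotImplementedError for any other exponent pair (the general
    solutions involve non-elementary functions and are not used here).
    """
    if params.q <= 0:
        raise ValueError("closed forms require q > 0")
    t = np.asarray(t, dtype=float)
    a, b = pair.a, pair.b
    m0, p, q = params.m0, params.p, params.q
    if pair.is_gompertz and abs(a - 1.0) < 1e-12:
        out = np.exp(p / q + (np.log(m0) - p / q) * np.exp(-q * t))
    elif abs(b - 1.0) < 1e-12 and a < 1.0 - 1e-12 and not pair.is_gompertz:
        c = 1.0 - a
        out = (p / q - (p / q - m0**c) * np.exp(-c * q * t)) ** (1.0 / c)
    elif abs(a - 1.0) < 1e-12 and abs(b - 2.0) < 1e-12:
        out = p / (q + (p / m0 - q) * np.exp(-p * t))
    else:
        raise NotImplementedError(
            f"no elementary closed form implemented for exponent pair {pair!r}"
        )
    return out if out.ndim else float(out)


def asymptotic_mass(pair: ExponentPair, params: GrowthParameters) -> float:
    """Equilibrium mass m_max where the growth rate vanishes.

    ``(p/q)**(1/(b-a))`` off the diagonal, ``exp(p/q)`` on it.  With ``q == 0``
    (and p > 0) growth is unbounded and ``inf`` is returned.
    """
    if params.q == 0:
        return math.inf if params.p > 0 else params.m0
    if pair.is_gompertz:
        return math.exp(params.p / params.q)
    return (params.p / params.q) ** (1.0 / (pair.b - pair.a))
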