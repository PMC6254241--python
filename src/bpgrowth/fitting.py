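"""Constrained least-squares fitting of growth curves to class averages.

For a fixed exponent pair (a, b) the remaining parameters (m0, p, q) are
chosen to minimize the unweighted sum of squared errors

    SSE_opt(a, b) = min over (m0, p, q) of
        sum_i ( mean mass of class i - m(mean age of class i) )**2,

with the biologically motivated constraints m0 > 10 g and p > q > 0 (q > 0
and p > 0 on the Gompertz diagonal, where p > q carries no meaning).  The
constraints are enforced by a smooth reparameterization (optimizing
log-offsets), so any off-the-shelf unconstrained local optimizer searches
the feasible interior only.

The public surface follows the model/results pattern:
:class:`BertalanffyPutter` is built from a class-average dataset and its
:meth:`~BertalanffyPutter.fit` returns a :class:`FitResult` carrying the
estimates, the achieved SSE, convergence diagnostics and a summary table.
Module-level helpers (:func:`sse`, :func:`starting_values`,
:func:`fit_fixed_pair`, ...) delegate to the class.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np
import pandas as pd
from scipy.optimize import least_squares, minimize

from .data import Dataset
from .growth import (
    ExponentPair,
    GrowthParameters,
    asymptotic_mass,
    solve_growth,
)

__all__ = [
    "FitConstraints",
    "FitResult",
    "BertalanffyPutter",
    "StartingValuesError",
    "sse",
    "initial_growth_rate",
    "starting_values",
    "fit_fixed_pair",
]

#: SSE assigned to infeasible / failed model evaluations.
SSE_SENTINEL = math.inf


class StartingValuesError(ValueError):
    """The closed-form starting-value rule does not apply (diagonal pair)."""


@dataclass(frozen=True)
class FitConstraints:
    """Feasible region for the non-exponent parameters.

    m0_min         : lower bound on the initial mass (grams); default 10 g,
                     a biologically reasonable floor for age-0 fish mass.
    require_p_gt_q : enforce p > q (meaningful off the diagonal, where it
                     guarantees a positive growth rate at small mass).
    require_q_pos  : enforce q > 0 (bounded growth).
    """

    m0_min: float = 10.0
    require_p_gt_q: bool = True
    require_q_pos: bool = True

    def __post_init__(self) -> None:
        if self.m0_min < 0:
            raise ValueError("m0_min must be non-negative")

    @classmethod
    def for_pair(cls, pair: ExponentPair, m0_min: float = 10.0) -> "FitConstraints":
        """Default constraint set: p > q off the diagonal, only p, q > 0 on it."""
        return cls(m0_min=m0_min, require_p_gt_q=not pair.is_gompertz)

    def satisfied_by(self, params: GrowthParameters) -> bool:
        if params.m0 <= self.m0_min:
            return False
        if self.require_q_pos and params.q <= 0:
            return False
        if self.require_p_gt_q and params.p <= params.q:
            return False
        return True


# ---------------------------------------------------------------------------
# reparameterization: theta in R^3  <->  feasible (m0, p, q)

def _unpack(theta: np.ndarray, con: FitConstraints) -> Optional[GrowthParameters]:
    with np.errstate(over="ignore"):
        m0 = con.m0_min + math.exp(min(theta[0], 700.0))
        q = math.exp(min(theta[2], 700.0))
        p = q + math.exp(min(theta[1], 700.0)) if con.require_p_gt_q else math.exp(
            min(theta[1], 700.0)
        )
    if not all(map(math.isfinite, (m0, p, q))):
        return None
    try:
        return GrowthParameters(m0, p, q)
    except ValueError:
        return None


def _pack(params: GrowthParameters, con: FitConstraints) -> np.ndarray:
    if not con.satisfied_by(params):
        raise ValueError(f"{params} violates constraints {con}")
    t0 = math.log(params.m0 - con.m0_min)
    t2 = math.log(params.q)
    t1 = math.log(params.p - params.q) if con.require_p_gt_q else math.log(params.p)
    return np.array([t0, t1, t2])


@dataclass
class FitResult:
    """Optimal (m0, p, q) and achieved SSE for one exponent pair.

    ``converged`` is False when no restart converged, when the optimizer
    reported failure, or when the fit collapsed onto the degenerate
    flat-curve attractor (a near-constant trajectory through the data mean,
    a known failure mode of the optimization).
    """

    pair: ExponentPair
    params: GrowthParameters
    sse: float
    converged: bool
    method: str
    n_evals: int = 0
    model: Optional["BertalanffyPutter"] = field(default=None, repr=False)

    @property
    def asymptotic_mass(self) -> float:
        return asymptotic_mass(self.pair, self.params)

    def predict(self, times) -> np.ndarray:
        """Fitted mass-at-age curve evaluated at ``times``."""
        traj = solve_growth(self.pair, self.params, np.atleast_1d(times))
        return traj.masses

    @property
    def resid(self) -> np.ndarray:
        if self.model is None:
            raise ValueError("result is not attached to a model/dataset")
        return self.model.data.masses - self.predict(self.model.data.ages)

    def aicc(self, k: int = 4) -> float:
        """Small-sample AIC of this fit with ``k`` estimated parameters."""
        from .selection import aicc as _aicc

        if self.model is None:
            raise ValueError("result is not attached to a model/dataset")
        return _aicc(self.sse, self.model.data.n_classes, k)

    def summary(self) -> str:
        lines = [
            "Bertalanffy-Putter growth fit",
            "=============================",
            f"exponent pair     a = {self.pair.a:.6g}, b = {self.pair.b:.6g}"
            + ("  (Gompertz limit)" if self.pair.is_gompertz else ""),
            f"method            {self.method}",
            f"converged         {self.converged}",
            f"function evals    {self.n_evals}",
            "-----------------------------",
            f"m0 (g)            {self.params.m0:.6g}",
            f"p                 {self.params.p:.6g}",
            f"q                 {self.params.q:.6g}",
            f"m_max (g)         {self.asymptotic_mass:.6g}",
            f"SSE (g^2)         {self.sse:.6f}",
        ]
        if self.model is not None:
            n = self.model.data.n_classes
            lines.append(f"N classes         {n}")
            lines.append(f"AICc (K=4)        {self.aicc(4):.4f}")
        return "\n".join(lines)


class BertalanffyPutter:
    """Bertalanffy-Putter growth model bound to a class-average dataset.

    Parameters
    ----------
    data : Dataset or pandas.DataFrame
        Mass-at-age class averages (columns age, mass, size when a frame).

    Examples
    --------
    >>> from bpgrowth.data import walleye_table1
    >>> model = BertalanffyPutter(walleye_table1())
    >>> res = model.fit(pair=ExponentPair(2/3, 1))
    >>> res.sse < 24000
    True
    """

    def __init__(self, data: Dataset | pd.DataFrame):
        if isinstance(data, pd.DataFrame):
            data = Dataset.from_dataframe(data)
        if data.n_classes < 4:
            raise ValueError(
                "need at least 4 classes (three starting-value points plus one)"
            )
        self.data = data

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame) -> "BertalanffyPutter":
        return cls(Dataset.from_dataframe(df))

    # -- objective ---------------------------------------------------------

    def sse(self, pair: ExponentPair, params: GrowthParameters) -> float:
        """Unweighted SSE of the curve m(t; pair, params) against the data.

        A failed integration (trajectory leaving the admissible mass range)
        maps to an infinite sentinel rather than raising.
        """
        traj = solve_growth(pair, params, self.data.ages)
        if not traj.success:
            return SSE_SENTINEL
        return float(np.sum((self.data.masses - traj.masses) ** 2))

    # -- starting values ---------------------------------------------------

    def initial_growth_rate(self) -> float:
        """Derivative at t = 0 of the quadratic through the first three classes."""
        t = self.data.ages[:3]
        y = self.data.masses[:3]
        if len(set(t.tolist())) < 3:
            raise ValueError("first three class ages must be distinct")
        coeffs = np.polyfit(t, y, 2)  # quadratic interpolation, 3 points
        return float(coeffs[1])  # d/dt (c2 t^2 + c1 t + c0) at t = 0

    def starting_values(self, pair: ExponentPair) -> GrowthParameters:
        """Rule-of-thumb start: m0 from the first class, (p, q) from assuming
        the asymptotic mass exceeds the largest class mean by 20%.

        Solving m_max = 1.2*max(m) for q gives q0 = p0 / (1.2*max(m))**(b-a);
        substituting into the growth equation at t = 0 with the interpolated
        initial slope m'(0) yields

            p0 = m'(0) * (1.2*max(m))**b
                 / ((1.2*max(m))**b * m0**a - (1.2*max(m))**a * m0**b).

        The rule degenerates on the diagonal (p0 diverges as b -> a); a
        :class:`StartingValuesError` is raised there and the fitter falls back
        to a Gompertz-specific analogue.
        """
        if pair.is_gompertz:
            raise StartingValuesError(
                "starting-value rule degenerates on the diagonal a == b"
            )
        a, b = pair.a, pair.b
        m0 = float(self.data.masses[0])
        mmax_guess = 1.2 * float(self.data.masses.max())
        slope = self.initial_growth_rate()
        denom = mmax_guess**b * m0**a - mmax_guess**a * m0**b
        if denom <= 0:
            raise StartingValuesError(
                f"starting-value denominator non-positive for pair {pair!r}"
            )
        p0 = slope * mmax_guess**b / denom
        q0 = p0 / mmax_guess ** (b - a)
        return GrowthParameters(m0, p0, q0)

    def _diagonal_starting_values(self, pair: ExponentPair) -> GrowthParameters:
        # Gompertz analogue of the off-diagonal rule: on the diagonal
        # m_max = exp(p/q), so m_max = 1.2*max(m) gives p/q = ln(1.2*max(m)),
        # and the initial slope m'(0) = q * m0**a * (ln m_max - ln m0)
        # determines q.
        m0 = float(self.data.masses[0])
        log_mmax = math.log(1.2 * float(self.data.masses.max()))
        slope = self.initial_growth_rate()
        gap = log_mmax - math.log(m0)
        if gap <= 0:
            gap = 0.1
        q0 = slope / (m0**pair.a * gap)
        return GrowthParameters(m0, q0 * log_mmax, q0)

    def default_start(self, pair: ExponentPair) -> GrowthParameters:
        """Starting values for any pair, with the diagonal fallback applied."""
        try:
            return self.starting_values(pair)
        except StartingValuesError:
            return self._diagonal_starting_values(pair)

    # -- degenerate-fit detection -----------------------------------------

    def _is_flat_curve(self, pair: ExponentPair, params: GrowthParameters) -> bool:
        # Failing optimizations often converge to a near-constant curve at the
        # mean of the class averages; flag trajectories whose variance is
        # below 1% of the data variance.
        traj = solve_growth(pair, params, self.data.ages)
        if not traj.success:
            return True
        return float(np.var(traj.masses)) < 0.01 * float(np.var(self.data.masses))

    # -- fitting -----------------------------------------------------------

    def fit(
        self,
        pair: ExponentPair,
        start: Optional[GrowthParameters] = None,
        constraints: Optional[FitConstraints] = None,
        method: str = "local-simplex",
        seed: int = 0,
        n_restarts: int = 5,
    ) -> FitResult:
        """Minimize SSE over (m0, p, q) at a fixed exponent pair.

        method : {"local-simplex", "constrained-gradient", "anneal"}
            Nelder-Mead simplex, quasi-Newton (both on the reparameterized
            unconstrained objective), or multiplicative simulated annealing.
        n_restarts : jittered restarts (parameters scaled by U(0.5, 2) draws,
            seeded) attempted when the primary start fails to converge.

        Never raises on optimization failure: the result then carries
        ``converged=False`` and the best (possibly infinite) SSE seen.
        """
        if method not in ("local-simplex", "constrained-gradient", "anneal"):
            raise ValueError(f"unknown method {method!r}")
        con = constraints or FitConstraints.for_pair(pair)
        if start is None:
            start = self.default_start(pair)
        if not con.satisfied_by(start):
            start = self._repair_start(start, con)

        if method == "anneal":
            return self._fit_anneal(pair, start, con, seed)

        rng = np.random.default_rng(seed)
        best = self._local_fit(pair, start, con, method)
        attempts = 0
        while (not best.converged or not math.isfinite(best.sse)) and attempts < n_restarts:
            attempts += 1
            jitter = rng.uniform(0.5, 2.0, size=3)
            try:
                jittered = GrowthParameters(
                    max(start.m0 * jitter[0], con.m0_min * 1.01 + 1e-9),
                    start.p * jitter[1],
                    start.q * jitter[2],
                )
            except ValueError:
                continue
            if not con.satisfied_by(jittered):
                jittered = self._repair_start(jittered, con)
            cand = self._local_fit(pair, jittered, con, method)
            if cand.sse < best.sse or (cand.converged and not best.converged
                                       and cand.sse <= best.sse * (1 + 1e-9)):
                best = cand
        return best

    def _repair_start(self, params: GrowthParameters, con: FitConstraints) -> GrowthParameters:
        m0 = max(params.m0, con.m0_min * 1.05 + 1e-6)
        q = max(params.q, 1e-12)
        p = params.p
        if con.require_p_gt_q and p <= q:
            p = q * 1.5 + 1e-12
        if p <= 0:
            p = 1e-6
        return GrowthParameters(m0, p, q)

    def _local_fit(
        self,
        pair: ExponentPair,
        start: GrowthParameters,
        con: FitConstraints,
        method: str,
    ) -> FitResult:
        n_evals = 0
        # optimizers dislike non-finite objectives; infeasible evaluations get
        # a huge finite penalty inside the loop and map back to inf at the end
        PENALTY = 1e30

        def objective(theta: np.ndarray) -> float:
            nonlocal n_evals
            n_evals += 1
            params = _unpack(theta, con)
            if params is None:
                return PENALTY
            value = self.sse(pair, params)
            return value if math.isfinite(value) else PENALTY

        def residuals(theta: np.ndarray) -> np.ndarray:
            nonlocal n_evals
            n_evals += 1
            params = _unpack(theta, con)
            if params is None:
                return np.full(self.data.n_classes, 1e12)
            traj = solve_growth(pair, params, self.data.ages)
            if not traj.success or not np.all(np.isfinite(traj.masses)):
                return np.full(self.data.n_classes, 1e12)
            return self.data.masses - traj.masses

        theta0 = _pack(start, con)
        start_sse = objective(theta0)
        if method == "local-simplex":
            # two chained simplex runs guard against premature collapse
            res = minimize(objective, theta0, method="Nelder-Mead",
                           options={"maxfev": 1500, "xatol": 1e-8, "fatol": 1e-9})
            res = minimize(objective, res.x, method="Nelder-Mead",
                           options={"maxfev": 1500, "xatol": 1e-10, "fatol": 1e-10})
            best_theta, best_sse, ok = res.x, res.fun, bool(res.success)
        else:  # constrained-gradient: trust-region least squares in the interior
            res = least_squares(residuals, theta0, method="trf",
                                xtol=1e-12, ftol=1e-12, gtol=1e-12, max_nfev=400)
            res2 = minimize(objective, res.x, method="Nelder-Mead",
                            options={"maxfev": 600, "xatol": 1e-10, "fatol": 1e-10})
            if res2.fun <= 2 * res.cost:
                best_theta, best_sse, ok = res2.x, res2.fun, bool(res.success or res2.success)
            else:
                best_theta, best_sse, ok = res.x, 2 * res.cost, bool(res.success)

        if best_sse > start_sse:  # optimizer may never worsen the start
            best_theta, best_sse = theta0, start_sse
        params = _unpack(best_theta, con)
        if params is None or best_sse >= PENALTY:
            return FitResult(pair, start, SSE_SENTINEL, False, method, n_evals, self)
        converged = ok and not self._is_flat_curve(pair, params)
        return FitResult(pair, params, float(best_sse), converged, method, n_evals, self)

    def _fit_anneal(
        self,
        pair: ExponentPair,
        start: GrowthParameters,
        con: FitConstraints,
        seed: int,
    ) -> FitResult:
        from .search import AnnealConfig, anneal_refine

        cfg = AnnealConfig(steps=20000, seed=seed, vary_exponents=False)
        res = anneal_refine(self.data, pair, start, cfg, constraints=con)
        return replace(res, method="anneal", model=self)


# ---------------------------------------------------------------------------
# functional surface


def sse(pair: ExponentPair, params: GrowthParameters, data: Dataset) -> float:
    """SSE of a fully specified growth curve against class averages."""
    return BertalanffyPutter(data).sse(pair, params)


def initial_growth_rate(data: Dataset) -> float:
    """Initial slope m'(0) from the quadratic through the first three classes."""
    return BertalanffyPutter(data).initial_growth_rate()


def starting_values(pair: ExponentPair, data: Dataset) -> GrowthParameters:
    """Rule-of-thumb starting values (raises StartingValuesError on the diagonal)."""
    return BertalanffyPutter(data).starting_values(pair)


def fit_fixed_pair(
    pair: ExponentPair,
    data: Dataset,
    start: Optional[GrowthParameters] = None,
    constraints: Optional[FitConstraints] = None,
    method: str = "local-simplex",
    seed: int = 0,
) -> FitResult:
    """Minimize SSE over (m0, p, q) at a fixed exponent pair."""
    return BertalanffyPutter(data).fit(
        pair, start=start, constraints=constraints, method=method, seed=seed
    )
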