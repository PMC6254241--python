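"""Exploring SSE_opt over the exponent-pair plane.

The optimal-SSE landscape ``SSE_opt(a, b)`` (minimum over m0, p, q at a
fixed exponent pair) is explored in three stages mirroring a coarse-to-fine
global optimization:

1. a coarse grid scan (step 0.1) taking, per grid point, the better of a
   general-purpose annealing run and a simplex fit;
2. fine row scans at fixed ``a`` with warm starts (each fit starts from the
   optimum of the previous ``b``), with the row extended in ``b`` until its
   minimum is interior (the "U-shape" stopping rule);
3. a custom multiplicative simulated annealing over all free parameters
   (exponents included), launched from the best surface points, which moves
   off the grid and decides between the general family (a < b) and its
   Gompertz diagonal limit (a == b).

All annealing proposals are multiplicative (parameters scaled by
``exp(sigma * u)``, u standard normal), so states stay positive by
construction; exponent moves leaving the ordered region ``0 <= a <= b <= 3``
are rejected.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .data import Dataset
from .fitting import (
    BertalanffyPutter,
    FitConstraints,
    FitResult,
    SSE_SENTINEL,
)
from .growth import DIAGONAL_TOL, ExponentPair, GrowthParameters

__all__ = [
    "GridSpec",
    "SSESurface",
    "AnnealConfig",
    "coarse_scan",
    "scan_row",
    "detect_interior_minimum",
    "anneal_refine",
    "global_optimum",
    "parameter_level_set",
    "LevelSetSample",
]


def _key(a: float, b: float) -> tuple[float, float]:
    return (round(float(a), 6), round(float(b), 6))


@dataclass(frozen=True)
class GridSpec:
    """Rectangular exponent-pair grid: a in [a_min, a_max] step ``step``,
    b from a + step up to b_max, optionally including the diagonal a == b."""

    a_min: float = 0.0
    a_max: float = 1.0
    b_max: float = 1.5
    step: float = 0.1
    include_diagonal: bool = True

    def __post_init__(self) -> None:
        if self.step <= 0:
            raise ValueError("step must be positive")
        if self.b_max <= self.a_min:
            raise ValueError("b_max must exceed a_min")

    def points(self) -> list[ExponentPair]:
        pts: list[ExponentPair] = []
        n_a = int(round((self.a_max - self.a_min) / self.step))
        for i in range(n_a + 1):
            a = round(self.a_min + i * self.step, 10)
            if self.include_diagonal:
                pts.append(ExponentPair(a, a))
            b = a + self.step
            while b <= self.b_max + 1e-9:
                pts.append(ExponentPair(a, round(b, 10)))
                b = round(b + self.step, 10)
        return pts


@dataclass
class SSESurface:
    """Map from exponent pairs to their fitted results.

    Every scanned grid point has an entry, possibly a non-converged sentinel
    (infinite SSE), so the scanning bookkeeping is complete by construction.
    """

    entries: dict[tuple[float, float], FitResult] = field(default_factory=dict)

    def add(self, result: FitResult) -> None:
        self.entries[_key(result.pair.a, result.pair.b)] = result

    def get(self, a: float, b: float) -> Optional[FitResult]:
        return self.entries.get(_key(a, b))

    def __len__(self) -> int:
        return len(self.entries)

    def __iter__(self):
        return iter(self.entries.values())

    def best(self, diagonal: Optional[bool] = None) -> FitResult:
        """Lowest-SSE entry; restrict to the diagonal family (True), the
        off-diagonal family (False), or neither (None)."""
        pool = [
            r
            for r in self.entries.values()
            if diagonal is None or r.pair.is_gompertz == diagonal
        ]
        if not pool:
            raise ValueError("surface has no entries in the requested family")
        return min(pool, key=lambda r: r.sse)

    def top(self, k: int, diagonal: Optional[bool] = None) -> list[FitResult]:
        pool = sorted(
            (
                r
                for r in self.entries.values()
                if (diagonal is None or r.pair.is_gompertz == diagonal)
                and math.isfinite(r.sse)
            ),
            key=lambda r: r.sse,
        )
        return pool[:k]

    def row_minima(self) -> dict[float, FitResult]:
        """Per-a minimum over b (the black-dot curve of the fine scan)."""
        rows: dict[float, FitResult] = {}
        for r in self.entries.values():
            a = round(r.pair.a, 6)
            if a not in rows or r.sse < rows[a].sse:
                rows[a] = r
        return dict(sorted(rows.items()))

    def to_dataframe(self) -> pd.DataFrame:
        rows = [
            {
                "a": r.pair.a,
                "b": r.pair.b,
                "m0": r.params.m0,
                "p": r.params.p,
                "q": r.params.q,
                "SSR": r.sse,
                "converged": r.converged,
            }
            for r in self.entries.values()
        ]
        return pd.DataFrame(rows).sort_values(["a", "b"]).reset_index(drop=True)


def detect_interior_minimum(sse_row: Sequence[float]) -> Optional[int]:
    """Index of the smallest finite value if it is strictly interior.

    "Interior" means neither the first nor the last *finite* position of the
    row (the U-shape criterion: a minimum flanked by worse fits on both
    sides).  Returns None when the row is all-sentinel or the minimum sits on
    an edge.
    """
    vals = np.asarray(list(sse_row), dtype=float)
    if len(vals) < 3:
        return None
    finite = np.flatnonzero(np.isfinite(vals))
    if len(finite) < 3:
        return None
    idx = finite[np.argmin(vals[finite])]
    if idx == finite[0] or idx == finite[-1]:
        return None
    return int(idx)


def coarse_scan(
    data: Dataset,
    grid: GridSpec,
    anneal_steps: int = 2000,
    seed: int = 0,
    methods: Sequence[str] = ("local-simplex", "anneal"),
) -> SSESurface:
    """First-stage scan: per grid point the best result over ``methods``
    (by default a simplex fit and a short general-purpose annealing run);
    diagonal points are fitted under the Gompertz limit equation."""
    model = BertalanffyPutter(data)
    surface = SSESurface()
    for pair in grid.points():
        start = model.default_start(pair)
        best: Optional[FitResult] = None
        for method in methods:
            if method == "anneal":
                cfg = AnnealConfig(steps=anneal_steps, seed=seed, vary_exponents=False)
                try:
                    cand = anneal_refine(data, pair, start, cfg)
                except ValueError:
                    continue
            else:
                cand = model.fit(pair, start=start, method=method, seed=seed)
            if best is None or cand.sse < best.sse:
                best = cand
        if best is None:
            best = FitResult(pair, start, SSE_SENTINEL, False, "none", 0, model)
        surface.add(best)
    return surface


def scan_row(
    data: Dataset,
    a: float,
    step: float = 0.01,
    b_max: float = 2.0,
    warm: bool = True,
    extend_increment: float = 0.25,
    b_cap: float = 3.0,
    method: str = "constrained-gradient",
    seed: int = 0,
) -> tuple[list[FitResult], Optional[int]]:
    """Fine scan of one row: fixed ``a``, b from a + step upward.

    With ``warm`` each fit starts from the previous b's optimum (the
    neighboring solutions are close, so warm starts speed convergence and
    avoid the bad local attractors).  After reaching ``b_max`` the row is
    extended in ``extend_increment`` jumps (hard cap ``b_cap``) until the row
    minimum is interior -- the automated version of the visual U-shape check.

    Returns the fitted row and the index of the interior minimum (None when
    no interior minimum exists even at the cap).
    """
    model = BertalanffyPutter(data)
    results: list[FitResult] = []
    b_values: list[float] = []
    b = a + step
    while b <= b_max + 1e-9:
        b_values.append(round(b, 10))
        b = round(b + step, 10)

    prev: Optional[GrowthParameters] = None
    def fit_at(bv: float) -> FitResult:
        nonlocal prev
        pair = ExponentPair(a, bv)
        start = prev if (warm and prev is not None) else None
        res = model.fit(pair, start=start, method=method, seed=seed)
        if warm and res.converged and math.isfinite(res.sse):
            prev = res.params
        return res

    for bv in b_values:
        results.append(fit_at(bv))

    idx = detect_interior_minimum([r.sse for r in results])
    b_next = b_values[-1] + extend_increment
    while idx is None and b_next <= b_cap + 1e-9:
        results.append(fit_at(round(b_next, 10)))
        idx = detect_interior_minimum([r.sse for r in results])
        b_next = round(b_next + extend_increment, 10)
    return results, idx


@dataclass(frozen=True)
class AnnealConfig:
    """Settings of the custom multiplicative simulated annealing.

    steps           : proposal steps in the loop (500,000 reproduces the
                      full-scale refinement; scans and tests use fewer).
    seed            : RNG seed (0 by default, so repeated runs agree).
    t0              : initial temperature; defaults to SSE(start)/10.
    t_decay         : total geometric temperature decay over the run.
    sigma0/sigma1   : initial/final multiplicative proposal scale
                      (log-normal step size), decayed geometrically.
    vary_exponents  : include the exponent(s) in the search; when the start
                      pair is diagonal the pair moves along the diagonal
                      (parameter set {a, m0, p, q}), otherwise {a, b, m0, p, q}.
    exponent_max    : upper bound for a and b (proposals beyond are rejected).
    """

    steps: int = 500_000
    seed: int = 0
    t0: Optional[float] = None
    t_decay: float = 1e-6
    sigma0: float = 0.1
    sigma1: float = 1e-4
    vary_exponents: bool = True
    exponent_max: float = 3.0

    def __post_init__(self) -> None:
        if self.steps < 1:
            raise ValueError("steps must be >= 1")
        if self.t0 is not None and self.t0 <= 0:
            raise ValueError("initial temperature must be positive")


def anneal_refine(
    data: Dataset,
    start_pair: ExponentPair,
    start_params: GrowthParameters,
    cfg: AnnealConfig,
    constraints: Optional[FitConstraints] = None,
    return_trace: bool = False,
) -> FitResult | tuple[FitResult, pd.DataFrame]:
    """Multiplicative simulated annealing from a feasible start.

    Each step multiplies one uniformly chosen active parameter by
    ``exp(sigma_k * u)`` with u ~ N(0, 1), so every visited state is strictly
    positive; Metropolis acceptance uses ``exp(-dSSE / T_k)`` with both the
    temperature and the proposal scale decaying geometrically.  The
    best-ever-visited state is returned.  Identical seeds give identical
    runs.
    """
    model = BertalanffyPutter(data)
    con = constraints or FitConstraints.for_pair(start_pair)
    diagonal = start_pair.is_gompertz

    if not con.satisfied_by(start_params):
        raise ValueError(f"infeasible annealing start: {start_params} under {con}")
    start_sse = model.sse(start_pair, start_params)
    if not math.isfinite(start_sse):
        raise ValueError("annealing start does not yield a valid trajectory")

    rng = np.random.default_rng(cfg.seed)
    t0 = cfg.t0 if cfg.t0 is not None else max(start_sse / 10.0, 1e-12)

    # state: [a, b, m0, p, q]; exponent indices active only if requested
    state = np.array(
        [start_pair.a, start_pair.b, start_params.m0, start_params.p, start_params.q]
    )
    if cfg.vary_exponents:
        active = [0, 2, 3, 4] if diagonal else [0, 1, 2, 3, 4]
    else:
        active = [2, 3, 4]
    cur_sse = start_sse
    best_state, best_sse = state.copy(), cur_sse
    n_evals = 1
    trace: list[tuple[int, float, float, bool]] = []

    def feasible(s: np.ndarray) -> Optional[tuple[ExponentPair, GrowthParameters]]:
        a, b, m0, p, q = s
        if a < 0 or b > cfg.exponent_max or b < a:
            return None
        if not diagonal and b - a < 10 * DIAGONAL_TOL:
            return None  # the off-diagonal family must keep a < b
        try:
            pair = ExponentPair(a, a) if diagonal else ExponentPair(a, b)
            params = GrowthParameters(m0, p, q)
        except ValueError:
            return None
        if not con.satisfied_by(params):
            return None
        return pair, params

    steps = cfg.steps
    sig_ratio = cfg.sigma1 / cfg.sigma0
    for k in range(steps):
        frac = k / max(steps - 1, 1)
        sigma = cfg.sigma0 * sig_ratio**frac
        temp = t0 * cfg.t_decay**frac
        idx = active[rng.integers(len(active))]
        prop = state.copy()
        prop[idx] *= math.exp(sigma * rng.standard_normal())
        if idx == 0 and diagonal:
            prop[1] = prop[0]  # pair moves along the diagonal
        fp = feasible(prop)
        accepted = False
        if fp is not None:
            pair_p, params_p = fp
            new_sse = model.sse(pair_p, params_p)
            n_evals += 1
            if math.isfinite(new_sse):
                d = new_sse - cur_sse
                if d <= 0 or rng.random() < math.exp(-d / temp):
                    state, cur_sse, accepted = prop, new_sse, True
                    if cur_sse < best_sse:
                        best_state, best_sse = state.copy(), cur_sse
        if return_trace:
            trace.append((k, temp, best_sse, accepted))

    a, b, m0, p, q = best_state
    pair = ExponentPair(a, a) if diagonal else ExponentPair(a, b)
    result = FitResult(
        pair,
        GrowthParameters(m0, p, q),
        float(best_sse),
        True,
        "anneal",
        n_evals,
        model,
    )
    if return_trace:
        df = pd.DataFrame(trace, columns=["step", "temperature", "best_sse", "accepted"])
        return result, df
    return result


def _profile_polish(
    model: BertalanffyPutter,
    res: FitResult,
    seed: int = 0,
    span: float = 0.06,
    passes: int = 2,
) -> FitResult:
    """Deterministic exponent refinement of a near-optimal candidate.

    The near-optimal SSE landscape forms a thin, strongly correlated ridge
    in (m0, p, q), along which stochastic moves diffuse slowly; the exponent
    profile SSE_opt(a[, b]) itself is smooth, however, so a bracketed 1-D
    minimization over each free exponent with warm-started inner fits
    converges quickly.  Diagonal candidates get one Brent pass over ``a``;
    off-diagonal candidates get ``passes`` rounds of coordinate descent over
    a and b.
    """
    from scipy.optimize import minimize_scalar

    diagonal = res.pair.is_gompertz
    best = res
    warm = {"params": res.params}

    def fit_at(pair: ExponentPair) -> FitResult:
        out = model.fit(
            pair, start=warm["params"], method="constrained-gradient", seed=seed
        )
        if out.converged and math.isfinite(out.sse):
            warm["params"] = out.params
        return out

    def profile_diag(a: float) -> float:
        if a < 0:
            return SSE_SENTINEL
        return fit_at(ExponentPair(a, a)).sse

    if diagonal:
        a0 = best.pair.a
        br = minimize_scalar(
            profile_diag,
            bounds=(max(a0 - span, 0.0), a0 + span),
            method="bounded",
            options={"xatol": 1e-4},
        )
        cand = fit_at(ExponentPair(br.x, br.x))
        if cand.sse < best.sse:
            best = cand
        return best

    for _ in range(passes):
        a0, b0 = best.pair.a, best.pair.b
        gap = 1e-4

        def profile_b(b: float) -> float:
            if b <= a0 + gap:
                return SSE_SENTINEL
            return fit_at(ExponentPair(a0, b)).sse

        br = minimize_scalar(
            profile_b,
            bounds=(max(b0 - span, a0 + gap), b0 + span),
            method="bounded",
            options={"xatol": 1e-4},
        )
        cand = fit_at(ExponentPair(a0, br.x))
        if cand.sse < best.sse:
            best = cand
        b0 = best.pair.b

        def profile_a(a: float) -> float:
            if a < 0 or a >= b0 - gap:
                return SSE_SENTINEL
            return fit_at(ExponentPair(a, b0)).sse

        br = minimize_scalar(
            profile_a,
            bounds=(max(best.pair.a - span, 0.0), min(best.pair.a + span, b0 - gap)),
            method="bounded",
            options={"xatol": 1e-4},
        )
        cand = fit_at(ExponentPair(br.x, b0))
        if cand.sse < best.sse:
            best = cand
    return best


def global_optimum(
    data: Dataset,
    surface: Optional[SSESurface] = None,
    anneal_config: Optional[AnnealConfig] = None,
    top_k: int = 2,
    polish: bool = True,
    seed: int = 0,
) -> tuple[FitResult, str]:
    """Refine the best surface points into the overall optimum.

    Launches the custom annealing from the ``top_k`` lowest-SSE surface
    entries of each family (general a < b, and the Gompertz diagonal), then
    polishes each annealing winner with a local fit at its final exponent
    pair followed by a deterministic exponent-profile refinement (the
    annealing explores globally; the profile step finishes the slow crawl
    along the thin near-optimal ridge).  Returns the overall best result
    together with its family label, ``"gompertz-diagonal"`` or
    ``"bertalanffy-putter"``.
    """
    if surface is None:
        surface = coarse_scan(data, GridSpec(), seed=seed)
    if len(surface) == 0:
        raise ValueError("empty SSE surface")
    cfg = anneal_config or AnnealConfig(steps=30_000, seed=seed)

    model = BertalanffyPutter(data)
    candidates: list[FitResult] = []
    for diagonal in (True, False):
        for res in surface.top(top_k, diagonal=diagonal):
            try:
                refined = anneal_refine(
                    data, res.pair, res.params, replace(cfg, vary_exponents=True)
                )
            except ValueError:
                refined = res
            if polish:
                polished = model.fit(
                    refined.pair, start=refined.params, method="constrained-gradient",
                    seed=seed,
                )
                if polished.sse < refined.sse:
                    refined = polished
                refined = _profile_polish(model, refined, seed=seed)
            candidates.append(refined)
    if not candidates:
        raise ValueError("no feasible candidate from the surface")
    best = min(candidates, key=lambda r: r.sse)
    family = "gompertz-diagonal" if best.pair.is_gompertz else "bertalanffy-putter"
    return best, family


@dataclass
class LevelSetSample:
    """Accepted (m0, p, q) states with SSE below a cap, from a seeded walk.

    ``spreads`` are per-coordinate standard deviations; ``thin_ridge_ratio``
    is the ratio of the smallest to the largest principal spread of the
    mean-relative sample cloud -- a small value diagnoses the thin,
    strongly correlated near-optimal ridge (weak parameter identifiability).
    """

    samples: np.ndarray  # shape (n, 3): columns m0, p, q
    sse_values: np.ndarray
    sse_cap: float

    @property
    def spreads(self) -> np.ndarray:
        return self.samples.std(axis=0)

    @property
    def thin_ridge_ratio(self) -> float:
        rel = self.samples / self.samples.mean(axis=0) - 1.0
        sv = np.linalg.svd(rel - rel.mean(axis=0), compute_uv=False)
        if sv[0] == 0:
            return 0.0
        return float(sv[-1] / sv[0])


def parameter_level_set(
    pair: ExponentPair,
    data: Dataset,
    sse_cap: float,
    n_samples: int = 300,
    seed: int = 0,
    step_sigma: float = 0.05,
    start: Optional[FitResult] = None,
    max_proposals_per_sample: int = 50,
) -> LevelSetSample:
    """Probe the near-optimal region of (m0, p, q) at a fixed exponent pair.

    Runs a seeded multiplicative random walk started at the pair's optimum,
    accepting states whose SSE stays at or below ``sse_cap`` and recording
    every accepted state until ``n_samples`` are collected.  Raises when the
    cap is at or below the pair's minimal SSE or when no proposal is ever
    accepted (suggesting a larger cap).
    """
    model = BertalanffyPutter(data)
    opt = start or model.fit(pair, method="constrained-gradient", seed=seed)
    if not math.isfinite(opt.sse):
        raise ValueError(f"no feasible optimum found at {pair!r}")
    if sse_cap <= opt.sse:
        raise ValueError(
            f"sse_cap={sse_cap} is not above the minimal SSE {opt.sse:.1f}; "
            "increase the cap"
        )
    rng = np.random.default_rng(seed)
    state = np.array(list(opt.params))
    samples = [state.copy()]
    sses = [opt.sse]
    budget = n_samples * max_proposals_per_sample
    while len(samples) < n_samples and budget > 0:
        budget -= 1
        prop = state * np.exp(step_sigma * rng.standard_normal(3))
        try:
            params = GrowthParameters(*prop)
        except ValueError:
            continue
        val = model.sse(pair, params)
        if val <= sse_cap:
            state = prop
            samples.append(state.copy())
            sses.append(val)
    if len(samples) < 2:
        raise ValueError("no proposal accepted; increase sse_cap or n_samples")
    return LevelSetSample(np.array(samples), np.array(sses), sse_cap)
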