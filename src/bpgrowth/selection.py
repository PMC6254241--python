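"""Model selection: small-sample AIC, pairwise Akaike weights, and the
near-optimality classification of exponent pairs.

For a model fitted by least squares to ``N`` class averages with ``K``
estimated parameters,

    AICc = N * ln(SSE / N) + 2K + 2K(K + 1) / (N - K - 1).

K follows the convention that the error variance counts as estimated: a fit
at a *given* exponent pair has K = 4 (m0, p, q + variance); optimizing one
exponent (the Gompertz diagonal family) gives K = 5 and optimizing both
gives K = 6.

Two models are compared through the pairwise Akaike weight

    w = exp(-delta/2) / (1 + exp(-delta/2)),     delta = AICc - AICc_best,

the probability that the model (rather than the best one) is true, at most
50%.  A pair is *acceptable* (near-optimal) when its weight against the best
model, both scored with K = 4, is at least t = 2.5%; algebraically this is
the SSE-ratio condition  SSE/SSE_best < (1/t - 1)**(2/N)  (= 1.757 for
N = 13).  A pair is *green* when its K = 4 AICc beats the best model's AICc
at the best model's correct K: the exponent-optimization penalty can make a
fixed pair preferable to the better-fitting optimized family.
"""

from __future__ import annotations

import enum
import math
import warnings
from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd

from .data import Dataset
from .fitting import BertalanffyPutter, FitResult
from .growth import ExponentPair

__all__ = [
    "aicc",
    "akaike_weight",
    "sse_ratio_threshold",
    "ModelScore",
    "RegionLabel",
    "classify_region",
    "weight_profile_b1",
]


def aicc(sse: float, n: int, k: int) -> float:
    """Small-sample Akaike information criterion of a least-squares fit."""
    if sse <= 0:
        raise ValueError("sse must be positive")
    if n <= k + 1:
        raise ValueError(f"AICc undefined for N={n} <= K+1={k + 1}")
    return n * math.log(sse / n) + 2 * k + 2 * k * (k + 1) / (n - k - 1)


def akaike_weight(aicc_model: float, aicc_best: float) -> float:
    """Pairwise Akaike weight of a model against the best model (max 0.5).

    A negative delta (the "best" model scoring worse) is allowed but warned
    about; the weight then exceeds 0.5.
    """
    delta = aicc_model - aicc_best
    if delta < 0:
        warnings.warn(
            "reference model has higher AICc than the compared model; "
            "weight exceeds 0.5",
            stacklevel=2,
        )
    e = math.exp(-delta / 2.0)
    return e / (1.0 + e)


def sse_ratio_threshold(n: int, t: float = 0.025) -> float:
    """Maximal acceptable SSE ratio over the best model: (1/t - 1)**(2/N)."""
    if not (0 < t <= 0.5):
        raise ValueError("acceptance level t must lie in (0, 0.5]")
    if n < 1:
        raise ValueError("N must be >= 1")
    return (1.0 / t - 1.0) ** (2.0 / n)


@dataclass(frozen=True)
class ModelScore:
    """Selection report entry for one model."""

    label: str
    sse: float
    n: int
    k: int
    aicc: float
    delta: float
    weight: float

    @classmethod
    def against_best(
        cls, label: str, sse: float, n: int, k: int, aicc_best: float
    ) -> "ModelScore":
        value = aicc(sse, n, k)
        return cls(label, sse, n, k, value, value - aicc_best,
                   akaike_weight(value, aicc_best))


class RegionLabel(enum.Enum):
    GREEN = "green"
    ACCEPTABLE_RED = "acceptable-red"
    REJECTED = "rejected"


def classify_region(
    surface,
    best: FitResult,
    best_family_k: int,
    t: float = 0.025,
    n: Optional[int] = None,
) -> dict[tuple[float, float], RegionLabel]:
    """Label every surface point green / acceptable-red / rejected.

    green          : the point's K = 4 AICc beats the best model's AICc at
                     its correct K (``best_family_k``, 5 for a diagonal
                     winner, 6 off-diagonal) -- parsimony prefers the fixed
                     pair despite its higher SSE.
    acceptable-red : not green, but the pairwise weight against the best
                     model with K = 4 on both sides reaches ``t``.
    rejected       : neither, or a non-converged (sentinel) fit.
    """
    if best_family_k not in (5, 6):
        raise ValueError("best_family_k must be 5 (diagonal) or 6 (free pair)")
    if best.model is not None and n is None:
        n = best.model.data.n_classes
    if n is None:
        raise ValueError("pass n when the best fit is not attached to a model")
    aicc_best_correct = aicc(best.sse, n, best_family_k)
    aicc_best_k4 = aicc(best.sse, n, 4)
    labels: dict[tuple[float, float], RegionLabel] = {}
    for res in surface:
        key = (round(res.pair.a, 6), round(res.pair.b, 6))
        if not res.converged or not math.isfinite(res.sse):
            labels[key] = RegionLabel.REJECTED
            continue
        value = aicc(res.sse, n, 4)
        if value < aicc_best_correct:
            labels[key] = RegionLabel.GREEN
        elif akaike_weight(value, aicc_best_k4) >= t:
            labels[key] = RegionLabel.ACCEPTABLE_RED
        else:
            labels[key] = RegionLabel.REJECTED
    return labels


def weight_profile_b1(
    data: Dataset,
    a_grid,
    overall_best_sse: Optional[float] = None,
    t: float = 0.025,
    method: str = "constrained-gradient",
    seed: int = 0,
) -> pd.DataFrame:
    """Akaike-weight profile of the generalized von Bertalanffy family (b = 1).

    Fits (a, 1) for every ``a`` in ``a_grid`` (warm-started in ascending
    order) and reports, per a, the pairwise weight against the best b = 1
    model of the grid and against the overall best model -- every AICc with
    K = 4.  When ``overall_best_sse`` is omitted the profile's own best SSE
    stands in (and the two weight columns coincide).

    Returns a frame with columns a, sse, weight_vs_b1_best,
    weight_vs_overall_best, acceptable.
    """
    model = BertalanffyPutter(data)
    n = data.n_classes
    a_values = sorted(float(a) for a in np.atleast_1d(np.asarray(a_grid, dtype=float)))
    fits: list[FitResult] = []
    prev = None
    for a in a_values:
        res = model.fit(ExponentPair(a, 1.0), start=prev, method=method, seed=seed)
        if res.converged and math.isfinite(res.sse):
            prev = res.params
        fits.append(res)
    sses = np.array([r.sse for r in fits])
    best_b1 = float(np.nanmin(np.where(np.isfinite(sses), sses, np.nan)))
    ref = best_b1 if overall_best_sse is None else float(overall_best_sse)
    aicc_b1 = aicc(best_b1, n, 4)
    aicc_ref = aicc(ref, n, 4)
    rows = []
    for a, r in zip(a_values, fits):
        if not math.isfinite(r.sse):
            rows.append({"a": a, "sse": r.sse, "weight_vs_b1_best": 0.0,
                         "weight_vs_overall_best": 0.0, "acceptable": False})
            continue
        value = aicc(r.sse, n, 4)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            w_row = akaike_weight(value, aicc_b1)
            w_all = akaike_weight(value, aicc_ref)
        rows.append(
            {
                "a": a,
                "sse": r.sse,
                "weight_vs_b1_best": w_row,
                "weight_vs_overall_best": w_all,
                "acceptable": w_all >= t,
            }
        )
    return pd.DataFrame(rows)
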