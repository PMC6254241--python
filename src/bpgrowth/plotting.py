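"""Minimal plotting: SSE contours over exponent pairs and curve overlays."""

from __future__ import annotations

import numpy as np

from .data import Dataset
from .fitting import FitResult
from .search import SSESurface


def plot_sse_contour(surface: SSESurface, ax=None, log10: bool = True):
    """Contour of SSE_opt over the scanned exponent pairs (tricontour)."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    df = surface.to_dataframe()
    finite = df[np.isfinite(df["SSR"])]
    z = np.log10(finite["SSR"]) if log10 else finite["SSR"]
    tc = ax.tricontourf(finite["a"], finite["b"], z, levels=20)
    ax.figure.colorbar(tc, ax=ax, label="log10 SSE" if log10 else "SSE")
    ax.set_xlabel("exponent a")
    ax.set_ylabel("exponent b")
    return ax


def plot_fit(result: FitResult, data: Dataset, ax=None, n_curve: int = 200):
    """Class averages with the fitted growth curve overlaid."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    t = np.linspace(0, float(data.ages.max()) * 1.05, n_curve)
    ax.plot(t, result.predict(t), label=f"fit a={result.pair.a:.3g}, b={result.pair.b:.3g}")
    ax.scatter(data.ages, data.masses, color="crimson", zorder=3, label="class averages")
    ax.set_xlabel("age (years)")
    ax.set_ylabel("mass (g)")
    ax.legend()
    return ax
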