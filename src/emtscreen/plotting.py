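"""Figures: dose-response curves and readout-correlation scatters."""

from __future__ import annotations

import numpy as np

__all__ = ["plot_dose_response", "plot_correlation"]


def plot_dose_response(results, concentrations=None, responses=None, ax=None,
                       label=None):
    """Fitted 4PL curve on a log-concentration axis, with the observed
    points when available (taken from the fit's model if not given)."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    if concentrations is None and results.model is not None:
        concentrations = results.model.conc
        responses = results.model.response
    if concentrations is not None:
        ax.semilogx(concentrations, responses, "o", color="0.3", ms=4)
        lo, hi = np.min(concentrations), np.max(concentrations)
    else:
        lo, hi = results.ic50 / 1e3, results.ic50 * 1e3
    grid = np.logspace(np.log10(lo) - 0.5, np.log10(hi) + 0.5, 200)
    ax.semilogx(grid, results.predict(grid), "-", label=label)
    ax.axhline(50.0, color="0.8", lw=0.8, zorder=0)
    ax.set_xlabel("concentration [nM]")
    ax.set_ylabel("effect [%]")
    if label:
        ax.legend(frameon=False)
    return ax


def plot_correlation(x, y, *, xlabel="", ylabel="", log=True, ax=None):
    """Scatter of two quantities (e.g. combined EMT IC50 vs kinase IC50)
    with the Spearman r and p annotated; censored pairs are dropped."""
    import matplotlib.pyplot as plt

    from .correlate import spearman

    if ax is None:
        _, ax = plt.subplots()
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    mask = np.isfinite(x) & np.isfinite(y)
    ax.plot(x[mask], y[mask], "o", color="tab:blue", ms=5)
    if log:
        ax.set_xscale("log")
        ax.set_yscale("log")
    res = spearman(x[mask], y[mask])
    ax.annotate(f"r = {res.r:.2f}\np = {res.p:.2g}", xy=(0.05, 0.95),
                xycoords="axes fraction", va="top")
    ax.set_xlabel(xlabel)
    ax.set_ylabel(ylabel)
    return ax
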