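"""Plot helpers for posterior, differential and dose-response results.

matplotlib is imported lazily so headless pipelines never pay for it.
"""

from __future__ import annotations

import numpy as np
import pandas as pd


def _ax(ax):
    if ax is None:
        import matplotlib.pyplot as plt

        _, ax = plt.subplots()
    return ax


def plot_pi_posterior(grid: np.ndarray, weights: np.ndarray, ax=None, **kwargs):
    """Posterior density of the new-RNA fraction from the grid backend."""
    ax = _ax(ax)
    dx = grid[1] - grid[0]
    ax.plot(grid, weights / dx, **kwargs)
    ax.set_xlabel("new-RNA fraction $\\pi$")
    ax.set_ylabel("posterior density")
    return ax


def plot_volcano(de_result: pd.DataFrame, q_threshold: float = 0.05, ax=None):
    """Effect size vs significance for a DE or enrichment table.

    Expects columns ``mean_diff`` (or ``fold_change``) and ``q_value``.
    """
    ax = _ax(ax)
    x = de_result["mean_diff"] if "mean_diff" in de_result else np.log2(de_result["fold_change"])
    y = -np.log10(np.clip(de_result["q_value"], 1e-300, None))
    sig = de_result["q_value"] < q_threshold
    ax.scatter(x[~sig], y[~sig], s=6, c="grey", alpha=0.6)
    ax.scatter(x[sig], y[sig], s=8, c="crimson")
    ax.axhline(-np.log10(q_threshold), ls="--", lw=0.8, c="black")
    ax.set_xlabel("effect size")
    ax.set_ylabel("$-\\log_{10}$ q")
    return ax


def plot_labeled_count_fit(counts: np.ndarray, probs: np.ndarray, ax=None):
    """Observed labeled-count histogram against the fitted distribution."""
    ax = _ax(ax)
    emp = np.bincount(np.asarray(counts, int), minlength=len(probs)) / len(counts)
    m = np.arange(max(len(emp), len(probs)))
    ax.bar(m[: len(emp)], emp, width=0.9, alpha=0.5, label="observed")
    ax.plot(np.arange(len(probs)), probs, "o-", ms=3, c="crimson", label="model")
    ax.set_xlabel("labeled molecules per cell")
    ax.set_ylabel("probability")
    ax.legend(frameon=False)
    return ax
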