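"""Plot renderers for the standard MR diagnostics.

Each helper takes the corresponding table (or SummarySet) and returns a
matplotlib Figure: forest of single-SNP estimates, exposure-vs-outcome
scatter with method slopes, leave-one-out caterpillar and funnel.
"""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from .estimators import MRResult
from .harmonise import SummarySet

__all__ = ["forest_plot", "scatter_plot", "leave_one_out_plot", "funnel_plot"]


def forest_plot(forest_table, ax=None):
    """Forest of per-SNP Wald ratios (black) and combined estimates (red)."""
    if ax is None:
        _, ax = plt.subplots(figsize=(6, 0.3 * len(forest_table) + 1.5))
    for y, row in enumerate(forest_table.itertuples(index=False)):
        combined = row.snp == "All"
        color = "tab:red" if combined else "black"
        ax.errorbar(row.estimate, y,
                    xerr=[[row.estimate - row.ci_low],
                          [row.ci_high - row.estimate]],
                    fmt="o", color=color, markersize=3)
    labels = [(r.method if r.snp == "All" else r.snp)
              for r in forest_table.itertuples(index=False)]
    ax.set_yticks(range(len(labels)), labels, fontsize=7)
    ax.axvline(0, color="grey", lw=0.8, ls="--")
    ax.set_xlabel("causal estimate per SNP")
    return ax.figure


def scatter_plot(summary_set: SummarySet, results: list[MRResult], ax=None):
    """SNP-outcome vs SNP-exposure effects with fitted method slopes."""
    if ax is None:
        _, ax = plt.subplots()
    bx, sx, by, sy = summary_set.arrays()
    ax.errorbar(bx, by, xerr=sx, yerr=sy, fmt="o", ms=3, color="black",
                ecolor="grey", elinewidth=0.7)
    grid = np.linspace(0, bx.max() * 1.05, 50)
    for res in results:
        icpt = res.intercept or 0.0
        ax.plot(grid, icpt + res.estimate * grid, label=res.method, lw=1)
    ax.set_xlabel("SNP effect on exposure")
    ax.set_ylabel("SNP effect on outcome")
    ax.legend(fontsize=7)
    return ax.figure


def leave_one_out_plot(loo_table, ax=None):
    """Caterpillar plot of estimates excluding each SNP in turn."""
    if ax is None:
        _, ax = plt.subplots(figsize=(6, 0.3 * len(loo_table) + 1.5))
    for y, row in enumerate(loo_table.itertuples(index=False)):
        color = "tab:red" if row.snp == "All" else "black"
        ax.errorbar(row.estimate, y,
                    xerr=[[row.estimate - row.ci_low],
                          [row.ci_high - row.estimate]],
                    fmt="o", color=color, markersize=3)
    ax.set_yticks(range(len(loo_table)), loo_table["snp"], fontsize=7)
    ax.set_xlabel("estimate excluding each SNP")
    return ax.figure


def funnel_plot(funnel_table, combined: list[MRResult] | None = None, ax=None):
    """Per-SNP estimates against precision; asymmetry suggests pleiotropy."""
    if ax is None:
        _, ax = plt.subplots()
    ax.plot(funnel_table["estimate"], funnel_table["precision"], "ko", ms=3)
    for res in combined or []:
        ax.axvline(res.estimate, lw=1, label=res.method)
    if combined:
        ax.legend(fontsize=7)
    ax.set_xlabel("per-SNP causal estimate")
    ax.set_ylabel("precision (1/se)")
    return ax.figure
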