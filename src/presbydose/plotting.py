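"""Plot helpers for dose–response curves and constraint tables."""

from __future__ import annotations

from typing import Mapping

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt

from .constraints import ConstraintTable, CurveSet

__all__ = ["plot_curves", "plot_constraints"]

_STRATUM_COLORS = {
    "<=49": "tab:red",
    "50-59": "tab:green",
    "60-69": "tab:blue",
    ">=70": "tab:orange",
}


def plot_curves(curve_set: CurveSet, ax: plt.Axes | None = None,
                risk_line: float | None = 0.05) -> plt.Axes:
    """Per-stratum NTCP curves (with percentile bands when present)."""
    if ax is None:
        _, ax = plt.subplots(figsize=(5, 4))
    for label, df in curve_set.curves.items():
        color = _STRATUM_COLORS.get(label)
        ax.plot(df["dose"], df["ntcp"], label=label, color=color)
        if {"lower", "upper"} <= set(df.columns):
            ax.fill_between(df["dose"], df["lower"], df["upper"],
                            alpha=0.15, color=color)
    if risk_line is not None:
        ax.axhline(risk_line, ls="--", lw=0.8, color="gray")
    ax.set_xlabel("EQD2 mean dose (Gy)")
    ax.set_ylabel("NTCP (chronic dysphagia)")
    ax.set_title(curve_set.roi)
    ax.legend(title="age", fontsize=8)
    return ax


def plot_constraints(table: ConstraintTable, ax: plt.Axes | None = None) -> plt.Axes:
    """Constraint doses by age stratum, one line per ROI."""
    if ax is None:
        _, ax = plt.subplots(figsize=(6, 4))
    wide = table.pivot(display=False)
    for roi, row in wide.iterrows():
        ax.plot(row.index, row.to_numpy(), marker="o", label=roi)
    ax.set_xlabel("age stratum")
    ax.set_ylabel(f"mean dose at NTCP = {table.risk_target:g} (Gy)")
    ax.legend(fontsize=8, ncol=2)
    return ax
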