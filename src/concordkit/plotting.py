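"""Dot-and-interval plots for prevalence shifts and pattern disaggregation."""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = ["plot_shifts", "plot_patterns"]


def plot_shifts(shifts: pd.DataFrame, sort_group: str | None = None, ax=None):
    """Percentage-point prevalence shifts per outcome, one dot per group.

    ``shifts`` is the tidy output of
    :func:`concordkit.estimation.prevalence_shift_table`.  Outcomes are
    sorted by the ``sort_group``'s shift when given.  Returns the axes.
    """
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(7, 0.45 * shifts["outcome_group"].nunique() + 1))
    order = list(shifts["outcome_group"].unique())
    if sort_group is not None:
        key = (
            shifts[shifts["group"] == sort_group]
            .set_index("outcome_group")["delta_pp"]
            .to_dict()
        )
        order = sorted(order, key=lambda o: -key.get(o, 0.0))
    ypos = {o: i for i, o in enumerate(order)}
    groups = list(shifts["group"].unique())
    cmap = plt.get_cmap("tab10")
    for gi, g in enumerate(groups):
        sub = shifts[shifts["group"] == g]
        y = sub["outcome_group"].map(ypos) + 0.08 * (gi - len(groups) / 2)
        ax.errorbar(
            sub["delta_pp"], y,
            xerr=[sub["delta_pp"] - sub["lower_pp"], sub["upper_pp"] - sub["delta_pp"]],
            fmt="o", ms=4, lw=1, color=cmap(gi % 10), label=g,
        )
    ax.axvline(0, color="0.5", lw=0.8)
    ax.set_yticks(range(len(order)), order)
    ax.invert_yaxis()
    ax.set_xlabel("prevalence shift, census minus EHR labeling (pp)")
    ax.legend(fontsize=8, ncol=2)
    return ax


def plot_patterns(patterns: pd.DataFrame, ax=None):
    """Disaggregated prevalences: aggregates (colored) and constituents (gray).

    ``patterns`` comes from
    :func:`concordkit.estimation.disaggregate_patterns`.  Circle areas scale
    with log10 of the member count.  Returns the axes.
    """
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(7, 0.4 * len(patterns) + 1))
    labels, y = [], 0
    for (labeling, group), sub in patterns.groupby(["labeling", "group"], sort=False):
        for _, row in sub.iterrows():
            is_agg = row["counterpart"] == "(aggregate)"
            color = "tab:red" if (is_agg and labeling == "CENSUS") else (
                "tab:blue" if is_agg else "0.6")
            size = 14 + 18 * np.log10(max(row["n"], 1))
            p, lo, hi = float(row["p"]), float(row["lower"]), float(row["upper"])
            ax.errorbar(
                100 * p, y,
                xerr=[[100 * (p - lo)], [100 * (hi - p)]],
                fmt="o", ms=size / 6, color=color, lw=1,
            )
            name = f"{labeling}-{group}" if is_agg else f"  {row['counterpart']} ({row['status']})"
            labels.append(name)
            y += 1
    ax.set_yticks(range(len(labels)), labels, fontsize=8)
    ax.invert_yaxis()
    ax.set_xlabel("prevalence (%)")
    return ax
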