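"""Learning-curve figures for scored cohorts (matplotlib)."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg", force=False)

import matplotlib.pyplot as plt
import pandas as pd

from .scoring import CHANCE_LEVELS


def plot_session_means(
    means: pd.DataFrame, metric: str, ax: "plt.Axes | None" = None
) -> "plt.Axes":
    """Group learning curves (mean +/- SEM per session) for one metric,
    with the analytic chance level as a dotted line where one exists.

    ``means`` is the ``session_means`` table from :func:`shuttleseq.stats.report`.
    """
    if ax is None:
        _, ax = plt.subplots(figsize=(7, 4))
    data = means[means["metric"] == metric]
    if data.empty:
        raise ValueError(f"no rows for metric {metric!r}")
    for group, sub in data.groupby("group"):
        sub = sub.sort_values("session")
        ax.errorbar(
            sub["session"], sub["mean"], yerr=sub["sem"], label=str(group),
            marker="o", markersize=3, capsize=2,
        )
    if metric in CHANCE_LEVELS:
        ax.axhline(CHANCE_LEVELS[metric], ls=":", color="gray", label="chance")
    ax.set_xlabel("session")
    ax.set_ylabel(f"{metric} (%)")
    ax.set_ylim(0, 100)
    ax.legend(frameon=False)
    return ax
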