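"""Diamond-grid visualization of the significance matrix.

Rows are metrics (grouped by family), columns are networks; a diamond
marks a (metric, network) cell whose FDR-adjusted group contrast is
significant at one or more thresholds, separately for static and dynamic
summaries.
"""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")  # headless environments
import matplotlib.pyplot as plt
import pandas as pd

FAMILY_COLORS = {
    "clustering": "#7b3294",
    "transitivity": "#7b3294",
    "char_path_length": "#e66101",
    "efficiency": "#e66101",
    "betweenness": "#1b7837",
    "degree": "#1b7837",
    "diameter": "#1b7837",
    "eccentricity": "#1b7837",
    "assortativity": "#d01c8b",
    "kcore": "#d01c8b",
}


def diamond_grid(significance: pd.DataFrame, condition: str, out_path=None):
    """Plot the diamond grid for one attentional condition.

    Parameters
    ----------
    significance
        Table from ``GroupThresholdAnova.significance_``.
    condition
        Condition label to plot (e.g. ``"OT"``).
    out_path
        When given, the figure is saved there and closed.
    """
    sub = significance[significance["condition"] == condition]
    if sub.empty:
        raise ValueError(f"no rows for condition {condition!r}")
    metrics = sorted(sub["metric"].unique())
    networks = sorted(sub["network"].unique())
    summary_types = ["dynamic", "static"]

    fig, axes = plt.subplots(
        1, 2, figsize=(2 + 1.2 * len(networks) * 2, 1 + 0.45 * len(metrics)),
        sharey=True,
    )
    for ax, stype in zip(axes, summary_types):
        cell = sub[sub["summary_type"] == stype]
        for yi, metric in enumerate(metrics):
            for xi, network in enumerate(networks):
                hit = cell[
                    (cell["metric"] == metric) & (cell["network"] == network)
                ]["significant"]
                if len(hit) and bool(hit.iloc[0]):
                    ax.scatter(
                        xi, yi, marker="D", s=90,
                        color=FAMILY_COLORS.get(metric, "0.3"),
                    )
        ax.set_xticks(range(len(networks)), networks)
        ax.set_yticks(range(len(metrics)), metrics)
        ax.set_xlim(-0.5, len(networks) - 0.5)
        ax.set_ylim(-0.5, len(metrics) - 0.5)
        ax.invert_yaxis()
        ax.set_title(f"{condition}: {'CV' if stype == 'dynamic' else 'mean'}")
        ax.grid(True, alpha=0.2)
    fig.tight_layout()
    if out_path is not None:
        fig.savefig(out_path, dpi=120)
        plt.close(fig)
    return fig
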