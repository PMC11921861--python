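"""Basic optional plots: network graph and centrality profiles.

Rendering is never part of the analysis contract; these helpers exist for
quick visual inspection.  Matplotlib is imported lazily so headless
pipelines never touch it.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .ggm import EDGE_EPS, PartialCorrelationNetwork


def plot_network(network: PartialCorrelationNetwork, ax=None):
    """Circle-layout graph; edge width ~ |weight|, green positive, red negative."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(5, 5))
    p = network.n_nodes
    angles = 2 * np.pi * np.arange(p) / p
    xy = np.column_stack([np.cos(angles), np.sin(angles)])
    for i in range(p):
        for j in range(i + 1, p):
            w = network.weights[i, j]
            if abs(w) <= EDGE_EPS:
                continue
            ax.plot(xy[[i, j], 0], xy[[i, j], 1],
                    color="seagreen" if w > 0 else "firebrick",
                    linewidth=6 * abs(w), alpha=0.8, zorder=1)
    ax.scatter(xy[:, 0], xy[:, 1], s=900, c="white", edgecolors="black",
               zorder=2)
    for i, label in enumerate(network.labels):
        ax.annotate(label, xy[i], ha="center", va="center", zorder=3)
    ax.set_axis_off()
    ax.set_aspect("equal")
    return ax


def plot_centrality(table: pd.DataFrame, ax=None):
    """Line profile per centrality index across nodes (z-scores advised)."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(6, 4))
    for col in table.columns:
        ax.plot(table[col].to_numpy(), table.index, marker="o", label=col)
    ax.set_xlabel("centrality")
    ax.legend(fontsize="small")
    return ax
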