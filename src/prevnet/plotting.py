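"""Static figures: network plot with a display threshold and strength plot."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import networkx as nx
import numpy as np
import pandas as pd

__all__ = ["plot_network", "plot_strength"]


def plot_network(network, cut: float = 0.15, path: str | Path | None = None, seed: int = 7):
    """Spring-layout network plot; edges below |cut| are omitted for clarity,
    positive edges drawn blue and negative red, width proportional to |w|."""
    w = np.asarray(network.weights)
    nodes = list(network.nodes)
    g = nx.Graph()
    g.add_nodes_from(nodes)
    p = len(nodes)
    for i in range(p):
        for j in range(i + 1, p):
            if abs(w[i, j]) >= cut and w[i, j] != 0.0:
                g.add_edge(nodes[i], nodes[j], weight=w[i, j])
    fig, ax = plt.subplots(figsize=(8, 8))
    pos = nx.spring_layout(g, seed=seed)
    colors = ["tab:blue" if d["weight"] > 0 else "tab:red" for _, _, d in g.edges(data=True)]
    widths = [4 * abs(d["weight"]) for _, _, d in g.edges(data=True)]
    nx.draw_networkx(g, pos, ax=ax, node_size=350, font_size=6,
                     edge_color=colors, width=widths, node_color="lightgray")
    ax.set_axis_off()
    if path is not None:
        fig.savefig(path, dpi=150, bbox_inches="tight")
        plt.close(fig)
    return fig


def plot_strength(centrality_by_wave: dict[int, pd.DataFrame], path: str | Path | None = None):
    """Strength-centrality profile per wave (one line per wave)."""
    fig, ax = plt.subplots(figsize=(6, 9))
    base = None
    for wave, table in sorted(centrality_by_wave.items()):
        t = table.sort_values("node").reset_index(drop=True)
        if base is None:
            base = t["node"]
        ax.plot(t["strength"], range(len(t)), marker="o", ms=3, label=f"T{wave}")
    ax.set_yticks(range(len(base)))
    ax.set_yticklabels(base, fontsize=6)
    ax.set_xlabel("strength")
    ax.legend()
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig
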