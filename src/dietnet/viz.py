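"""Basic network and centrality plot exports (matplotlib, Agg-safe)."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402
import networkx as nx  # noqa: E402
import numpy as np  # noqa: E402
import pandas as pd  # noqa: E402

from dietnet.centrality import to_graph  # noqa: E402

__all__ = ["plot_network", "plot_centrality_profile"]


def plot_network(weight: np.ndarray, names: list[str], path,
                 predictability: pd.Series | None = None) -> None:
    """Spring-layout network plot; edge width tracks weight, node ring
    size tracks predictability when given."""
    G = to_graph(weight, names)
    pos = nx.spring_layout(G, seed=0, weight="weight")
    fig, ax = plt.subplots(figsize=(7, 7))
    widths = [4.0 * d["weight"] for _, _, d in G.edges(data=True)]
    sizes = 600 * (predictability.reindex(names).fillna(0.0).to_numpy() + 0.3) \
        if predictability is not None else 400
    nx.draw_networkx(G, pos=pos, ax=ax, width=widths, node_size=sizes,
                     node_color="#f4c7c3", edge_color="#4c72b0",
                     font_size=8)
    ax.set_axis_off()
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_centrality_profile(table: pd.DataFrame, path) -> None:
    """z-scored strength/closeness/betweenness profile per node."""
    z = (table - table.mean()) / table.std(ddof=1)
    fig, axes = plt.subplots(1, z.shape[1], figsize=(3 * z.shape[1], 6),
                             sharey=True)
    for ax, col in zip(np.atleast_1d(axes), z.columns):
        ax.plot(z[col].to_numpy(), range(len(z)), marker="o")
        ax.set_title(col)
        ax.axvline(0.0, color="grey", lw=0.5)
    np.atleast_1d(axes)[0].set_yticks(range(len(z)), z.index)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
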