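"""Rendering helpers: cluster maps and DoC-coloured localisation maps."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

__all__ = ["cluster_map", "doc_map"]


def cluster_map(table, labels, path=None, ax=None, color="tab:green"):
    """Scatter of localisations with clustered points highlighted."""
    if ax is None:
        _, ax = plt.subplots(figsize=(6, 6))
    x = np.asarray(table["x_nm"], float)
    y = np.asarray(table["y_nm"], float)
    noise = labels < 0
    ax.scatter(x[noise], y[noise], s=1, c="0.7", linewidths=0)
    ax.scatter(x[~noise], y[~noise], s=1, c=color, linewidths=0)
    ax.set_aspect("equal")
    ax.set_xlabel("x (nm)")
    ax.set_ylabel("y (nm)")
    if path:
        ax.figure.savefig(path, dpi=200)
        plt.close(ax.figure)
    return ax


def doc_map(table, scores, path=None, ax=None):
    """Localisations coloured by DoC score (−1 separated … +1 colocalised)."""
    if ax is None:
        _, ax = plt.subplots(figsize=(6, 6))
    sc = ax.scatter(
        np.asarray(table["x_nm"], float),
        np.asarray(table["y_nm"], float),
        s=1, c=np.asarray(scores, float), cmap="coolwarm", vmin=-1, vmax=1,
        linewidths=0,
    )
    ax.figure.colorbar(sc, ax=ax, label="DoC score")
    ax.set_aspect("equal")
    ax.set_xlabel("x (nm)")
    ax.set_ylabel("y (nm)")
    if path:
        ax.figure.savefig(path, dpi=200)
        plt.close(ax.figure)
    return ax
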