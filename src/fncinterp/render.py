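"""Matplotlib rendering of FNC matrices and latent-grid montages.

Display conventions only — the stored data are never modified here.  The
optional transforms (lower-triangle population-mean removal, ×2 scaling of
difference maps) exist purely for visual contrast.
"""

from __future__ import annotations

import matplotlib
matplotlib.use("Agg", force=False)

import matplotlib.pyplot as plt
import numpy as np

from .fnc_data import devectorize


def fnc_heatmap(matrix: np.ndarray, ax=None, vlim: float = 1.0,
                remove_lower_mean: np.ndarray | None = None,
                scale: float = 1.0):
    """Render one C x C matrix; optionally subtract a population mean in the
    lower triangle and scale by ``scale`` (display only)."""
    m = np.array(matrix, dtype=float)
    if remove_lower_mean is not None:
        il = np.tril_indices(m.shape[0], k=-1)
        m[il] = (m[il] - np.asarray(remove_lower_mean)[il]) * scale
    if ax is None:
        _, ax = plt.subplots(figsize=(3, 3))
    im = ax.imshow(m, cmap="RdBu_r", vmin=-vlim, vmax=vlim)
    ax.set_xticks([])
    ax.set_yticks([])
    return im


def grid_montage(decoded: np.ndarray, side: int, n_components: int,
                 path=None, vlim: float = 1.0, cell_inches: float = 0.8):
    """Montage of all decoded grid nodes, row 0 at the top.

    ``decoded`` is (side^2, V) in row-major node order.  Returns the figure;
    saves a PNG when ``path`` is given.
    """
    fig, axes = plt.subplots(side, side,
                             figsize=(side * cell_inches, side * cell_inches))
    for node in range(side * side):
        ax = axes[node // side][node % side]
        fnc_heatmap(devectorize(decoded[node], n_components), ax=ax, vlim=vlim)
    fig.tight_layout(pad=0.1)
    if path is not None:
        fig.savefig(path, dpi=100)
        plt.close(fig)
    return fig


def state_panel(medians: dict, n_components: int, path=None, vlim: float = 1.0):
    """One row per group, one column per state, of median state matrices."""
    groups = sorted({g for g, _ in medians})
    states = sorted({s for _, s in medians})
    fig, axes = plt.subplots(len(groups), len(states),
                             figsize=(2.2 * len(states), 2.2 * len(groups)),
                             squeeze=False)
    for gi, g in enumerate(groups):
        for si, s in enumerate(states):
            ax = axes[gi][si]
            if (g, s) in medians:
                fnc_heatmap(devectorize(medians[(g, s)], n_components),
                            ax=ax, vlim=vlim)
            ax.set_title(f"{g} S{s}", fontsize=8)
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=100)
        plt.close(fig)
    return fig
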