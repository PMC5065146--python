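"""Figure helpers: 8-panel activity maps and the noise-sweep errorbar plot.

Panels are laid out on a 3x3 grid with one panel per direction channel
arranged compass-style around a central legend; the gray scale is fixed to
[0, 1] so maps are comparable across populations and figures.
"""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np

from .stimulus import DIRECTION_NAMES, DIRECTION_VECTORS

__all__ = ["plot_activity", "plot_sweep"]

# compass-style panel position (row, col) per direction channel
_PANEL_POS = {
    0: (1, 2),   # right
    1: (0, 2),   # up-right
    2: (0, 1),   # up
    3: (0, 0),   # up-left
    4: (1, 0),   # left
    5: (2, 0),   # down-left
    6: (2, 1),   # down
    7: (2, 2),   # down-right
}


def plot_activity(field: np.ndarray, path, *, title: str | None = None,
                  cmap: str = "gray") -> None:
    """Write an 8-panel map of an (H, W, 8) activity field to ``path``."""
    if field.ndim != 3 or field.shape[-1] != 8:
        raise ValueError("expected an (H, W, 8) activity field")
    fig, axes = plt.subplots(3, 3, figsize=(9, 9))
    for d in range(8):
        r, c = _PANEL_POS[d]
        ax = axes[r][c]
        ax.imshow(field[..., d], vmin=0.0, vmax=1.0, cmap=cmap,
                  interpolation="nearest")
        dx, dy = DIRECTION_VECTORS[d]
        ax.set_title(DIRECTION_NAMES[d], fontsize=9)
        ax.set_xticks([])
        ax.set_yticks([])
    mid = axes[1][1]
    mid.axis("off")
    for d in range(8):
        dx, dy = DIRECTION_VECTORS[d]
        mid.annotate("", xy=(0.5 + 0.35 * dx, 0.5 - 0.35 * dy),
                     xytext=(0.5, 0.5),
                     arrowprops=dict(arrowstyle="->", lw=1.2))
    mid.text(0.5, 0.02, "direction channels", ha="center", fontsize=8)
    if title:
        fig.suptitle(title)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_sweep(sweep_df, path, *, title: str | None = None) -> None:
    """Errorbar plot (mean +- SEM) of classification error vs noise scale."""
    fig, ax = plt.subplots(figsize=(5, 4))
    ax.errorbar(sweep_df["alpha"], sweep_df["mean_error"],
                yerr=sweep_df["sem"], marker="o", capsize=3)
    ax.set_xlabel(r"noise scale $\alpha$")
    ax.set_ylabel("mean classification error")
    ax.set_ylim(-0.05, 1.05)
    if title:
        ax.set_title(title)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
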