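"""Figure rendering: swarm plots of per-cell metrics and demograph heatmaps."""

from __future__ import annotations

from pathlib import Path
from typing import Mapping, Sequence

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np

from .demograph import Demograph

__all__ = ["swarm_plot", "demograph_heatmap"]


def swarm_plot(groups: Mapping[str, Sequence[float]], metric: str,
               path: str | Path, seed: int = 0) -> None:
    """Per-cell points with jitter, a light grey mean circle and an SD bar."""
    rng = np.random.default_rng(seed)
    fig, ax = plt.subplots(figsize=(1.2 * max(len(groups), 2) + 1, 4))
    for i, (name, values) in enumerate(groups.items()):
        v = np.asarray(values, float)
        x = i + rng.uniform(-0.18, 0.18, size=v.size)
        ax.plot(x, v, "o", ms=3, alpha=0.6, color="C0", zorder=1)
        m, s = v.mean(), v.std(ddof=1) if v.size > 1 else 0.0
        ax.plot([i, i], [m - s, m + s], "-", color="black", lw=2, zorder=2)
        ax.plot(i, m, "o", ms=10, mfc="lightgrey", mec="grey", zorder=3)
    ax.set_xticks(range(len(groups)), list(groups))
    ax.set_ylabel(metric)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def demograph_heatmap(demo: Demograph, path: str | Path,
                      cmap: str = "viridis") -> None:
    """Render a demograph matrix; unoccupied bins are left blank."""
    fig, ax = plt.subplots(figsize=(6, 4))
    m = np.ma.masked_invalid(demo.matrix)
    extent = (0, demo.matrix.shape[1] * demo.bin_step_um,
              demo.matrix.shape[0], 0)
    im = ax.imshow(m, aspect="auto", cmap=cmap, extent=extent,
                   interpolation="nearest")
    ax.set_xlabel("distance from non-hyphal pole (µm)")
    ax.set_ylabel(f"cells (sorted by length), stage: {demo.stage_group}")
    fig.colorbar(im, ax=ax, label=f"normalized {demo.channel} intensity")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
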