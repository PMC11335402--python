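"""Minimal heat-map export for grid-valued surfaces (convenience only)."""

from __future__ import annotations

from pathlib import Path

import numpy as np

from .morphospace import TheoreticalGrid


def surface_heatmap(
    grid: TheoreticalGrid,
    values: np.ndarray,
    path: str | Path,
    title: str = "",
    cmap: str = "viridis",
) -> None:
    """Render per-cell values over the PC1-PC2 grid to an image file.

    NaN cells (impossible morphospace or skipped solves) are left blank.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    field = np.asarray(values, dtype=float).reshape(grid.ny, grid.nx)
    fig, ax = plt.subplots(figsize=(6, 4.5))
    im = ax.pcolormesh(grid.pc1_values, grid.pc2_values, field, cmap=cmap, shading="nearest")
    fig.colorbar(im, ax=ax)
    ax.set_xlabel("PC1")
    ax.set_ylabel("PC2")
    if title:
        ax.set_title(title)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
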