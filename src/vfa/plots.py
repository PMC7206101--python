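"""Figure helpers: cost heat maps and agreement plots (PNG output)."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from .evaluation import bland_altman
from .feature_selection import CostMap, heatmap_matrix

__all__ = ["save_cost_heatmap", "save_bland_altman_plot", "save_correlation_plot"]


def save_cost_heatmap(
    cost_map: CostMap, grid_rows: int, grid_cols: int, path: str | Path,
    upsample: int = 8,
) -> Path:
    """Render the per-spot cost as an interpolated heat map."""
    raster = heatmap_matrix(cost_map, grid_rows, grid_cols, upsample=upsample)
    fig, ax = plt.subplots(figsize=(4.5, 4))
    im = ax.imshow(raster, cmap="viridis",
                   extent=(-0.5, grid_cols - 0.5, grid_rows - 0.5, -0.5))
    ax.set_xlabel("column")
    ax.set_ylabel("row")
    fig.colorbar(im, ax=ax, label="spot cost j")
    fig.tight_layout()
    path = Path(path)
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return path


def save_bland_altman_plot(pred, truth, path: str | Path) -> Path:
    """Bland-Altman agreement plot with the +/- 1 SD limits."""
    ba = bland_altman(pred, truth)
    fig, ax = plt.subplots(figsize=(5, 4))
    ax.scatter(ba["table"]["mean"], ba["table"]["difference"], s=18, alpha=0.7)
    ax.axhline(ba["mean_difference"], color="k", lw=1)
    for lim in ba["limits_1sd"]:
        ax.axhline(lim, color="r", ls="--", lw=1)
    ax.set_xlabel("mean of prediction and reference (mg/L)")
    ax.set_ylabel("difference (mg/L)")
    fig.tight_layout()
    path = Path(path)
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return path


def save_correlation_plot(pred, truth, path: str | Path) -> Path:
    """Prediction vs reference scatter with identity and best-fit lines."""
    pred = np.asarray(pred, dtype=float)
    truth = np.asarray(truth, dtype=float)
    slope, intercept = np.polyfit(truth, pred, 1)
    fig, ax = plt.subplots(figsize=(4.5, 4.5))
    ax.scatter(truth, pred, s=18, alpha=0.7)
    lim = (0, max(truth.max(), pred.max()) * 1.05)
    ax.plot(lim, lim, "k:", lw=1, label="y = x")
    xs = np.linspace(*lim, 50)
    ax.plot(xs, slope * xs + intercept, "r-", lw=1,
            label=f"fit: {slope:.2f}x + {intercept:.2f}")
    ax.set_xlabel("reference concentration (mg/L)")
    ax.set_ylabel("predicted concentration (mg/L)")
    ax.legend(frameon=False)
    fig.tight_layout()
    path = Path(path)
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return path
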