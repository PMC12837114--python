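"""Figures: accuracy bars with CI whiskers, cross-condition heatmap,
gaze-position heatmap over stimulus space."""

from __future__ import annotations

from pathlib import Path
from typing import Mapping

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np

from vsabci.evaluate import AccuracyEstimate, CrossConditionResult
from vsabci.gaze import FusedGazeTrace

CHANCE = 1.0 / 6.0


def accuracy_bars(
    estimates: Mapping[str, AccuracyEstimate],
    path: str | Path,
    title: str = "Single-trial selection accuracy",
) -> Path:
    """Bar chart of accuracies with bootstrap CI whiskers and chance line."""
    names = list(estimates)
    points = [estimates[n].point for n in names]
    err = np.array(
        [
            [estimates[n].point - estimates[n].ci_low for n in names],
            [estimates[n].ci_high - estimates[n].point for n in names],
        ]
    )
    fig, ax = plt.subplots(figsize=(1.6 * len(names) + 2, 4))
    ax.bar(names, points, yerr=err, capsize=4, color="#4878a8")
    ax.axhline(CHANCE, ls="--", color="gray", label="chance (1/6)")
    ax.set_ylim(0, 1.05)
    ax.set_ylabel("selection accuracy")
    ax.set_title(title)
    ax.legend(frameon=False)
    fig.tight_layout()
    path = Path(path)
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return path


def cross_condition_heatmap(
    result: CrossConditionResult, path: str | Path
) -> Path:
    """Train-condition x test-condition accuracy grid."""
    conds = result.conditions
    grid = np.array(
        [[result.matrix[(a, b)].point for b in conds] for a in conds]
    )
    fig, ax = plt.subplots(figsize=(5, 4.2))
    im = ax.imshow(grid, vmin=0, vmax=1, cmap="viridis")
    ax.set_xticks(range(len(conds)), conds)
    ax.set_yticks(range(len(conds)), conds)
    ax.set_xlabel("test condition")
    ax.set_ylabel("train condition")
    for i in range(len(conds)):
        for j in range(len(conds)):
            ax.text(
                j, i, f"{grid[i, j]:.2f}", ha="center", va="center",
                color="white" if grid[i, j] < 0.6 else "black",
            )
    fig.colorbar(im, ax=ax, label="selection accuracy")
    fig.tight_layout()
    path = Path(path)
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return path


def gaze_heatmap(
    trace: FusedGazeTrace,
    target_positions: np.ndarray,
    path: str | Path,
    cued_target: int | None = None,
    extent_deg: float = 18.0,
    bins: int = 60,
) -> Path:
    """2-D histogram of valid gaze samples with target crosshairs."""
    v = trace.valid
    fig, ax = plt.subplots(figsize=(5, 5))
    ax.hist2d(
        trace.x[v], trace.y[v], bins=bins,
        range=[[-extent_deg, extent_deg], [-extent_deg, extent_deg]],
        cmap="magma",
    )
    for i, (x, y) in enumerate(target_positions):
        color = "red" if i == cued_target else "white"
        ax.plot(x, y, "+", color=color, markersize=14, markeredgewidth=2)
    ax.set_xlabel("x (deg)")
    ax.set_ylabel("y (deg)")
    ax.set_aspect("equal")
    fig.tight_layout()
    path = Path(path)
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return path
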