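"""Static PNG plot helpers (momentum curves, score series, heat maps)."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt  # noqa: E402
import pandas as pd  # noqa: E402


def momentum_curve_plot(series_pair, path, labels=("Player 1", "Player 2")):
    """Two-player momentum trajectory over the point index."""
    fig, ax = plt.subplots(figsize=(10, 4))
    for series, label in zip(series_pair, labels):
        ax.plot(range(1, len(series) + 1), series.m, label=label, linewidth=1.2)
    ax.axhline(0.0, color="grey", linewidth=0.6)
    ax.set_xlabel("point")
    ax.set_ylabel("momentum")
    ax.legend(frameon=False)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return path


def score_time_series_plot(frame: pd.DataFrame, path):
    """Stacked cumulative points / games / sets panels for one match."""
    fig, axes = plt.subplots(3, 1, figsize=(10, 7), sharex=True)
    for ax, kind in zip(axes, ("points", "games", "sets")):
        for player, style in ((1, "-"), (2, "--")):
            ax.step(frame["point_no"], frame[f"{kind}_{player}"], style,
                    where="post", label=f"Player {player}")
        ax.set_ylabel(kind)
    axes[0].legend(frameon=False)
    axes[-1].set_xlabel("point")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return path


def correlation_heatmap(matrix: pd.DataFrame, path):
    """Signed heat map of an event correlation matrix."""
    fig, ax = plt.subplots(figsize=(8, 7))
    im = ax.imshow(matrix.to_numpy(), vmin=-1, vmax=1, cmap="RdBu_r")
    ax.set_xticks(range(len(matrix.columns)), matrix.columns, rotation=90, fontsize=7)
    ax.set_yticks(range(len(matrix.index)), matrix.index, fontsize=7)
    fig.colorbar(im, ax=ax, shrink=0.8)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return path
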