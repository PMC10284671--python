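"""Result visualizations: screen score-vs-rank and ranked correlation curves."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd


def plot_screen_scores(screen_rows: pd.DataFrame, path: str | Path) -> None:
    """Interaction score against gene rank, calls highlighted.

    Lethal candidates sit at the positive extreme (left), alleviating at the
    negative extreme (right); uncalled genes form the grey body of the curve.
    """
    df = screen_rows.dropna(subset=["interaction_score"]).reset_index(drop=True)
    ranks = np.arange(1, len(df) + 1)
    fig, ax = plt.subplots(figsize=(7, 4))
    colors = df["call"].map(
        {"lethal": "#c0392b", "alleviating": "#2980b9", "none": "0.7"}
    )
    ax.scatter(ranks, df["interaction_score"], s=8, c=colors, linewidths=0)
    ax.axhline(0, color="0.3", lw=0.8)
    ax.set_xlabel("gene rank (by interaction score)")
    ax.set_ylabel("interaction score  −log10(p) × sign(Δmedian)")
    ax.set_title("GI screen: lethal (red) and alleviating (blue) candidates")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_ranked_correlations(
    ess_rows: pd.DataFrame, knee_pos: int, knee_neg: int, path: str | Path
) -> None:
    """Ranked Pearson-r curves with the knee thresholds marked."""
    fig, axes = plt.subplots(1, 2, figsize=(9, 4), sharey=False)
    pos = ess_rows[ess_rows["r"] > 0].sort_values("r", ascending=False)
    neg = ess_rows[ess_rows["r"] < 0].sort_values("r", ascending=True)
    axes[0].plot(np.arange(1, len(pos) + 1), pos["r"], ".", ms=3, color="#c0392b")
    axes[0].axvline(knee_pos, color="0.2", ls="--", lw=0.8, label=f"knee @ {knee_pos}")
    axes[0].set_title("positive (co-essential)")
    axes[1].plot(np.arange(1, len(neg) + 1), neg["r"], ".", ms=3, color="#2980b9")
    axes[1].axvline(knee_neg, color="0.2", ls="--", lw=0.8, label=f"knee @ {knee_neg}")
    axes[1].set_title("negative (anti-essential)")
    for ax in axes:
        ax.set_xlabel("rank")
        ax.set_ylabel("Pearson r")
        ax.legend(frameon=False, fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
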