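"""Basic figures: CVA scatter, bite-force box plots, correlogram biplots."""

from __future__ import annotations

from typing import Optional, Sequence

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

__all__ = ["DIET_COLORS", "cva_scatter", "boxplot_with_jitter", "correlogram_biplot"]

# Publication-style diet-group colours.
DIET_COLORS = {
    "HOK": "#1f3b99",   # dark blue
    "NEH": "#7b2d8b",   # purple
    "CCH": "#8c8c8c",   # grey
    "ICH": "#000000",   # black
    "SWJ": "#e68a00",   # orange
}


def _color_for(label: str) -> str:
    return DIET_COLORS.get(str(label), "#2a6f4e")


def cva_scatter(scores: np.ndarray, labels: Sequence, pct: Sequence[float],
                path: str, title: str = "CVA") -> None:
    """CV1 x CV2 scatter coloured by group (CV1 only if one axis)."""
    scores = np.asarray(scores)
    fig, ax = plt.subplots(figsize=(6, 5))
    y = scores[:, 1] if scores.shape[1] > 1 else np.zeros(len(scores))
    for g in dict.fromkeys(map(str, labels)):
        m = np.asarray([str(l) == g for l in labels])
        ax.scatter(scores[m, 0], y[m], label=g, color=_color_for(g), s=30, alpha=0.85)
    ax.set_xlabel(f"CV1 ({pct[0]:.2f}%)")
    if scores.shape[1] > 1:
        ax.set_ylabel(f"CV2 ({pct[1]:.2f}%)")
    ax.legend(frameon=False, fontsize=8)
    ax.set_title(title)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def boxplot_with_jitter(values: Sequence[float], labels: Sequence, path: str,
                        ylabel: str = "bite force", seed: int = 0) -> None:
    values = np.asarray(values, dtype=float)
    labels = np.asarray([str(l) for l in labels])
    groups = list(dict.fromkeys(labels))
    rng = np.random.default_rng(seed)
    fig, ax = plt.subplots(figsize=(6, 4.5))
    data = [values[labels == g] for g in groups]
    ax.boxplot(data, tick_labels=groups, showfliers=False)
    for i, (g, d) in enumerate(zip(groups, data), start=1):
        x = i + rng.uniform(-0.12, 0.12, size=len(d))
        ax.scatter(x, d, color=_color_for(g), s=18, alpha=0.8, zorder=3)
    ax.set_ylabel(ylabel)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def correlogram_biplot(correlograms, path: str, alpha: float = 0.05) -> None:
    """Moran's I against class mean distance; significant classes filled."""
    fig, ax = plt.subplots(figsize=(6.5, 4.5))
    for cg in np.atleast_1d(correlograms):
        ok = np.isfinite(cg.morans_I)
        ax.plot(cg.mean_distance_km[ok], cg.morans_I[ok], "-", lw=1, label=cg.variable)
        sig = ok & np.isfinite(cg.p_perm) & (cg.p_perm < alpha)
        ax.scatter(cg.mean_distance_km[ok], cg.morans_I[ok], s=18, facecolors="none",
                   edgecolors="k")
        ax.scatter(cg.mean_distance_km[sig], cg.morans_I[sig], s=24, color="k", zorder=3)
    ax.axhline(0.0, color="grey", lw=0.8, ls="--")
    ax.set_xlabel("mean distance (km)")
    ax.set_ylabel("Moran's I")
    ax.legend(frameon=False, fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
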