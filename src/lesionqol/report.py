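"""Figure and table rendering for association results.

Every number shown in a figure is read from the tidy tables the association
stage wrote; nothing is recomputed here.  Heatmaps encode -log10(p) with the
screen's alpha marked on the colour bar and the sign of the estimate by
glyph; the header strip groups predictors by hemisphere (left / right /
midline).
"""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

__all__ = ["render_group_comparison", "render_screen_heatmap", "render_scatter"]

_HEMI_COLOR = {"left": "#4472c4", "right": "#70ad47", "midline": "#c00000"}


def render_group_comparison(table: pd.DataFrame, out_path: str | Path) -> Path:
    """Bar chart of left/right group medians with star annotations.

    ``table`` is the laterality-comparison output (one row per scale).
    """
    out_path = Path(out_path)
    n = len(table)
    fig, ax = plt.subplots(figsize=(max(6, 0.6 * n), 4))
    x = np.arange(n)
    ax.bar(x - 0.2, table["median_left"], width=0.4, label="left-sided", color="#4472c4")
    ax.bar(x + 0.2, table["median_right"], width=0.4, label="right-sided", color="#70ad47")
    for i, (_, row) in enumerate(table.iterrows()):
        if row["stars"]:
            ax.text(i, max(row["median_left"], row["median_right"]) + 2,
                    row["stars"], ha="center", fontsize=10)
    ax.set_xticks(x)
    ax.set_xticklabels(table.index, rotation=60, ha="right", fontsize=8)
    ax.set_ylabel("median score (0-100)")
    ax.set_ylim(0, 112)
    ax.legend(frameon=False)
    fig.tight_layout()
    fig.savefig(out_path, dpi=120)
    plt.close(fig)
    return out_path


def _hemisphere_of(predictor: str, hemi_lookup: dict[str, str] | None) -> str:
    if hemi_lookup and predictor in hemi_lookup:
        return hemi_lookup[predictor]
    for token in predictor.split(":"):
        if token.startswith("LH_"):
            return "left"
        if token.startswith("RH_"):
            return "right"
    return "midline"


def render_screen_heatmap(
    p_values: pd.DataFrame,
    estimates: pd.DataFrame,
    alpha: float,
    out_path: str | Path,
    title: str = "",
    hemi_lookup: dict[str, str] | None = None,
) -> Path:
    """Predictor x scale heatmap of -log10(p) with significance markers.

    Cells below ``alpha`` are marked "+" or "-" according to the sign of the
    estimate; a banner replaces the markers when no cell is significant.
    The top strip colours predictors by hemisphere.
    """
    out_path = Path(out_path)
    logp = -np.log10(p_values.to_numpy(dtype=float))
    n_pred, n_scale = p_values.shape
    fig, ax = plt.subplots(figsize=(max(6, 0.12 * n_pred), max(3, 0.45 * n_scale) + 0.6))
    im = ax.imshow(
        np.nan_to_num(logp.T, nan=0.0), aspect="auto", cmap="viridis",
        vmin=0, vmax=max(4.0, -np.log10(alpha) + 1),
    )
    cb = fig.colorbar(im, ax=ax, fraction=0.03)
    cb.set_label("-log10 p")
    cb.ax.axhline(-np.log10(alpha), color="red", lw=1.5)
    # hemisphere strip above the matrix
    for j, pred in enumerate(p_values.index):
        ax.add_patch(
            plt.Rectangle((j - 0.5, -1.4), 1, 0.8, clip_on=False,
                          color=_HEMI_COLOR[_hemisphere_of(str(pred), hemi_lookup)])
        )
    sig = (p_values.to_numpy(dtype=float) < alpha)
    if sig.any():
        for j in range(n_pred):
            for i in range(n_scale):
                if sig[j, i]:
                    glyph = "+" if estimates.iloc[j, i] >= 0 else "-"
                    ax.text(j, i, glyph, ha="center", va="center",
                            color="white", fontsize=7)
    else:
        ax.set_xlabel(f"no cells significant at alpha = {alpha}")
    ax.set_yticks(range(n_scale))
    ax.set_yticklabels(p_values.columns, fontsize=7)
    ax.set_xticks([])
    ax.set_title(title or f"correlation screen (alpha = {alpha})", fontsize=10)
    fig.tight_layout()
    fig.savefig(out_path, dpi=120)
    plt.close(fig)
    return out_path


def render_scatter(
    x: pd.Series,
    y: pd.Series,
    r: float,
    p: float,
    out_path: str | Path,
    xlabel: str = "within-network connectivity (z)",
    ylabel: str = "score (0-100)",
) -> Path:
    """Scatter of one node's connectivity against one scale, annotated with
    the r and p taken from the association table (not recomputed)."""
    out_path = Path(out_path)
    fig, ax = plt.subplots(figsize=(4.2, 3.6))
    ax.scatter(x, y, s=14, alpha=0.7, color="#4472c4")
    ok = x.notna() & y.notna()
    if ok.sum() >= 2:
        coef = np.polyfit(x[ok], y[ok], 1)
        xv = np.linspace(float(x[ok].min()), float(x[ok].max()), 50)
        ax.plot(xv, np.polyval(coef, xv), color="#c00000", lw=1.5)
    ax.set_xlabel(xlabel)
    ax.set_ylabel(ylabel)
    ax.set_title(f"R = {r:.2f}, p = {p:.2g}", fontsize=10)
    fig.tight_layout()
    fig.savefig(out_path, dpi=120)
    plt.close(fig)
    return out_path
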