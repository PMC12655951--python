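"""Figure helpers: per-parameter box plots, correlation panel, PCA biplot."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from .genostats import PcaResult

LOADING_SCALE = 5.0  # biplot loadings are scaled for readability, scores never


def boxplots(
    features: pd.DataFrame, parameters: list[str], out_path: str | Path,
    group: str = "genotype",
) -> None:
    """One box plot per mechanical parameter, grouped by genotype."""
    n = len(parameters)
    ncol = min(n, 3)
    nrow = (n + ncol - 1) // ncol
    fig, axes = plt.subplots(nrow, ncol, figsize=(4 * ncol, 3 * nrow), squeeze=False)
    groups = sorted(features[group].dropna().unique())
    for ax, param in zip(axes.flat, parameters):
        data = [features.loc[features[group] == g, param].dropna() for g in groups]
        ax.boxplot(data, tick_labels=groups)
        ax.set_title(param)
        ax.tick_params(axis="x", rotation=45)
    for ax in axes.flat[n:]:
        ax.set_visible(False)
    fig.tight_layout()
    fig.savefig(out_path, dpi=150)
    plt.close(fig)


def correlation_panel(
    r: pd.DataFrame, mask: pd.DataFrame, out_path: str | Path
) -> None:
    """Heatmap of Pearson r with non-significant cells blanked."""
    shown = r.where(mask)
    fig, ax = plt.subplots(figsize=(1.0 * len(r) + 2, 1.0 * len(r) + 1))
    im = ax.imshow(shown.to_numpy(), vmin=-1, vmax=1, cmap="RdBu")
    ax.set_xticks(range(len(r)), r.columns, rotation=45, ha="right")
    ax.set_yticks(range(len(r)), r.index)
    for i in range(len(r)):
        for j in range(len(r)):
            val = shown.iat[i, j]
            ax.text(j, i, f"{val:.2f}" if np.isfinite(val) else "",
                    ha="center", va="center", fontsize=8)
    fig.colorbar(im, ax=ax, label="Pearson r (p < 0.05)")
    fig.tight_layout()
    fig.savefig(out_path, dpi=150)
    plt.close(fig)


def pca_biplot(
    result: PcaResult, out_path: str | Path,
    groups: pd.Series | None = None,
) -> None:
    """Scores on PC1/PC2 with loading vectors scaled by LOADING_SCALE."""
    fig, ax = plt.subplots(figsize=(7, 6))
    sc = result.scores
    if groups is not None:
        for g in sorted(groups.dropna().unique()):
            sel = groups.loc[sc.index] == g
            ax.scatter(sc.loc[sel, "PC1"], sc.loc[sel, "PC2"], s=18, label=str(g))
        ax.legend(fontsize=8)
    else:
        ax.scatter(sc["PC1"], sc["PC2"], s=18)
    for var in result.loadings.index:
        lx, ly = result.loadings.loc[var, ["PC1", "PC2"]] * LOADING_SCALE
        ax.annotate("", xy=(lx, ly), xytext=(0, 0),
                    arrowprops=dict(arrowstyle="->", color="black"))
        ax.text(lx * 1.08, ly * 1.08, var, fontsize=8)
    evr = result.explained_variance_ratio
    ax.set_xlabel(f"PC1 ({evr[0] * 100:.1f}%)")
    ax.set_ylabel(f"PC2 ({evr[1] * 100:.1f}%)")
    ax.axhline(0, lw=0.5, color="grey")
    ax.axvline(0, lw=0.5, color="grey")
    fig.tight_layout()
    fig.savefig(out_path, dpi=150)
    plt.close(fig)
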