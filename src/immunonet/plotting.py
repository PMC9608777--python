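"""Plot helpers for the main pipeline outputs (matplotlib, Agg-safe)."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402
import pandas as pd  # noqa: E402

__all__ = ["plot_roc_curves", "plot_preservation", "plot_module_trait"]


def plot_roc_curves(curves: dict[str, pd.DataFrame], aucs: dict[str, float] | None = None, ax=None):
    """Overlay ROC curves; ``curves`` maps model name -> (fpr, tpr) table."""
    if ax is None:
        _, ax = plt.subplots(figsize=(4, 4))
    for name, df in curves.items():
        label = name if not aucs else f"{name} (AUC={aucs.get(name, float('nan')):.2f})"
        ax.plot(df["fpr"], df["tpr"], label=label)
    ax.plot([0, 1], [0, 1], ls="--", c="grey", lw=0.8)
    ax.set_xlabel("False positive rate")
    ax.set_ylabel("True positive rate")
    ax.legend(fontsize=8)
    return ax


def plot_preservation(table: pd.DataFrame, z_min: float = 10.0, ax=None):
    """Module size vs Z-summary scatter with the preservation threshold."""
    if ax is None:
        _, ax = plt.subplots(figsize=(4, 4))
    ax.scatter(table["n_genes"], table["z_summary"])
    for m, row in table.iterrows():
        ax.annotate(str(m), (row["n_genes"], row["z_summary"]), fontsize=8)
    ax.axhline(z_min, ls="--", c="gold")
    ax.set_xlabel("module size (genes)")
    ax.set_ylabel("Z-summary")
    return ax


def plot_module_trait(assoc: pd.DataFrame, ax=None):
    """Module x trait heatmap of Spearman correlations."""
    mat = assoc.pivot(index="module", columns="trait", values="spearman_rho")
    if ax is None:
        _, ax = plt.subplots(figsize=(1 + mat.shape[1], 0.5 * len(mat) + 1))
    im = ax.imshow(mat.to_numpy(), cmap="RdBu_r", vmin=-1, vmax=1)
    ax.set_xticks(range(mat.shape[1]), mat.columns, rotation=45, ha="right")
    ax.set_yticks(range(len(mat)), mat.index)
    plt.colorbar(im, ax=ax, label="Spearman rho")
    return ax
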