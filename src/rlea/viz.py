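"""Heatmap and dendrogram rendering.

Plots are written straight to file with the Agg backend; nothing here
requires a display.
"""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np
from scipy.cluster import hierarchy

from .preprocess import LinkageTree


def render_heatmap(matrix, alpha: float, path: str, row_order=None) -> str:
    """Heatmap of -log10 raw p-values, n cell types x m locus sets.

    Cells whose adjusted p-value clears ``alpha`` are drawn with a heavy
    dark-red border so that multiple-testing survivors stand out, the
    same emphasis encoded in the ``survives_correction`` column of the
    result CSVs.
    """
    neglog = matrix.neg_log10
    survives = matrix.survives
    if row_order is not None:
        neglog = neglog.loc[row_order]
        survives = survives.loc[row_order]
    values = neglog.to_numpy(dtype=float)
    values = np.where(np.isfinite(values), values, np.nanmax(values[np.isfinite(values)], initial=0.0))
    n, m = values.shape
    fig, ax = plt.subplots(
        figsize=(max(4.0, 0.6 * m + 2.5), max(3.0, 0.35 * n + 1.5))
    )
    im = ax.imshow(values, cmap="Reds", aspect="auto")
    ax.set_xticks(range(m), labels=list(neglog.columns), rotation=45, ha="right")
    ax.set_yticks(range(n), labels=list(neglog.index))
    for i in range(n):
        for j in range(m):
            if bool(survives.iloc[i, j]):
                ax.add_patch(
                    plt.Rectangle(
                        (j - 0.5, i - 0.5), 1, 1,
                        fill=False, edgecolor="darkred", linewidth=2.5,
                    )
                )
    fig.colorbar(im, ax=ax, label=r"$-\log_{10}\,p$")
    ax.set_title(f"Enrichment (outlined: adjusted p < {alpha:g})")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return path


def render_dendrogram(tree: LinkageTree, path: str) -> str:
    """Draw the cell-type dendrogram; Newick text goes next to it."""
    fig, ax = plt.subplots(figsize=(max(4.0, 0.5 * len(tree.labels) + 2), 4))
    hierarchy.dendrogram(tree.merges, labels=tree.labels, ax=ax)
    ax.set_ylabel("merge height (Euclidean)")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
    newick_path = path.rsplit(".", 1)[0] + ".nwk"
    with open(newick_path, "w") as fh:
        fh.write(tree.to_newick() + "\n")
    return path


def dendrogram_leaf_order(tree: LinkageTree) -> list:
    """Leaf labels in dendrogram display order."""
    order = hierarchy.leaves_list(tree.merges)
    return [tree.labels[i] for i in order]
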