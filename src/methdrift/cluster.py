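"""Ward biclustering of the called-probe intra-pair ΔBeta matrix.

Rows (probes) and columns (donors) are clustered independently with Ward
linkage on Euclidean distances; a 2-cluster cut of the donor tree gives the
low-grade / high-grade grouping readout.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from sklearn.metrics import rand_score

from .model import ValidationError


@dataclass
class BiclusterResult:
    row_linkage: np.ndarray
    col_linkage: np.ndarray
    row_order: list[str]  # probe ids in dendrogram leaf order
    col_order: list[str]  # donor ids in dendrogram leaf order
    col_labels2: pd.Series  # donor -> cluster label at the 2-cluster cut


def ward_bicluster(delta_beta: pd.DataFrame) -> BiclusterResult:
    """Bicluster a probes x donors ΔBeta matrix (Ward / Euclidean).

    scipy's linkage is deterministic for a given input order; equal-height
    merges resolve to the lowest-index pair.
    """
    if delta_beta.shape[0] < 2 or delta_beta.shape[1] < 2:
        raise ValidationError("biclustering needs at least 2 probes and 2 donors")
    if delta_beta.isna().any().any():
        raise ValidationError("ΔBeta matrix contains missing values")
    X = delta_beta.to_numpy(dtype=float)
    row_linkage = hierarchy.linkage(X, method="ward")
    col_linkage = hierarchy.linkage(X.T, method="ward")
    row_order = [delta_beta.index[i] for i in hierarchy.leaves_list(row_linkage)]
    col_order = [delta_beta.columns[i] for i in hierarchy.leaves_list(col_linkage)]
    labels = hierarchy.fcluster(col_linkage, 2, criterion="maxclust")
    col_labels2 = pd.Series(labels, index=delta_beta.columns, name="cluster")
    return BiclusterResult(row_linkage, col_linkage, row_order, col_order, col_labels2)


def rand_index(labels_a, labels_b) -> float:
    """Rand index between two partitions of the same items."""
    return float(rand_score(np.asarray(labels_a), np.asarray(labels_b)))


def plot_heatmap(delta_beta: pd.DataFrame, result: BiclusterResult, path) -> None:
    """Optional heatmap export of the biclustered matrix (requires matplotlib)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    ordered = delta_beta.loc[result.row_order, result.col_order]
    lim = max(abs(float(ordered.values.min())), abs(float(ordered.values.max())), 1e-9)
    fig, ax = plt.subplots(figsize=(6, 8))
    im = ax.imshow(ordered.values, aspect="auto", cmap="RdBu_r", vmin=-lim, vmax=lim)
    ax.set_xticks(range(len(result.col_order)))
    ax.set_xticklabels(result.col_order, rotation=90, fontsize=6)
    ax.set_yticks([])
    ax.set_xlabel("donor")
    ax.set_ylabel(f"{len(result.row_order)} called probes")
    fig.colorbar(im, ax=ax, label="intra-pair ΔBeta")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
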