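"""Diagnostic plots: class dendrogram, loading heatmaps, metric bars."""

from __future__ import annotations

from typing import Mapping, Sequence

import numpy as np

from .modeling import METRIC_NAMES, MetricsReport
from .selection import ClassDendrogram, PCASelectionResult


def plot_dendrogram(dend: ClassDendrogram, ax=None):
    """Class-mean dendrogram (Mahalanobis heights)."""
    import matplotlib.pyplot as plt
    from scipy.cluster import hierarchy

    if ax is None:
        _, ax = plt.subplots(figsize=(5, 4))
    hierarchy.dendrogram(dend.linkage, labels=dend.labels, ax=ax)
    ax.set_ylabel("Mahalanobis distance between class means")
    return ax


def plot_loadings_heatmap(
    result: PCASelectionResult,
    signal_of: Mapping[str, str],
    n_pcs: int = 5,
    ax=None,
):
    """|loading| heatmap of the first PCs, rows grouped by source signal."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(4, 8))
    order = np.argsort([signal_of.get(n, "?") for n in result.feature_names], kind="stable")
    W = np.abs(result.loadings[order, :n_pcs])
    im = ax.imshow(W, aspect="auto", cmap="viridis")
    ax.set_xticks(range(n_pcs), [f"PC{j+1}" for j in range(n_pcs)])
    ax.set_yticks(range(len(order)), [result.feature_names[i] for i in order], fontsize=5)
    ax.figure.colorbar(im, ax=ax, label="|loading|")
    return ax


def plot_metric_bars(reports: Mapping[str, MetricsReport], ax=None):
    """Grouped bar chart of metric means with SD error bars per family."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(8, 4))
    families = list(reports)
    width = 0.8 / len(METRIC_NAMES)
    xs = np.arange(len(families))
    for j, m in enumerate(METRIC_NAMES):
        means = [float(reports[f].mean[m]) for f in families]
        stds = [float(reports[f].std[m]) for f in families]
        ax.bar(xs + j * width, means, width, yerr=stds, capsize=2, label=m.upper())
    ax.set_xticks(xs + 0.4 - width / 2, families, rotation=20)
    ax.set_ylim(0, 1.05)
    ax.legend(ncol=5, fontsize=8)
    return ax
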