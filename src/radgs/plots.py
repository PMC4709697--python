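"""Diagnostic plots: MAF spectrum, genotype/effect PCA, accuracy boxes.

All functions draw on a provided or fresh matplotlib Axes and return it;
callers decide about saving.  Kept deliberately minimal — these are
run-inspection aids, not publication figures.
"""

from __future__ import annotations

import numpy as np


def _axes(ax):
    if ax is not None:
        return ax
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    _, ax = plt.subplots()
    return ax


def maf_histogram(X, ax=None, bins=20):
    """Minor-allele-frequency spectrum of a 0/1/2 matrix (NaN allowed)."""
    X = np.asarray(X, dtype=float)
    p = np.nanmean(X, axis=0) / 2.0
    maf = np.minimum(p, 1 - p)
    ax = _axes(ax)
    ax.hist(maf[np.isfinite(maf)], bins=bins, range=(0, 0.5),
            color="#4878d0", edgecolor="white")
    ax.set_xlabel("minor allele frequency")
    ax.set_ylabel("markers")
    return ax


def pca_scatter(scores, labels=None, ax=None):
    """First two PC scores, optionally colored by group label."""
    scores = np.asarray(scores, dtype=float)
    ax = _axes(ax)
    if labels is None:
        ax.scatter(scores[:, 0], scores[:, 1], s=12)
    else:
        labels = np.asarray(labels)
        for lab in np.unique(labels):
            m = labels == lab
            ax.scatter(scores[m, 0], scores[m, 1], s=12, label=str(lab))
        ax.legend(title="group", fontsize="small")
    ax.set_xlabel("PC1")
    ax.set_ylabel("PC2")
    return ax


def accuracy_boxplot(results, by="method", value="accuracy", ax=None):
    """Box plot of per-repeat accuracies from a cross_validate table."""
    ax = _axes(ax)
    groups = results.groupby(by)[value]
    names = list(groups.groups)
    ax.boxplot([groups.get_group(n).dropna() for n in names],
               tick_labels=names)
    ax.set_ylabel(value)
    return ax
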