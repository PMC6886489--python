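"""Figures: dendrogram, PCA scatter, and ratio bar plots."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt  # noqa: E402
from scipy.cluster.hierarchy import dendrogram  # noqa: E402

_TYPE_COLORS = {"control": "tab:blue", "CR": "tab:cyan", "WDR": "tab:red",
                "mixed": "tab:gray"}


def plot_dendrogram(results, ax=None):
    """Ward dendrogram of the retained-sample clustering."""
    if ax is None:
        _, ax = plt.subplots(figsize=(10, 4))
    dendrogram(results.clusters.linkage, ax=ax, no_labels=True,
               color_threshold=None)
    ax.set_ylabel("Ward merge height")
    ax.set_title("Replicate clustering (retained sample)")
    return ax


def plot_pca(results, ax=None):
    """PC1/PC2 scatter colored by cluster type."""
    if ax is None:
        _, ax = plt.subplots(figsize=(6, 5))
    scores = results.pca_scores
    assign = results.clusters.assignment
    types = assign.map(results.clusters.cluster_types)
    for ctype in sorted(types.unique()):
        sel = types.index[types == ctype]
        ax.scatter(scores.loc[sel, "PC1"], scores.loc[sel, "PC2"],
                   s=18, label=ctype,
                   color=_TYPE_COLORS.get(ctype, "tab:olive"))
    evr = results.pca_explained
    ax.set_xlabel(f"PC1 ({evr[0] * 100:.1f}%)")
    ax.set_ylabel(f"PC2 ({evr[1] * 100:.1f}%)")
    ax.legend(frameon=False, fontsize=8)
    return ax


def plot_ratio_bars(results, ax=None):
    """Per-target relative-expression bars with the control line at y = 1."""
    if ax is None:
        _, ax = plt.subplots(figsize=(8, 4))
    df = results.ratios
    df = df[df["treatment"] != results.model.control_treatment]
    labels = [f"{r.target}\n{r.cultivar}/{r.treatment}"
              for r in df.itertuples()]
    ax.bar(range(len(df)), df["ratio"], color="tab:purple", width=0.7)
    ax.axhline(1.0, color="black", linewidth=1)  # control expression level
    ax.set_xticks(range(len(df)), labels, fontsize=7, rotation=45,
                  ha="right")
    ax.set_ylabel("relative expression ratio")
    return ax
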