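"""Basic static plots: growth curve, keyword trends, heatmap, dendrogram."""

from __future__ import annotations

import numpy as np


def _pyplot():
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    return plt


def plot_annual_counts(series: dict[int, float], fit=None, path="annual_counts.png"):
    """Annual publication counts, optionally with the fitted exponential."""
    plt = _pyplot()
    fig, ax = plt.subplots(figsize=(7, 4))
    years = sorted(series)
    ax.scatter(years, [series[y] for y in years], s=12, label="publications")
    if fit is not None:
        xs = np.linspace(min(years), max(years), 200)
        ax.plot(xs, fit.predict(xs), "r-",
                label=f"y = {fit.a:.2f} exp({fit.b:.3f} x), doubling {fit.doubling_time:.2f} yr")
    ax.set_xlabel("year")
    ax.set_ylabel("publications")
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_keyword_proportions(series_by_keyword: dict[str, dict[int, float]],
                             path="keyword_trends.png"):
    """Per-keyword annual prevalence lines."""
    plt = _pyplot()
    fig, ax = plt.subplots(figsize=(7, 4))
    for kw, series in series_by_keyword.items():
        years = sorted(series)
        ax.plot(years, [series[y] for y in years], label=kw)
    ax.set_xlabel("year")
    ax.set_ylabel("proportion of publications")
    ax.legend(fontsize=7)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_heatmap(matrix, clustering=None, n_clusters: int = 6, path="heatmap.png"):
    """Keyword x year relative-frequency heatmap, cluster-ordered if given."""
    plt = _pyplot()
    order = matrix.years
    if clustering is not None:
        labels = clustering.cut(n_clusters)
        order = sorted(matrix.years, key=lambda y: (labels[y], y))
    cols = [matrix.years.index(y) for y in order]
    fig, ax = plt.subplots(figsize=(10, max(4, 0.15 * len(matrix.keywords))))
    im = ax.imshow(matrix.values[:, cols], aspect="auto", cmap="viridis")
    ax.set_xticks(range(len(order)), [str(y) for y in order], rotation=90, fontsize=5)
    ax.set_yticks(range(len(matrix.keywords)), matrix.keywords, fontsize=5)
    fig.colorbar(im, ax=ax, label="relative frequency")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_dendrogram(clustering, path="dendrogram.png"):
    """Year dendrogram from the linkage matrix."""
    from scipy.cluster.hierarchy import dendrogram

    plt = _pyplot()
    fig, ax = plt.subplots(figsize=(9, 4))
    dendrogram(clustering.linkage, labels=[str(y) for y in clustering.years],
               ax=ax, leaf_font_size=7)
    ax.set_ylabel(f"merge height ({clustering.method})")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
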