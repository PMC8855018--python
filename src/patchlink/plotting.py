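"""Debug plots: land-use map, patch network, model effect summaries."""

from __future__ import annotations

import numpy as np


def plot_landscape(raster, patches=None, graph=None, sites=None, ax=None):
    """Land-use grid with optional patch centroids, planar edges and sites.

    Returns the matplotlib axes.  Intended as a quick structural check of a
    generated or loaded landscape, not as publication cartography.
    """
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(6, 6))
    ax.imshow(raster.grid, origin="upper", interpolation="nearest",
              cmap="viridis")
    nrow = raster.grid.shape[0]
    res = raster.resolution

    def to_rc(x, y):
        return (x / res - 0.5), (nrow - y / res - 0.5)

    if patches is not None:
        centroids = {p.id: to_rc(*p.centroid) for p in patches}
        xs, ys = zip(*centroids.values())
        ax.scatter(xs, ys, s=12, c="white", edgecolors="black", zorder=3)
        if graph is not None:
            for (i, j), dist in graph.edges.items():
                if not np.isfinite(dist):
                    continue
                xi, yi = centroids[i]
                xj, yj = centroids[j]
                ax.plot([xi, xj], [yi, yj], "-", c="white", lw=0.7, zorder=2)
    if sites is not None:
        for _, row in sites.iterrows():
            cx, cy = to_rc(row["x"], row["y"])
            ax.plot(cx, cy, "r^", ms=5, zorder=4)
    ax.set_xticks([])
    ax.set_yticks([])
    return ax


def plot_coefficients(results, ax=None):
    """Coefficient dot-and-whisker plot (95% CI) for one fitted model."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(5, 3))
    ci = results.conf_int(0.05)
    terms = [t for t in results.params.index if t != "const"]
    y = np.arange(len(terms))
    ax.errorbar(
        [results.params[t] for t in terms], y,
        xerr=np.array([[results.params[t] - ci.loc[t, 0] for t in terms],
                       [ci.loc[t, 1] - results.params[t] for t in terms]]),
        fmt="o", color="black", capsize=3)
    ax.axvline(0, color="grey", lw=0.8, ls="--")
    ax.set_yticks(y, terms)
    ax.set_xlabel("coefficient (scaled predictors)")
    return ax
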