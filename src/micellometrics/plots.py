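"""Optional matplotlib views of reporting results.

Violin-style distribution plots (median, interquartile box, KDE body)
and 2D joint-density maps.  Figures are written to file; nothing here is
needed for the numeric outputs and the default pipeline never imports
this module.
"""

from __future__ import annotations

import numpy as np

from .reporting import DescriptorSeries, JointDensity

__all__ = ["violin_plot", "joint_density_plot"]


def violin_plot(series: list[DescriptorSeries], path: str | None = None,
                ylabel: str = ""):
    """Violin plot of one or more descriptor distributions: KDE body,
    interquartile box, median dot."""
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(1.2 + 1.1 * len(series), 3.5))
    for k, s in enumerate(series):
        half = 0.4 * s.kde_density / max(s.kde_density.max(), 1e-300)
        ax.fill_betweenx(s.kde_grid, k - half, k + half, alpha=0.6,
                         lw=0.5)
        q1, med, q3 = s.quartiles
        ax.add_patch(plt.Rectangle((k - 0.05, q1), 0.1, q3 - q1,
                                   color="k", alpha=0.8))
        ax.plot([k], [med], "wo", ms=4, zorder=5)
    ax.set_xticks(range(len(series)),
                  [s.name or str(i) for i, s in enumerate(series)])
    ax.set_ylabel(ylabel)
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig


def joint_density_plot(jd: JointDensity, path: str | None = None,
                       xlabel: str = "", ylabel: str = ""):
    """Filled-contour map of a 2D joint density with its maxima marked."""
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(4.0, 3.5))
    ax.contourf(jd.x_grid, jd.y_grid, jd.density, levels=12)
    if jd.maxima:
        mx = np.asarray(jd.maxima)
        ax.plot(mx[:, 0], mx[:, 1], "r+", ms=8)
    ax.set_xlabel(xlabel)
    ax.set_ylabel(ylabel)
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig
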