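"""Distribution summaries, joint densities and correlations.

Summary statistics are always computed on the raw per-frame values;
kernel density estimates are a presentation transform only.  Standard
errors use block averaging (the frames of one trajectory are correlated,
so the naive SE underestimates), with 10 blocks by default.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from scipy.stats import gaussian_kde, pearsonr

__all__ = ["DescriptorSeries", "JointDensity", "CorrelationTable",
           "summarize", "joint_distribution", "correlate"]


@dataclass
class DescriptorSeries:
    """Per-frame series with mean, block-averaged SE, quartiles and KDE."""

    name: str
    values: np.ndarray
    mean: float
    se: float
    quartiles: tuple[float, float, float]
    kde_grid: np.ndarray
    kde_density: np.ndarray
    n_blocks: int


def summarize(values, name: str = "", n_blocks: int = 10,
              kde_points: int = 256) -> DescriptorSeries:
    """Mean, block-averaged standard error, quartiles and KDE density."""
    values = np.asarray(values, float)
    if len(values) < n_blocks:
        raise ValueError(
            f"need at least n_blocks={n_blocks} values, have {len(values)}")
    blocks = np.array_split(values, n_blocks)
    block_means = np.array([b.mean() for b in blocks])
    se = float(block_means.std(ddof=1) / np.sqrt(n_blocks))
    q1, med, q3 = np.percentile(values, [25, 50, 75])
    if values.std() > 0:
        kde = gaussian_kde(values)
        pad = 3.0 * values.std()
        grid = np.linspace(values.min() - pad, values.max() + pad,
                           kde_points)
        dens = kde(grid)
    else:
        grid = np.linspace(values[0] - 1.0, values[0] + 1.0, kde_points)
        dens = np.zeros(kde_points)
    return DescriptorSeries(
        name=name, values=values, mean=float(values.mean()), se=se,
        quartiles=(float(q1), float(med), float(q3)),
        kde_grid=grid, kde_density=dens, n_blocks=n_blocks)


@dataclass
class JointDensity:
    """2D KDE on a rectangular grid with its local maxima."""

    x_grid: np.ndarray
    y_grid: np.ndarray
    density: np.ndarray            # (len(y), len(x)), unit mass
    maxima: list[tuple[float, float]]


def joint_distribution(x, y, grid: tuple[int, int] = (64, 64),
                       peak_threshold: float = 0.05) -> JointDensity:
    """Unit-mass 2D kernel density of two aligned series, with local
    maxima above ``peak_threshold`` of the global peak reported (used to
    expose bimodal shape/size populations)."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if len(x) != len(y):
        raise ValueError("series lengths differ")
    if len(x) < 10:
        raise ValueError("need at least 10 points")
    if x.std() == 0 or y.std() == 0:
        raise ValueError(
            "zero-variance input; use a 1D summary (summarize) instead")
    kde = gaussian_kde(np.vstack([x, y]))
    pad_x, pad_y = 2.0 * x.std(), 2.0 * y.std()
    gx = np.linspace(x.min() - pad_x, x.max() + pad_x, grid[0])
    gy = np.linspace(y.min() - pad_y, y.max() + pad_y, grid[1])
    mx, my = np.meshgrid(gx, gy)
    dens = kde(np.vstack([mx.ravel(), my.ravel()])).reshape(my.shape)
    mass = dens.sum() * (gx[1] - gx[0]) * (gy[1] - gy[0])
    dens = dens / mass
    local_max = (ndimage.maximum_filter(dens, size=5) == dens) \
        & (dens > peak_threshold * dens.max())
    ys, xs = np.nonzero(local_max)
    maxima = [(float(gx[j]), float(gy[i])) for i, j in zip(ys, xs)]
    return JointDensity(x_grid=gx, y_grid=gy, density=dens, maxima=maxima)


@dataclass
class CorrelationTable:
    """Pearson correlations between named descriptor series."""

    r: dict[tuple[str, str], float]
    n: int

    def as_dataframe(self):
        import pandas as pd

        rows = [{"x": a, "y": b, "pearson_r": v}
                for (a, b), v in self.r.items()]
        return pd.DataFrame(rows)


def correlate(descriptors: dict[str, np.ndarray],
              pairs: list[tuple[str, str]] | None = None) -> CorrelationTable:
    """Pairwise Pearson r; default pairs are Rg against every other
    descriptor when an "rg" series is present, else all pairs."""
    series = {k: np.asarray(v, float) for k, v in descriptors.items()}
    lengths = {len(v) for v in series.values()}
    if len(lengths) != 1:
        raise ValueError("descriptor series are not frame-aligned")
    n = lengths.pop()
    if pairs is None:
        keys = list(series)
        if "rg" in series:
            pairs = [("rg", k) for k in keys if k != "rg"]
        else:
            pairs = [(a, b) for i, a in enumerate(keys)
                     for b in keys[i + 1:]]
    out: dict[tuple[str, str], float] = {}
    for a, b in pairs:
        xa, xb = series[a], series[b]
        if xa.std() == 0 or xb.std() == 0:
            out[(a, b)] = float("nan")
        else:
            out[(a, b)] = float(pearsonr(xa, xb).statistic)
    return CorrelationTable(r=out, n=n)
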