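"""Gaussian expression landscapes over a 2D network layout.

Node-wise values (typically log2 fold changes) are smoothed onto a pixel grid:
each pixel takes the Gaussian-kernel-weighted MEAN of the node values,

    value(x) = sum_i v_i w_i / sum_i w_i,   w_i = exp(-||x - p_i||² / (2σ²)),

with σ in normalized layout units (default 0.04 on the unit square). The
weighted mean keeps the grid in the units of the node values (a maximum
principle bounds every pixel by the node-value range), and pixels far from all
nodes (total weight < 1e-6) are masked as background. Rendered with a
diverging colormap centered at 0: warm colors mark upregulation, cold colors
downregulation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import networkx as nx
import numpy as np
from matplotlib.colors import TwoSlopeNorm

logger = logging.getLogger(__name__)

WEIGHT_FLOOR = 1e-6

__all__ = ["Layout2D", "LandscapeGrid", "compute_layout", "gaussian_landscape", "render_landscape"]


@dataclass(frozen=True)
class Layout2D:
    """Per-node (x, y) positions normalized to the unit square."""

    positions: Mapping[str, tuple[float, float]]

    def __post_init__(self) -> None:
        for node, (x, y) in self.positions.items():
            if not (0.0 <= x <= 1.0 and 0.0 <= y <= 1.0):
                raise ValueError(f"position of {node!r} outside unit square: {(x, y)}")


@dataclass
class LandscapeGrid:
    resolution: int
    sigma: float
    values: np.ndarray  # (resolution, resolution); row = y, column = x
    mask: np.ndarray    # True where support is too low (background)


def compute_layout(graph: nx.Graph, seed: int = 1) -> Layout2D:
    """Deterministic force-directed (spring) layout rescaled to [0, 1]²."""
    if graph.number_of_nodes() == 0:
        raise ValueError("cannot lay out an empty graph")
    if graph.number_of_nodes() == 1:
        node = next(iter(graph.nodes))
        return Layout2D(positions={node: (0.5, 0.5)})
    raw = nx.spring_layout(graph, seed=seed)
    coords = np.array([raw[n] for n in graph.nodes])
    lo, hi = coords.min(axis=0), coords.max(axis=0)
    span = np.where(hi - lo > 0, hi - lo, 1.0)
    scaled = (coords - lo) / span
    return Layout2D(
        positions={
            node: (float(x), float(y)) for node, (x, y) in zip(graph.nodes, scaled)
        }
    )


def gaussian_landscape(
    layout: Layout2D,
    values: Mapping[str, float],
    sigma: float = 0.04,
    resolution: int = 512,
) -> LandscapeGrid:
    """Smooth node values onto a resolution × resolution grid (see module docs).

    Laid-out nodes without a value are excluded with a logged count.
    """
    if sigma <= 0:
        raise ValueError(f"sigma must be > 0, got {sigma}")
    if resolution < 1:
        raise ValueError(f"resolution must be >= 1, got {resolution}")
    nodes = [n for n in layout.positions if n in values]
    n_missing = len(layout.positions) - len(nodes)
    if n_missing:
        logger.info("excluded %d laid-out node(s) without a value", n_missing)
    if not nodes:
        raise ValueError("no laid-out node has a value")
    points = np.array([layout.positions[n] for n in nodes])  # (n, 2)
    node_values = np.array([values[n] for n in nodes])

    axis = (np.arange(resolution) + 0.5) / resolution
    gx, gy = np.meshgrid(axis, axis)  # rows index y, columns x
    dx = gx[..., None] - points[:, 0]
    dy = gy[..., None] - points[:, 1]
    weights = np.exp(-(dx**2 + dy**2) / (2.0 * sigma**2))
    total = weights.sum(axis=-1)
    mask = total < WEIGHT_FLOOR
    with np.errstate(invalid="ignore", divide="ignore"):
        grid = (weights * node_values).sum(axis=-1) / total
    grid[mask] = 0.0
    return LandscapeGrid(resolution=resolution, sigma=sigma, values=grid, mask=mask)


def render_landscape(
    grid: LandscapeGrid,
    path,
    layout: Layout2D | None = None,
    cmap: str = "Spectral_r",
    title: str | None = None,
) -> None:
    """Write the landscape as a PNG with a diverging colormap centered at 0;
    masked pixels render as neutral background. Optionally overdraws node
    positions."""
    display = np.ma.masked_array(grid.values, mask=grid.mask)
    limit = float(np.abs(display).max()) if display.count() else 1.0
    limit = limit if limit > 0 else 1.0
    norm = TwoSlopeNorm(vmin=-limit, vcenter=0.0, vmax=limit)
    fig, ax = plt.subplots(figsize=(6, 6))
    cmap_obj = plt.get_cmap(cmap).copy()
    cmap_obj.set_bad("0.92")
    image = ax.imshow(
        display, origin="lower", extent=(0, 1, 0, 1), cmap=cmap_obj, norm=norm
    )
    if layout is not None:
        xs = [p[0] for p in layout.positions.values()]
        ys = [p[1] for p in layout.positions.values()]
        ax.scatter(xs, ys, s=6, c="black", linewidths=0)
    if title:
        ax.set_title(title)
    ax.set_xticks([])
    ax.set_yticks([])
    fig.colorbar(image, ax=ax, shrink=0.8, label="relative expression (log2 FC)")
    try:
        fig.savefig(path, dpi=150, bbox_inches="tight")
    except OSError as exc:
        raise OSError(f"could not write landscape image to {path}: {exc}") from exc
    finally:
        plt.close(fig)


def write_grid_tsv(grid: LandscapeGrid, path) -> None:
    out = np.where(grid.mask, np.nan, grid.values)
    np.savetxt(path, out, delimiter="\t", fmt="%.6g")
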