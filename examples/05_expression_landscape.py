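"""Render a Gaussian expression landscape over a network layout.

Builds a small synthetic interactome, assigns each node a log2 fold change
(a smooth gradient plus noise, so the landscape shows coherent warm/cold
regions), and smooths the values onto a 256 × 256 grid with the Gaussian
kernel (sigma 0.04 in layout units). Output: landscape.png in scratch/ (or
the current directory if scratch/ is absent).
"""

from pathlib import Path

import numpy as np

from netbiomark import (
    augment_with_connectors,
    compute_layout,
    filter_interactions,
    gaussian_landscape,
    induced_subgraph,
    render_landscape,
)
from netbiomark.simulate import simulate_interactome

truth = simulate_interactome(
    n_background=100, seed_sizes=(40, 45), overlap=6,
    n_isolated_clusters=2, cluster_size=2, seed=3,
)
channels = ("experimental", "database")
filtered = filter_interactions(truth.interactions, channels, 0.400)
graph = augment_with_connectors(
    filtered, induced_subgraph(filtered, truth.seed_sets)
).graph

layout = compute_layout(graph, seed=1)
rng = np.random.default_rng(5)
values = {
    node: 4.0 * (x - 0.5) + rng.normal(0, 0.3)
    for node, (x, y) in layout.positions.items()
}

grid = gaussian_landscape(layout, values, sigma=0.04, resolution=256)
unmasked = grid.values[~grid.mask]
print(f"grid: {grid.resolution}x{grid.resolution}, "
      f"{grid.mask.mean():.0%} background, value range "
      f"[{unmasked.min():.2f}, {unmasked.max():.2f}]")

out_dir = Path("scratch") if Path("scratch").is_dir() else Path(".")
out = out_dir / "landscape.png"
render_landscape(grid, out, layout=layout, title="synthetic expression landscape")
print(f"wrote {out}")
# Warm (red) pixels mark upregulated neighbourhoods, cold (blue) pixels
# downregulated ones; pixels far from every node are neutral background.
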