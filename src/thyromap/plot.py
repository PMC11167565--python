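"""Display of incidence maps and phase topographies.

Reproduces the atlas display conventions — a 1 x 1 mm² grid overlay in the
front view and 0.4 x 0.4 mm² in the section view, with the cartilage
skeleton outline for orientation.  Styling is non-normative.
"""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg", force=False)
import matplotlib.pyplot as plt
import numpy as np

from .atlas import IncidenceMap, Topography
from .frames import load_skeleton_template

__all__ = ["plot_incidence_map", "plot_topography"]

_GRID_MM = {"front": 1.0, "section": 0.4}


def _decorate(ax, grid, view):
    g = _GRID_MM[view]
    x0, x1 = grid.x_range
    s0, s1 = grid.second_range
    ax.set_xticks(np.arange(np.ceil(x0 / g) * g, x1 + g / 2, g))
    ax.set_yticks(np.arange(np.ceil(s0 / g) * g, s1 + g / 2, g))
    ax.grid(True, lw=0.3, color="0.7")
    ax.set_xlabel("X (mm)")
    ax.set_ylabel(("Y" if view == "front" else "Z") + " (mm)")
    ax.set_aspect("equal")
    skel = load_skeleton_template()
    outlines = skel.front_outlines if view == "front" else skel.section_outlines
    for line in outlines.values():
        ax.plot(line[:, 0], line[:, 1], color="0.3", lw=0.8)


def plot_incidence_map(imap: IncidenceMap, ax=None):
    """Render one incidence map (fraction of specimens per cell)."""
    if ax is None:
        _, ax = plt.subplots(figsize=(5, 5))
    grid = imap.grid
    extent = (*grid.x_range, *grid.second_range)
    im = ax.imshow(imap.values, origin="upper", extent=extent, cmap="Blues",
                   vmin=0, vmax=1)
    _decorate(ax, grid, imap.view)
    ax.set_title(f"incidence {imap.phase or ''} (N={imap.n_specimens})")
    plt.colorbar(im, ax=ax, fraction=0.046, label="incidence k/N")
    return ax.figure


def plot_topography(topo: Topography, ax=None):
    """Overlay the per-phase threshold regions in enlargement order."""
    if ax is None:
        _, ax = plt.subplots(figsize=(5, 5))
    cmap = plt.get_cmap("viridis")
    n = max(len(topo.entries), 1)
    for i, (phase, region) in enumerate(topo.entries):
        if region.is_empty:
            continue
        grid = region.grid
        extent = (*grid.x_range, *grid.second_range)
        masked = np.ma.masked_where(~region.pixels, np.ones(region.pixels.shape))
        ax.imshow(masked, origin="upper", extent=extent,
                  cmap=matplotlib.colors.ListedColormap([cmap(i / n)]),
                  alpha=0.45, interpolation="nearest")
        ax.plot([], [], color=cmap(i / n), lw=4, label=phase)
    if topo.entries:
        _decorate(ax, topo.entries[0][1].grid, topo.view)
    ax.legend(fontsize=7, loc="lower right")
    ax.set_title(f"phase topography ({topo.view}, tau={topo.tau:g})")
    return ax.figure
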