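"""Matplotlib conveniences for the polarity analyses (no scientific claims).

Matplotlib is imported lazily and is an optional dependency
(``pip install icpolarity[plot]``).
"""

from __future__ import annotations

import numpy as np


def plot_skewness_histogram(records, ax=None, bins=60):
    """Histogram of topography skewness, split by dominance sign."""
    import matplotlib.pyplot as plt

    ax = ax or plt.gca()
    pos = records.loc[records["dominance"] == 1, "skewness"]
    neg = records.loc[records["dominance"] == -1, "skewness"]
    ax.hist(pos, bins=bins, color="tab:red", alpha=0.7,
            label="positive-dominant")
    ax.hist(neg, bins=bins, color="tab:blue", alpha=0.7,
            label="negative-dominant")
    ax.set_xlabel("topography skewness")
    ax.set_ylabel("IC count")
    ax.legend()
    return ax


def plot_density_grid(grid, ax=None):
    """Angle-by-RV probability grid as an image."""
    import matplotlib.pyplot as plt

    ax = ax or plt.gca()
    im = ax.imshow(grid.values.T, origin="lower", aspect="auto",
                   extent=[grid.angle_edges[0], grid.angle_edges[-1],
                           grid.rv_edges[0], grid.rv_edges[-1]],
                   cmap="viridis")
    ax.set_xlabel("radial-deviation angle (deg)")
    ax.set_ylabel("residual variance (%)")
    plt.colorbar(im, ax=ax, label="probability")
    return ax


def plot_topography(topography, electrodes, ax=None, levels=16):
    """Crude 2-D scalp map: azimuthal-equidistant projection + contours."""
    import matplotlib.pyplot as plt
    from matplotlib.tri import Triangulation

    ax = ax or plt.gca()
    pos = np.stack([e.position for e in electrodes])
    r = np.linalg.norm(pos, axis=1)
    incl = np.arccos(np.clip(pos[:, 2] / r, -1, 1))
    az = np.arctan2(pos[:, 1], pos[:, 0])
    x, y = incl * np.cos(az), incl * np.sin(az)
    tri = Triangulation(x, y)
    vmax = np.max(np.abs(topography))
    c = ax.tricontourf(tri, topography, levels=levels, cmap="RdBu_r",
                       vmin=-vmax, vmax=vmax)
    ax.scatter(x, y, s=4, c="k")
    ax.set_aspect("equal")
    ax.set_axis_off()
    plt.colorbar(c, ax=ax)
    return ax
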