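"""Topographic interpolation of per-channel values over the forehead.

Scalar channel values (session-averaged activations, priority scores)
are interpolated onto a regular grid with piecewise-linear barycentric
interpolation on the Delaunay triangulation of the channel positions.
The linear interpolant is exact at the channel locations and cannot
overshoot the channel value range; grid cells outside the convex hull of
the channels are masked, never extrapolated.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping

import numpy as np
from scipy.interpolate import LinearNDInterpolator
from scipy.spatial import QhullError

from .containers import ChannelLayout

__all__ = ["TopoMap", "interpolate_topomap", "plot_topomap"]


@dataclass
class TopoMap:
    """Interpolated 2-D map of per-channel values.

    ``grid`` is (resolution x resolution) with NaN outside the channel
    convex hull; ``mask`` is True where the grid is valid.
    """

    x: np.ndarray  # (resolution,) cm
    y: np.ndarray  # (resolution,) cm
    grid: np.ndarray  # (resolution, resolution), NaN outside hull
    mask: np.ndarray  # bool, True inside hull
    positions: np.ndarray  # (n_channels, 2)
    values: np.ndarray  # (n_channels,)
    channel_ids: np.ndarray

    def to_frame(self):
        import pandas as pd

        xx, yy = np.meshgrid(self.x, self.y)
        return pd.DataFrame({"x_cm": xx.ravel(), "y_cm": yy.ravel(), "value": self.grid.ravel()})


def interpolate_topomap(
    layout: ChannelLayout,
    values: Mapping[int, float] | np.ndarray,
    resolution: int | tuple[int, int] = 64,
) -> TopoMap:
    """Piecewise-linear interpolation of channel values onto a grid.

    Parameters
    ----------
    values : mapping channel id -> value, or array aligned with
        ``layout.channel_ids``. One finite value per channel is required.
    resolution : int or (nx, ny)
        Grid cells per axis over the layout bounding box.

    Raises
    ------
    ValueError
        On non-finite values (names the channels) or a degenerate
        (collinear) layout.
    """
    if isinstance(values, Mapping):
        try:
            vals = np.array([float(values[int(c)]) for c in layout.channel_ids])
        except KeyError as exc:
            raise ValueError(f"missing value for channel {exc.args[0]}") from None
    else:
        vals = np.asarray(values, dtype=float)
        if vals.shape != (layout.n_channels,):
            raise ValueError(
                f"values must have one entry per channel ({layout.n_channels}), got {vals.shape}"
            )
    bad = layout.channel_ids[~np.isfinite(vals)]
    if bad.size:
        raise ValueError(f"non-finite value(s) for channel(s) {bad.tolist()}")
    nx, ny = (resolution, resolution) if isinstance(resolution, int) else resolution
    xmin, xmax, ymin, ymax = layout.bounding_box
    x = np.linspace(xmin, xmax, nx)
    y = np.linspace(ymin, ymax, ny)
    xx, yy = np.meshgrid(x, y)
    try:
        interp = LinearNDInterpolator(layout.positions, vals)
    except QhullError as exc:
        raise ValueError("degenerate (collinear) channel layout") from exc
    grid = interp(np.column_stack([xx.ravel(), yy.ravel()])).reshape(ny, nx)
    mask = np.isfinite(grid)
    return TopoMap(
        x=x,
        y=y,
        grid=grid,
        mask=mask,
        positions=layout.positions.copy(),
        values=vals,
        channel_ids=layout.channel_ids.copy(),
    )


def plot_topomap(
    tm: TopoMap,
    path: str | Path,
    title: str = "",
    unit: str = "",
    cmap: str = "turbo",
) -> Path:
    """Render an interpolated map with the channel overlay to a PNG file."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 4.2))
    extent = (tm.x[0], tm.x[-1], tm.y[0], tm.y[-1])
    im = ax.imshow(tm.grid, origin="lower", extent=extent, cmap=cmap, aspect="equal")
    ax.scatter(
        tm.positions[:, 0],
        tm.positions[:, 1],
        s=22,
        facecolors="none",
        edgecolors="gray",
        linewidths=0.9,
    )
    cbar = fig.colorbar(im, ax=ax, shrink=0.85)
    if unit:
        cbar.set_label(unit)
    ax.set_xlabel("x (cm)")
    ax.set_ylabel("y (cm)")
    if title:
        ax.set_title(title)
    path = Path(path)
    fig.tight_layout()
    fig.savefig(path, dpi=110)
    plt.close(fig)
    return path
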