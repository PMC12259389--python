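"""Spatial summaries of verified detections across a recorder array.

Call counts per recorder are standardized by the hours of audio analyzed at
that location, then interpolated over the array with inverse distance
weighting (IDW): the value at a grid cell is the weighted mean of the sample
rates with weights d^(-power). IDW is exact at the sample points and can
never overshoot the data range, which makes it a conservative way to draw a
calling-density surface over a PAM grid. Coordinates are assumed planar
(projected meters); geographic projection is the caller's job.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist

__all__ = ["AruLocation", "DensityGrid", "standardize_rates", "idw_interpolate", "read_locations_csv", "write_grid_csv"]


@dataclass
class AruLocation:
    id: str
    x: float
    y: float
    hours_analyzed: float

    def __post_init__(self) -> None:
        if self.hours_analyzed <= 0:
            raise ValueError("hours_analyzed must be positive")


@dataclass
class DensityGrid:
    xs: np.ndarray  # cell-center x coordinates (meters)
    ys: np.ndarray
    values: np.ndarray  # (len(ys), len(xs)) call rate per hour
    power: float


def standardize_rates(events, locations) -> dict:
    """Calls per hour per recorder: event count / hours analyzed.

    ``events`` may be detection events (with ``source_id``) or a mapping
    id -> count. Every event source must be a known location; locations with
    no events get rate 0.
    """
    locs = {loc.id: loc for loc in locations}
    if len(locs) != len(list(locations)):
        raise ValueError("location ids must be unique")
    counts = dict.fromkeys(locs, 0)
    if isinstance(events, dict):
        for sid, n in events.items():
            if sid not in locs:
                raise ValueError(f"unknown source id {sid!r}")
            counts[sid] = int(n)
    else:
        for ev in events:
            sid = ev.source_id
            if sid not in locs:
                raise ValueError(f"unknown source id {sid!r}")
            counts[sid] += 1
    return {sid: counts[sid] / locs[sid].hours_analyzed for sid in locs}


def idw_interpolate(
    points,
    grid_shape: tuple | None = None,
    power: float = 2.0,
    bounds: tuple | None = None,
) -> DensityGrid:
    """Inverse-distance-weighted surface over a rectangular grid.

    ``points`` is a sequence of (x, y, rate). Every point contributes to
    every cell with weight d^(-power); a cell coincident with a point takes
    that point's exact value. ``bounds`` is (xmin, xmax, ymin, ymax),
    defaulting to the point extent; the default resolution is 50 cells along
    the larger extent.
    """
    pts = np.asarray([(x, y) for x, y, _ in points], dtype=float)
    vals = np.asarray([r for _, _, r in points], dtype=float)
    if len(pts) == 0:
        raise ValueError("need at least one point")
    if power <= 0:
        raise ValueError("power must be positive")
    if bounds is None:
        xmin, xmax = pts[:, 0].min(), pts[:, 0].max()
        ymin, ymax = pts[:, 1].min(), pts[:, 1].max()
    else:
        xmin, xmax, ymin, ymax = bounds
    if grid_shape is None:
        extent = max(xmax - xmin, ymax - ymin, 1e-9)
        cell = extent / 50.0
        nx = max(int(round((xmax - xmin) / cell)) + 1, 2)
        ny = max(int(round((ymax - ymin) / cell)) + 1, 2)
    else:
        ny, nx = grid_shape
    xs = np.linspace(xmin, xmax, nx)
    ys = np.linspace(ymin, ymax, ny)
    gx, gy = np.meshgrid(xs, ys)
    cells = np.column_stack([gx.ravel(), gy.ravel()])
    d = cdist(cells, pts)
    exact = d < 1e-9
    with np.errstate(divide="ignore"):
        w = d ** (-power)
    out = np.empty(len(cells))
    has_exact = exact.any(axis=1)
    out[has_exact] = vals[exact.argmax(axis=1)[has_exact]]
    rest = ~has_exact
    out[rest] = (w[rest] @ vals) / w[rest].sum(axis=1)
    return DensityGrid(xs=xs, ys=ys, values=out.reshape(ny, nx), power=power)


def read_locations_csv(path) -> list:
    """Locations CSV with columns id, x, y, hours."""
    df = pd.read_csv(path)
    required = {"id", "x", "y", "hours"}
    if not required.issubset(df.columns):
        raise ValueError(f"locations CSV needs columns {sorted(required)}, found {list(df.columns)}")
    return [
        AruLocation(str(r["id"]), float(r["x"]), float(r["y"]), float(r["hours"]))
        for _, r in df.iterrows()
    ]


def write_grid_csv(grid: DensityGrid, path) -> None:
    """Grid as long-form CSV (x, y, value)."""
    gx, gy = np.meshgrid(grid.xs, grid.ys)
    pd.DataFrame(
        {"x": gx.ravel(), "y": gy.ravel(), "value": grid.values.ravel()}
    ).to_csv(path, index=False)


def plot_grid(grid: DensityGrid, path) -> None:
    """Optional heat-map rendering of the interpolated surface."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 5))
    im = ax.pcolormesh(grid.xs, grid.ys, grid.values, shading="auto", cmap="magma")
    fig.colorbar(im, ax=ax, label="calls per hour")
    ax.set_xlabel("x (m)")
    ax.set_ylabel("y (m)")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
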