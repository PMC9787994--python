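"""Structural habitat metrics from height-normalized LiDAR data.

Six stand-level metrics describe canopy structure: top canopy height,
gap fraction, horizontal heterogeneity (Moran's I), vertical evenness
(Pielou's J of the plant-area profile), shrub density, and canopy
density.  The first three are computed from a canopy height model (CHM)
at several raster resolutions; the last three from a vertical plant-area
density (PAD) profile estimated with the MacArthur-Horn attenuation
method on 10-m columns with 1-m height bins.

Heights are meters above ground, areas hectares.  Grids are 2-D arrays
with origin at the upper-left corner and ``nan`` as the missing-value
sentinel.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage

__all__ = [
    "CanopyGrid",
    "PADProfile",
    "rasterize_chm",
    "aggregate_chm",
    "estimate_pad_profile",
    "top_canopy_height",
    "gap_fraction",
    "morans_i",
    "vertical_evenness",
    "shrub_density",
    "canopy_density",
    "clip_to_compartment",
    "compute_structural_metrics",
    "CHM_METRICS",
    "PROFILE_METRICS",
]

#: metrics computed from the CHM, one value per raster resolution
CHM_METRICS = ("top_canopy_height", "gap_fraction", "horizontal_heterogeneity")
#: metrics computed from the 10-m PAD profile (single resolution)
PROFILE_METRICS = ("vertical_evenness", "shrub_density", "canopy_density")


@dataclass
class CanopyGrid:
    """Canopy height raster.

    Attributes
    ----------
    resolution : float
        Cell size in meters.
    origin : tuple of float
        Map coordinates ``(x, y)`` of the upper-left corner.
    cells : ndarray
        2-D float array of canopy heights (m); ``nan`` marks missing.
    """

    resolution: float
    origin: tuple[float, float]
    cells: np.ndarray

    def __post_init__(self) -> None:
        self.cells = np.asarray(self.cells, dtype=float)
        if self.resolution <= 0:
            raise ValueError("resolution must be positive")
        with np.errstate(invalid="ignore"):
            if np.any(self.cells < 0):
                raise ValueError("canopy heights must be >= 0 or missing")

    @property
    def shape(self) -> tuple[int, int]:
        return self.cells.shape

    def cell_centers(self) -> tuple[np.ndarray, np.ndarray]:
        """Return x and y coordinates of every cell center (2-D arrays)."""
        ny, nx = self.cells.shape
        x0, y0 = self.origin
        xs = x0 + (np.arange(nx) + 0.5) * self.resolution
        ys = y0 - (np.arange(ny) + 0.5) * self.resolution
        return np.meshgrid(xs, ys)

    def area_ha(self) -> float:
        """Area covered by non-missing cells, hectares."""
        n = int(np.sum(~np.isnan(self.cells)))
        return n * self.resolution**2 / 1e4


@dataclass
class PADProfile:
    """Vertical plant-area density profile on 10-m columns.

    ``pad`` has one row per column and one entry per 1-m height bin,
    in relative units per meter; ``column_xy`` holds column centers.
    Columns flagged in ``missing`` had no returns.
    """

    column_xy: np.ndarray
    bin_edges: np.ndarray
    pad: np.ndarray
    missing: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.column_xy = np.atleast_2d(np.asarray(self.column_xy, dtype=float))
        self.bin_edges = np.asarray(self.bin_edges, dtype=float)
        self.pad = np.atleast_2d(np.asarray(self.pad, dtype=float))
        if np.any(np.diff(self.bin_edges) <= 0):
            raise ValueError("bin edges must be strictly increasing")
        if np.any(self.pad < 0):
            raise ValueError("PAD values must be >= 0")
        if self.missing is None:
            self.missing = np.zeros(self.pad.shape[0], dtype=bool)

    @property
    def n_columns(self) -> int:
        return self.pad.shape[0]

    def mean_profile(self) -> np.ndarray:
        """Mean PAD of each vertical segment across non-missing columns."""
        valid = self.pad[~self.missing]
        if valid.size == 0:
            return np.zeros(self.pad.shape[1])
        return valid.mean(axis=0)


# ---------------------------------------------------------------------------
# CHM construction and aggregation
# ---------------------------------------------------------------------------

def rasterize_chm(points, footprint, resolution: float = 0.5) -> CanopyGrid:
    """Rasterize height-normalized returns into a canopy height model.

    Each cell takes the maximum return height falling in it.  Cells with
    no returns are filled with the nearest populated cell's value within
    a 3-cell radius, and with 0 beyond that.

    Parameters
    ----------
    points : ndarray (n, 3)
        Columns x, y, height with ground at ~0.
    footprint : tuple
        Bounds ``(xmin, ymin, xmax, ymax)`` or a shapely polygon.
    """
    xmin, ymin, xmax, ymax = _bounds(footprint)
    nx = max(int(np.ceil((xmax - xmin) / resolution)), 1)
    ny = max(int(np.ceil((ymax - ymin) / resolution)), 1)
    cells = np.full((ny, nx), -1.0)

    pts = np.asarray(points, dtype=float).reshape(-1, 3)
    if pts.size:
        ix = np.floor((pts[:, 0] - xmin) / resolution).astype(int)
        iy = np.floor((ymax - pts[:, 1]) / resolution).astype(int)
        ok = (ix >= 0) & (ix < nx) & (iy >= 0) & (iy < ny)
        np.maximum.at(cells, (iy[ok], ix[ok]), pts[ok, 2])
        n_in = int(ok.sum())
    else:
        n_in = 0

    empty = cells < 0
    if n_in == 0:
        warnings.warn("no points in footprint; returning all-zero CHM")
        cells[:] = 0.0
    elif empty.any():
        # nearest populated cell, limited to a 3-cell radius
        dist, (ii, jj) = ndimage.distance_transform_edt(
            empty, return_indices=True
        )
        fill = cells[ii, jj]
        fill[dist > 3.0] = 0.0
        cells[empty] = fill[empty]
    return CanopyGrid(resolution=resolution, origin=(xmin, ymax), cells=cells)


def aggregate_chm(grid: CanopyGrid, target_resolution: float) -> CanopyGrid:
    """Aggregate a CHM to a coarser resolution by block means.

    Each coarse cell is the mean of its constituent fine cells, ignoring
    missing values.  The target must be an integer multiple of the
    source resolution.
    """
    ratio = target_resolution / grid.resolution
    if target_resolution < grid.resolution or abs(ratio - round(ratio)) > 1e-9:
        raise ValueError(
            f"target resolution {target_resolution} is not an integral "
            f"multiple of source resolution {grid.resolution}"
        )
    r = int(round(ratio))
    if r == 1:
        return replace(grid, cells=grid.cells.copy())
    ny, nx = grid.cells.shape
    py, px = (-ny) % r, (-nx) % r
    padded = np.pad(
        grid.cells, ((0, py), (0, px)), constant_values=np.nan
    )
    blocks = padded.reshape(padded.shape[0] // r, r, padded.shape[1] // r, r)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-nan blocks
        coarse = np.nanmean(blocks, axis=(1, 3))
    return CanopyGrid(
        resolution=target_resolution, origin=grid.origin, cells=coarse
    )


# ---------------------------------------------------------------------------
# MacArthur-Horn plant-area profile
# ---------------------------------------------------------------------------

def estimate_pad_profile(
    points,
    footprint,
    column_resolution: float = 10.0,
    bin_width: float = 1.0,
    k: float = 1.0,
) -> PADProfile:
    """Estimate vertical plant-area density by return attenuation.

    For each column, with ``N(z)`` the number of returns at height <= z,
    the plant-area density of bin [z, z + dz) is

        PAD = ln( N(z + dz) / max(N(z), 1) ) / (k * dz)

    i.e. the log-ratio of cumulative returns across the bin, scaled by
    the extinction coefficient ``k``.  Bins above the highest return are
    0.  Columns without returns are flagged missing.
    """
    xmin, ymin, xmax, ymax = _bounds(footprint)
    nx = max(int(np.ceil((xmax - xmin) / column_resolution)), 1)
    ny = max(int(np.ceil((ymax - ymin) / column_resolution)), 1)
    pts = np.asarray(points, dtype=float).reshape(-1, 3)

    zmax = float(pts[:, 2].max()) if pts.size else 0.0
    n_bins = max(int(np.ceil(zmax / bin_width)), 1)
    edges = np.arange(n_bins + 1) * bin_width

    xs = xmin + (np.arange(nx) + 0.5) * column_resolution
    ys = ymax - (np.arange(ny) + 0.5) * column_resolution
    gx, gy = np.meshgrid(xs, ys)
    column_xy = np.column_stack([gx.ravel(), gy.ravel()])

    pad = np.zeros((nx * ny, n_bins))
    missing = np.ones(nx * ny, dtype=bool)
    if pts.size:
        ix = np.floor((pts[:, 0] - xmin) / column_resolution).astype(int)
        iy = np.floor((ymax - pts[:, 1]) / column_resolution).astype(int)
        ok = (ix >= 0) & (ix < nx) & (iy >= 0) & (iy < ny)
        col = iy[ok] * nx + ix[ok]
        z = pts[ok, 2]
        for c in np.unique(col):
            zc = z[col == c]
            # cumulative returns at or below each bin edge
            n_below = np.searchsorted(np.sort(zc), edges, side="right")
            ratio = n_below[1:] / np.maximum(n_below[:-1], 1)
            with np.errstate(divide="ignore"):
                vals = np.log(np.maximum(ratio, 1.0)) / (k * bin_width)
            pad[c] = vals
            missing[c] = False
    return PADProfile(
        column_xy=column_xy, bin_edges=edges, pad=pad, missing=missing
    )


# ---------------------------------------------------------------------------
# The six structural metrics
# ---------------------------------------------------------------------------

def top_canopy_height(grid: CanopyGrid) -> float:
    """Mean cell height (m) over non-missing cells."""
    cells = grid.cells
    if np.all(np.isnan(cells)):
        raise ValueError("top_canopy_height undefined: all cells missing")
    return float(np.nanmean(cells))


def gap_fraction(grid: CanopyGrid) -> float:
    """Proportion of cells strictly below 2/3 of the mean canopy height.

    For an all-zero grid the threshold is 0 and the strict inequality
    yields 0 (no gaps), by convention.
    """
    cells = grid.cells
    valid = cells[~np.isnan(cells)]
    if valid.size == 0:
        raise ValueError("gap_fraction undefined: all cells missing")
    threshold = (2.0 / 3.0) * valid.mean()
    return float(np.mean(valid < threshold))


def morans_i(grid: CanopyGrid | np.ndarray) -> float:
    """Moran's I spatial autocorrelation with binary rook contiguity.

        I = (n / W) * sum_ij w_ij (x_i - m)(x_j - m) / sum_i (x_i - m)^2

    where w_ij = 1 for horizontally or vertically adjacent cell pairs and
    W is the number of ordered neighbor pairs.  Pairs involving missing
    cells are excluded.  Returns ``nan`` when fewer than two cells are
    present or the variance is zero.
    """
    cells = grid.cells if isinstance(grid, CanopyGrid) else np.asarray(grid, float)
    valid = ~np.isnan(cells)
    n = int(valid.sum())
    if n < 2:
        return float("nan")
    mean = np.nanmean(cells)
    dev = np.where(valid, cells - mean, 0.0)
    ss = float(np.sum(dev[valid] ** 2))
    if ss == 0.0:
        return float("nan")
    # unordered neighbor products, then doubled for the symmetric sum
    cross = w = 0.0
    for a, b, va, vb in (
        (dev[:, :-1], dev[:, 1:], valid[:, :-1], valid[:, 1:]),
        (dev[:-1, :], dev[1:, :], valid[:-1, :], valid[1:, :]),
    ):
        pair = va & vb
        cross += float(np.sum(a[pair] * b[pair]))
        w += float(pair.sum())
    if w == 0:
        return float("nan")
    return (n / (2 * w)) * (2 * cross) / ss


def vertical_evenness(profile: PADProfile | np.ndarray) -> float:
    """Pielou's evenness of the plant-area profile.

    Shannon entropy of the PAD proportions divided by ln(m), with m the
    number of 1-m segments from the ground up to the highest vegetated
    segment (zero segments within the canopy count toward m but add no
    entropy).  Undefined (``nan``) for an empty profile or m < 2.
    """
    pad = _as_mean_profile(profile)
    nz = np.nonzero(pad > 0)[0]
    if nz.size == 0:
        return float("nan")
    m = int(nz[-1]) + 1
    if m < 2:
        return float("nan")
    p = pad[:m] / pad[:m].sum()
    p = p[p > 0]
    h = -float(np.sum(p * np.log(p)))
    return h / np.log(m)


def shrub_density(profile: PADProfile | np.ndarray) -> float:
    """Sum of PAD over the shrub layer: bins [1,2), [2,3), [3,4), [4,5) m."""
    pad = _as_mean_profile(profile)
    return float(pad[1:5].sum())


def canopy_density(profile: PADProfile | np.ndarray, grid: CanopyGrid) -> float:
    """Sum of PAD over segments entirely within the top third of the canopy.

    The canopy top is the mean CHM height plus two standard deviations
    (accounting for within-stand variability); a segment [a, b) counts
    when a >= (2/3)*top and b <= top.
    """
    pad = _as_mean_profile(profile)
    cells = grid.cells[~np.isnan(grid.cells)]
    top = float(cells.mean() + 2 * cells.std(ddof=1)) if cells.size > 1 else float(cells.mean())
    if top <= 0:
        warnings.warn("canopy top <= 0; canopy density set to 0")
        return 0.0
    lower = np.arange(pad.size)
    upper = lower + 1.0
    inside = (lower >= (2.0 / 3.0) * top - 1e-9) & (upper <= top + 1e-9)
    return float(pad[inside].sum())


# ---------------------------------------------------------------------------
# Clipping
# ---------------------------------------------------------------------------

def clip_to_compartment(obj, polygon):
    """Clip a grid, point array, or PAD profile to a compartment polygon.

    Keeps cells / points / columns whose centers fall inside the
    polygon.  Returns ``(clipped, area_ha)`` where the area is that of
    the retained cells (grids) or the polygon (points, profiles).
    """
    import shapely

    poly = shapely.geometry.shape(polygon) if isinstance(polygon, dict) else polygon
    if not poly.is_valid:
        raise ValueError("invalid polygon")
    if isinstance(obj, CanopyGrid):
        gx, gy = obj.cell_centers()
        inside = shapely.contains_xy(poly, gx.ravel(), gy.ravel()).reshape(gx.shape)
        cells = np.where(inside, obj.cells, np.nan)
        if not inside.any():
            warnings.warn("polygon does not intersect grid; empty result")
        clipped = replace(obj, cells=cells)
        return clipped, clipped.area_ha()
    if isinstance(obj, PADProfile):
        inside = shapely.contains_xy(
            poly, obj.column_xy[:, 0], obj.column_xy[:, 1]
        )
        if not inside.any():
            warnings.warn("polygon contains no profile columns; empty result")
        clipped = PADProfile(
            column_xy=obj.column_xy[inside],
            bin_edges=obj.bin_edges,
            pad=obj.pad[inside],
            missing=obj.missing[inside],
        )
        return clipped, poly.area / 1e4
    pts = np.asarray(obj, dtype=float).reshape(-1, 3)
    inside = shapely.contains_xy(poly, pts[:, 0], pts[:, 1])
    if pts.size and not inside.any():
        warnings.warn("polygon contains no points; empty result")
    return pts[inside], poly.area / 1e4


# ---------------------------------------------------------------------------
# Convenience: all metrics for one compartment
# ---------------------------------------------------------------------------

def compute_structural_metrics(
    grid: CanopyGrid,
    profile: PADProfile,
    resolutions=(0.5, 2.0, 5.0, 10.0),
) -> dict[str, float]:
    """All six metrics for one compartment.

    CHM metrics are computed at every requested resolution (suffix
    ``_<res>m``); profile metrics once.  The canopy-density height
    window uses the native-resolution grid.
    """
    out: dict[str, float] = {}
    for res in resolutions:
        g = aggregate_chm(grid, res) if res != grid.resolution else grid
        tag = _res_tag(res)
        out[f"top_canopy_height_{tag}"] = top_canopy_height(g)
        out[f"gap_fraction_{tag}"] = gap_fraction(g)
        out[f"horizontal_heterogeneity_{tag}"] = morans_i(g)
    mean_pad = profile.mean_profile()
    out["vertical_evenness"] = vertical_evenness(mean_pad)
    out["shrub_density"] = shrub_density(mean_pad)
    out["canopy_density"] = canopy_density(mean_pad, grid)
    return out


def _res_tag(res: float) -> str:
    return f"{res:g}m".replace(".", "p")


def _as_mean_profile(profile) -> np.ndarray:
    if isinstance(profile, PADProfile):
        return profile.mean_profile()
    return np.asarray(profile, dtype=float).ravel()


def _bounds(footprint) -> tuple[float, float, float, float]:
    if hasattr(footprint, "bounds"):
        return footprint.bounds
    xmin, ymin, xmax, ymax = footprint
    return float(xmin), float(ymin), float(xmax), float(ymax)
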