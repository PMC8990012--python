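"""Layered grid maps for lost-person simulation.

A search map is a square grid of cells carrying three co-registered layers:

* ``elevation`` -- meters above sea level,
* ``linear_features`` -- boolean mask of followable one-dimensional elements
  (trails, roads, railroads, powerline easements, stream lines, shorelines,
  and elevation-derived ridge/drainage lines),
* ``inaccessible`` -- boolean mask of cells the agent may never occupy
  (lake and river interiors).

The reference configuration is a 20 km x 20 km region discretized into
3000 x 3000 cells of 6.67 m x 6.67 m.  Positions use (x=column, y=row)
order with x increasing east and y increasing north; indexing is 0-based,
and raster arrays are indexed ``raster[y, x]``.

Besides readers for real layers (single-band GeoTIFF or plain text arrays,
GeoJSON vectors), the module provides a seeded synthetic-map generator that
emulates the same structure -- smooth relief, trail networks, lakes -- for
testing and scaled-down studies.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import shapely
from scipy import ndimage
from shapely.geometry import Polygon, shape as shapely_shape
from skimage.draw import line as bresenham_line
from skimage.feature import canny

#: Default map geometry: 20 km extent over 3000 cells -> 6.67 m cells.
MAP_EXTENT_M = 20000.0
DEFAULT_GRID_CELLS = 3000
DEFAULT_CELL_SIZE = MAP_EXTENT_M / DEFAULT_GRID_CELLS


@dataclass
class GridMap:
    """Co-registered raster layers describing one search map.

    Parameters
    ----------
    elevation : (R, C) float array, meters above sea level.
    linear_features : (R, C) bool array.
    inaccessible : (R, C) bool array; disjoint from ``linear_features``
        (a shoreline cell is a feature, an interior cell is inaccessible,
        never both).
    cell_size : meters per cell side.
    transform : optional (origin_x, origin_y) of the cell (0, 0) center in
        world coordinates, for maps derived from georeferenced data.
    crs : optional coordinate-reference-system tag (carried, never used).
    """

    elevation: np.ndarray
    linear_features: np.ndarray
    inaccessible: np.ndarray
    cell_size: float = DEFAULT_CELL_SIZE
    transform: Optional[tuple[float, float]] = None
    crs: Optional[str] = None

    def __post_init__(self) -> None:
        self.elevation = np.asarray(self.elevation, dtype=float)
        self.linear_features = np.asarray(self.linear_features, dtype=bool)
        self.inaccessible = np.asarray(self.inaccessible, dtype=bool)
        if not (
            self.elevation.shape
            == self.linear_features.shape
            == self.inaccessible.shape
        ):
            raise ValueError(
                "layer shape mismatch: elevation %s, linear_features %s, "
                "inaccessible %s"
                % (
                    self.elevation.shape,
                    self.linear_features.shape,
                    self.inaccessible.shape,
                )
            )
        if self.elevation.ndim != 2:
            raise ValueError("layers must be 2-D rasters")
        if self.cell_size <= 0:
            raise ValueError("cell_size must be positive")
        overlap = self.linear_features & self.inaccessible
        if overlap.any():
            ys, xs = np.nonzero(overlap)
            raise ValueError(
                "linear_features and inaccessible overlap at %d cells, "
                "first (x=%d, y=%d); resolve with assemble_map"
                % (len(xs), xs[0], ys[0])
            )

    @property
    def rows(self) -> int:
        return self.elevation.shape[0]

    @property
    def cols(self) -> int:
        return self.elevation.shape[1]

    @property
    def center(self) -> tuple[int, int]:
        """Central cell (x, y); IPP placement for paper-style maps."""
        return (self.cols // 2, self.rows // 2)

    def in_bounds(self, x: int, y: int) -> bool:
        return 0 <= x < self.cols and 0 <= y < self.rows

    def accessible(self, x: int, y: int) -> bool:
        return self.in_bounds(x, y) and not self.inaccessible[y, x]

    def world_to_cell(self, wx: float, wy: float) -> tuple[int, int]:
        """Map world coordinates to the nearest cell using the transform."""
        if self.transform is None:
            raise ValueError("GridMap has no geo-transform")
        ox, oy = self.transform
        return (
            int(np.floor((wx - ox) / self.cell_size + 0.5)),
            int(np.floor((wy - oy) / self.cell_size + 0.5)),
        )


# ---------------------------------------------------------------------------
# Elevation-derived linear features
# ---------------------------------------------------------------------------

def gradient_magnitude(elevation: np.ndarray, sigma: float = 3.0) -> np.ndarray:
    """Smoothed magnitude of the elevation gradient.

    The two gradient components are the responses of derivative-of-Gaussian
    filters at scale ``sigma`` (in cells); their Euclidean norm is then
    smoothed with a Gaussian of the same scale.  Ridge crests and drainage
    lines appear as extrema of this field.

    Raises
    ------
    ValueError
        If ``sigma <= 0`` or elevation contains non-finite values (the first
        offending cells are named).
    """
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    elevation = np.asarray(elevation, dtype=float)
    bad = ~np.isfinite(elevation)
    if bad.any():
        ys, xs = np.nonzero(bad)
        cells = ", ".join(f"(x={x}, y={y})" for x, y in list(zip(xs, ys))[:5])
        raise ValueError(
            f"elevation contains {bad.sum()} non-finite cells, first: {cells}"
        )
    gx = ndimage.gaussian_filter(elevation, sigma, order=(0, 1))
    gy = ndimage.gaussian_filter(elevation, sigma, order=(1, 0))
    return ndimage.gaussian_filter(np.hypot(gx, gy), sigma)


def detect_elevation_linear_features(
    gradient_mag: np.ndarray,
    canny_sigma: float = 3.0,
    low_quantile: float = 0.70,
    high_quantile: float = 0.90,
) -> np.ndarray:
    """Extract ridge/drainage lines as Canny edges of the gradient magnitude.

    Hysteresis thresholds default to quantiles of the magnitude field so the
    detector adapts to relief scale.  A degenerate (constant) field yields an
    empty mask.
    """
    if not 0 <= low_quantile < high_quantile <= 1:
        raise ValueError("thresholds must satisfy 0 <= low < high <= 1")
    gradient_mag = np.asarray(gradient_mag, dtype=float)
    if np.ptp(gradient_mag) == 0:
        return np.zeros(gradient_mag.shape, dtype=bool)
    return canny(
        gradient_mag,
        sigma=canny_sigma,
        low_threshold=low_quantile,
        high_threshold=high_quantile,
        use_quantiles=True,
    )


# ---------------------------------------------------------------------------
# Vector layers
# ---------------------------------------------------------------------------

def rasterize_polylines(
    polylines: Sequence[Sequence[tuple[float, float]]],
    shape: tuple[int, int],
) -> np.ndarray:
    """Burn polylines (vertices in cell coordinates, (x, y)) into a mask.

    Each segment is walked with Bresenham's algorithm, giving an 8-connected
    chain of cells; vertices are rounded to the nearest cell and clipped to
    the map extent.  The result is independent of traversal direction and
    idempotent.
    """
    rows, cols = shape
    mask = np.zeros(shape, dtype=bool)
    for poly in polylines:
        verts = [
            (
                int(np.clip(np.floor(x + 0.5), 0, cols - 1)),
                int(np.clip(np.floor(y + 0.5), 0, rows - 1)),
            )
            for x, y in poly
        ]
        if len(verts) == 1:
            x, y = verts[0]
            mask[y, x] = True
        for a, b in zip(verts[:-1], verts[1:]):
            # canonical endpoint order: Bresenham is asymmetric, drawing
            # from the lexicographically smaller endpoint makes the mask
            # independent of traversal direction
            (x0, y0), (x1, y1) = sorted((a, b))
            rr, cc = bresenham_line(y0, x0, y1, x1)
            mask[rr, cc] = True
    return mask


def build_water_layers(
    water_polygons: Sequence,
    shape: tuple[int, int],
) -> tuple[np.ndarray, np.ndarray]:
    """Split water bodies into inaccessible interiors and shoreline features.

    Polygons may be shapely ``Polygon`` objects or exterior-ring coordinate
    sequences, in cell coordinates.  A cell belongs to a water body when its
    center intersects the polygon.  The one-cell-wide outline of each body is
    the shoreline (to be OR-ed into linear features); the eroded remainder is
    the inaccessible interior.  The two outputs are disjoint; a body smaller
    than ~3x3 cells has a shoreline but no interior.
    """
    rows, cols = shape
    water = np.zeros(shape, dtype=bool)
    for poly in water_polygons:
        if not isinstance(poly, Polygon):
            poly = Polygon(poly)
        if not poly.is_valid:
            raise ValueError("water polygon is not simple (self-intersecting)")
        x0, y0, x1, y1 = poly.bounds
        xs = np.arange(max(0, int(np.floor(x0))), min(cols, int(np.ceil(x1)) + 1))
        ys = np.arange(max(0, int(np.floor(y0))), min(rows, int(np.ceil(y1)) + 1))
        if len(xs) == 0 or len(ys) == 0:
            continue
        gx, gy = np.meshgrid(xs, ys)
        hit = shapely.intersects_xy(poly, gx.ravel(), gy.ravel()).reshape(gx.shape)
        water[ys[0] : ys[-1] + 1, xs[0] : xs[-1] + 1] |= hit
    interior = ndimage.binary_erosion(water, structure=np.ones((3, 3), dtype=bool))
    shoreline = water & ~interior
    return interior, shoreline


# ---------------------------------------------------------------------------
# Assembly
# ---------------------------------------------------------------------------

def assemble_map(
    elevation: np.ndarray,
    feature_masks: Sequence[np.ndarray] = (),
    inaccessible_masks: Sequence[np.ndarray] = (),
    cell_size: float = DEFAULT_CELL_SIZE,
    transform: Optional[tuple[float, float]] = None,
    crs: Optional[str] = None,
) -> GridMap:
    """Combine co-registered layers into a :class:`GridMap`.

    Feature masks are OR-ed together, as are inaccessible masks; where the two
    overlap (e.g. a stream line crossing a lake interior) the cell is resolved
    as inaccessible, preserving the disjointness invariant.
    """
    elevation = np.asarray(elevation, dtype=float)
    features = np.zeros(elevation.shape, dtype=bool)
    for m in feature_masks:
        m = np.asarray(m, dtype=bool)
        if m.shape != elevation.shape:
            raise ValueError(
                f"feature mask shape {m.shape} != elevation shape {elevation.shape}"
            )
        features |= m
    inaccessible = np.zeros(elevation.shape, dtype=bool)
    for m in inaccessible_masks:
        m = np.asarray(m, dtype=bool)
        if m.shape != elevation.shape:
            raise ValueError(
                f"inaccessible mask shape {m.shape} != elevation shape "
                f"{elevation.shape}"
            )
        inaccessible |= m
    features &= ~inaccessible
    return GridMap(elevation, features, inaccessible, cell_size, transform, crs)


# ---------------------------------------------------------------------------
# Synthetic maps
# ---------------------------------------------------------------------------

@dataclass
class SyntheticMapConfig:
    """Recipe for a reproducible synthetic search map.

    Relief is a sum of random Gaussian hills, trails are jittered polylines
    crossing the map, and lakes are circular blobs kept away from the central
    cell so the standard IPP stays accessible.  The same seed always yields
    the bit-identical map.
    """

    rows: int = 300
    cols: int = 300
    cell_size: float = DEFAULT_CELL_SIZE
    n_bumps: int = 12
    bump_amplitude_m: float = 60.0
    bump_width_cells: float = 40.0
    n_trails: int = 3
    trail_waypoints: int = 6
    n_lakes: int = 2
    lake_radius_cells: float = 12.0
    elevation_features: bool = True
    feature_sigma: float = 3.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_bumps", "n_trails", "n_lakes"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.rows < 3 or self.cols < 3:
            raise ValueError("grid must be at least 3x3")


def generate_synthetic_map(config: SyntheticMapConfig) -> GridMap:
    """Generate a seeded synthetic :class:`GridMap` from ``config``."""
    rng = np.random.default_rng(config.seed)
    rows, cols = config.rows, config.cols

    ys, xs = np.mgrid[0:rows, 0:cols]
    elevation = np.zeros((rows, cols), dtype=float)
    for _ in range(config.n_bumps):
        cx = rng.uniform(0, cols - 1)
        cy = rng.uniform(0, rows - 1)
        amp = config.bump_amplitude_m * rng.uniform(0.3, 1.0)
        width = config.bump_width_cells * rng.uniform(0.5, 1.5)
        elevation += amp * np.exp(
            -((xs - cx) ** 2 + (ys - cy) ** 2) / (2.0 * width**2)
        )

    trails = []
    for _ in range(config.n_trails):
        # a jittered path from one map edge to the opposite one
        if rng.random() < 0.5:
            x_knots = np.linspace(0, cols - 1, config.trail_waypoints)
            y_knots = rng.uniform(0.1 * rows, 0.9 * rows, config.trail_waypoints)
        else:
            y_knots = np.linspace(0, rows - 1, config.trail_waypoints)
            x_knots = rng.uniform(0.1 * cols, 0.9 * cols, config.trail_waypoints)
        trails.append(list(zip(x_knots, y_knots)))
    trail_mask = rasterize_polylines(trails, (rows, cols))

    min_dim = min(rows, cols)
    lakes = []
    if config.n_lakes > 0:
        if min_dim < 4 * config.lake_radius_cells:
            raise ValueError(
                "grid too small to host requested lakes: min dimension "
                f"{min_dim} < 4 x lake radius {config.lake_radius_cells}"
            )
        cx0, cy0 = cols // 2, rows // 2
        keepout = config.lake_radius_cells + 5
        for _ in range(config.n_lakes):
            for _attempt in range(100):
                r = config.lake_radius_cells * rng.uniform(0.6, 1.0)
                lx = rng.uniform(r, cols - 1 - r)
                ly = rng.uniform(r, rows - 1 - r)
                if np.hypot(lx - cx0, ly - cy0) > keepout:
                    break
            lakes.append(shapely.Point(lx, ly).buffer(r, quad_segs=8))
    interior, shoreline = build_water_layers(lakes, (rows, cols))

    feature_masks = [trail_mask, shoreline]
    if config.elevation_features:
        grad = gradient_magnitude(elevation, sigma=config.feature_sigma)
        feature_masks.append(
            detect_elevation_linear_features(grad, canny_sigma=config.feature_sigma)
        )
    return assemble_map(
        elevation,
        feature_masks=feature_masks,
        inaccessible_masks=[interior],
        cell_size=config.cell_size,
    )


# ---------------------------------------------------------------------------
# I/O for real layers
# ---------------------------------------------------------------------------

def read_elevation(path: str) -> np.ndarray:
    """Read an elevation raster: single-band GeoTIFF or delimited text array."""
    path = str(path)
    if path.lower().endswith((".tif", ".tiff")):
        import tifffile

        arr = np.asarray(tifffile.imread(path), dtype=float)
        if arr.ndim == 3:
            arr = arr[..., 0]
        return arr
    return np.loadtxt(path, dtype=float)


def read_geojson_features(path: str) -> tuple[list, list]:
    """Read a GeoJSON file, returning (polylines, polygons).

    LineString/MultiLineString geometries become vertex lists (cell or world
    coordinates, as stored); Polygon/MultiPolygon geometries become shapely
    polygons (water bodies).
    """
    with open(path) as fh:
        doc = json.load(fh)
    feats = doc["features"] if doc.get("type") == "FeatureCollection" else [doc]
    lines: list = []
    polys: list = []
    for feat in feats:
        geom = shapely_shape(feat["geometry"] if "geometry" in feat else feat)
        if geom.geom_type == "LineString":
            lines.append(list(geom.coords))
        elif geom.geom_type == "MultiLineString":
            lines.extend(list(g.coords) for g in geom.geoms)
        elif geom.geom_type == "Polygon":
            polys.append(geom)
        elif geom.geom_type == "MultiPolygon":
            polys.extend(geom.geoms)
        else:
            raise ValueError(f"unsupported geometry type {geom.geom_type!r}")
    return lines, polys


def save_gridmap(grid: GridMap, path: str) -> None:
    """Persist a GridMap as a compressed array file."""
    np.savez_compressed(
        path,
        elevation=grid.elevation,
        linear_features=grid.linear_features,
        inaccessible=grid.inaccessible,
        cell_size=grid.cell_size,
        transform=np.asarray(grid.transform if grid.transform else [np.nan, np.nan]),
    )


def load_gridmap(path: str) -> GridMap:
    with np.load(path) as data:
        transform = data["transform"]
        return GridMap(
            data["elevation"],
            data["linear_features"],
            data["inaccessible"],
            float(data["cell_size"]),
            None if np.isnan(transform).any() else (transform[0], transform[1]),
        )
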