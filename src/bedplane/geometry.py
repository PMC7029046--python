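"""Planar observation windows.

A :class:`Window` is an outer polygon (in metres) minus a set of hole
polygons ("gaps" where nothing can be observed).  It provides area,
containment, uniform sampling and the *set covariance*

    C(s) = |W ∩ (W + s)|,

the denominator of the translation edge correction used by all
second-order summary statistics.  Rectangles use the closed form
``(a - |dx|) (b - |dy|)``; general polygons use the FFT autocorrelation
of a binary raster of the window (default 1024 x 1024 over the bounding
box), bilinearly interpolated at the requested shift.
"""

from __future__ import annotations

import json
from typing import Iterable, Sequence

import numpy as np
import shapely
import shapely.affinity
from scipy.ndimage import map_coordinates
from scipy.signal import fftconvolve
from shapely.geometry import Polygon, box, mapping, shape

__all__ = ["Window", "InvalidGeometryError"]


class InvalidGeometryError(ValueError):
    """Raised for self-intersecting or otherwise degenerate window geometry."""


def _as_polygon(obj) -> Polygon:
    if isinstance(obj, Polygon):
        return obj
    return Polygon(obj)


class Window:
    """Observation region: outer polygon minus disjoint interior holes.

    Parameters
    ----------
    outer:
        Shapely polygon or coordinate sequence for the outer boundary.
        If ``outer`` already carries interior rings they are taken as
        holes (and ``holes`` must then be empty).
    holes:
        Hole polygons, each strictly inside ``outer`` and pairwise
        disjoint.
    raster_size:
        Per-axis resolution of the raster used for polygon set
        covariance.

    Boundary convention: points on the outer boundary count as inside,
    points on a hole boundary count as outside.
    """

    def __init__(self, outer, holes: Iterable = (), raster_size: int = 1024):
        outer = _as_polygon(outer)
        holes = [_as_polygon(h) for h in holes]
        if list(outer.interiors):
            if holes:
                raise InvalidGeometryError(
                    "pass holes either as interior rings or separately, not both"
                )
            holes = [Polygon(ring) for ring in outer.interiors]
            outer = Polygon(outer.exterior)
        # normalise winding; accept either orientation on input
        outer = shapely.geometry.polygon.orient(outer, sign=1.0)
        holes = [shapely.geometry.polygon.orient(h, sign=1.0) for h in holes]
        if not outer.is_valid:
            raise InvalidGeometryError("outer polygon is invalid (self-intersecting?)")
        for h in holes:
            if not h.is_valid:
                raise InvalidGeometryError("hole polygon is invalid")
            if not outer.contains(h):
                raise InvalidGeometryError("hole not strictly inside outer polygon")
        for i, a in enumerate(holes):
            for b in holes[i + 1:]:
                if a.intersects(b):
                    raise InvalidGeometryError("holes overlap")
        self.outer = outer
        self.holes = holes
        self.polygon = Polygon(
            outer.exterior.coords, [h.exterior.coords for h in holes]
        )
        if self.polygon.area <= 0:
            raise InvalidGeometryError("window has zero area")
        self.raster_size = int(raster_size)
        self.kind = "rectangle" if self._is_rectangle() else "polygon"
        shapely.prepare(self.outer)
        self._prepared_holes = list(self.holes)
        for h in self._prepared_holes:
            shapely.prepare(h)
        self._cov_grid = None
        self._mask_cache = None

    # ------------------------------------------------------------------ #
    # constructors

    @classmethod
    def rectangle(cls, xmin: float, ymin: float, xmax: float, ymax: float,
                  raster_size: int = 1024) -> "Window":
        if not (xmax > xmin and ymax > ymin):
            raise InvalidGeometryError("rectangle must have positive extent")
        return cls(box(xmin, ymin, xmax, ymax), raster_size=raster_size)

    @classmethod
    def from_geojson(cls, obj, raster_size: int = 1024) -> "Window":
        """Build a window from a GeoJSON Polygon (dict, JSON string or path)."""
        if isinstance(obj, (str, bytes)):
            try:
                obj = json.loads(obj)
            except (ValueError, TypeError):
                with open(obj) as fh:
                    obj = json.load(fh)
        if obj.get("type") == "Feature":
            obj = obj["geometry"]
        geom = shape(obj)
        if not isinstance(geom, Polygon):
            raise InvalidGeometryError(f"expected GeoJSON Polygon, got {obj.get('type')}")
        return cls(geom, raster_size=raster_size)

    def to_geojson(self) -> dict:
        """GeoJSON Polygon: first ring outer, subsequent rings holes."""
        return mapping(self.polygon)

    # ------------------------------------------------------------------ #

    def _is_rectangle(self) -> bool:
        if self.holes:
            return False
        return self.outer.equals(box(*self.outer.bounds))

    @property
    def area(self) -> float:
        """Window area in m² (holes subtracted)."""
        return self.polygon.area

    @property
    def bounds(self) -> tuple[float, float, float, float]:
        return self.outer.bounds

    @property
    def side_lengths(self) -> tuple[float, float]:
        xmin, ymin, xmax, ymax = self.bounds
        return xmax - xmin, ymax - ymin

    def translate(self, dx: float, dy: float) -> "Window":
        poly = shapely.affinity.translate(self.polygon, dx, dy)
        return Window(poly, raster_size=self.raster_size)

    # ------------------------------------------------------------------ #
    # containment

    def contains_points(self, x, y=None) -> np.ndarray:
        """Vectorised containment with the documented boundary convention."""
        if y is None:
            xy = np.asarray(x, dtype=float)
            x, y = xy[..., 0], xy[..., 1]
        x = np.atleast_1d(np.asarray(x, dtype=float))
        y = np.atleast_1d(np.asarray(y, dtype=float))
        if self.kind == "rectangle":
            xmin, ymin, xmax, ymax = self.bounds
            return (x >= xmin) & (x <= xmax) & (y >= ymin) & (y <= ymax)
        pts = shapely.points(x, y)
        inside = shapely.covers(self.outer, pts)
        for h in self._prepared_holes:
            inside &= ~shapely.covers(h, pts)
        return inside

    def contains(self, point: Sequence[float]) -> bool:
        return bool(self.contains_points([point])[0])

    # ------------------------------------------------------------------ #
    # sampling

    def uniform_points(self, n: int, rng) -> np.ndarray:
        """``n`` i.i.d. uniform points inside the window, shape (n, 2).

        Rejection sampling from the bounding box.
        """
        n = int(n)
        if n < 0:
            raise ValueError("n must be >= 0")
        if n == 0:
            return np.empty((0, 2))
        if self.area <= 0:
            raise InvalidGeometryError("cannot sample from a zero-area window")
        rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
        xmin, ymin, xmax, ymax = self.bounds
        frac = self.area / ((xmax - xmin) * (ymax - ymin))
        out = []
        got = 0
        while got < n:
            m = max(16, int(1.3 * (n - got) / frac))
            x = rng.uniform(xmin, xmax, m)
            y = rng.uniform(ymin, ymax, m)
            keep = self.contains_points(x, y)
            pts = np.column_stack([x[keep], y[keep]])
            out.append(pts)
            got += len(pts)
        return np.concatenate(out)[:n]

    # ------------------------------------------------------------------ #
    # set covariance

    def _mask_raster(self):
        """Binary raster of the window over its bounding box (cached)."""
        if self._mask_cache is None:
            ns = self.raster_size
            xmin, ymin, xmax, ymax = self.bounds
            dx = (xmax - xmin) / ns
            dy = (ymax - ymin) / ns
            xc = xmin + (np.arange(ns) + 0.5) * dx
            yc = ymin + (np.arange(ns) + 0.5) * dy
            outer_is_rect = self.outer.equals(box(*self.outer.bounds))
            if outer_is_rect:
                mask = np.ones((ns, ns), dtype=bool)
            else:
                xx, yy = np.meshgrid(xc, yc)
                mask = shapely.contains_xy(
                    self.outer, xx.ravel(), yy.ravel()).reshape(ns, ns)
            # holes only need testing within their own bounding boxes
            for h in self.holes:
                hx0, hy0, hx1, hy1 = h.bounds
                ix = np.flatnonzero((xc >= hx0 - dx) & (xc <= hx1 + dx))
                iy = np.flatnonzero((yc >= hy0 - dy) & (yc <= hy1 + dy))
                if not len(ix) or not len(iy):
                    continue
                hxx, hyy = np.meshgrid(xc[ix], yc[iy])
                inside = shapely.contains_xy(h, hxx.ravel(), hyy.ravel())
                sub = mask[np.ix_(iy, ix)]
                sub &= ~inside.reshape(len(iy), len(ix))
                mask[np.ix_(iy, ix)] = sub
            self._mask_cache = (mask, dx, dy)
        return self._mask_cache

    def _covariance_grid(self):
        if self._cov_grid is None:
            mask, dx, dy = self._mask_raster()
            m = mask.astype(np.float32)
            grid = fftconvolve(m, m[::-1, ::-1], mode="full") * (dx * dy)
            np.clip(grid, 0.0, None, out=grid)
            self._cov_grid = (grid.astype(float), dx, dy)
        return self._cov_grid

    def set_covariance(self, shift) -> float:
        """Area of overlap between the window and itself shifted by ``shift``."""
        s = np.asarray(shift, dtype=float).ravel()
        return float(self.set_covariance_many([s[0]], [s[1]])[0])

    def set_covariance_many(self, dx, dy) -> np.ndarray:
        """Vectorised set covariance for arrays of shift components."""
        dx = np.asarray(dx, dtype=float)
        dy = np.asarray(dy, dtype=float)
        if self.kind == "rectangle":
            a, b = self.side_lengths
            return np.maximum(a - np.abs(dx), 0.0) * np.maximum(b - np.abs(dy), 0.0)
        grid, px, py = self._covariance_grid()
        ns = self.raster_size
        ix = dx / px + (ns - 1)
        iy = dy / py + (ns - 1)
        vals = map_coordinates(grid, [iy, ix], order=1, mode="constant", cval=0.0)
        return np.clip(vals, 0.0, None)

    def translation_weights(self, dx, dy) -> np.ndarray:
        """Translation edge-correction weights |W| / |W ∩ (W + s)|.

        Covariances below 1e-9·|W| are floored to avoid blow-ups for
        shifts close to the window diameter.
        """
        cov = self.set_covariance_many(dx, dy)
        floor = 1e-9 * self.area
        return self.area / np.maximum(cov, floor)

    # ------------------------------------------------------------------ #

    def __repr__(self) -> str:  # pragma: no cover
        return (f"Window(kind={self.kind!r}, area={self.area:.4g} m², "
                f"holes={len(self.holes)})")
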