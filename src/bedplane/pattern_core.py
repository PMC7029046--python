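"""Marked point patterns, intensity estimation and size summaries."""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import gaussian_filter

from .geometry import Window

__all__ = [
    "PointPattern",
    "IntensityMap",
    "SizeSummary",
    "mean_intensity",
    "kernel_intensity_map",
    "size_summary",
    "TAXA",
]

log = logging.getLogger(__name__)

#: Recognised taxon labels; anything else is coerced to "other" on file read.
TAXA = ("Oncocerida", "Ammonoidea", "Orthocerida", "other")


class PointPattern:
    """A set of planar points inside a :class:`Window`, with optional marks.

    Marks are per-point arrays: ``taxon`` (strings), ``angle_deg``
    (orientation in degrees, counterclockwise from +x, NaN if absent),
    ``length_mm`` and ``width_mm`` (NaN if absent).

    Every point must lie inside the window; offending indices are
    reported in the raised error.  Duplicate coordinates are allowed but
    logged (traced outlines can collide at their centres).
    """

    def __init__(self, window: Window, xy, taxon=None, angle_deg=None,
                 length_mm=None, width_mm=None, validate: bool = True):
        self.window = window
        xy = np.asarray(xy, dtype=float).reshape(-1, 2)
        self.xy = xy
        n = len(xy)

        def _mark(values, dtype=float):
            if values is None:
                return None
            arr = np.asarray(values, dtype=dtype)
            if len(arr) != n:
                raise ValueError("mark length does not match number of points")
            return arr

        self.taxon = _mark(taxon, dtype=object)
        self.angle_deg = _mark(angle_deg)
        if self.angle_deg is not None:
            self.angle_deg = np.where(
                np.isnan(self.angle_deg), np.nan, self.angle_deg % 360.0
            )
        self.length_mm = _mark(length_mm)
        self.width_mm = _mark(width_mm)

        if validate and n:
            inside = window.contains_points(xy)
            if not inside.all():
                bad = np.flatnonzero(~inside)
                raise ValueError(
                    f"{bad.size} point(s) outside the window at indices {bad.tolist()}"
                )
            if n > 1:
                uniq = len(np.unique(xy, axis=0))
                if uniq < n:
                    log.warning("point pattern contains %d duplicate coordinate(s)",
                                n - uniq)

    @property
    def n(self) -> int:
        return len(self.xy)

    @property
    def intensity(self) -> float:
        """Mean intensity λ̄ = n / |W| in points per m²."""
        return self.n / self.window.area

    def subset(self, taxon: str) -> "PointPattern":
        """Sub-pattern of points carrying the given taxon label."""
        if self.taxon is None:
            raise ValueError("pattern has no taxon marks")
        keep = np.asarray([t == taxon for t in self.taxon])
        return self._take(keep)

    def _take(self, keep) -> "PointPattern":
        def sub(a):
            return None if a is None else a[keep]
        return PointPattern(self.window, self.xy[keep], taxon=sub(self.taxon),
                            angle_deg=sub(self.angle_deg),
                            length_mm=sub(self.length_mm),
                            width_mm=sub(self.width_mm), validate=False)

    def __len__(self) -> int:
        return self.n

    def __repr__(self) -> str:  # pragma: no cover
        return f"PointPattern(n={self.n}, window_area={self.window.area:.3g} m²)"


@dataclass
class IntensityMap:
    """Kernel-smoothed intensity surface on a regular grid.

    ``values`` holds points/m², NaN outside the window mask.
    """

    values: np.ndarray
    x_centres: np.ndarray
    y_centres: np.ndarray
    cell: float
    bandwidth: float
    mask: np.ndarray

    @property
    def total_mass(self) -> float:
        """Integral of the map over the window mask (≈ n)."""
        vals = np.where(self.mask, self.values, 0.0)
        return float(vals.sum() * self.cell ** 2)

    def max_cell(self) -> tuple[float, float]:
        """(x, y) centre of the cell with the largest intensity."""
        vals = np.where(self.mask, self.values, -np.inf)
        iy, ix = np.unravel_index(np.argmax(vals), vals.shape)
        return float(self.x_centres[ix]), float(self.y_centres[iy])


@dataclass
class SizeSummary:
    mean_length_mm: float
    median_length_mm: float
    mean_width_mm: float
    median_width_mm: float
    n_with_size: int
    empty: bool = False


def mean_intensity(pattern: PointPattern) -> float:
    """Average number of points per unit area, n / |W|."""
    area = pattern.window.area
    if area <= 0:
        raise ValueError("window has zero area")
    return pattern.n / area


def kernel_intensity_map(pattern: PointPattern, bandwidth: float | None = None,
                         cell: float | None = None) -> IntensityMap:
    """Edge-corrected Gaussian kernel intensity estimate.

    The raw kernel density in each cell is divided by the fraction of
    the kernel mass (centred on that cell) falling inside the window, so
    the surface integrates to approximately n.

    Defaults: bandwidth = 0.1 x shorter bounding-box side, cell =
    bandwidth / 4.
    """
    w = pattern.window
    sx, sy = w.side_lengths
    if bandwidth is None:
        bandwidth = 0.1 * min(sx, sy)
    if bandwidth <= 0:
        raise ValueError("bandwidth must be > 0")
    if cell is None:
        cell = bandwidth / 4.0
    if cell <= 0:
        raise ValueError("cell must be > 0")
    if cell > min(sx, sy):
        raise ValueError("cell size exceeds the window extent")

    xmin, ymin, xmax, ymax = w.bounds
    nx = max(2, int(np.ceil(sx / cell)))
    ny = max(2, int(np.ceil(sy / cell)))
    x_edges = xmin + np.arange(nx + 1) * cell
    y_edges = ymin + np.arange(ny + 1) * cell
    x_centres = 0.5 * (x_edges[:-1] + x_edges[1:])
    y_centres = 0.5 * (y_edges[:-1] + y_edges[1:])

    counts, _, _ = np.histogram2d(pattern.xy[:, 0], pattern.xy[:, 1],
                                  bins=[x_edges, y_edges])
    counts = counts.T  # (ny, nx)
    sigma_px = bandwidth / cell
    raw = gaussian_filter(counts, sigma=sigma_px, mode="constant") / cell ** 2

    xx, yy = np.meshgrid(x_centres, y_centres)
    mask = w.contains_points(xx.ravel(), yy.ravel()).reshape(ny, nx)
    inside_frac = gaussian_filter(mask.astype(float), sigma=sigma_px,
                                  mode="constant")
    with np.errstate(divide="ignore", invalid="ignore"):
        corrected = np.where(mask & (inside_frac > 0), raw / inside_frac, np.nan)
    return IntensityMap(values=corrected, x_centres=x_centres,
                        y_centres=y_centres, cell=cell, bandwidth=bandwidth,
                        mask=mask)


def size_summary(pattern: PointPattern, taxon: str | None = None) -> SizeSummary:
    """Mean/median of length and width marks, optionally for one taxon."""
    p = pattern.subset(taxon) if taxon is not None else pattern
    if p.length_mm is None or p.width_mm is None:
        return SizeSummary(np.nan, np.nan, np.nan, np.nan, 0, empty=True)
    sized = ~(np.isnan(p.length_mm) | np.isnan(p.width_mm))
    if not sized.any():
        return SizeSummary(np.nan, np.nan, np.nan, np.nan, 0, empty=True)
    L = p.length_mm[sized]
    W = p.width_mm[sized]
    return SizeSummary(
        mean_length_mm=float(np.mean(L)),
        median_length_mm=float(np.median(L)),
        mean_width_mm=float(np.mean(W)),
        median_width_mm=float(np.median(W)),
        n_with_size=int(sized.sum()),
    )
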