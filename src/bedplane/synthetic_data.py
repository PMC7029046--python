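"""Synthetic bedding-plane scenes.

Generates marked multi-taxon point patterns with the statistical
structure the analysis pipeline assumes: a pair-clustered oncocerid
layer, a denser spatially random ammonoid layer, a sparse orthocerid
layer, a fraction of the window masked by unobservable "gaps", dispersed
orientations, near-symmetric widths and right-skewed lengths.

Everything is deterministic given the master seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
from scipy import stats
from shapely.geometry import Point

from .geometry import InvalidGeometryError, Window
from .models import GaussPoissonPairs, HomPoisson, InhomPoisson, simulate_model
from .pattern_core import PointPattern

__all__ = ["SceneConfig", "generate_scene", "generate_gap_mask", "write_scene"]


@dataclass
class SceneConfig:
    """Configuration of a synthetic scene (defaults sized like an
    80 m² surface with ~73 pair-clustered oncocerids)."""

    window_width: float = 8.0
    window_height: float = 10.0
    # oncocerid pair layer
    oncocerid_target_n: float = 73.0
    pair_radius: float = 0.28
    pair_retention: float = 0.75
    # other layers (homogeneous intensities; ammonoids optionally log-linear)
    ammonoid_intensity: float = 3.42
    ammonoid_log_linear: tuple[float, float, float] | None = None
    orthocerid_intensity: float = 1.0
    # gaps
    gap_fraction: float = 0.09
    # orientation marks: uniform when mu is None, else von Mises
    orientation_mu_deg: float | None = None
    orientation_kappa: float = 2.0
    # oncocerid size marks
    width_mean_mm: float = 55.0
    width_sd_mm: float = 12.0
    length_shape: float = 3.0
    length_scale_mm: float = 31.3
    # orthocerid size marks (smaller shells)
    ortho_width_mean_mm: float = 16.0
    ortho_width_sd_mm: float = 3.0
    ortho_length_shape: float = 3.0
    ortho_length_scale_mm: float = 18.3
    #: raster resolution for the gap-corrected window's set covariance
    raster_size: int = 1024
    seed: int = 0

    def __post_init__(self):
        if min(self.ammonoid_intensity, self.orthocerid_intensity,
               self.oncocerid_target_n) < 0:
            raise ValueError("layer intensities must be >= 0")
        if not 0.0 <= self.gap_fraction <= 0.5:
            raise ValueError("gap fraction must lie in [0, 0.5]")

    def to_json(self) -> dict:
        return asdict(self)


def generate_gap_mask(window: Window, fraction: float, seed=None,
                      max_attempts: int = 2000,
                      radius_range: tuple[float, float] = (0.25, 0.6)) -> Window:
    """Remove random non-overlapping discs until the masked area is
    within ±1 percentage point of ``fraction``.

    The input window must be hole-free.  fraction = 0 returns the window
    unchanged.
    """
    if not 0.0 <= fraction <= 0.5:
        raise ValueError("gap fraction must lie in [0, 0.5]")
    if window.holes:
        raise InvalidGeometryError("gap mask requires a hole-free window")
    if fraction == 0.0:
        return window
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    area = window.area
    target = fraction * area
    holes = []
    masked = 0.0
    margin = 0.05
    xmin, ymin, xmax, ymax = window.bounds
    attempts = 0
    while masked < target - 0.009 * area:
        attempts += 1
        if attempts > max_attempts:
            raise RuntimeError(
                f"could not reach the target gap fraction {fraction} after "
                f"{max_attempts} attempts")
        needed = target - masked
        radius = min(rng.uniform(*radius_range), np.sqrt(needed / np.pi))
        cx = rng.uniform(xmin + radius + margin, xmax - radius - margin)
        cy = rng.uniform(ymin + radius + margin, ymax - radius - margin)
        disc = Point(cx, cy).buffer(radius, quad_segs=32)
        if not window.outer.contains(disc):
            continue
        if any(disc.distance(h) < margin for h in holes):
            continue
        holes.append(disc)
        masked += disc.area
    return Window(window.outer, holes, raster_size=window.raster_size)


def _orientation_marks(cfg: SceneConfig, n: int, rng) -> np.ndarray:
    if cfg.orientation_mu_deg is None:
        return rng.uniform(0.0, 360.0, n)
    mu = np.radians(cfg.orientation_mu_deg)
    return np.degrees(rng.vonmises(mu, cfg.orientation_kappa, n)) % 360.0


def _size_marks(n: int, rng, width_mean, width_sd, length_shape, length_scale):
    a = (0.0 - width_mean) / width_sd  # truncate widths at 0
    widths = stats.truncnorm.rvs(a, np.inf, loc=width_mean, scale=width_sd,
                                 size=n, random_state=rng)
    lengths = rng.gamma(length_shape, length_scale, n)
    return lengths, widths


def generate_scene(cfg: SceneConfig | None = None,
                   seed=None) -> PointPattern:
    """Generate one marked multi-taxon scene.

    Layers are simulated on the full (gap-free) rectangle and then
    thinned by the gap mask — a fossil under cover is unobservable, not
    displaced.  The returned pattern's window carries the gap holes.
    The oncocerid parent intensity is target_n / ((1 + P) |W_full|), so
    the expected observed oncocerid count is target_n × (1 − gap
    fraction).
    """
    cfg = cfg or SceneConfig()
    rng = (seed if isinstance(seed, np.random.Generator)
           else np.random.default_rng(cfg.seed if seed is None else seed))
    full = Window.rectangle(0.0, 0.0, cfg.window_width, cfg.window_height,
                            raster_size=cfg.raster_size)
    masked = generate_gap_mask(full, cfg.gap_fraction, rng)

    layers = []  # (taxon, xy, sized)
    kappa = cfg.oncocerid_target_n / ((1.0 + cfg.pair_retention) * full.area)
    onco = simulate_model(
        GaussPoissonPairs(kappa, cfg.pair_radius, cfg.pair_retention), full, rng)
    layers.append(("Oncocerida", onco.xy,
                   (cfg.width_mean_mm, cfg.width_sd_mm,
                    cfg.length_shape, cfg.length_scale_mm)))
    if cfg.ammonoid_intensity > 0 or cfg.ammonoid_log_linear:
        spec = (InhomPoisson(*cfg.ammonoid_log_linear)
                if cfg.ammonoid_log_linear
                else HomPoisson(cfg.ammonoid_intensity))
        layers.append(("Ammonoidea", simulate_model(spec, full, rng).xy, None))
    if cfg.orthocerid_intensity > 0:
        layers.append(("Orthocerida",
                       simulate_model(HomPoisson(cfg.orthocerid_intensity),
                                      full, rng).xy,
                       (cfg.ortho_width_mean_mm, cfg.ortho_width_sd_mm,
                        cfg.ortho_length_shape, cfg.ortho_length_scale_mm)))

    xs, taxa, angles, lengths, widths = [], [], [], [], []
    for taxon, xy, size_spec in layers:
        keep = masked.contains_points(xy) if len(xy) else np.zeros(0, bool)
        xy = xy[keep]
        n = len(xy)
        xs.append(xy)
        taxa.extend([taxon] * n)
        angles.append(_orientation_marks(cfg, n, rng))
        if size_spec is not None:
            wm, wsd, lsh, lsc = size_spec
            L, W = _size_marks(n, rng, wm, wsd, lsh, lsc)
        else:
            L = np.full(n, np.nan)
            W = np.full(n, np.nan)
        lengths.append(L)
        widths.append(W)

    xy = np.concatenate(xs) if xs else np.empty((0, 2))
    return PointPattern(masked, xy, taxon=np.array(taxa, dtype=object),
                        angle_deg=np.concatenate(angles),
                        length_mm=np.concatenate(lengths),
                        width_mm=np.concatenate(widths), validate=False)


def write_scene(pattern: PointPattern, cfg: SceneConfig, prefix) -> dict:
    """Write a scene to <prefix>.csv / <prefix>.geojson / <prefix>.json.

    Returns the paths written.  The config (with its resolved seed) is
    emitted alongside the data for provenance.
    """
    from .cli_io import write_pattern, write_window
    paths = {
        "pattern": f"{prefix}.csv",
        "window": f"{prefix}.geojson",
        "config": f"{prefix}.json",
    }
    write_pattern(pattern, paths["pattern"])
    write_window(pattern.window, paths["window"])
    with open(paths["config"], "w") as fh:
        json.dump(cfg.to_json(), fh, indent=2)
    return paths
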