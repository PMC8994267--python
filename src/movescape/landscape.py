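"""Synthetic valley landscapes, covariate layers and development scenarios.

The study system is a mountain valley whose bottom holds the high-quality
habitat, two towns and a network of trails, roads and a railway, flanked by
steep, partly barren ridges.  This module generates such landscapes with
known structure, derives the covariate rasters the movement models consume
(town-distance decays, trail-road density, slope, availability), and encodes
the three development scenarios (reference / current / future).

All computation is in projected metres on a regular grid (default 120 m
cells); the CRS is carried as a metadata tag only.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import shapely
from scipy.ndimage import gaussian_filter
from shapely.geometry import LineString, Polygon, box

__all__ = [
    "GridGeometry",
    "CovariateStack",
    "VectorScene",
    "ScenarioSpec",
    "LandscapeConfig",
    "generate_landscape",
    "town_distance_layer",
    "line_density_layer",
    "availability_mask",
    "apply_future_development",
    "generate_labelled_tracks",
    "scenario_stack",
]

# Slope above which barren/ice terrain is considered impassable (degrees).
STEEP_SLOPE_DEG = 35.0
# Buffer within which an endpoint is "on" a linear feature (metres).
ON_FEATURE_BUFFER_M = 30.0


# ---------------------------------------------------------------------------
# grid geometry
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class GridGeometry:
    """Regular raster grid in projected metres.

    Row 0 is the southern (lowest-y) row; arrays are indexed ``[row, col]``.
    """

    n_rows: int
    n_cols: int
    cell_size: float = 120.0
    origin_x: float = 0.0
    origin_y: float = 0.0
    crs: str = "local-metres"

    @property
    def width(self) -> float:
        return self.n_cols * self.cell_size

    @property
    def height(self) -> float:
        return self.n_rows * self.cell_size

    @property
    def bounds(self) -> tuple[float, float, float, float]:
        return (
            self.origin_x,
            self.origin_y,
            self.origin_x + self.width,
            self.origin_y + self.height,
        )

    @property
    def shape(self) -> tuple[int, int]:
        return (self.n_rows, self.n_cols)

    def cell_centres(self) -> tuple[np.ndarray, np.ndarray]:
        """Meshgrids ``(X, Y)`` of cell-centre coordinates, shape (n_rows, n_cols)."""
        xs = self.origin_x + (np.arange(self.n_cols) + 0.5) * self.cell_size
        ys = self.origin_y + (np.arange(self.n_rows) + 0.5) * self.cell_size
        return np.meshgrid(xs, ys)

    def rowcol(self, x, y) -> tuple[np.ndarray, np.ndarray]:
        """Cell indices containing points (x, y).  No bounds check."""
        col = np.floor((np.asarray(x) - self.origin_x) / self.cell_size).astype(int)
        row = np.floor((np.asarray(y) - self.origin_y) / self.cell_size).astype(int)
        return row, col

    def in_bounds(self, x, y) -> np.ndarray:
        x = np.asarray(x)
        y = np.asarray(y)
        x0, y0, x1, y1 = self.bounds
        return (x >= x0) & (x < x1) & (y >= y0) & (y < y1)

    def clip_rowcol(self, row, col):
        return (
            np.clip(row, 0, self.n_rows - 1),
            np.clip(col, 0, self.n_cols - 1),
        )


# ---------------------------------------------------------------------------
# covariate stack & vector scene
# ---------------------------------------------------------------------------


@dataclass
class CovariateStack:
    """Named co-registered raster layers plus an availability mask.

    ``anthropogenic_names`` flags the development covariates whose effects are
    removed under the reference scenario.
    """

    geometry: GridGeometry
    layers: dict[str, np.ndarray]
    anthropogenic_names: frozenset[str] = frozenset()
    availability_mask: np.ndarray | None = None

    def __post_init__(self):
        if self.availability_mask is None:
            self.availability_mask = np.ones(self.geometry.shape, dtype=bool)
        self.validate()

    def validate(self) -> None:
        shape = self.geometry.shape
        for name, layer in self.layers.items():
            if layer.shape != shape:
                raise ValueError(
                    f"layer {name!r} shape {layer.shape} != grid shape {shape}"
                )
        if self.availability_mask.shape != shape:
            raise ValueError("availability mask shape mismatch")
        if not self.availability_mask.any():
            raise ValueError("availability mask has no available cells")
        unknown = self.anthropogenic_names - set(self.layers)
        if unknown:
            raise ValueError(f"anthropogenic names not in layers: {sorted(unknown)}")
        for name, layer in self.layers.items():
            if not np.isfinite(layer[self.availability_mask]).all():
                raise ValueError(f"layer {name!r} has non-finite values inside mask")

    def copy(self) -> "CovariateStack":
        return CovariateStack(
            geometry=self.geometry,
            layers={k: v.copy() for k, v in self.layers.items()},
            anthropogenic_names=self.anthropogenic_names,
            availability_mask=self.availability_mask.copy(),
        )

    def value_at(self, name: str, x, y) -> np.ndarray:
        row, col = self.geometry.clip_rowcol(*self.geometry.rowcol(x, y))
        return self.layers[name][row, col]


@dataclass
class VectorScene:
    """Vector geometry of the synthetic valley."""

    towns: list[Polygon]
    linear_features: list[tuple[str, LineString]]  # class in {trail, road, railway}
    patches: list[Polygon]
    transects: list[LineString]
    focal_area: Polygon | None = None

    def lines_of(self, *classes: str) -> list[LineString]:
        return [g for cls, g in self.linear_features if cls in classes]

    def validate(self, geometry: GridGeometry) -> None:
        bbox = box(*geometry.bounds)
        for geoms, label in [
            (self.towns, "town"),
            ([g for _, g in self.linear_features], "linear feature"),
            (self.patches, "patch"),
            (self.transects, "transect"),
        ]:
            for g in geoms:
                if not g.is_valid or g.is_empty:
                    raise ValueError(f"invalid/empty {label} geometry")
                if not bbox.intersects(g):
                    raise ValueError(f"{label} outside grid bounds")
        if len(self.patches) >= 2:
            for i in range(len(self.patches)):
                for j in range(i + 1, len(self.patches)):
                    if self.patches[i].intersects(self.patches[j]):
                        raise ValueError("habitat patches must be disjoint")


@dataclass
class ScenarioSpec:
    """A named development scenario.

    ``reference`` removes anthropogenic effects (coefficients zeroed by the
    simulator) and restores town/developed cells to available habitat;
    ``future`` typically overrides the trail-density layer and mask.
    """

    name: str
    layer_overrides: dict[str, np.ndarray] = field(default_factory=dict)
    mask_override: np.ndarray | None = None
    zero_anthropogenic: bool = False

    def __post_init__(self):
        if self.name == "reference" and not self.zero_anthropogenic:
            raise ValueError("reference scenario requires zero_anthropogenic=True")

    def validate_against(self, stack: CovariateStack) -> None:
        unknown = set(self.layer_overrides) - set(stack.layers)
        if unknown:
            raise ValueError(f"scenario overrides unknown layers: {sorted(unknown)}")


def scenario_stack(stack: CovariateStack, scenario: ScenarioSpec) -> CovariateStack:
    """Apply a scenario's layer and mask overrides to a stack."""
    scenario.validate_against(stack)
    new = stack.copy()
    for name, layer in scenario.layer_overrides.items():
        new.layers[name] = layer.copy()
    if scenario.mask_override is not None:
        new.availability_mask = scenario.mask_override.copy()
    new.validate()
    return new


# ---------------------------------------------------------------------------
# derived layers
# ---------------------------------------------------------------------------


def _distance_to_geoms(geometry: GridGeometry, geoms) -> np.ndarray:
    """Distance (m) from every cell centre to the union of geometries."""
    X, Y = geometry.cell_centres()
    pts = shapely.points(np.column_stack([X.ravel(), Y.ravel()]))
    union = shapely.union_all(list(geoms))
    d = shapely.distance(pts, union)
    return d.reshape(geometry.shape)


def town_distance_layer(
    towns,
    geometry: GridGeometry,
    mode: str = "capped_linear",
    range_m: float = 5000.0,
) -> np.ndarray:
    """Town-proximity covariate raster.

    ``capped_linear`` is distance-like: 0 at the town edge rising linearly to
    1 at ``range_m`` and beyond.  ``exp_decay`` is proximity-like: 1 at the
    town edge decaying as ``exp(-d / range_m)``.
    """
    if not 500.0 <= range_m <= 5000.0:
        raise ValueError("range_m must be within [500, 5000] m")
    if mode not in ("capped_linear", "exp_decay"):
        raise ValueError(f"unknown mode {mode!r}")
    if not towns:
        warnings.warn("no towns given; returning constant far-distance layer")
        far = 1.0 if mode == "capped_linear" else 0.0
        return np.full(geometry.shape, far)
    d = _distance_to_geoms(geometry, towns)
    if mode == "capped_linear":
        return np.minimum(d, range_m) / range_m
    return np.exp(-d / range_m)


def _segment_circle_lengths(p0, p1, centres, radius):
    """Exact length of segment p0->p1 inside a circle around each centre.

    Closed-form quadratic clip; vectorised over centres (n, 2).
    """
    d = p1 - p0
    seg_len = float(np.hypot(*d))
    if seg_len == 0.0:
        return np.zeros(len(centres))
    f = p0 - centres  # (n, 2)
    a = seg_len**2
    b = 2.0 * (f @ d)
    c = np.einsum("ij,ij->i", f, f) - radius**2
    disc = b * b - 4.0 * a * c
    out = np.zeros(len(centres))
    hit = disc > 0
    if not hit.any():
        return out
    sq = np.sqrt(disc[hit])
    t0 = np.clip((-b[hit] - sq) / (2 * a), 0.0, 1.0)
    t1 = np.clip((-b[hit] + sq) / (2 * a), 0.0, 1.0)
    out[hit] = (t1 - t0) * seg_len
    return out


def _iter_segments(lines):
    """Segments in a canonical order so accumulated sums do not depend on
    the order the caller lists the lines (floating-point associativity)."""
    segs = []
    for line in lines:
        coords = np.asarray(line.coords)
        for i in range(len(coords) - 1):
            p0 = tuple(coords[i])
            p1 = tuple(coords[i + 1])
            segs.append((p1, p0) if p1 < p0 else (p0, p1))
    segs.sort()
    for p0, p1 in segs:
        yield np.asarray(p0), np.asarray(p1)


def line_density_layer(
    lines, geometry: GridGeometry, radius_m: float = 500.0
) -> np.ndarray:
    """Linear-feature density in km/km² within ``radius_m`` of each cell centre.

    Exact circle-segment geometry (no rasterised kernel), so a straight line
    through a cell centre contributes its full chord 2r.
    """
    if radius_m <= geometry.cell_size:
        raise ValueError("radius must exceed the cell size")
    density = np.zeros(geometry.shape)
    if not lines:
        return density
    X, Y = geometry.cell_centres()
    centres = np.column_stack([X.ravel(), Y.ravel()])
    total = np.zeros(len(centres))
    for p0, p1 in _iter_segments(lines):
        # restrict to cells whose centre can be within radius of the segment
        lo = np.minimum(p0, p1) - radius_m
        hi = np.maximum(p0, p1) + radius_m
        near = (
            (centres[:, 0] >= lo[0])
            & (centres[:, 0] <= hi[0])
            & (centres[:, 1] >= lo[1])
            & (centres[:, 1] <= hi[1])
        )
        if near.any():
            total[near] += _segment_circle_lengths(
                np.asarray(p0, float), np.asarray(p1, float), centres[near], radius_m
            )
    # length_m -> km, circle area m^2 -> km^2
    density = (total * 1000.0 / (np.pi * radius_m**2)).reshape(geometry.shape)
    return density


def availability_mask(
    barren: np.ndarray,
    slope_deg: np.ndarray,
    developed_polygons,
    geometry: GridGeometry,
    include_developed: bool = True,
) -> np.ndarray:
    """Boolean raster of available habitat.

    Unavailable cells are steep barren/ice terrain (slope > 35 degrees) and,
    unless ``include_developed`` is False (reference conditions), cells inside
    town/developed polygons.
    """
    unavailable = (barren.astype(bool)) & (slope_deg > STEEP_SLOPE_DEG)
    if include_developed and developed_polygons:
        X, Y = geometry.cell_centres()
        union = shapely.union_all(list(developed_polygons))
        inside = shapely.contains_xy(union, X.ravel(), Y.ravel()).reshape(
            geometry.shape
        )
        unavailable = unavailable | inside
    available = ~unavailable
    if not available.any():
        raise ValueError("all cells unavailable")
    return available


# ---------------------------------------------------------------------------
# synthetic landscape generator
# ---------------------------------------------------------------------------


@dataclass
class LandscapeConfig:
    """Configuration of the synthetic valley.

    Defaults give a 200 x 200 cell (24 x 24 km) east-west valley with two
    towns on the valley floor, a trail/road network whose density scales with
    ``trail_intensity``, and steep partly-barren flanking ridges.
    """

    n_rows: int = 200
    n_cols: int = 200
    cell_size: float = 120.0
    correlation_length_m: float = 2000.0  # habitat-quality GRF smoothness
    valley_halfwidth_m: float = 2000.0
    ridge_ramp_m: float = 1500.0
    # town centres as fractions of grid width/height, size in metres
    town_positions: tuple[tuple[float, float], ...] = ((0.33, 0.5), (0.67, 0.5))
    town_size_m: tuple[float, float] = (2400.0, 4600.0)
    trail_intensity: float = 1.0
    n_spur_trails: int = 16
    town_decay_range_m: float = 5000.0  # HMM capped-linear distance range
    town_prox_range_m: float = 500.0  # SSF exponential-decay range
    density_radius_m: float = 500.0

    def __post_init__(self):
        if self.n_rows < 50 or self.n_cols < 50:
            raise ValueError("grid must be at least 50 x 50 cells")
        if self.trail_intensity < 0:
            raise ValueError("trail_intensity must be >= 0")


def _make_towns(config: LandscapeConfig, geom: GridGeometry) -> list[Polygon]:
    towns = []
    w, h = config.town_size_m
    for fx, fy in config.town_positions:
        cx = geom.origin_x + fx * geom.width
        cy = geom.origin_y + fy * geom.height
        poly = box(cx - w / 2, cy - h / 2, cx + w / 2, cy + h / 2)
        x0, y0, x1, y1 = geom.bounds
        if not box(x0, y0, x1, y1).contains(poly):
            raise ValueError(
                f"town at fraction ({fx}, {fy}) extends outside the grid"
            )
        towns.append(poly)
    union = shapely.union_all(towns)
    if union.area >= 0.999 * geom.width * geom.height:
        raise ValueError("towns cover the entire grid")
    return towns


def _valley_axis(config: LandscapeConfig, geom: GridGeometry, n: int = 60):
    """Points along the (gently meandering) valley centre line."""
    xs = np.linspace(geom.origin_x, geom.origin_x + geom.width, n)
    yc = geom.origin_y + geom.height / 2
    amp = 0.25 * config.valley_halfwidth_m
    ys = yc + amp * np.sin(2 * np.pi * (xs - geom.origin_x) / geom.width * 1.5)
    return np.column_stack([xs, ys])


def _make_linear_features(
    config: LandscapeConfig, geom: GridGeometry, rng: np.random.Generator
) -> list[tuple[str, LineString]]:
    feats: list[tuple[str, LineString]] = []
    axis = _valley_axis(config, geom)
    yc = geom.origin_y + geom.height / 2
    # railway always present (on/off covariate only, not in trail-road density)
    rail = axis.copy()
    rail[:, 1] -= 700.0
    feats.append(("railway", LineString(rail)))
    if config.trail_intensity > 0:
        road = axis.copy()
        road[:, 1] += 500.0
        feats.append(("road", LineString(road)))
        main_trail = axis.copy()
        main_trail[:, 1] -= 300.0
        feats.append(("trail", LineString(main_trail)))
        # recreational spur trails concentrate in the developed reach of the
        # valley (between and around the towns), as in mountain tourist towns
        n_spurs = int(round(config.trail_intensity * config.n_spur_trails))
        x0, y0, x1, y1 = geom.bounds
        fx_lo = min(p[0] for p in config.town_positions) - 0.05
        fx_hi = max(p[0] for p in config.town_positions) + 0.05
        for _ in range(n_spurs):
            fx = rng.uniform(max(fx_lo, 0.05), min(fx_hi, 0.95))
            sx = geom.origin_x + fx * geom.width
            sy = np.interp(sx, axis[:, 0], axis[:, 1])
            direction = rng.choice([-1.0, 1.0])
            length = rng.uniform(1500.0, config.valley_halfwidth_m + 2000.0)
            n_verts = 6
            ts = np.linspace(0, 1, n_verts)
            xs = sx + rng.normal(0, 400.0, n_verts).cumsum() * ts
            ys = sy + direction * length * ts
            xs = np.clip(xs, x0 + 1.0, x1 - 1.0)
            ys = np.clip(ys, y0 + 1.0, y1 - 1.0)
            feats.append(("trail", LineString(np.column_stack([xs, ys]))))
        # short in-valley connector trails near towns
        for fx, fy in config.town_positions:
            cx = geom.origin_x + fx * geom.width
            for dy in (-1200.0, 1500.0):
                seg = LineString(
                    [
                        (max(cx - 2500.0, x0 + 1), yc + dy),
                        (min(cx + 2500.0, x1 - 1), yc + dy),
                    ]
                )
                feats.append(("trail", seg))
    return feats


def generate_landscape(
    config: LandscapeConfig, seed: int
) -> tuple[CovariateStack, VectorScene]:
    """Generate a synthetic valley landscape; deterministic given ``seed``.

    Layers produced: ``habitat`` (Gaussian-random-field quality plus valley
    bonus), ``slope`` (degrees, steep flanking ridges), ``barren`` (0/1),
    ``dist_town_m`` (raw metres), ``town_dist`` (capped-linear, 5 km),
    ``town_prox`` (exponential decay, 500 m), ``trail_density`` (km/km²,
    trails + roads within 500 m).
    """
    rng = np.random.default_rng(seed)
    geom = GridGeometry(
        n_rows=config.n_rows, n_cols=config.n_cols, cell_size=config.cell_size
    )
    towns = _make_towns(config, geom)
    feats = _make_linear_features(config, geom, rng)

    X, Y = geom.cell_centres()
    axis = _valley_axis(config, geom)
    y_axis = np.interp(X, axis[:, 0], axis[:, 1])
    dy = np.abs(Y - y_axis)

    # habitat quality: smooth random field + valley-bottom bonus
    sigma_cells = config.correlation_length_m / config.cell_size
    field_ = gaussian_filter(rng.standard_normal(geom.shape), sigma_cells)
    field_ = (field_ - field_.mean()) / (field_.std() + 1e-12)
    habitat = field_ + 1.5 * np.exp(-((dy / config.valley_halfwidth_m) ** 2))

    # slope: gentle valley floor ramping to steep ridges, mild noise
    ramp = np.clip((dy - config.valley_halfwidth_m) / config.ridge_ramp_m, 0.0, 1.0)
    slope_noise = gaussian_filter(rng.standard_normal(geom.shape), 2.0) * 4.0
    slope = 4.0 + 41.0 * ramp + slope_noise
    slope = np.clip(slope, 0.0, 60.0)

    # barren above treeline on the ridges (with some noise)
    barren_noise = gaussian_filter(rng.standard_normal(geom.shape), 3.0)
    barren = ((ramp > 0.55) & (barren_noise > -0.8)).astype(float)

    dist_town_m = _distance_to_geoms(geom, towns)
    town_dist = np.minimum(dist_town_m, config.town_decay_range_m) / (
        config.town_decay_range_m
    )
    town_prox = np.exp(-dist_town_m / config.town_prox_range_m)

    density_lines = [g for cls, g in feats if cls in ("trail", "road")]
    trail_density = line_density_layer(density_lines, geom, config.density_radius_m)

    mask = availability_mask(barren, slope, towns, geom, include_developed=True)

    stack = CovariateStack(
        geometry=geom,
        layers={
            "habitat": habitat,
            "slope": slope,
            "barren": barren,
            "dist_town_m": dist_town_m,
            "town_dist": town_dist,
            "town_prox": town_prox,
            "trail_density": trail_density,
        },
        anthropogenic_names=frozenset({"town_dist", "town_prox", "trail_density"}),
        availability_mask=mask,
    )

    # habitat patches at the valley ends, outside town influence
    yc = geom.origin_y + geom.height / 2
    patch_w = 0.08 * geom.width
    patch_h = 2.0 * config.valley_halfwidth_m * 0.6
    x0, y0, x1, y1 = geom.bounds
    patches = [
        box(x0 + 0.02 * geom.width, yc - patch_h / 2, x0 + 0.02 * geom.width + patch_w,
            yc + patch_h / 2),
        box(x1 - 0.02 * geom.width - patch_w, yc - patch_h / 2,
            x1 - 0.02 * geom.width, yc + patch_h / 2),
    ]
    # cross-valley transects through each town
    transects = []
    for fx, _fy in config.town_positions:
        tx = geom.origin_x + fx * geom.width
        transects.append(LineString([(tx, y0), (tx, y1)]))
    # focal area: valley bottom between the towns, +/- 5 km of the axis
    fx0 = geom.origin_x + config.town_positions[0][0] * geom.width
    fx1 = geom.origin_x + config.town_positions[1][0] * geom.width
    focal = box(fx0, yc - 5000.0, fx1, yc + 5000.0).intersection(box(x0, y0, x1, y1))

    scene = VectorScene(
        towns=towns,
        linear_features=feats,
        patches=patches,
        transects=transects,
        focal_area=focal,
    )
    scene.validate(geom)
    return stack, scene


# ---------------------------------------------------------------------------
# future development
# ---------------------------------------------------------------------------


def _dedupe_lines(lines) -> list[LineString]:
    seen = set()
    out = []
    for g in lines:
        key = shapely.normalize(g).wkb
        if key not in seen:
            seen.add(key)
            out.append(g)
    return out


def apply_future_development(
    stack: CovariateStack,
    scene: VectorScene,
    new_town_polygons=(),
    informal_trails=(),
    density_radius_m: float = 500.0,
) -> tuple[CovariateStack, VectorScene]:
    """Expand the developed footprint and add informal trails.

    Recomputes the availability mask (expanded towns unavailable) and the
    trail-density layer (formal + informal trails + roads, de-duplicated);
    all other layers are unchanged.
    """
    geom = stack.geometry
    bbox = box(*geom.bounds)
    for g in list(new_town_polygons) + list(informal_trails):
        if not bbox.intersects(g):
            raise ValueError("new development geometry outside grid bounds")

    new_towns = list(scene.towns) + list(new_town_polygons)
    new_feats = list(scene.linear_features) + [
        ("trail", g) for g in informal_trails
    ]
    density_lines = _dedupe_lines(
        [g for cls, g in new_feats if cls in ("trail", "road")]
    )

    new_stack = stack.copy()
    new_stack.layers["trail_density"] = line_density_layer(
        density_lines, geom, density_radius_m
    )
    new_stack.availability_mask = availability_mask(
        stack.layers["barren"],
        stack.layers["slope"],
        new_towns,
        geom,
        include_developed=True,
    )
    new_stack.validate()

    new_scene = VectorScene(
        towns=new_towns,
        linear_features=new_feats,
        patches=list(scene.patches),
        transects=list(scene.transects),
        focal_area=scene.focal_area,
    )
    return new_stack, new_scene


# ---------------------------------------------------------------------------
# ground-truth track generation
# ---------------------------------------------------------------------------


def generate_labelled_tracks(
    stack: CovariateStack,
    scene: VectorScene,
    true_hmm,
    true_ssf: dict[str, float],
    n_animals: int,
    n_steps: int,
    fix_interval_h: float = 2.0,
    seed: int = 0,
    start_time: str = "2021-07-01T00:00:00",
):
    """Simulate tracks from known HMM + SSF parameters, keeping state labels.

    Drives the path simulator with the supplied ground-truth parameters and
    returns a pandas DataFrame with columns ``animal_id, timestamp, x, y,
    true_state`` suitable for writing as a track CSV.  Deterministic given
    ``seed``.
    """
    import pandas as pd

    from movescape.simulate import ScenarioBundle, SimConfig, simulate_ensemble
    from movescape.ssf import DesignSpec

    spec = DesignSpec.from_coefficients(true_ssf)
    beta = np.array([true_ssf[t] for t in spec.terms])
    bundle = ScenarioBundle(
        name="truth",
        stack=stack,
        scene=scene,
        hmm_params=true_hmm,
        design_spec=spec,
        beta=beta,
    )
    config = SimConfig(
        n_paths=n_animals, steps_per_path=n_steps, seed=seed,
        fixes_per_day=int(round(24.0 / fix_interval_h)),
    )
    ensemble = simulate_ensemble(config, bundle)

    rows = []
    t0 = np.datetime64(start_time)
    step_td = np.timedelta64(int(fix_interval_h * 3600), "s")
    for p in range(ensemble.n_paths):
        n_used = ensemble.steps_used[p]
        for t in range(n_used + 1):
            rows.append(
                (
                    f"animal_{p:03d}",
                    t0 + t * step_td,
                    ensemble.xy[p, t, 0],
                    ensemble.xy[p, t, 1],
                    int(ensemble.states[p, t]),
                )
            )
    df = pd.DataFrame(rows, columns=["animal_id", "timestamp", "x", "y", "true_state"])
    return df
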