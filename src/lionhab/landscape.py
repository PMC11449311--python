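"""Covariate rasters for habitat-selection modelling.

The covariates mirror a savannah rangeland shared by lions and pastoralists:
vegetation cover (percent shrub/forest in a 50 m radius), terrain ruggedness
(TRI), seasonal vegetation greenness (EVI), distance to the nearest river
course, and two proxies of human activity derived from mapped pastoralist
homesteads ("bomas"): distance to the nearest boma and boma density within a
1/3/5 km radius.  Human layers come in wet- and dry-season variants because
herders vacate part of the landscape (the shortgrass plains analogue) during
the wet season.  All continuous covariates are centered and scaled before
entering any model; the scaling constants are stored on the stack.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from scipy.spatial import cKDTree
from shapely.geometry import LineString, Polygon, box

from .raster import RasterGrid

#: base covariate names understood by the model formulas
BASE_COVARIATES = ("cover", "tri", "evi", "dist_river", "dist_human", "dens_human")


@dataclass
class PointSet:
    """A set of mapped point features (bomas, water points, river vertices)."""

    points: np.ndarray  # (n, 2) x/y meters
    kind: str  # {boma, water, river_vertex}
    season_tag: str = "static"

    def __post_init__(self) -> None:
        self.points = np.atleast_2d(np.asarray(self.points, dtype=float))
        if self.points.size and self.points.shape[1] != 2:
            raise ValueError("points must be (n, 2)")
        if self.points.size and not np.all(np.isfinite(self.points)):
            raise ValueError("points must be finite")

    def __len__(self) -> int:
        return 0 if self.points.size == 0 else self.points.shape[0]


@dataclass
class CovariateStack:
    """Named raster layers sharing one grid geometry, plus scaling constants.

    Seasonal layers carry ``_wet`` / ``_dry`` suffixes (e.g. ``evi_wet``);
    :meth:`resolve` picks the season-appropriate variant.  ``scaling`` maps a
    layer name to the (mean, sd) used for centering/scaling; a stack whose
    ``scaling`` is populated holds *scaled* layers.
    """

    layers: dict
    scaling: dict = field(default_factory=dict)
    flags: list = field(default_factory=list)

    def __post_init__(self) -> None:
        grids = list(self.layers.values())
        for g in grids[1:]:
            if not g.same_geometry(grids[0]):
                raise ValueError("all stack layers must share grid geometry")

    @property
    def template(self) -> RasterGrid:
        return next(iter(self.layers.values()))

    def resolve(self, name: str, season: str) -> RasterGrid:
        """Season-appropriate layer for a base covariate name."""
        seasonal = f"{name}_{season}"
        if seasonal in self.layers:
            return self.layers[seasonal]
        if name in self.layers:
            return self.layers[name]
        raise KeyError(f"no layer {name!r} (season {season!r}) in stack")

    def resolve_name(self, name: str, season: str) -> str:
        seasonal = f"{name}_{season}"
        return seasonal if seasonal in self.layers else name

    def base_names(self) -> list:
        seen: dict = {}
        for key in self.layers:
            base = key
            for suf in ("_wet", "_dry"):
                if key.endswith(suf):
                    base = key[: -len(suf)]
            seen.setdefault(base, None)
        return list(seen)


# ---------------------------------------------------------------------------
# Derived layers
# ---------------------------------------------------------------------------

def _disc_kernel(radius: float, cell_size: float) -> np.ndarray:
    """Boolean closed-disc footprint (distance from center <= radius)."""
    r_cells = int(np.floor(radius / cell_size))
    offs = np.arange(-r_cells, r_cells + 1)
    dx, dy = np.meshgrid(offs, offs)
    return (dx * dx + dy * dy) * cell_size**2 <= radius**2 + 1e-9


def percent_cover(binary_cover: RasterGrid, radius: float, template: RasterGrid | None = None) -> RasterGrid:
    """Percent of pixels classified as cover within a closed disc of ``radius``.

    With ``template=None`` the disc is centered at every input cell; otherwise
    it is centered at the template's cell centers (exact pixel enumeration).
    Only in-bounds pixels enter numerator and denominator.
    """
    vals = binary_cover.values
    if not np.all(np.isin(vals[~binary_cover.is_nodata()], (0.0, 1.0))):
        raise ValueError("binary_cover values must be in {0, 1}")
    if radius < binary_cover.cell_size:
        raise ValueError("radius must be >= the fine cell size")
    if template is None:
        kernel = _disc_kernel(radius, binary_cover.cell_size).astype(float)
        num = ndimage.convolve(vals, kernel, mode="constant", cval=0.0)
        den = ndimage.convolve(np.ones_like(vals), kernel, mode="constant", cval=0.0)
        return binary_cover.copy_with(100.0 * num / den)
    # exact enumeration against the fine pixel centers
    fx, fy = binary_cover.cell_centers()
    pix = np.column_stack([fx.ravel(), fy.ravel()])
    tree = cKDTree(pix)
    cx, cy = template.cell_centers()
    centers = np.column_stack([cx.ravel(), cy.ravel()])
    out = np.empty(len(centers))
    flat = vals.ravel()
    for i, c in enumerate(centers):
        idx = tree.query_ball_point(c, radius)
        out[i] = 100.0 * flat[idx].sum() / len(idx) if idx else np.nan
    return template.copy_with(out.reshape(template.values.shape))


def terrain_ruggedness_index(dem: RasterGrid) -> RasterGrid:
    """TRI: sqrt of the summed squared elevation differences to the 8 neighbors.

    Edge cells use only their in-bounds neighbors.
    """
    if dem.nrow < 3 or dem.ncol < 3:
        raise ValueError("DEM must be at least 3x3")
    z = dem.values
    acc = np.zeros_like(z)
    for dr in (-1, 0, 1):
        for dc in (-1, 0, 1):
            if dr == 0 and dc == 0:
                continue
            shifted = np.full_like(z, np.nan)
            rs = slice(max(dr, 0), z.shape[0] + min(dr, 0))
            rd = slice(max(-dr, 0), z.shape[0] + min(-dr, 0))
            cs = slice(max(dc, 0), z.shape[1] + min(dc, 0))
            cd = slice(max(-dc, 0), z.shape[1] + min(-dc, 0))
            shifted[rd, cd] = z[rs, cs]
            diff = shifted - z
            acc += np.where(np.isnan(diff), 0.0, diff**2)
    return dem.copy_with(np.sqrt(acc))


def distance_raster(points: PointSet, template: RasterGrid) -> RasterGrid:
    """Euclidean distance (m) from each cell center to the nearest point."""
    if len(points) == 0:
        raise ValueError("point set is empty")
    cx, cy = template.cell_centers()
    tree = cKDTree(points.points)
    d, _ = tree.query(np.column_stack([cx.ravel(), cy.ravel()]))
    return template.copy_with(d.reshape(template.values.shape), season_tag=points.season_tag)


def density_raster(points: PointSet, template: RasterGrid, radius: float) -> RasterGrid:
    """Count of points within a closed disc of ``radius`` around each cell center."""
    if not radius > 0:
        raise ValueError("radius must be > 0")
    cx, cy = template.cell_centers()
    centers = np.column_stack([cx.ravel(), cy.ravel()])
    if len(points) == 0:
        counts = np.zeros(len(centers))
    else:
        tree = cKDTree(points.points)
        counts = tree.query_ball_point(centers, radius, return_length=True).astype(float)
    return template.copy_with(counts.reshape(template.values.shape), season_tag=points.season_tag)


def distance_to_polyline(line: LineString, template: RasterGrid) -> RasterGrid:
    """Distance (m) from each cell center to a polyline (e.g. a river course)."""
    import shapely

    cx, cy = template.cell_centers()
    pts = shapely.points(np.column_stack([cx.ravel(), cy.ravel()]))
    d = shapely.distance(pts, line)
    return template.copy_with(d.reshape(template.values.shape))


# ---------------------------------------------------------------------------
# Scaling and extraction
# ---------------------------------------------------------------------------

def scale_covariates(stack: CovariateStack) -> CovariateStack:
    """Center and scale every layer; store the (mean, sd) constants.

    Seasonal layers are scaled with their own constants.  A constant layer
    (fewer than two distinct non-nodata values) is an error.
    """
    layers, scaling = {}, {}
    for name, grid in stack.layers.items():
        mask = grid.is_nodata()
        vals = grid.values[~mask]
        if np.unique(vals).size < 2:
            raise ValueError(f"layer {name!r} is constant; cannot scale")
        mean = float(vals.mean())
        sd = float(vals.std(ddof=0))
        scaled = np.where(mask, grid.nodata, (grid.values - mean) / sd)
        layers[name] = grid.copy_with(scaled)
        scaling[name] = (mean, sd)
    return CovariateStack(layers=layers, scaling=scaling, flags=list(stack.flags))


def unscale(stack: CovariateStack, name: str, values):
    """Invert the stored centering/scaling for one layer."""
    mean, sd = stack.scaling[name]
    return np.asarray(values) * sd + mean


def extract_covariates(stack: CovariateStack, x, y, season: str, names=None) -> dict:
    """Sample the season-appropriate layers at (x, y).

    Returns a dict of base covariate name -> value (array for vector input);
    nodata propagates as NaN.  Out-of-extent coordinates raise.
    """
    if names is None:
        names = [n for n in BASE_COVARIATES if _has_base(stack, n)]
    return {n: stack.resolve(n, season).sample(x, y) for n in names}


def _has_base(stack: CovariateStack, name: str) -> bool:
    return any(k in stack.layers for k in (name, f"{name}_wet", f"{name}_dry"))


def extract_matrix(stack: CovariateStack, xs, ys, seasons, names) -> np.ndarray:
    """Vectorized extraction: (n, len(names)) matrix, season-aware per row."""
    xs = np.asarray(xs, dtype=float)
    ys = np.asarray(ys, dtype=float)
    seasons = np.asarray(seasons)
    out = np.empty((xs.size, len(names)))
    for season in np.unique(seasons):
        m = seasons == season
        for j, name in enumerate(names):
            out[m, j] = stack.resolve(name, season).sample(xs[m], ys[m])
    return out


# ---------------------------------------------------------------------------
# Synthetic landscape generator
# ---------------------------------------------------------------------------

@dataclass
class LandscapeParams:
    """Generator settings for the synthetic rangeland.

    Defaults emulate a heterogeneous ~30x30 km slice of savannah: patchy
    shrub/forest cover averaging ~30%, moderate relief, a meandering river,
    clustered bomas of which most vacate the western plains in the wet season.
    """

    n_bomas_dry: int = 150
    n_boma_clusters: int = 12
    boma_cluster_sd: float = 1500.0  # m
    vacate_fraction: float = 0.85
    n_water_points: int = 40
    patch_scale: float = 1500.0  # correlation length of cover/EVI fields, m
    dem_relief: float = 250.0  # m, sd of the smoothed elevation field
    density_radii_km: tuple = (1.0, 3.0, 5.0)


def _smooth_field(rng: np.random.Generator, shape, sigma_cells: float) -> np.ndarray:
    """Smooth correlated Gaussian field, standardized to mean 0 / sd 1."""
    z = ndimage.gaussian_filter(rng.standard_normal(shape), sigma_cells, mode="reflect")
    return (z - z.mean()) / z.std()


def _random_river(rng: np.random.Generator, bounds, n_vertices: int = 14) -> LineString:
    xmin, ymin, xmax, ymax = bounds
    xs = np.linspace(xmin, xmax, n_vertices)
    ys = np.empty(n_vertices)
    ys[0] = rng.uniform(ymin + 0.3 * (ymax - ymin), ymin + 0.7 * (ymax - ymin))
    amp = 0.12 * (ymax - ymin)
    for i in range(1, n_vertices):
        ys[i] = np.clip(ys[i - 1] + rng.normal(0, amp), ymin, ymax)
    return LineString(np.column_stack([xs, ys]))


def generate_synthetic_landscape(
    seed: int,
    extent: tuple = (30_000.0, 30_000.0),
    cell_size: float = 200.0,
    params: LandscapeParams | None = None,
):
    """Build a raw (unscaled) synthetic covariate stack plus its point sets.

    Returns ``(stack, pointsets, study_area, vacate_polygon)`` where
    ``pointsets`` maps {bomas_dry, bomas_wet, water, river} to PointSets and
    ``vacate_polygon`` is the wet-season vacated sub-region (western plains).
    """
    params = params or LandscapeParams()
    width, height = extent
    ncol = int(round(width / cell_size))
    nrow = int(round(height / cell_size))
    if ncol < 50 or nrow < 50:
        raise ValueError("degenerate extent: need at least 50x50 cells")
    rng = np.random.default_rng(seed)
    template = RasterGrid(np.zeros((nrow, ncol)), origin_x=0.0, origin_y=height, cell_size=cell_size)
    sigma = params.patch_scale / cell_size

    # cover: logistic transform of a smooth field, percent in [0, 100]
    cover = 100.0 / (1.0 + np.exp(-(1.3 * _smooth_field(rng, (nrow, ncol), sigma) - 0.9)))
    # terrain: smooth DEM (more rugged in the east) -> TRI
    dem_z = _smooth_field(rng, (nrow, ncol), sigma * 1.5)
    east = np.linspace(0.2, 1.0, ncol)[None, :]
    dem = params.dem_relief * (dem_z * east) + 1500.0
    tri = terrain_ruggedness_index(template.copy_with(dem))
    # EVI: wet season greener on average than dry
    evi_dry = np.clip(0.22 + 0.07 * _smooth_field(rng, (nrow, ncol), sigma), 0.01, None)
    evi_wet = np.clip(evi_dry + 0.14 + 0.04 * _smooth_field(rng, (nrow, ncol), sigma), 0.01, None)
    # river course and distance layer
    river = _random_river(rng, template.bounds)
    dist_river = distance_to_polyline(river, template)

    study_area = box(*template.bounds)
    # western plains: vacated by herders in the wet season
    xmin, ymin, xmax, ymax = template.bounds
    vacate_polygon = box(xmin, ymin, xmin + 0.4 * (xmax - xmin), ymax)

    bomas_dry, bomas_wet = place_bomas_seasonal(
        study_area,
        params.n_bomas_dry,
        vacate_polygon,
        params.vacate_fraction,
        seed=int(rng.integers(2**31)),
        n_clusters=params.n_boma_clusters,
        cluster_sd=params.boma_cluster_sd,
    ) if params.n_bomas_dry > 0 else (
        PointSet(np.empty((0, 2)), "boma", "dry"),
        PointSet(np.empty((0, 2)), "boma", "wet"),
    )
    water = PointSet(
        np.column_stack([rng.uniform(xmin, xmax, params.n_water_points), rng.uniform(ymin, ymax, params.n_water_points)]),
        "water",
    )

    layers = {
        "cover": template.copy_with(cover),
        "tri": tri,
        "evi_wet": template.copy_with(evi_wet, season_tag="wet"),
        "evi_dry": template.copy_with(evi_dry, season_tag="dry"),
        "dist_river": dist_river,
    }
    flags = []
    for season, bomas in (("dry", bomas_dry), ("wet", bomas_wet)):
        if len(bomas) == 0:
            nod = template.copy_with(np.full((nrow, ncol), template.nodata), season_tag=season)
            layers[f"dist_human_{season}"] = nod
            flags.append(f"dist_human_{season}:all_nodata")
            for r in params.density_radii_km:
                layers[f"dens_human_{r:g}km_{season}"] = template.copy_with(np.zeros((nrow, ncol)), season_tag=season)
        else:
            layers[f"dist_human_{season}"] = distance_raster(bomas, template)
            for r in params.density_radii_km:
                layers[f"dens_human_{r:g}km_{season}"] = density_raster(bomas, template, r * 1000.0)
    if params.n_water_points > 0:
        layers["dist_water"] = distance_raster(water, template)

    stack = CovariateStack(layers=layers, flags=flags)
    pointsets = {
        "bomas_dry": bomas_dry,
        "bomas_wet": bomas_wet,
        "water": water,
        "river": PointSet(np.asarray(river.coords), "river_vertex"),
    }
    return stack, pointsets, study_area, vacate_polygon


def place_bomas_seasonal(
    region: Polygon,
    n_dry: int,
    vacate_polygon: Polygon,
    vacate_fraction: float,
    seed: int,
    n_clusters: int = 12,
    cluster_sd: float = 1500.0,
):
    """Clustered dry-season boma points; a random ``vacate_fraction`` of those
    inside ``vacate_polygon`` are removed to form the wet-season set."""
    import shapely

    if n_dry <= 0:
        raise ValueError("n_dry must be positive")
    if not (0.0 <= vacate_fraction <= 1.0):
        raise ValueError("vacate_fraction must be in [0, 1]")
    rng = np.random.default_rng(seed)
    xmin, ymin, xmax, ymax = region.bounds
    parents = np.column_stack([rng.uniform(xmin, xmax, n_clusters), rng.uniform(ymin, ymax, n_clusters)])
    pts = []
    while len(pts) < n_dry:
        parent = parents[rng.integers(n_clusters)]
        cand = parent + rng.normal(0, cluster_sd, 2)
        if region.contains(shapely.points(cand)):
            pts.append(cand)
    dry = np.array(pts)
    inside = shapely.contains(vacate_polygon, shapely.points(dry))
    remove = inside & (rng.uniform(size=n_dry) < vacate_fraction)
    wet = dry[~remove]
    return PointSet(dry, "boma", "dry"), PointSet(wet, "boma", "wet")
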