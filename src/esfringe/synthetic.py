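"""Seeded synthetic two-date landscapes and village ES matrices.

The generator emulates a polycentric metropolitan region: one or more urban
cores whose socio-economic intensity (population, GDP, nighttime light,
built-up share) decays with distance, a fringe ring that widens between the
two dates, large contiguous water bodies, climate and erosion-factor input
layers at a fine (ES) resolution nested inside the 1-km feature grid, a
Voronoi village tessellation, and village ES vectors drawn from planted
bundle archetypes.  Everything is driven by a single splittable seed, so
identical scenarios are bit-identical across runs.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import ndimage

from .grids import (
    LAND_USE_CODES,
    LandscapeStack,
    RasterLayer,
    VillageTessellation,
    broadcast_to_fine,
)
from .zonation import (
    FEATURE_NAMES,
    FRINGE,
    RURAL,
    URBAN,
    PoiFunctionConfig,
    ZoneMap,
    assemble_features,
    mask_water,
)

ES_NAMES = ("FP", "CS", "WY", "SC", "TN", "TP", "HQ", "LA")
#: SOM/archetype orientation: TN/TP appear as purification scores (higher = better)
SOM_NAMES = ("FP", "CS", "WY", "SC", "TNp", "TPp", "HQ", "LA")

POI_CATEGORIES = ("commercial", "public", "industrial", "transport", "residential")


@dataclass
class LandscapeScenario:
    """Parameters of one synthetic two-date landscape.

    The coarse grid (``grid_rows`` x ``grid_cols`` cells of ``cell_size_m``)
    is the 1-km feature/zonation grid; every coarse cell is refined into
    ``refine_factor`` x ``refine_factor`` fine cells for the ES layers
    (default 33, i.e. ~30 m subcells in 1-km cells).
    """

    grid_rows: int = 32
    grid_cols: int = 32
    cell_size_m: float = 1000.0
    refine_factor: int = 33
    n_cores: int = 2
    core_centers: list[tuple[float, float]] | None = None  # (row, col) coarse coords
    decay_length_cells: float = 5.0
    urban_radius_cells: float = 4.0
    fringe_radius_cells: float = 8.0
    expansion_factor: float = 0.5
    water_fraction: float = 0.08
    noise_sd: float = 0.1
    n_poi: int = 800
    n_villages: int = 90
    seed: int = 0

    def __post_init__(self) -> None:
        if self.grid_rows < 8 or self.grid_cols < 8:
            raise ValueError("grid must be at least 8x8")
        if not (0.0 <= self.water_fraction < 0.5):
            raise ValueError("water_fraction must lie in [0, 0.5)")
        if self.expansion_factor < 0:
            raise ValueError("expansion_factor must be >= 0")
        if self.core_centers is not None:
            for r, c in self.core_centers:
                if not (0 <= r < self.grid_rows and 0 <= c < self.grid_cols):
                    raise ValueError("core center outside grid")

    @property
    def fine_shape(self) -> tuple[int, int]:
        return (self.grid_rows * self.refine_factor,
                self.grid_cols * self.refine_factor)

    @property
    def fine_cell_size_m(self) -> float:
        return self.cell_size_m / self.refine_factor


# ---------------------------------------------------------------------------
# helpers


def _smooth_field(rng: np.random.Generator, shape: tuple[int, int],
                  sigma: float) -> np.ndarray:
    """Spatially correlated field in [0, 1] from smoothed white noise."""
    f = ndimage.gaussian_filter(rng.standard_normal(shape), sigma=sigma)
    lo, hi = f.min(), f.max()
    return (f - lo) / (hi - lo) if hi > lo else np.zeros(shape)


def _core_centers(scenario: LandscapeScenario,
                  rng: np.random.Generator) -> np.ndarray:
    if scenario.core_centers is not None:
        return np.asarray(scenario.core_centers, dtype=float)
    margin = 0.25
    rows = rng.uniform(margin * scenario.grid_rows, (1 - margin) * scenario.grid_rows,
                       scenario.n_cores)
    cols = rng.uniform(margin * scenario.grid_cols, (1 - margin) * scenario.grid_cols,
                       scenario.n_cores)
    return np.column_stack([rows, cols])


def core_distance(shape: tuple[int, int], centers: np.ndarray,
                  scale: float = 1.0) -> np.ndarray:
    """Distance (in coarse-cell units) from each cell centre to the nearest core.

    ``scale`` converts the grid's own cell units to coarse units (e.g.
    1/refine_factor for a fine grid).
    """
    ii, jj = np.indices(shape)
    r = (ii + 0.5) * scale
    c = (jj + 0.5) * scale
    d = np.full(shape, np.inf)
    for cr, cc in centers:
        d = np.minimum(d, np.hypot(r - (cr + 0.5), c - (cc + 0.5)))
    return d


def _grow_water_patches(scenario: LandscapeScenario,
                        rng: np.random.Generator) -> np.ndarray:
    """Contiguous water patches covering ~ water_fraction of coarse cells."""
    shape = (scenario.grid_rows, scenario.grid_cols)
    target = int(round(scenario.water_fraction * shape[0] * shape[1]))
    water = np.zeros(shape, dtype=bool)
    if target == 0:
        return water
    n_patches = max(1, target // 30)
    per_patch = target // n_patches
    for _ in range(n_patches):
        seed_cell = (int(rng.integers(shape[0])), int(rng.integers(shape[1])))
        frontier = [seed_cell]
        grown = 0
        while frontier and grown < per_patch:
            k = int(rng.integers(len(frontier)))
            i, j = frontier.pop(k)
            if water[i, j]:
                continue
            water[i, j] = True
            grown += 1
            for di, dj in ((1, 0), (-1, 0), (0, 1), (0, -1)):
                ni, nj = i + di, j + dj
                if 0 <= ni < shape[0] and 0 <= nj < shape[1] and not water[ni, nj]:
                    frontier.append((ni, nj))
    return water


def _zone_truth(dist: np.ndarray, urban_r: float, fringe_r: float) -> np.ndarray:
    zones = np.full(dist.shape, RURAL, dtype=float)
    zones[dist <= fringe_r] = FRINGE
    zones[dist <= urban_r] = URBAN
    return zones


# land-use-conditioned ES coefficients used when painting input layers
_AET_FRACTION = {1: 0.60, 2: 0.70, 3: 0.62, 4: 0.85, 5: 0.95, 6: 0.35, 7: 0.45}
_USLE_CF = {1: 0.25, 2: 0.003, 3: 0.05, 4: 0.01, 5: 0.0, 6: 0.001, 7: 0.6}
_USLE_P = {1: 0.35, 2: 1.0, 3: 1.0, 4: 1.0, 5: 0.0, 6: 0.01, 7: 1.0}
_POL_N = {1: 15.0, 2: 2.0, 3: 4.0, 4: 1.0, 5: 0.5, 6: 10.0, 7: 3.0}
_POL_P = {1: 2.0, 2: 0.2, 3: 0.4, 4: 0.1, 5: 0.05, 6: 1.5, 7: 0.3}


def _by_land_use(land_use: np.ndarray, table: dict[int, float]) -> np.ndarray:
    lut = np.zeros(max(table) + 1)
    for code, val in table.items():
        lut[code] = val
    return lut[land_use.astype(int)]


def _generate_land_use(
    scenario: LandscapeScenario,
    dist_fine: np.ndarray,
    water_fine: np.ndarray,
    builtup_threshold: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Fine-grid categorical land use conditioned on core distance and water."""
    shape = dist_fine.shape
    f_built = _smooth_field(rng, shape, sigma=scenario.refine_factor / 2)
    f_veg = _smooth_field(rng, shape, sigma=scenario.refine_factor)
    f_bare = _smooth_field(rng, shape, sigma=scenario.refine_factor / 3)

    score = np.exp(-dist_fine / scenario.decay_length_cells) + 0.15 * (f_built - 0.5)
    lu = np.full(shape, LAND_USE_CODES["cropland"], dtype=float)
    lu[f_veg > 0.78] = LAND_USE_CODES["forest"]
    lu[(f_veg > 0.62) & (f_veg <= 0.78)] = LAND_USE_CODES["grassland"]
    lu[f_bare > 0.985] = LAND_USE_CODES["bare"]
    lu[score > builtup_threshold] = LAND_USE_CODES["builtup"]
    # wetland fringes adjacent to large water
    near_water = ndimage.binary_dilation(water_fine, iterations=scenario.refine_factor // 4 + 1)
    lu[near_water & ~water_fine & (f_veg > 0.5)] = LAND_USE_CODES["wetland"]
    lu[water_fine] = LAND_USE_CODES["water"]
    # scattered small ponds (kept below the masking threshold)
    pond = _smooth_field(rng, shape, sigma=2) > 0.995
    lu[pond & ~water_fine] = LAND_USE_CODES["water"]
    return lu


def _build_stack(
    scenario: LandscapeScenario,
    date_tag: str,
    centers: np.ndarray,
    water_coarse: np.ndarray,
    decay: float,
    builtup_threshold: float,
    seeds: list[np.random.Generator],
) -> LandscapeStack:
    rows, cols = scenario.grid_rows, scenario.grid_cols
    fshape = scenario.fine_shape
    rf = scenario.refine_factor
    fine_cell = scenario.fine_cell_size_m

    rng_int, rng_lu, rng_clim, rng_poi = seeds

    dist_coarse = core_distance((rows, cols), centers)
    dist_fine = core_distance(fshape, centers, scale=1.0 / rf)
    water_fine = broadcast_to_fine(water_coarse, rf).astype(bool)

    def noisy(base: np.ndarray, rng: np.random.Generator) -> np.ndarray:
        if scenario.noise_sd == 0:
            return base
        return np.clip(base * (1.0 + scenario.noise_sd * rng.standard_normal(base.shape)), 0, None)

    base = np.exp(-dist_coarse / decay)
    pop = noisy(50.0 + 8000.0 * base, rng_int)
    gdp = noisy(2.0 + 600.0 * base, rng_int)          # million currency / km^2
    ntl = noisy(1.0 + 60.0 * base, rng_int)

    land_use = _generate_land_use(scenario, dist_fine, water_fine,
                                  builtup_threshold, rng_lu)

    # climate: gentle north-south gradients plus correlated noise
    ii = np.indices(fshape)[0] / fshape[0]
    temp = 15.5 + 2.0 * ii + 1.0 * (_smooth_field(rng_clim, fshape, rf) - 0.5)
    precip = 1100.0 + 250.0 * (1 - ii) + 120.0 * (_smooth_field(rng_clim, fshape, rf) - 0.5)
    aet = precip * _by_land_use(land_use, _AET_FRACTION) \
        * (0.9 + 0.2 * _smooth_field(rng_clim, fshape, rf))

    usle_R = 0.18 * precip + 20.0 * _smooth_field(rng_clim, fshape, rf)
    usle_K = 0.2 + 0.2 * _smooth_field(rng_clim, fshape, rf)
    d_max = dist_fine.max() or 1.0
    usle_LS = 0.5 + 6.0 * (dist_fine / d_max) ** 2 \
        + 2.0 * _smooth_field(rng_clim, fshape, rf)
    usle_Cf = _by_land_use(land_use, _USLE_CF)
    usle_P = _by_land_use(land_use, _USLE_P)

    hss = 0.4 + 0.8 * _smooth_field(rng_clim, fshape, rf)
    pol_N = _by_land_use(land_use, _POL_N)
    pol_P = _by_land_use(land_use, _POL_P)

    # landscape aesthetics: smooth suitability peaking near the cores
    la = np.exp(-dist_fine / (1.5 * scenario.decay_length_cells))
    la = la + 0.1 * (_smooth_field(rng_clim, fshape, rf) - 0.5)
    la = np.clip((la - la.min()) / (la.max() - la.min() + 1e-12), 0, 1)

    def fine_layer(values: np.ndarray, name: str, units: str = "") -> RasterLayer:
        return RasterLayer(values=values, name=name, units=units,
                           cell_size_m=fine_cell)

    layers = {
        "land_use": fine_layer(land_use, "land_use", "category"),
        "population_density": fine_layer(broadcast_to_fine(pop, rf),
                                         "population_density", "persons/km2"),
        "gdp_density": fine_layer(broadcast_to_fine(gdp, rf),
                                  "gdp_density", "Mcurrency/km2"),
        "ntl": fine_layer(broadcast_to_fine(ntl, rf), "ntl", "relative radiance"),
        "temperature": fine_layer(temp, "temperature", "degC"),
        "precipitation": fine_layer(precip, "precipitation", "mm"),
        "aet": fine_layer(aet, "aet", "mm"),
        "usle_R": fine_layer(usle_R, "usle_R", "MJ.mm/(hm2.h.a)"),
        "usle_K": fine_layer(usle_K, "usle_K", "t.h/(MJ.mm)"),
        "usle_LS": fine_layer(usle_LS, "usle_LS", "dimensionless"),
        "usle_Cf": fine_layer(usle_Cf, "usle_Cf", "dimensionless"),
        "usle_P": fine_layer(usle_P, "usle_P", "dimensionless"),
        "hss": fine_layer(hss, "hss", "dimensionless"),
        "pol_N": fine_layer(pol_N, "pol_N", "kg/(ha.a)"),
        "pol_P": fine_layer(pol_P, "pol_P", "kg/(ha.a)"),
        "la": fine_layer(la, "la", "suitability [0,1]"),
    }

    # POIs: locations drawn with probability proportional to intensity
    w = (base + 0.02).ravel()
    w /= w.sum()
    n_poi = scenario.n_poi
    cells = rng_poi.choice(rows * cols, size=n_poi, p=w)
    ci, cj = np.unravel_index(cells, (rows, cols))
    px = (cj + rng_poi.random(n_poi)) * scenario.cell_size_m
    py = (ci + rng_poi.random(n_poi)) * scenario.cell_size_m
    cat = rng_poi.choice(POI_CATEGORIES, size=n_poi,
                         p=(0.3, 0.2, 0.15, 0.15, 0.2))
    poi = pd.DataFrame({"x": px, "y": py, "category": cat})

    return LandscapeStack(date_tag=date_tag, layers=layers, poi=poi)


# ---------------------------------------------------------------------------
# public API


def generate_landscape_pair(
    scenario: LandscapeScenario,
) -> tuple[LandscapeStack, LandscapeStack, ZoneMap, ZoneMap]:
    """Generate two aligned landscape stacks and their ground-truth zone maps.

    Ground-truth zones come from distance thresholds around the cores on the
    noiseless intensity field; between the dates the fringe's outer radius
    grows by ``expansion_factor`` (and the urban core by a quarter of it),
    emulating fringe-dominated outward expansion.
    """
    ss = np.random.SeedSequence(scenario.seed)
    children = [np.random.default_rng(s) for s in ss.spawn(10)]
    rng_layout = children[0]

    centers = _core_centers(scenario, rng_layout)
    water_coarse = _grow_water_patches(scenario, rng_layout)

    r_u0, r_f0 = scenario.urban_radius_cells, scenario.fringe_radius_cells
    r_u1 = r_u0 * (1.0 + 0.25 * scenario.expansion_factor)
    r_f1 = r_f0 * (1.0 + scenario.expansion_factor)

    dist = core_distance((scenario.grid_rows, scenario.grid_cols), centers)
    z0 = ZoneMap(_zone_truth(dist, r_u0, r_f0), date_tag="t0",
                 cell_size_m=scenario.cell_size_m)
    z1 = ZoneMap(_zone_truth(dist, r_u1, r_f1), date_tag="t1",
                 cell_size_m=scenario.cell_size_m)

    decay0 = scenario.decay_length_cells
    decay1 = scenario.decay_length_cells * (1.0 + 0.5 * scenario.expansion_factor)
    thr0 = np.exp(-scenario.fringe_radius_cells / decay0) * 2.2
    thr1 = np.exp(-r_f1 / decay1) * 2.2

    stack0 = _build_stack(scenario, "t0", centers, water_coarse, decay0, thr0,
                          children[1:5])
    stack1 = _build_stack(scenario, "t1", centers, water_coarse, decay1, thr1,
                          children[5:9])
    return stack0, stack1, z0, z1


def generate_villages(scenario: LandscapeScenario) -> VillageTessellation:
    """Seeded Voronoi tessellation of the coarse grid into villages."""
    ss = np.random.SeedSequence(scenario.seed)
    rng = np.random.default_rng(ss.spawn(10)[9])
    rows, cols = scenario.grid_rows, scenario.grid_cols
    n = min(scenario.n_villages, rows * cols)
    sites_r = rng.uniform(0, rows, n)
    sites_c = rng.uniform(0, cols, n)
    ii, jj = np.indices((rows, cols))
    d = (ii[..., None] + 0.5 - sites_r) ** 2 + (jj[..., None] + 0.5 - sites_c) ** 2
    labels = d.argmin(axis=-1) + 1
    ids = np.unique(labels)
    return VillageTessellation(labels=labels, ids=ids,
                               cell_size_m=scenario.cell_size_m)


def generate_labeled_points(
    stack: LandscapeStack,
    truth: ZoneMap,
    n: int,
    seed: int,
    refine_factor: int | None = None,
    balanced: bool = False,
    poi_config: PoiFunctionConfig | None = None,
    min_water_km2: float = 1.0,
) -> pd.DataFrame:
    """Sample n labeled points with their six classification features.

    Points fall uniformly over non-water-masked coarse cells (class-balanced
    sampling optionally); each carries the containing cell's features and
    its ground-truth class.  This stands in for the manual expert-labeling
    protocol that real studies use.
    """
    if n < 30:
        raise ValueError("need at least 30 labeled points")
    if refine_factor is None:
        refine_factor = round(stack.shape[0] / truth.values.shape[0])
    water = mask_water(stack, min_area_km2=min_water_km2)
    feats = assemble_features(stack, refine_factor, mask=water, config=poi_config)
    valid = ~feats.mask & truth.valid_mask
    cells = np.flatnonzero(valid.ravel())
    if cells.size == 0:
        raise ValueError("no valid cells to sample")
    rng = np.random.default_rng(seed)
    labels_flat = truth.values.ravel()
    if balanced:
        chosen: list[np.ndarray] = []
        per = n // 3
        for cls in (RURAL, FRINGE, URBAN):
            pool = cells[labels_flat[cells] == cls]
            if pool.size == 0:
                raise ValueError(f"class {cls} absent from valid cells")
            chosen.append(rng.choice(pool, size=per, replace=True))
        rest = rng.choice(cells, size=n - 3 * per, replace=True)
        idx = np.concatenate(chosen + [rest])
    else:
        idx = rng.choice(cells, size=n, replace=True)
    ri, ci = np.unravel_index(idx, feats.shape)
    X = feats.features_at(ri, ci)
    x = (ci + rng.random(n)) * feats.cell_size_m
    y = (ri + rng.random(n)) * feats.cell_size_m
    df = pd.DataFrame(X, columns=list(FEATURE_NAMES))
    df.insert(0, "y", y)
    df.insert(0, "x", x)
    df["label"] = labels_flat[idx].astype(int)
    return df


# ---------------------------------------------------------------------------
# planted ES bundle archetypes


#: normalized archetype means on the SOM orientation (TNp/TPp = purification)
DEFAULT_ARCHETYPES: dict[str, tuple[float, ...]] = {
    "key trade-offs":      (0.10, 0.10, 0.90, 0.10, 0.20, 0.20, 0.10, 0.90),
    "mild trade-offs":     (0.25, 0.40, 0.80, 0.40, 0.45, 0.45, 0.40, 0.75),
    "key synergistic":     (0.80, 0.80, 0.75, 0.80, 0.80, 0.80, 0.80, 0.80),
    "CS-HQ-LA":            (0.30, 0.90, 0.30, 0.50, 0.50, 0.50, 0.85, 0.85),
    "HQ-LA":               (0.30, 0.50, 0.30, 0.80, 0.50, 0.50, 0.85, 0.90),
    "water purification":  (0.35, 0.40, 0.50, 0.30, 0.95, 0.95, 0.50, 0.40),
    "FP":                  (0.95, 0.40, 0.30, 0.35, 0.40, 0.40, 0.35, 0.30),
}


@dataclass
class BundleArchetypeLibrary:
    """Named mean ES profiles used to plant recoverable village bundles."""

    archetypes: dict[str, np.ndarray] = field(
        default_factory=lambda: {k: np.asarray(v) for k, v in DEFAULT_ARCHETYPES.items()}
    )
    within_sd: float = 0.05

    def __post_init__(self) -> None:
        if len(set(self.archetypes)) != len(self.archetypes):
            raise ValueError("archetype names must be unique")
        for name, m in self.archetypes.items():
            m = np.asarray(m, dtype=float)
            if m.shape != (8,) or (m < 0).any() or (m > 1).any():
                raise ValueError(f"archetype {name!r} mean must lie in [0,1]^8")
            self.archetypes[name] = m

    @property
    def names(self) -> list[str]:
        return list(self.archetypes)


def scaled_mean(mean: np.ndarray, separation: float) -> np.ndarray:
    """Contrast-scale an archetype mean about the hypercube centre, clipped."""
    return np.clip(0.5 + separation * (mean - 0.5), 0.0, 1.0)


def generate_village_es_matrix(
    library: BundleArchetypeLibrary,
    n_per_archetype: int,
    separation: float = 1.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Village ES vectors drawn from planted archetypes.

    Each row is its archetype's contrast-scaled mean plus Gaussian noise of
    scale ``within_sd``, clipped to [0,1]; the ground-truth archetype is
    kept in the ``archetype`` column.
    """
    if not library.archetypes:
        raise ValueError("empty archetype library")
    if n_per_archetype < 2:
        raise ValueError("need at least 2 villages per archetype")
    if separation <= 0:
        raise ValueError("separation must be positive")
    rng = np.random.default_rng(seed)
    rows, names = [], []
    for name, mean in library.archetypes.items():
        m = scaled_mean(mean, separation)
        noise = library.within_sd * rng.standard_normal((n_per_archetype, 8))
        rows.append(np.clip(m + noise, 0.0, 1.0))
        names.extend([name] * n_per_archetype)
    df = pd.DataFrame(np.vstack(rows), columns=list(SOM_NAMES))
    df.insert(0, "village_id", np.arange(1, len(df) + 1))
    df["archetype"] = names
    return df
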