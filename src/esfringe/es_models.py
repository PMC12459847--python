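"""Eight ecosystem-service indicator layers at the fine (ES) resolution.

Implemented services: food production (FP, Miami/Thornthwaite-Memorial
climatic production potential scaled by a land-use revision coefficient),
carbon storage (CS, four-pool lookup), water yield (WY, precipitation minus
actual evapotranspiration), soil conservation (SC, USLE-factor retention),
nitrogen and phosphorus output (TN/TP, hydrological-sensitivity-corrected
export coefficients — a disservice: more output means less purification),
habitat quality (HQ, suitability discounted by a saturating degradation
response), and landscape aesthetics (LA, accepted as a pre-computed
suitability layer).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .grids import CODE_TO_LAND_USE, LAND_USE_CODES, LandscapeStack, RasterLayer

log = logging.getLogger(__name__)

ES_NAMES = ("FP", "CS", "WY", "SC", "TN", "TP", "HQ", "LA")


# ---------------------------------------------------------------------------
# food production (Miami / Thornthwaite-Memorial)

#: production potential ceiling (kg/ha.a)
W_MAX = 30000.0


def production_potential_temperature(T: np.ndarray | float) -> np.ndarray | float:
    """Temperature-limited potential WT = 30000 / (1 + e^(1.315 - 0.119 T))."""
    return W_MAX / (1.0 + np.exp(1.315 - 0.119 * np.asarray(T, dtype=float)))


def production_potential_precipitation(
    R: np.ndarray | float, printed_form: bool = False
) -> np.ndarray | float:
    """Precipitation-limited potential WR.

    Default is the bounded multiplicative form 30000 (1 - e^(-0.000664 R)).
    ``printed_form`` switches to the division variant 30000 / (1 - e^(-0.000664 R)),
    which is unbounded as R -> 0 and retained only for fidelity checks.
    """
    R = np.asarray(R, dtype=float)
    term = 1.0 - np.exp(-0.000664 * R)
    return W_MAX / term if printed_form else W_MAX * term

def max_evapotranspiration(T: np.ndarray | float) -> np.ndarray | float:
    """Annual maximum evapotranspiration L = 300 + 25 T + 0.05 T^3 (mm)."""
    T = np.asarray(T, dtype=float)
    return 300.0 + 25.0 * T + 0.05 * T**3


def actual_evapotranspiration_estimate(
    R: np.ndarray | float, T: np.ndarray | float
) -> np.ndarray | float:
    """Turc-style actual evapotranspiration V = 1.05 R / sqrt(1 + (1.05 R / L)^2)."""
    L = max_evapotranspiration(T)
    x = 1.05 * np.asarray(R, dtype=float)
    return x / np.sqrt(1.0 + (x / L) ** 2)


def production_potential_evapotranspiration(
    V: np.ndarray | float, printed_form: bool = False
) -> np.ndarray | float:
    """Evapotranspiration-limited potential WV = 30000 (1 - e^(-0.0009695 (V - 20)))."""
    V = np.asarray(V, dtype=float)
    term = 1.0 - np.exp(-0.0009695 * (V - 20.0))
    return W_MAX / term if printed_form else W_MAX * term


def standard_production_potential(
    T: np.ndarray | float, R: np.ndarray | float, printed_form: bool = False
) -> np.ndarray | float:
    """Standard climatic production potential W = min(WT, WR, WV)."""
    WT = production_potential_temperature(T)
    WR = production_potential_precipitation(R, printed_form)
    V = actual_evapotranspiration_estimate(R, T)
    WV = production_potential_evapotranspiration(V, printed_form)
    return np.minimum(np.minimum(WT, WR), WV)


#: default integrated revision coefficients K_i per land-use code (placeholders,
#: land-use-keyed: only cropping systems realise the climatic potential)
DEFAULT_KI = {
    LAND_USE_CODES["cropland"]: 0.85,
    LAND_USE_CODES["forest"]: 0.10,
    LAND_USE_CODES["grassland"]: 0.25,
    LAND_USE_CODES["wetland"]: 0.15,
    LAND_USE_CODES["water"]: 0.05,
    LAND_USE_CODES["builtup"]: 0.02,
    LAND_USE_CODES["bare"]: 0.01,
}


def food_production(
    temperature: np.ndarray,
    precipitation: np.ndarray,
    land_use: np.ndarray,
    ki: dict[int, float] | None = None,
    printed_form: bool = False,
) -> np.ndarray:
    """FP layer: Y_i = W(T, R) * K_i(land use), kg/ha.a."""
    if not (np.isfinite(temperature).all() and np.isfinite(precipitation).all()):
        raise ValueError("non-finite climate inputs")
    ki = ki or DEFAULT_KI
    missing = set(np.unique(land_use).astype(int)) - set(ki)
    if missing:
        raise KeyError(f"K_i missing for land-use codes {sorted(missing)}")
    W = standard_production_potential(temperature, precipitation, printed_form)
    lut = np.zeros(max(ki) + 1)
    for code, k in ki.items():
        lut[code] = k
    return W * lut[land_use.astype(int)]


# ---------------------------------------------------------------------------
# soil conservation, water yield, carbon, nutrients


def soil_conservation(
    R_e: np.ndarray, K_e: np.ndarray, LS: np.ndarray,
    C_f: np.ndarray, P_f: np.ndarray,
) -> np.ndarray:
    """SC = R K LS (1 - C P), t/km^2, clamped at >= 0."""
    for name, a in (("R", R_e), ("K", K_e), ("LS", LS), ("C", C_f), ("P", P_f)):
        if np.nanmin(a) < 0:
            raise ValueError(f"negative USLE factor {name}")
    return np.clip(R_e * K_e * LS * (1.0 - C_f * P_f), 0.0, None)


def water_yield(P: np.ndarray, AET: np.ndarray) -> np.ndarray:
    """WY = (1 - AET/P) P = P - AET, clamped at >= 0; P = 0 yields 0 (mm)."""
    P = np.asarray(P, dtype=float)
    AET = np.asarray(AET, dtype=float)
    if np.nanmin(P) < 0 or np.nanmin(AET) < 0:
        raise ValueError("negative water-yield inputs")
    y = np.clip(P - AET, 0.0, None)
    return np.where(P == 0, 0.0, y)


#: default carbon pools (C_above, C_below, C_soil, C_dead), t/ha
DEFAULT_CARBON_POOLS = {
    LAND_USE_CODES["cropland"]:  (5.0, 1.0, 80.0, 0.5),
    LAND_USE_CODES["forest"]:    (60.0, 15.0, 120.0, 5.0),
    LAND_USE_CODES["grassland"]: (3.0, 6.0, 90.0, 1.0),
    LAND_USE_CODES["wetland"]:   (10.0, 5.0, 140.0, 2.0),
    LAND_USE_CODES["water"]:     (0.0, 0.0, 0.0, 0.0),
    LAND_USE_CODES["builtup"]:   (1.0, 0.5, 30.0, 0.0),
    LAND_USE_CODES["bare"]:      (0.5, 0.2, 20.0, 0.0),
}


def carbon_total(pools: tuple[float, float, float, float]) -> float:
    """Total stock C_tot = C_above + C_below + C_soil + C_dead (t/ha)."""
    if any(p < 0 for p in pools):
        raise ValueError("carbon pools must be non-negative")
    return float(sum(pools))


def carbon_storage(
    land_use: np.ndarray,
    pool_table: dict[int, tuple[float, float, float, float]] | None = None,
) -> np.ndarray:
    """CS layer: per-cell total carbon stock looked up by land use (t/ha)."""
    table = pool_table or DEFAULT_CARBON_POOLS
    missing = set(np.unique(land_use[np.isfinite(land_use)]).astype(int)) - set(table)
    if missing:
        raise KeyError(f"carbon pools missing for codes {sorted(missing)}")
    lut = np.zeros(max(table) + 1)
    for code, pools in table.items():
        lut[code] = carbon_total(pools)
    out = np.full(land_use.shape, np.nan)
    ok = np.isfinite(land_use)
    out[ok] = lut[land_use[ok].astype(int)]
    return out


def nutrient_export(hss: np.ndarray, pol: np.ndarray) -> np.ndarray:
    """Corrected nutrient output ALV = HSS * pol (kg/ha.a).

    Higher output means lower water-purification capacity.
    """
    if np.nanmin(hss) < 0 or np.nanmin(pol) < 0:
        raise ValueError("HSS and export coefficients must be non-negative")
    return hss * pol


# ---------------------------------------------------------------------------
# habitat quality


@dataclass
class ThreatSpec:
    """One habitat threat: source land-use code, weight, linear max distance."""

    source_code: int
    weight: float
    max_dist_m: float


@dataclass
class HabitatParams:
    """Habitat suitability per land use, threat roster and half-saturation k."""

    suitability: dict[int, float] = field(default_factory=lambda: {
        LAND_USE_CODES["cropland"]: 0.4,
        LAND_USE_CODES["forest"]: 1.0,
        LAND_USE_CODES["grassland"]: 0.7,
        LAND_USE_CODES["wetland"]: 0.9,
        LAND_USE_CODES["water"]: 0.8,
        LAND_USE_CODES["builtup"]: 0.0,
        LAND_USE_CODES["bare"]: 0.2,
    })
    threats: list[ThreatSpec] = field(default_factory=lambda: [
        ThreatSpec(LAND_USE_CODES["builtup"], 0.7, 3000.0),
        ThreatSpec(LAND_USE_CODES["cropland"], 0.3, 1000.0),
    ])
    k: float = 0.5

    def __post_init__(self) -> None:
        if self.k <= 0:
            raise ValueError("half-saturation constant k must be positive")
        for code, h in self.suitability.items():
            if not (0.0 <= h <= 1.0):
                raise ValueError(f"suitability for code {code} outside [0,1]")


def habitat_degradation(
    land_use: np.ndarray, params: HabitatParams, cell_size_m: float
) -> np.ndarray:
    """Degradation D in [0,1]: weighted linear-decay distance to threat sources.

    Threat weights are normalised to sum to 1; each threat contributes
    max(0, 1 - d/d_max) with d the Euclidean distance to its nearest source.
    """
    total_w = sum(t.weight for t in params.threats)
    if total_w <= 0:
        return np.zeros(land_use.shape)
    D = np.zeros(land_use.shape)
    for t in params.threats:
        if t.max_dist_m <= 0:
            raise ValueError("threat max distance must be positive")
        src = land_use == t.source_code
        if not src.any():
            continue
        dist = ndimage.distance_transform_edt(~src, sampling=cell_size_m)
        D += (t.weight / total_w) * np.clip(1.0 - dist / t.max_dist_m, 0.0, 1.0)
    return np.clip(D, 0.0, 1.0)


def habitat_quality(
    land_use: np.ndarray, D: np.ndarray, params: HabitatParams
) -> np.ndarray:
    """HQ layer: Q = H_j (1 - D^2 / (D^2 + k^2)), in [0,1]."""
    if params.k <= 0:
        raise ValueError("half-saturation constant k must be positive")
    if np.nanmin(D) < -1e-12 or np.nanmax(D) > 1 + 1e-12:
        raise ValueError("degradation must lie in [0,1]")
    lut = np.zeros(max(params.suitability) + 1)
    for code, h in params.suitability.items():
        lut[code] = h
    H = lut[land_use.astype(int)]
    return H * (1.0 - D**2 / (D**2 + params.k**2))


# ---------------------------------------------------------------------------
# stack assembly


@dataclass
class ESParams:
    """Parameter bundle for all services."""

    ki: dict[int, float] = field(default_factory=lambda: dict(DEFAULT_KI))
    carbon_pools: dict[int, tuple[float, float, float, float]] = field(
        default_factory=lambda: dict(DEFAULT_CARBON_POOLS))
    habitat: HabitatParams = field(default_factory=HabitatParams)
    printed_fp_form: bool = False


@dataclass
class ESStack:
    """Eight aligned ES layers for one date."""

    date_tag: str
    layers: dict[str, RasterLayer]

    def __post_init__(self) -> None:
        missing = set(ES_NAMES) - set(self.layers)
        if missing:
            raise ValueError(f"missing ES layers: {sorted(missing)}")
        ref = self.layers["FP"]
        for layer in self.layers.values():
            ref.check_aligned(layer)

    def __getitem__(self, name: str) -> RasterLayer:
        return self.layers[name]


def assemble_es_stack(
    stack: LandscapeStack,
    params: ESParams | None = None,
    mask: np.ndarray | None = None,
) -> ESStack:
    """Compute all eight service layers from one landscape stack.

    ``mask`` (fine-grid boolean, True = excluded) propagates as NaN into
    every layer.  LA is passed through from the input ``la`` layer.
    Negative physical values are clamped to zero; the clamp count is logged.
    """
    params = params or ESParams()
    lu = stack["land_use"].values

    fp = food_production(stack["temperature"].values,
                         stack["precipitation"].values,
                         lu, params.ki, params.printed_fp_form)
    cs = carbon_storage(lu, params.carbon_pools)
    wy = water_yield(stack["precipitation"].values, stack["aet"].values)
    sc = soil_conservation(stack["usle_R"].values, stack["usle_K"].values,
                           stack["usle_LS"].values, stack["usle_Cf"].values,
                           stack["usle_P"].values)
    tn = nutrient_export(stack["hss"].values, stack["pol_N"].values)
    tp = nutrient_export(stack["hss"].values, stack["pol_P"].values)
    D = habitat_degradation(lu, params.habitat, stack.cell_size_m)
    hq = habitat_quality(lu, D, params.habitat)
    la = stack["la"].values.copy()

    values = {"FP": fp, "CS": cs, "WY": wy, "SC": sc,
              "TN": tn, "TP": tp, "HQ": hq, "LA": la}
    units = {"FP": "kg/(ha.a)", "CS": "t/ha", "WY": "mm", "SC": "t/km2",
             "TN": "kg/(ha.a)", "TP": "kg/(ha.a)", "HQ": "[0,1]", "LA": "[0,1]"}
    ref = stack["land_use"]
    layers = {}
    for name, v in values.items():
        n_neg = int(np.sum(v < 0))
        if n_neg:
            log.warning("clamping %d negative %s cells to 0", n_neg, name)
            v = np.clip(v, 0.0, None)
        if mask is not None:
            v = np.where(mask, np.nan, v)
        layers[name] = ref.copy_with(v, name=name, units=units[name])
    return ESStack(date_tag=stack.date_tag, layers=layers)
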