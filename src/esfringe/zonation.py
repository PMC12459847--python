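"""Urban / fringe / rural zonation from gridded indicators.

Six features are computed per 1-km analysis cell — population density, GDP
density, construction-land share (PLAND), nighttime-light brightness,
landscape-fragmentation entropy and a POI-based urban-function score — and a
multilayer-perceptron classifier assigns each cell to rural (0), fringe (1)
or urban (2).  Large water bodies are masked out before classification.
Across two dates the zone maps are typed into a five-class transition
typology and summarised as a row-stochastic transfer matrix.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import IntEnum
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import ndimage
from sklearn.metrics import recall_score
from sklearn.model_selection import train_test_split
from sklearn.neural_network import MLPClassifier

from .grids import (
    LAND_USE_CODES,
    AlignmentError,
    LandscapeStack,
    RasterLayer,
    block_reduce,
)

RURAL, FRINGE, URBAN = 0, 1, 2
ZONE_NAMES = {RURAL: "rural", FRINGE: "fringe", URBAN: "urban"}

FEATURE_NAMES = (
    "population_density",
    "gdp_density",
    "pland",
    "ntl",
    "fragmentation_w",
    "poi_function",
)


@dataclass
class ZoneMap:
    """Categorical 1-km raster of rural (0) / fringe (1) / urban (2) cells.

    Masked cells hold NaN.
    """

    values: np.ndarray
    date_tag: str = ""
    cell_size_m: float = 1000.0
    origin: tuple[float, float] = (0.0, 0.0)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        codes = np.unique(self.values[np.isfinite(self.values)])
        if not np.isin(codes, [RURAL, FRINGE, URBAN]).all():
            raise ValueError("zone map contains undeclared codes")

    @property
    def valid_mask(self) -> np.ndarray:
        return np.isfinite(self.values)

    def class_shares(self) -> pd.Series:
        v = self.values[self.valid_mask].astype(int)
        counts = np.bincount(v, minlength=3)
        return pd.Series(counts / counts.sum(), index=["rural", "fringe", "urban"])


class Transition(IntEnum):
    URBAN_MAINTENANCE = 0
    URBAN_EXPANSION = 1
    FRINGE_MAINTENANCE = 2
    FRINGE_EXPANSION = 3
    RURAL_RETENTION = 4
    EXCLUDED = 5


TRANSITION_NAMES = {
    Transition.URBAN_MAINTENANCE: "urban_maintenance",
    Transition.URBAN_EXPANSION: "urban_expansion",
    Transition.FRINGE_MAINTENANCE: "fringe_maintenance",
    Transition.FRINGE_EXPANSION: "fringe_expansion",
    Transition.RURAL_RETENTION: "rural_retention",
    Transition.EXCLUDED: "excluded",
}


@dataclass
class TransitionMap:
    values: np.ndarray  # Transition codes, NaN where masked at either date
    cell_size_m: float = 1000.0

    def shares(self) -> pd.Series:
        v = self.values[np.isfinite(self.values)].astype(int)
        counts = np.bincount(v, minlength=6)
        names = [TRANSITION_NAMES[Transition(i)] for i in range(6)]
        return pd.Series(counts / max(counts.sum(), 1), index=names)


@dataclass
class PoiFunctionConfig:
    """Weights and kernel bandwidth for the POI urban-function feature.

    Weights are per POI category and must sum to 1; unlisted categories get
    weight 0.  The default bandwidth equals one analysis cell (1 km).
    """

    weights: Mapping[str, float] = field(default_factory=dict)
    bandwidth_m: float = 1000.0

    def validate(self, categories: list[str] | None = None) -> dict[str, float]:
        if self.bandwidth_m <= 0:
            raise ValueError("kernel bandwidth must be positive")
        w = dict(self.weights)
        if not w:
            cats = categories or []
            if cats:
                w = {c: 1.0 / len(cats) for c in cats}  # equal weights default
            else:
                return {}
        total = sum(w.values())
        if any(v < 0 for v in w.values()) or not np.isclose(total, 1.0, atol=1e-9):
            raise ValueError("POI weights must be non-negative and sum to 1")
        return w


@dataclass
class ClassifierSpec:
    """Multilayer-perceptron configuration for 3-class zonation."""

    hidden_sizes: tuple[int, int] = (128, 64)
    dropout_rate: float = 0.5  # recorded; realised as L2 + early stopping
    learning_rate: float = 0.001
    train_fraction: float = 0.8
    max_epochs: int = 200
    batch_size: int = 32
    alpha: float = 1e-4
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 < self.train_fraction < 1.0):
            raise ValueError("train_fraction must lie in (0, 1)")
        if any(h <= 0 for h in self.hidden_sizes):
            raise ValueError("hidden sizes must be positive")


@dataclass
class FeatureGrid:
    """Per-1-km-cell classification features, NaN on masked cells."""

    features: dict[str, np.ndarray]  # name -> (rows, cols) arrays
    mask: np.ndarray                 # True where cell is masked out
    cell_size_m: float = 1000.0
    origin: tuple[float, float] = (0.0, 0.0)

    @property
    def shape(self) -> tuple[int, int]:
        return self.mask.shape

    def matrix(self) -> np.ndarray:
        """(n_cells, 6) feature matrix in FEATURE_NAMES order (all cells)."""
        return np.column_stack([self.features[n].ravel() for n in FEATURE_NAMES])

    def features_at(self, rows: np.ndarray, cols: np.ndarray) -> np.ndarray:
        return np.column_stack(
            [self.features[n][rows, cols] for n in FEATURE_NAMES]
        )


# ---------------------------------------------------------------------------
# water masking and per-cell features


def mask_water(stack: LandscapeStack, min_area_km2: float = 1.0) -> np.ndarray:
    """Boolean fine-grid mask of large water bodies.

    Connected water components (4-connectivity) whose area is strictly
    greater than ``min_area_km2`` are marked True; smaller water is kept.
    """
    if "land_use" not in stack:
        raise KeyError("stack has no land_use layer")
    lu = stack["land_use"]
    water = lu.values == LAND_USE_CODES["water"]
    labels, n = ndimage.label(water)
    if n == 0:
        return np.zeros_like(water, dtype=bool)
    areas = ndimage.sum_labels(np.ones_like(labels), labels, index=np.arange(1, n + 1))
    areas_km2 = areas * lu.cell_area_km2()
    # strictly greater than the threshold, robust to float accumulation
    big = np.flatnonzero(areas_km2 > min_area_km2 * (1 + 1e-9)) + 1
    return np.isin(labels, big)


def compute_pland(land_use: np.ndarray, builtup_code: int = LAND_USE_CODES["builtup"]) -> float:
    """Construction-land share (%) of the valid area of one window."""
    valid = np.isfinite(land_use)
    total = valid.sum()
    if total == 0:
        raise ValueError("window is entirely nodata")
    return float((land_use[valid] == builtup_code).sum()) / total * 100.0


def compute_fragmentation(land_use: np.ndarray) -> float:
    """Shannon entropy (nats) of land-type proportions in one window.

    W = -sum X_n ln X_n over the land types present, with 0 ln 0 := 0.
    """
    vals = land_use[np.isfinite(land_use)]
    if vals.size == 0:
        raise ValueError("window is entirely nodata")
    _, counts = np.unique(vals, return_counts=True)
    p = counts / counts.sum()
    return float(-(p * np.log(p)).sum())


def poi_kernel_density(
    poi: pd.DataFrame,
    centers_x: np.ndarray,
    centers_y: np.ndarray,
    bandwidth_m: float,
) -> dict[str, np.ndarray]:
    """Gaussian kernel density of each POI category at given cell centres.

    Returns per-category density (points per m^2) arrays of shape centers.
    """
    out: dict[str, np.ndarray] = {}
    norm = 1.0 / (2.0 * np.pi * bandwidth_m**2)
    for cat, grp in poi.groupby("category"):
        dx = centers_x[..., None] - grp["x"].to_numpy()[None, :]
        dy = centers_y[..., None] - grp["y"].to_numpy()[None, :]
        d2 = dx * dx + dy * dy
        out[str(cat)] = norm * np.exp(-0.5 * d2 / bandwidth_m**2).sum(axis=-1)
    return out


def compute_poi_shares(densities: Mapping[str, float], weights: Mapping[str, float]) -> dict[str, float]:
    """Per-type function shares F_i = n_i w_i / sum(n_i w_i) x 100 (%).

    Returns an empty dict when no POI mass is present.
    """
    terms = {c: densities.get(c, 0.0) * w for c, w in weights.items()}
    total = sum(terms.values())
    if total <= 0:
        return {}
    return {c: v / total * 100.0 for c, v in terms.items()}


def compute_poi_function(
    poi: pd.DataFrame,
    config: PoiFunctionConfig,
    grid_shape: tuple[int, int],
    cell_size_m: float,
    origin: tuple[float, float] = (0.0, 0.0),
) -> np.ndarray:
    """Weighted POI kernel-density total per cell, min-max rescaled to [0,100].

    The per-type shares F_i are scale-free; the cell feature used for
    classification is the weighted density total so that the urban-to-rural
    density gradient is preserved.
    """
    rows, cols = grid_shape
    if poi.empty:
        return np.zeros(grid_shape)
    cats = sorted(poi["category"].astype(str).unique())
    weights = config.validate(cats)
    jj, ii = np.meshgrid(np.arange(cols), np.arange(rows))
    cx = origin[0] + (jj + 0.5) * cell_size_m
    cy = origin[1] + (ii + 0.5) * cell_size_m
    dens = poi_kernel_density(poi, cx, cy, config.bandwidth_m)
    total = np.zeros(grid_shape)
    for cat, w in weights.items():
        if cat in dens:
            total += w * dens[cat]
    lo, hi = total.min(), total.max()
    if hi - lo <= 0:
        return np.zeros(grid_shape)
    return (total - lo) / (hi - lo) * 100.0


def assemble_features(
    stack: LandscapeStack,
    refine_factor: int,
    mask: np.ndarray | None = None,
    config: PoiFunctionConfig | None = None,
) -> FeatureGrid:
    """Compute the six classification features per 1-km cell.

    ``refine_factor`` is the number of fine (ES-resolution) cells per coarse
    cell edge.  ``mask`` is a fine-grid boolean water mask; a coarse cell is
    masked when more than half of its fine cells are masked.
    """
    config = config or PoiFunctionConfig()
    lu = stack["land_use"]
    fr, fc = lu.shape
    if fr % refine_factor or fc % refine_factor:
        raise AlignmentError("fine grid is not a multiple of the refine factor")
    rows, cols = fr // refine_factor, fc // refine_factor
    coarse_cell = lu.cell_size_m * refine_factor

    if mask is None:
        mask = np.zeros((fr, fc), dtype=bool)
    coarse_mask = block_reduce(mask.astype(float), refine_factor) > 0.5

    feats: dict[str, np.ndarray] = {}
    lu_masked = np.where(mask, np.nan, lu.values)
    pland = np.full((rows, cols), np.nan)
    frag = np.full((rows, cols), np.nan)
    for i in range(rows):
        for j in range(cols):
            if coarse_mask[i, j]:
                continue
            win = lu_masked[
                i * refine_factor:(i + 1) * refine_factor,
                j * refine_factor:(j + 1) * refine_factor,
            ]
            if not np.isfinite(win).any():
                coarse_mask[i, j] = True
                continue
            pland[i, j] = compute_pland(win)
            frag[i, j] = compute_fragmentation(win)
    feats["pland"] = pland
    feats["fragmentation_w"] = frag

    for name in ("population_density", "gdp_density", "ntl"):
        vals = np.where(mask, np.nan, stack[name].values)
        feats[name] = block_reduce(vals, refine_factor)

    feats["poi_function"] = compute_poi_function(
        stack.poi, config, (rows, cols), coarse_cell, lu.origin
    )

    for name in FEATURE_NAMES:
        feats[name] = np.where(coarse_mask, np.nan, feats[name])
    return FeatureGrid(
        features=feats, mask=coarse_mask, cell_size_m=coarse_cell, origin=lu.origin
    )


# ---------------------------------------------------------------------------
# classifier


def standardize(X: np.ndarray, mean: np.ndarray | None = None,
                std: np.ndarray | None = None) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Z-standardise columns; zero-variance columns map to 0."""
    if mean is None:
        mean = np.nanmean(X, axis=0)
        std = np.nanstd(X, axis=0)
    std_safe = np.where(std > 0, std, 1.0)
    return (X - mean) / std_safe, mean, std


@dataclass
class ZoneClassifier:
    """Trained MLP plus the feature standardisation fitted with it."""

    model: MLPClassifier
    mean: np.ndarray
    std: np.ndarray
    accuracy: float
    per_class_recall: np.ndarray

    def predict(self, X: np.ndarray) -> np.ndarray:
        Xs, _, _ = standardize(X, self.mean, self.std)
        proba = self.model.predict_proba(Xs)
        # argmax ties break toward the lower class code (rural < fringe < urban)
        return np.argmax(proba, axis=1)


def train_classifier(samples: pd.DataFrame, spec: ClassifierSpec | None = None) -> ZoneClassifier:
    """Fit the zonation MLP on a labeled sample table.

    ``samples`` holds the six feature columns plus a ``label`` column in
    {0, 1, 2}.  An 80/20 stratified split yields held-out accuracy
    (correct / total) and per-class recall.
    """
    spec = spec or ClassifierSpec()
    X = samples[list(FEATURE_NAMES)].to_numpy(dtype=float)
    y = samples["label"].to_numpy(dtype=int)
    if not np.isfinite(X).all():
        raise ValueError("non-finite feature values in training samples")
    if len(np.unique(y)) < 3:
        raise ValueError("all three classes must be present in the labels")
    X_tr, X_te, y_tr, y_te = train_test_split(
        X, y, train_size=spec.train_fraction, stratify=y, random_state=spec.seed
    )
    if len(np.unique(y_tr)) < 3:
        raise ValueError("a class is missing from the training split")
    Xs_tr, mean, std = standardize(X_tr)
    model = MLPClassifier(
        hidden_layer_sizes=spec.hidden_sizes,
        activation="relu",
        solver="adam",
        learning_rate_init=spec.learning_rate,
        alpha=spec.alpha,
        batch_size=spec.batch_size,
        max_iter=spec.max_epochs,
        early_stopping=True,
        n_iter_no_change=20,
        validation_fraction=0.1,
        random_state=spec.seed,
    )
    model.fit(Xs_tr, y_tr)
    Xs_te, _, _ = standardize(X_te, mean, std)
    pred = model.predict(Xs_te)
    acc = float((pred == y_te).mean())
    rec = recall_score(y_te, pred, labels=[0, 1, 2], average=None, zero_division=0)
    return ZoneClassifier(model=model, mean=mean, std=std,
                          accuracy=acc, per_class_recall=np.asarray(rec))


def classify_zones(features: FeatureGrid, clf: ZoneClassifier, date_tag: str = "") -> ZoneMap:
    """Apply a trained classifier to every unmasked cell of a feature grid."""
    X = features.matrix()
    valid = np.isfinite(X).all(axis=1) & ~features.mask.ravel()
    out = np.full(X.shape[0], np.nan)
    if valid.any():
        out[valid] = clf.predict(X[valid])
    return ZoneMap(
        values=out.reshape(features.shape),
        date_tag=date_tag,
        cell_size_m=features.cell_size_m,
        origin=features.origin,
    )


# ---------------------------------------------------------------------------
# transitions


def type_transitions(z0: ZoneMap, z1: ZoneMap,
                     rural_to_urban: str = "urban_expansion") -> TransitionMap:
    """Five-class transition typology between two zone maps.

    Backward moves (urban/fringe toward rural, urban to fringe) are
    excluded.  Direct rural-to-urban jumps are not one of the five named
    types; they count as urban expansion by default, or are excluded when
    ``rural_to_urban="excluded"``.
    """
    if z0.values.shape != z1.values.shape:
        raise AlignmentError("zone maps are not aligned")
    if rural_to_urban not in ("urban_expansion", "excluded"):
        raise ValueError("rural_to_urban must be 'urban_expansion' or 'excluded'")
    a, b = z0.values, z1.values
    out = np.full(a.shape, np.nan)
    valid = np.isfinite(a) & np.isfinite(b)
    table = {
        (URBAN, URBAN): Transition.URBAN_MAINTENANCE,
        (FRINGE, URBAN): Transition.URBAN_EXPANSION,
        (FRINGE, FRINGE): Transition.FRINGE_MAINTENANCE,
        (RURAL, FRINGE): Transition.FRINGE_EXPANSION,
        (RURAL, RURAL): Transition.RURAL_RETENTION,
        (URBAN, FRINGE): Transition.EXCLUDED,
        (URBAN, RURAL): Transition.EXCLUDED,
        (FRINGE, RURAL): Transition.EXCLUDED,
        (RURAL, URBAN): (
            Transition.URBAN_EXPANSION
            if rural_to_urban == "urban_expansion"
            else Transition.EXCLUDED
        ),
    }
    for (c0, c1), code in table.items():
        out[valid & (a == c0) & (b == c1)] = int(code)
    return TransitionMap(values=out, cell_size_m=z0.cell_size_m)


def transfer_matrix(z0: ZoneMap, z1: ZoneMap) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Row-stochastic 3x3 zone transfer matrix plus absolute areas (km^2).

    Rows are the earlier date's classes, columns the later date's; rows are
    normalised over the cells valid at both dates.
    """
    if z0.values.shape != z1.values.shape:
        raise AlignmentError("zone maps are not aligned")
    valid = np.isfinite(z0.values) & np.isfinite(z1.values)
    if not valid.any():
        raise ValueError("no jointly valid cells")
    a = z0.values[valid].astype(int)
    b = z1.values[valid].astype(int)
    counts = np.zeros((3, 3))
    np.add.at(counts, (a, b), 1)
    idx = ["rural", "fringe", "urban"]
    areas = pd.DataFrame(counts * (z0.cell_size_m / 1000.0) ** 2, index=idx, columns=idx)
    row_sums = counts.sum(axis=1, keepdims=True)
    shares = np.divide(counts, row_sums, out=np.zeros_like(counts), where=row_sums > 0)
    return pd.DataFrame(shares, index=idx, columns=idx), areas
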