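"""Planar grid containers used throughout the pipeline.

All spatial data live on axis-aligned regular grids in a local planar
coordinate system: row-major indexing, origin at the top-left cell corner,
half-open cell intervals.  There is no CRS handling — the analysis is
resolution-relative, not georeferenced.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

#: canonical land-use codes
LAND_USE_CODES = {
    "cropland": 1,
    "forest": 2,
    "grassland": 3,
    "wetland": 4,
    "water": 5,
    "builtup": 6,
    "bare": 7,
}
CODE_TO_LAND_USE = {v: k for k, v in LAND_USE_CODES.items()}

NODATA = -9999.0


class AlignmentError(ValueError):
    """Raised when two layers do not share grid, cell size and origin."""


@dataclass
class RasterLayer:
    """A single named 2-D layer on a regular planar grid.

    ``values`` is a float array; nodata cells hold NaN internally and are
    serialised with the ``nodata`` sentinel.  Categorical layers store
    integer codes as floats.
    """

    values: np.ndarray
    name: str
    units: str = ""
    nodata: float = NODATA
    cell_size_m: float = 1000.0
    origin: tuple[float, float] = (0.0, 0.0)  # (x, y) of top-left corner

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError(f"layer {self.name!r} must be 2-D")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    @property
    def valid_mask(self) -> np.ndarray:
        return np.isfinite(self.values)

    def aligned_with(self, other: "RasterLayer") -> bool:
        return (
            self.shape == other.shape
            and np.isclose(self.cell_size_m, other.cell_size_m)
            and np.allclose(self.origin, other.origin)
        )

    def check_aligned(self, other: "RasterLayer") -> None:
        if not self.aligned_with(other):
            raise AlignmentError(
                f"layers {self.name!r} and {other.name!r} are not aligned"
            )

    def copy_with(self, values: np.ndarray, name: str | None = None,
                  units: str | None = None) -> "RasterLayer":
        return RasterLayer(
            values=np.asarray(values, dtype=float),
            name=self.name if name is None else name,
            units=self.units if units is None else units,
            nodata=self.nodata,
            cell_size_m=self.cell_size_m,
            origin=self.origin,
        )

    def cell_area_km2(self) -> float:
        return (self.cell_size_m / 1000.0) ** 2


#: layer roster expected in a full landscape stack
STACK_LAYERS = (
    "land_use", "population_density", "gdp_density", "ntl",
    "temperature", "precipitation", "aet",
    "usle_R", "usle_K", "usle_LS", "usle_Cf", "usle_P",
    "hss", "pol_N", "pol_P", "la",
)


@dataclass
class LandscapeStack:
    """Aligned named raster layers plus POI points for one date.

    ``poi`` is a DataFrame with columns ``x``, ``y`` (planar metres) and
    ``category``.
    """

    date_tag: str
    layers: dict[str, RasterLayer]
    poi: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(columns=["x", "y", "category"])
    )

    def __post_init__(self) -> None:
        ref = next(iter(self.layers.values()))
        for layer in self.layers.values():
            ref.check_aligned(layer)
        lu = self.layers.get("land_use")
        if lu is not None:
            codes = np.unique(lu.values[np.isfinite(lu.values)])
            unknown = set(codes.astype(int)) - set(LAND_USE_CODES.values())
            if unknown:
                raise ValueError(f"unknown land-use codes: {sorted(unknown)}")

    def __getitem__(self, name: str) -> RasterLayer:
        return self.layers[name]

    def __contains__(self, name: str) -> bool:
        return name in self.layers

    @property
    def shape(self) -> tuple[int, int]:
        return next(iter(self.layers.values())).shape

    @property
    def cell_size_m(self) -> float:
        return next(iter(self.layers.values())).cell_size_m


@dataclass
class VillageTessellation:
    """Village partition of the analysis grid.

    ``labels`` assigns every coarse (feature-scale) cell a village id in
    ``ids``; together the villages partition the grid exactly.
    """

    labels: np.ndarray            # (rows, cols) int village id per coarse cell
    ids: np.ndarray               # unique ids, sorted
    cell_size_m: float = 1000.0
    origin: tuple[float, float] = (0.0, 0.0)

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=int)
        self.ids = np.asarray(self.ids, dtype=int)
        if len(np.unique(self.ids)) != len(self.ids):
            raise ValueError("village ids must be unique")
        present = np.unique(self.labels)
        if not np.isin(present, self.ids).all():
            raise ValueError("labels contain ids not in the id list")

    @property
    def n_villages(self) -> int:
        return len(self.ids)

    def cell_counts(self) -> pd.Series:
        vals, counts = np.unique(self.labels, return_counts=True)
        return pd.Series(counts, index=vals).reindex(self.ids, fill_value=0)

    def centroids(self) -> pd.DataFrame:
        """Planar centroids (cell-centre average) per village, in metres."""
        rows, cols = np.indices(self.labels.shape)
        x = self.origin[0] + (cols + 0.5) * self.cell_size_m
        y = self.origin[1] + (rows + 0.5) * self.cell_size_m
        df = pd.DataFrame({"id": self.labels.ravel(), "x": x.ravel(), "y": y.ravel()})
        out = df.groupby("id")[["x", "y"]].mean()
        return out.reindex(self.ids)


def block_reduce(values: np.ndarray, factor: int, how: str = "mean") -> np.ndarray:
    """Aggregate a fine grid into (factor x factor) blocks.

    NaNs are ignored in means; a block of all-NaN yields NaN.
    """
    r, c = values.shape
    if r % factor or c % factor:
        raise ValueError("grid shape must be a multiple of the block factor")
    blocks = values.reshape(r // factor, factor, c // factor, factor)
    blocks = blocks.transpose(0, 2, 1, 3).reshape(r // factor, c // factor, -1)
    if how == "mean":
        import warnings
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            return np.nanmean(blocks, axis=-1)
    if how == "sum":
        return np.nansum(blocks, axis=-1)
    raise ValueError(f"unknown reduction {how!r}")


def broadcast_to_fine(values: np.ndarray, factor: int) -> np.ndarray:
    """Replicate each coarse cell over its (factor x factor) fine block."""
    return np.kron(values, np.ones((factor, factor)))
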