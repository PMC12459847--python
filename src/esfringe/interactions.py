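"""Village-scale ES interaction analysis.

Raster service layers are aggregated to village means, min-max normalised,
and analysed three ways: Spearman rank-correlation matrices (positive =
synergy, negative = trade-off), a coupling-coordination degree model (CCDM)
with a six-level A-F classification, and a standard deviational ellipse
summarising the spatial trend of weighted village points.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .es_models import ES_NAMES, ESStack
from .grids import VillageTessellation, broadcast_to_fine
from .zonation import TRANSITION_NAMES, Transition, TransitionMap, ZoneMap

log = logging.getLogger(__name__)

#: services that are disservices on the raw scale (more output = worse)
DISSERVICES = ("TN", "TP")

LEVELS = ("A", "B", "C", "D", "E", "F")
LEVEL_DESCRIPTIONS = {
    "A": "High-quality coordination",
    "B": "Good coordination",
    "C": "Low coordination",
    "D": "Mild incoordination",
    "E": "Moderate incoordination",
    "F": "Extreme incoordination",
}


# ---------------------------------------------------------------------------
# aggregation and normalisation


def aggregate_villages(
    es: ESStack,
    villages: VillageTessellation,
    refine_factor: int,
) -> pd.DataFrame:
    """Area-weighted village mean of each service layer.

    Village labels live on the coarse grid and are broadcast to the fine ES
    grid; NaN (masked) cells are excluded.  Villages with no valid cell are
    dropped with a log note.
    """
    labels_fine = broadcast_to_fine(villages.labels, refine_factor).astype(int)
    out = pd.DataFrame({"village_id": villages.ids}).set_index("village_id")
    max_id = labels_fine.max()
    for name in ES_NAMES:
        v = es[name].values.ravel()
        lab = labels_fine.ravel()
        ok = np.isfinite(v)
        sums = np.bincount(lab[ok], weights=v[ok], minlength=max_id + 1)
        counts = np.bincount(lab[ok], minlength=max_id + 1)
        with np.errstate(invalid="ignore"):
            means = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
        out[name] = means[villages.ids]
    dropped = out.index[out.isna().any(axis=1)]
    if len(dropped):
        log.info("dropping %d villages with no valid cells", len(dropped))
        out = out.drop(index=dropped)
    out["date_tag"] = es.date_tag
    return out.reset_index()


def normalize(table: pd.DataFrame, per_date: bool = False) -> pd.DataFrame:
    """Min-max normalise each service column to [0,1].

    By default the minimum and maximum are pooled over all dates present so
    that levels and changes stay comparable across time; ``per_date=True``
    normalises within each date.  A constant column maps to all zeros with a
    warning.
    """
    if len(table) < 2:
        raise ValueError("need at least 2 rows to normalise")
    out = table.copy()

    def _norm(df: pd.DataFrame) -> pd.DataFrame:
        res = df.copy()
        for name in ES_NAMES:
            col = df[name].to_numpy(dtype=float)
            lo, hi = np.nanmin(col), np.nanmax(col)
            if hi - lo <= 0:
                log.warning("constant indicator %s normalised to 0", name)
                res[name] = 0.0
            else:
                res[name] = (col - lo) / (hi - lo)
        return res

    if per_date and "date_tag" in table:
        out = pd.concat(
            [_norm(g) for _, g in out.groupby("date_tag", sort=False)],
            ignore_index=True,
        )
    else:
        out = _norm(out)
    return out


def village_zone_attribution(
    villages: VillageTessellation, zones: ZoneMap
) -> pd.Series:
    """Majority zone code per village; ties break toward the lower code."""
    df = pd.DataFrame({
        "village_id": villages.labels.ravel(),
        "zone": zones.values.ravel(),
    }).dropna()
    def majority(s: pd.Series) -> int:
        counts = s.value_counts()
        top = counts[counts == counts.max()].index
        return int(min(top))
    return df.groupby("village_id")["zone"].apply(majority)


def village_transition_attribution(
    villages: VillageTessellation, transitions: TransitionMap
) -> pd.Series:
    """Majority transition type name per village (ties -> lower code)."""
    df = pd.DataFrame({
        "village_id": villages.labels.ravel(),
        "code": transitions.values.ravel(),
    }).dropna()
    def majority(s: pd.Series) -> str:
        counts = s.value_counts()
        top = counts[counts == counts.max()].index
        return TRANSITION_NAMES[Transition(int(min(top)))]
    return df.groupby("village_id")["code"].apply(majority)


# ---------------------------------------------------------------------------
# Spearman trade-off / synergy matrices


def spearman_matrix(
    table: pd.DataFrame,
    mode: str = "levels",
    min_villages: int = 5,
) -> pd.DataFrame:
    """8x8 Spearman rank-correlation matrix over villages.

    ``mode="levels"`` correlates the indicator values in ``table``;
    ``mode="changes"`` expects one row per village per date and correlates
    per-village differences value(t1) - value(t0).  A zero-variance
    indicator yields NaN coefficients (noted in the log).
    """
    if mode == "changes":
        dates = sorted(table["date_tag"].unique())
        if len(dates) != 2:
            raise ValueError("changes mode needs exactly two dates")
        t0 = table[table.date_tag == dates[0]].set_index("village_id")
        t1 = table[table.date_tag == dates[1]].set_index("village_id")
        common = t0.index.intersection(t1.index)
        data = (t1.loc[common, list(ES_NAMES)]
                - t0.loc[common, list(ES_NAMES)])
    elif mode == "levels":
        data = table[list(ES_NAMES)]
    else:
        raise ValueError("mode must be 'levels' or 'changes'")
    if len(data) < min_villages:
        raise ValueError(f"stratum has fewer than {min_villages} villages")
    X = data.to_numpy(dtype=float)
    const = X.std(axis=0) == 0
    with np.errstate(invalid="ignore"):
        rho = stats.spearmanr(X).statistic
    rho = np.atleast_2d(rho)
    np.fill_diagonal(rho, 1.0)
    if const.any():
        which = [ES_NAMES[i] for i in np.flatnonzero(const)]
        log.warning("zero-variance indicators in stratum: %s", which)
        rho[const, :] = np.nan
        rho[:, const] = np.nan
        for i in np.flatnonzero(const):
            rho[i, i] = 1.0
    return pd.DataFrame(rho, index=list(ES_NAMES), columns=list(ES_NAMES))


def stratified_spearman(
    table: pd.DataFrame,
    strata: pd.Series,
    mode: str = "levels",
    min_villages: int = 5,
) -> dict[str, pd.DataFrame]:
    """Spearman matrix per stratum (e.g. per transition type or date)."""
    out: dict[str, pd.DataFrame] = {}
    s = strata.reindex(table["village_id"]).to_numpy()
    for name in pd.unique(s):
        sub = table[s == name]
        ids = sub["village_id"].unique()
        if len(ids) < min_villages:
            log.info("skipping stratum %s with %d villages", name, len(ids))
            continue
        out[str(name)] = spearman_matrix(sub, mode=mode, min_villages=min_villages)
    return out


# ---------------------------------------------------------------------------
# coupling coordination degree model


@dataclass
class CCDMConfig:
    """Weights and variants of the coupling-coordination degree model.

    Default indicator weights are 0.12 for seven services and 0.16 for
    habitat quality (summing to exactly 1).  The default coupling variant is
    the geometric-mean / arithmetic-mean ratio, which meets the model's
    stated contract (C = 1 when all subsystems are equal, C = 0 when any is
    absent); the literal product form is available as ``printed_product``.
    D combines C and T as their product by default, with the square-root
    convention behind a flag.  TN/TP are inverted to purification scores
    before entering T unless ``disservice_handling="raw"``.
    """

    weights: dict[str, float] = field(default_factory=lambda: {
        "FP": 0.12, "CS": 0.12, "WY": 0.12, "SC": 0.12,
        "TN": 0.12, "TP": 0.12, "HQ": 0.16, "LA": 0.12,
    })
    coupling_variant: str = "gm_am_ratio"       # or "printed_product"
    d_combiner: str = "printed_product"         # or "sqrt_product"
    disservice_handling: str = "invert"         # or "raw"

    def __post_init__(self) -> None:
        w = np.array([self.weights[n] for n in ES_NAMES])
        if (w < 0).any() or not np.isclose(w.sum(), 1.0, atol=1e-9):
            raise ValueError("CCDM weights must be non-negative and sum to 1")
        if self.coupling_variant not in ("gm_am_ratio", "printed_product"):
            raise ValueError("unknown coupling variant")
        if self.d_combiner not in ("printed_product", "sqrt_product"):
            raise ValueError("unknown D combiner")

    def weight_vector(self) -> np.ndarray:
        return np.array([self.weights[n] for n in ES_NAMES])


def orient_disservices(U: np.ndarray, config: CCDMConfig) -> np.ndarray:
    """Invert TN/TP columns (1 - u) so that higher means better purification."""
    U = np.array(U, dtype=float, copy=True)
    if config.disservice_handling == "invert":
        for name in DISSERVICES:
            i = ES_NAMES.index(name)
            U[..., i] = 1.0 - U[..., i]
    return U


def coupling_degree(U: np.ndarray, config: CCDMConfig | None = None) -> float:
    """Coupling degree C in [0,1] of one indicator vector.

    Default variant: C = GM(U) / AM(U) (= k (prod U)^(1/k) / sum U), equal to
    1 iff all indicators are equal and 0 iff any indicator is 0.  The
    ``printed_product`` variant is
    C = {prod U / prod_{i<j}(U_i + U_j)}^(1/k).
    """
    config = config or CCDMConfig()
    U = np.asarray(U, dtype=float)
    if (U < 0).any() or (U > 1).any():
        raise ValueError("indicators must lie in [0,1]")
    k = U.size
    if config.coupling_variant == "gm_am_ratio":
        s = U.sum()
        if s == 0:
            return 0.0
        gm = np.prod(U) ** (1.0 / k)
        return float(gm / (s / k))
    # printed product form
    num = np.prod(U)
    den = 1.0
    for i in range(k):
        for j in range(k):
            if i != j:
                den *= U[i] + U[j]
    if den == 0:
        return 0.0
    return float((num / den) ** (1.0 / k))


def composite_index(U: np.ndarray, config: CCDMConfig | None = None) -> float:
    """Composite development level T = weighted sum of the oriented indicators."""
    config = config or CCDMConfig()
    U = np.asarray(U, dtype=float)
    w = config.weight_vector()
    if U.shape[-1] != w.size:
        raise ValueError("indicator vector length does not match weights")
    return float(U @ w)


def coordination_degree(C: float, T: float, config: CCDMConfig | None = None) -> float:
    """Coordination degree D from C and T (product by default)."""
    config = config or CCDMConfig()
    if not (0 <= C <= 1 and 0 <= T <= 1):
        raise ValueError("C and T must lie in [0,1]")
    D = C * T if config.d_combiner == "printed_product" else float(np.sqrt(C * T))
    if not (0 <= D <= 1):
        raise ValueError("D outside [0,1]")
    return D


def classify_level(D: float) -> str:
    """Six-level classification of D on half-open intervals.

    [0,0.2] F, (0.2,0.4] E, (0.4,0.5] D, (0.5,0.6] C, (0.6,0.8] B, (0.8,1] A.
    """
    if not (0 <= D <= 1):
        raise ValueError("D must lie in [0,1]")
    if D <= 0.2:
        return "F"
    if D <= 0.4:
        return "E"
    if D <= 0.5:
        return "D"
    if D <= 0.6:
        return "C"
    if D <= 0.8:
        return "B"
    return "A"


def ccdm_table(
    normalized: pd.DataFrame, config: CCDMConfig | None = None
) -> pd.DataFrame:
    """Per-village CCDM outputs (C, T, D, level) for one date's rows."""
    config = config or CCDMConfig()
    U_all = orient_disservices(
        normalized[list(ES_NAMES)].to_numpy(dtype=float), config
    )
    rows = []
    for (_, rec), U in zip(normalized.iterrows(), U_all):
        C = coupling_degree(U, config)
        T = composite_index(U, config)
        D = coordination_degree(C, T, config)
        rows.append({
            "village_id": rec["village_id"],
            "date_tag": rec.get("date_tag", ""),
            "C": C, "T": T, "D": D, "level": classify_level(D),
        })
    return pd.DataFrame(rows)


def level_transfer(
    ccdm_t0: pd.DataFrame, ccdm_t1: pd.DataFrame
) -> pd.DataFrame:
    """6x6 row-stochastic matrix of coordination-level changes A..F."""
    t0 = ccdm_t0.set_index("village_id")["level"]
    t1 = ccdm_t1.set_index("village_id")["level"]
    common = t0.index.intersection(t1.index)
    if len(common) != len(t0) or len(common) != len(t1):
        raise ValueError("village ids do not match between dates")
    counts = pd.crosstab(t0.loc[common], t1.loc[common])
    counts = counts.reindex(index=LEVELS, columns=LEVELS, fill_value=0).astype(float)
    sums = counts.sum(axis=1)
    shares = counts.div(sums.where(sums > 0, 1.0), axis=0)
    return shares


def mean_d_by_group(ccdm: pd.DataFrame, groups: pd.Series) -> pd.Series:
    """Mean coordination degree per village group (e.g. transition type)."""
    g = groups.reindex(ccdm["village_id"]).to_numpy()
    return ccdm.assign(group=g).groupby("group")["D"].mean()


# ---------------------------------------------------------------------------
# standard deviational ellipse


@dataclass
class DeviationalEllipse:
    center: tuple[float, float]
    semi_major: float
    semi_minor: float
    orientation_deg: float  # [0, 180), angle of the major axis from +x


def deviational_ellipse(
    points: np.ndarray, weights: np.ndarray | None = None
) -> DeviationalEllipse:
    """Weighted standard deviational ellipse of planar points.

    Centre is the weighted mean; axes are the square roots of the weighted
    coordinate-covariance eigenvalues; orientation is the major-axis angle.
    Collinear points give a zero minor axis.
    """
    P = np.asarray(points, dtype=float)
    if P.ndim != 2 or P.shape[1] != 2 or P.shape[0] < 2:
        raise ValueError("need at least 2 planar points")
    w = np.ones(len(P)) if weights is None else np.asarray(weights, dtype=float)
    if (w < 0).any() or w.sum() <= 0:
        raise ValueError("weights must be non-negative with positive total")
    w = w / w.sum()
    center = w @ P
    X = P - center
    cov = (X * w[:, None]).T @ X
    vals, vecs = np.linalg.eigh(cov)  # ascending
    vals = np.clip(vals, 0.0, None)
    major, minor = np.sqrt(vals[1]), np.sqrt(vals[0])
    vx, vy = vecs[:, 1]
    ang = np.degrees(np.arctan2(vy, vx)) % 180.0
    return DeviationalEllipse(
        center=(float(center[0]), float(center[1])),
        semi_major=float(major),
        semi_minor=float(minor),
        orientation_deg=float(ang),
    )
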