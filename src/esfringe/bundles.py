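"""ES bundle detection: SOM clustering with Davies-Bouldin model selection.

Village ES vectors (8 normalised indicators, nitrogen/phosphorus oriented as
purification scores) are projected onto a self-organizing map; the node
codebook is then agglomerated into k groups for k in a candidate range
(default 2-15) and the Davies-Bouldin index of the induced village partition
selects k.  Clusters are named from their mean profiles by a rule cascade
over the seven bundle classes, and bundle changes between dates are
summarised as row-stochastic transfer matrices.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage

from .synthetic import DEFAULT_ARCHETYPES, SOM_NAMES

log = logging.getLogger(__name__)

BUNDLE_NAMES = (
    "key trade-offs",
    "mild trade-offs",
    "key synergistic",
    "CS-HQ-LA",
    "HQ-LA",
    "water purification",
    "FP",
)


@dataclass
class SOMConfig:
    """Self-organizing-map training configuration.

    Map size defaults to the ~5 sqrt(n) nodes heuristic on a square lattice.
    Learning rate and neighbourhood radius decay linearly over the epochs.
    """

    map_rows: int | None = None
    map_cols: int | None = None
    epochs: int = 500
    learning_rate: float = 0.5
    final_learning_rate: float = 0.01
    initial_radius: float | None = None
    final_radius: float = 0.5
    seed: int = 0
    k_range: tuple[int, int] = (2, 15)

    def resolve_map(self, n: int) -> tuple[int, int]:
        if self.map_rows and self.map_cols:
            return self.map_rows, self.map_cols
        side = max(2, int(np.ceil(np.sqrt(5.0 * np.sqrt(n)))))
        return side, side


class SelfOrganizingMap:
    """Minimal online SOM with Gaussian neighbourhood and linear decay."""

    def __init__(self, config: SOMConfig, dim: int, n: int) -> None:
        self.config = config
        self.rows, self.cols = config.resolve_map(n)
        self.dim = dim
        rr, cc = np.indices((self.rows, self.cols))
        self._node_pos = np.column_stack([rr.ravel(), cc.ravel()]).astype(float)
        self.codebook = np.zeros((self.rows * self.cols, dim))
        self.quantization_trace: list[float] = []

    @property
    def n_nodes(self) -> int:
        return self.rows * self.cols

    def _init_codebook(self, X: np.ndarray, rng: np.random.Generator) -> None:
        # sample-based init with a small jitter so nodes start distinct
        idx = rng.integers(0, len(X), size=self.n_nodes)
        self.codebook = X[idx] + 0.01 * rng.standard_normal((self.n_nodes, self.dim))

    def bmu(self, X: np.ndarray) -> np.ndarray:
        d = ((X[:, None, :] - self.codebook[None, :, :]) ** 2).sum(axis=2)
        return d.argmin(axis=1)

    def quantization_error(self, X: np.ndarray) -> float:
        b = self.bmu(X)
        return float(np.linalg.norm(X - self.codebook[b], axis=1).mean())

    def fit(self, X: np.ndarray) -> "SelfOrganizingMap":
        if len(X) < 2:
            raise ValueError("need at least 2 rows to fit a SOM")
        if not np.isfinite(X).all():
            raise ValueError("non-finite rows in SOM input")
        cfg = self.config
        rng = np.random.default_rng(cfg.seed)
        self._init_codebook(X, rng)
        r0 = cfg.initial_radius or max(self.rows, self.cols) / 2.0
        n_epochs = cfg.epochs
        for epoch in range(n_epochs):
            t = epoch / max(n_epochs - 1, 1)
            lr = cfg.learning_rate + t * (cfg.final_learning_rate - cfg.learning_rate)
            radius = r0 + t * (cfg.final_radius - r0)
            order = rng.permutation(len(X))
            for i in order:
                x = X[i]
                b = int(((x - self.codebook) ** 2).sum(axis=1).argmin())
                d2 = ((self._node_pos - self._node_pos[b]) ** 2).sum(axis=1)
                h = np.exp(-d2 / (2.0 * radius * radius))
                self.codebook += (lr * h)[:, None] * (x - self.codebook)
            if epoch % max(n_epochs // 25, 1) == 0 or epoch == n_epochs - 1:
                self.quantization_trace.append(self.quantization_error(X))
        return self


def fit_som(table: pd.DataFrame, config: SOMConfig | None = None
            ) -> tuple[SelfOrganizingMap, np.ndarray]:
    """Fit a SOM on the 8 indicator columns; return the map and BMU per row."""
    config = config or SOMConfig()
    if table.empty:
        raise ValueError("empty village table")
    X = table[list(SOM_NAMES)].to_numpy(dtype=float)
    som = SelfOrganizingMap(config, dim=X.shape[1], n=len(X)).fit(X)
    return som, som.bmu(X)


def davies_bouldin(X: np.ndarray, labels: np.ndarray) -> float:
    """Davies-Bouldin index: mean over clusters of the worst-pair ratio
    (sigma_i + sigma_j) / d(c_i, c_j); lower is better.

    sigma is the mean Euclidean distance to the cluster centroid.  Raises on
    fewer than 2 clusters or an empty cluster; coincident centroids give inf
    with a warning.
    """
    labels = np.asarray(labels)
    uniq = np.unique(labels)
    k = len(uniq)
    if k < 2:
        raise ValueError("Davies-Bouldin needs at least 2 clusters")
    centroids = np.stack([X[labels == c].mean(axis=0) for c in uniq])
    sigma = np.array([
        np.linalg.norm(X[labels == c] - centroids[i], axis=1).mean()
        for i, c in enumerate(uniq)
    ])
    score = 0.0
    warned = False
    for i in range(k):
        worst = 0.0
        for j in range(k):
            if i == j:
                continue
            d = np.linalg.norm(centroids[i] - centroids[j])
            if d == 0:
                if not warned:
                    log.warning("coincident centroids -> infinite DB ratio")
                    warned = True
                worst = np.inf
            else:
                worst = max(worst, (sigma[i] + sigma[j]) / d)
        score += worst
    return float(score / k)


@dataclass
class BundlePartition:
    """SOM-derived clustering of villages with the DB selection trace."""

    assignments: pd.DataFrame        # village_id, (date_tag), cluster
    selected_k: int
    db_scores: dict[int, float]      # candidate k -> DB (NaN if degenerate)
    cluster_profiles: pd.DataFrame   # cluster x 8 mean indicator profile


def select_k(table: pd.DataFrame, config: SOMConfig | None = None
             ) -> BundlePartition:
    """SOM + prototype agglomeration + Davies-Bouldin cluster-count selection.

    For each candidate k, the SOM codebook is Ward-agglomerated into k
    prototype groups; villages inherit their best-matching node's group and
    the DB index is computed on the villages.  The k with the lowest DB wins
    (ties toward the smaller k).
    """
    config = config or SOMConfig()
    X = table[list(SOM_NAMES)].to_numpy(dtype=float)
    n = len(X)
    lo, hi = config.k_range
    lo = max(2, lo)
    hi = min(hi, n - 1)
    if hi < lo:
        raise ValueError("candidate cluster range is empty")
    som, bmu = fit_som(table, config)
    if np.allclose(X, X[0]):
        raise ValueError("degenerate input: all village vectors identical")
    # agglomerate occupied prototypes only: dead interpolating nodes carry no
    # villages and would distort the Ward merge structure
    occupied = np.unique(bmu)
    node_to_occ = {node: i for i, node in enumerate(occupied)}
    bmu_occ = np.array([node_to_occ[b] for b in bmu])
    Z = linkage(som.codebook[occupied], method="ward")
    scores: dict[int, float] = {}
    labelings: dict[int, np.ndarray] = {}
    for k in range(lo, hi + 1):
        node_groups = fcluster(Z, t=k, criterion="maxclust")
        village_labels = node_groups[bmu_occ]
        if len(np.unique(village_labels)) < 2:
            scores[k] = float("nan")
            continue
        scores[k] = davies_bouldin(X, village_labels)
        labelings[k] = village_labels
    finite = {k: s for k, s in scores.items() if np.isfinite(s)}
    if not finite:
        raise ValueError("all candidate cluster counts are degenerate")
    best_k = min(finite, key=lambda k: (finite[k], k))
    labels = labelings[best_k]
    # relabel clusters 1..k in order of first appearance for stability
    _, labels = np.unique(labels, return_inverse=True)
    labels = labels + 1
    cols = ["village_id"] + (["date_tag"] if "date_tag" in table else [])
    assignments = table[cols].copy()
    assignments["cluster"] = labels
    profiles = (
        pd.DataFrame(X, columns=list(SOM_NAMES))
        .assign(cluster=labels)
        .groupby("cluster")
        .mean()
    )
    return BundlePartition(
        assignments=assignments,
        selected_k=int(len(np.unique(labels))),
        db_scores=scores,
        cluster_profiles=profiles,
    )


# ---------------------------------------------------------------------------
# rule-based bundle naming


@dataclass
class LabelingThresholds:
    high: float = 0.6
    low: float = 0.3


def _label_profile(p: pd.Series, thr: LabelingThresholds) -> tuple[str, str]:
    """Name one cluster mean profile; returns (bundle name, rule trace)."""
    hi, lo = thr.high, thr.low
    others_to = [p[n] for n in ("FP", "CS", "SC", "TNp", "TPp", "HQ")]
    if p["WY"] >= hi and p["LA"] >= hi and p["FP"] <= lo:
        if max(others_to) <= lo:
            return "key trade-offs", "WY&LA high, FP low, all others low"
        return "mild trade-offs", "WY&LA high, FP low, others moderate"
    if min(p[n] for n in SOM_NAMES) >= hi:
        return "key synergistic", "all indicators balanced-high"
    if p["CS"] >= hi and p["HQ"] >= hi and p["LA"] >= hi:
        return "CS-HQ-LA", "CS, HQ and LA jointly dominant"
    if p["HQ"] >= hi and p["LA"] >= hi and p["SC"] >= 0.5:
        return "HQ-LA", "HQ & LA dominant with strong SC"
    if p["TNp"] >= hi and p["TPp"] >= hi:
        return "water purification", "purification scores dominant"
    if p["FP"] >= hi and p["FP"] == max(p[n] for n in SOM_NAMES):
        return "FP", "food production dominant"
    # nearest-archetype fallback
    best, dist = None, np.inf
    for name, mean in DEFAULT_ARCHETYPES.items():
        d = float(np.linalg.norm(p[list(SOM_NAMES)].to_numpy(dtype=float)
                                 - np.asarray(mean)))
        if d < dist:
            best, dist = name, d
    log.info("profile matched no rule; nearest archetype %s", best)
    return str(best), f"fallback: nearest archetype ({best})"


def label_bundles(
    partition: BundlePartition, thresholds: LabelingThresholds | None = None
) -> pd.DataFrame:
    """Bundle name per cluster from its mean profile, with the rule trace."""
    thr = thresholds or LabelingThresholds()
    rows = []
    for cluster, profile in partition.cluster_profiles.iterrows():
        name, trace = _label_profile(profile, thr)
        rows.append({"cluster": cluster, "bundle": name, "rule_trace": trace})
    return pd.DataFrame(rows).set_index("cluster")


def village_bundles(partition: BundlePartition,
                    labeling: pd.DataFrame) -> pd.DataFrame:
    """Join cluster assignments with bundle names per village (and date)."""
    out = partition.assignments.copy()
    out["bundle"] = labeling["bundle"].reindex(out["cluster"]).to_numpy()
    return out


def bundle_transfer(
    labels_t0: pd.Series,
    labels_t1: pd.Series,
    transitions: pd.Series | None = None,
) -> dict[str, pd.DataFrame]:
    """Row-stochastic 7x7 bundle transfer matrices between two dates.

    ``labels_*`` map village_id -> bundle name.  Returns the overall matrix
    under key "overall" plus one per transition type when ``transitions``
    (village_id -> type name) is given.
    """
    common = labels_t0.index.intersection(labels_t1.index)
    if len(common) != len(labels_t0) or len(common) != len(labels_t1):
        raise ValueError("village ids do not match between dates")

    def matrix(ids: pd.Index) -> pd.DataFrame:
        counts = pd.crosstab(labels_t0.loc[ids], labels_t1.loc[ids])
        counts = counts.reindex(index=list(BUNDLE_NAMES),
                                columns=list(BUNDLE_NAMES), fill_value=0).astype(float)
        sums = counts.sum(axis=1)
        return counts.div(sums.where(sums > 0, 1.0), axis=0)

    out = {"overall": matrix(common)}
    if transitions is not None:
        for t in pd.unique(transitions.reindex(common).dropna()):
            ids = common[transitions.reindex(common) == t]
            if len(ids):
                out[str(t)] = matrix(pd.Index(ids))
    return out
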