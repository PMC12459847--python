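"""End-to-end pipeline: synthesis -> zonation -> ES layers -> interactions -> bundles.

The pipeline is lazy: each stage is a cached property of :class:`PipelineState`,
so partial runs (e.g. only features) do no extra work.  ``run_pipeline``
executes everything, writes compact CSV/JSON/GeoJSON outputs and a manifest
with a config snapshot and per-file SHA-256 hashes; rerunning from the
manifest reproduces the outputs hash-identically.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field, replace
from functools import cached_property
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as pio
from .bundles import (
    BundlePartition,
    SOMConfig,
    bundle_transfer,
    label_bundles,
    select_k,
    village_bundles,
)
from .es_models import ES_NAMES, ESParams, assemble_es_stack
from .grids import RasterLayer
from .interactions import (
    CCDMConfig,
    DISSERVICES,
    aggregate_villages,
    ccdm_table,
    deviational_ellipse,
    level_transfer,
    mean_d_by_group,
    normalize,
    spearman_matrix,
    stratified_spearman,
    village_transition_attribution,
    village_zone_attribution,
)
from .synthetic import (
    SOM_NAMES,
    LandscapeScenario,
    generate_labeled_points,
    generate_landscape_pair,
    generate_villages,
)
from .zonation import (
    FEATURE_NAMES,
    ClassifierSpec,
    PoiFunctionConfig,
    ZoneMap,
    assemble_features,
    classify_zones,
    mask_water,
    train_classifier,
    transfer_matrix,
    type_transitions,
)

log = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Full configuration of one pipeline run.

    The global ``seed`` drives every stochastic stage through derived
    sub-seeds; per-stage seeds in the nested configs are overridden.
    """

    scenario: LandscapeScenario = field(default_factory=LandscapeScenario)
    poi: PoiFunctionConfig = field(default_factory=PoiFunctionConfig)
    classifier: ClassifierSpec = field(default_factory=ClassifierSpec)
    es: ESParams = field(default_factory=ESParams)
    ccdm: CCDMConfig = field(default_factory=CCDMConfig)
    som: SOMConfig = field(default_factory=SOMConfig)
    n_labeled_points: int = 1000
    min_water_km2: float = 1.0
    rural_to_urban: str = "urban_expansion"
    seed: int = 0

    def derived_seeds(self) -> dict[str, int]:
        state = np.random.SeedSequence(self.seed).generate_state(6)
        names = ("scenario", "points_t0", "points_t1",
                 "classifier_t0", "classifier_t1", "som")
        return {n: int(s % (2**31)) for n, s in zip(names, state)}

    def to_dict(self) -> dict:
        d = asdict(self)
        d["poi"]["weights"] = dict(self.poi.weights)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        def build(key, klass):
            if key in d and isinstance(d[key], dict):
                sub = dict(d[key])
                if key == "scenario" and sub.get("core_centers") is not None:
                    sub["core_centers"] = [tuple(c) for c in sub["core_centers"]]
                if key == "classifier" and "hidden_sizes" in sub:
                    sub["hidden_sizes"] = tuple(sub["hidden_sizes"])
                if key == "som" and "k_range" in sub:
                    sub["k_range"] = tuple(sub["k_range"])
                if key == "es":
                    for tbl in ("ki", "carbon_pools"):
                        if tbl in sub:
                            sub[tbl] = {int(k): (tuple(v) if isinstance(v, (list, tuple)) else v)
                                        for k, v in sub[tbl].items()}
                    sub.pop("habitat", None)  # habitat defaults; not YAML-configurable
                d[key] = klass(**sub)
        build("scenario", LandscapeScenario)
        build("poi", PoiFunctionConfig)
        build("classifier", ClassifierSpec)
        build("es", ESParams)
        build("ccdm", CCDMConfig)
        build("som", SOMConfig)
        return cls(**d)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        return cls.from_dict(pio.load_yaml(path))


class _WarningCounter(logging.Handler):
    def __init__(self) -> None:
        super().__init__(level=logging.WARNING)
        self.count = 0

    def emit(self, record: logging.LogRecord) -> None:  # noqa: D102
        self.count += 1


class PipelineState:
    """Lazy stage graph over one configuration."""

    def __init__(self, config: PipelineConfig) -> None:
        self.config = config
        self.seeds = config.derived_seeds()
        self.scenario = replace(config.scenario, seed=self.seeds["scenario"])

    # -- synthesis ---------------------------------------------------------

    @cached_property
    def landscapes(self):
        return generate_landscape_pair(self.scenario)

    @property
    def stacks(self):
        return self.landscapes[0], self.landscapes[1]

    @property
    def zone_truth(self):
        return self.landscapes[2], self.landscapes[3]

    @cached_property
    def villages(self):
        return generate_villages(self.scenario)

    # -- zonation ----------------------------------------------------------

    @cached_property
    def water_masks(self):
        return tuple(
            mask_water(s, self.config.min_water_km2) for s in self.stacks
        )

    @cached_property
    def features(self):
        return tuple(
            assemble_features(s, self.scenario.refine_factor, mask=m,
                              config=self.config.poi)
            for s, m in zip(self.stacks, self.water_masks)
        )

    @cached_property
    def labeled_points(self):
        out = []
        for i, (stack, truth) in enumerate(zip(self.stacks, self.zone_truth)):
            out.append(generate_labeled_points(
                stack, truth, self.config.n_labeled_points,
                seed=self.seeds[f"points_t{i}"],
                refine_factor=self.scenario.refine_factor,
                poi_config=self.config.poi,
                min_water_km2=self.config.min_water_km2,
            ))
        return tuple(out)

    @cached_property
    def classifiers(self):
        out = []
        for i, pts in enumerate(self.labeled_points):
            spec = replace(self.config.classifier, seed=self.seeds[f"classifier_t{i}"])
            out.append(train_classifier(pts, spec))
        return tuple(out)

    @cached_property
    def zones(self) -> tuple[ZoneMap, ZoneMap]:
        return tuple(
            classify_zones(f, clf, date_tag=f"t{i}")
            for i, (f, clf) in enumerate(zip(self.features, self.classifiers))
        )

    @cached_property
    def transitions(self):
        return type_transitions(*self.zones, rural_to_urban=self.config.rural_to_urban)

    @cached_property
    def transfer(self):
        return transfer_matrix(*self.zones)

    # -- ecosystem services --------------------------------------------------

    @cached_property
    def es_stacks(self):
        return tuple(assemble_es_stack(s, self.config.es) for s in self.stacks)

    @cached_property
    def village_es_raw(self) -> pd.DataFrame:
        tables = [
            aggregate_villages(es, self.villages, self.scenario.refine_factor)
            for es in self.es_stacks
        ]
        return pd.concat(tables, ignore_index=True)

    @cached_property
    def village_es_normalized(self) -> pd.DataFrame:
        return normalize(self.village_es_raw)

    @cached_property
    def village_transitions(self) -> pd.Series:
        return village_transition_attribution(self.villages, self.transitions)

    # -- interactions --------------------------------------------------------

    @cached_property
    def spearman(self):
        table = self.village_es_normalized
        out = {
            f"levels_{d}": spearman_matrix(table[table.date_tag == d])
            for d in sorted(table.date_tag.unique())
        }
        out["changes_overall"] = spearman_matrix(table, mode="changes")
        per_type = stratified_spearman(table, self.village_transitions,
                                       mode="changes")
        out.update({f"changes_{k}": v for k, v in per_type.items()})
        return out

    @cached_property
    def ccdm(self):
        table = self.village_es_normalized
        dates = sorted(table.date_tag.unique())
        return tuple(
            ccdm_table(table[table.date_tag == d], self.config.ccdm)
            for d in dates
        )

    @cached_property
    def level_transfer_matrix(self) -> pd.DataFrame:
        return level_transfer(*self.ccdm)

    @cached_property
    def mean_d_by_transition(self) -> pd.DataFrame:
        rows = {}
        for ccdm in self.ccdm:
            d = ccdm["date_tag"].iloc[0]
            rows[d] = mean_d_by_group(ccdm, self.village_transitions)
        return pd.DataFrame(rows)

    @cached_property
    def ellipses(self):
        cents = self.villages.centroids()
        out = {}
        for ccdm in self.ccdm:
            d = ccdm["date_tag"].iloc[0]
            by_village = ccdm.set_index("village_id")
            w = (by_village["D"] <= 0.5).astype(float).reindex(cents.index).fillna(0.0)
            if w.sum() == 0:
                log.info("no incoordination villages at %s; unweighted ellipse", d)
                w[:] = 1.0
            out[d] = deviational_ellipse(cents.to_numpy(), w.to_numpy())
        return out

    # -- bundles ---------------------------------------------------------------

    @cached_property
    def som_table(self) -> pd.DataFrame:
        """Normalized village table on SOM orientation (TN/TP inverted)."""
        t = self.village_es_normalized.copy()
        for name in DISSERVICES:
            t[name] = 1.0 - t[name]
        t = t.rename(columns={"TN": "TNp", "TP": "TPp"})
        return t[["village_id", "date_tag", *SOM_NAMES]]

    @cached_property
    def bundle_partition(self) -> BundlePartition:
        som_cfg = replace(self.config.som, seed=self.seeds["som"])
        return select_k(self.som_table, som_cfg)

    @cached_property
    def bundle_labels(self) -> pd.DataFrame:
        return label_bundles(self.bundle_partition)

    @cached_property
    def village_bundle_table(self) -> pd.DataFrame:
        return village_bundles(self.bundle_partition, self.bundle_labels)

    @cached_property
    def bundle_transfer_matrices(self):
        t = self.village_bundle_table
        dates = sorted(t.date_tag.unique())
        s0 = t[t.date_tag == dates[0]].set_index("village_id")["bundle"]
        s1 = t[t.date_tag == dates[1]].set_index("village_id")["bundle"]
        return bundle_transfer(s0, s1, self.village_transitions)


# ---------------------------------------------------------------------------
# output writing and manifest


def _zone_layer(z: ZoneMap, name: str) -> RasterLayer:
    return RasterLayer(values=z.values, name=name, units="zone code",
                       cell_size_m=z.cell_size_m, origin=z.origin)


def _safe(name: str) -> str:
    return name.replace(" ", "_").replace("/", "-")


def write_outputs(state: PipelineState, out_dir: str | Path) -> list[Path]:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    def w(path: Path) -> Path:
        written.append(path)
        return path

    for i, (truth, zones) in enumerate(zip(state.zone_truth, state.zones)):
        w(pio.write_raster(_zone_layer(truth, "zone_truth"), out / f"zones_truth_t{i}.asc"))
        w(pio.write_raster(_zone_layer(zones, "zones"), out / f"zones_t{i}.asc"))
        feats = state.features[i]
        df = pd.DataFrame({n: feats.features[n].ravel() for n in FEATURE_NAMES})
        df.insert(0, "cell", np.arange(len(df)))
        w(pio.write_table(df, out / f"features_t{i}.csv"))

    metrics = {
        f"t{i}": {"accuracy": clf.accuracy,
                  "per_class_recall": clf.per_class_recall.tolist()}
        for i, clf in enumerate(state.classifiers)
    }
    p = out / "classifier_metrics.json"
    p.write_text(json.dumps(metrics, indent=2, sort_keys=True))
    w(p)

    tmap = state.transitions
    w(pio.write_raster(
        RasterLayer(tmap.values, "transitions", cell_size_m=tmap.cell_size_m),
        out / "transitions.asc"))
    w(pio.write_table(tmap.shares().rename("share").to_frame(),
                      out / "transition_shares.csv", index=True))
    shares, areas = state.transfer
    w(pio.write_table(shares, out / "transfer_matrix.csv", index=True))
    w(pio.write_table(areas, out / "transfer_areas_km2.csv", index=True))

    w(pio.write_villages(state.villages, out / "villages.geojson"))
    w(pio.write_table(state.village_es_raw, out / "village_es_raw.csv"))
    w(pio.write_table(state.village_es_normalized, out / "village_es_normalized.csv"))

    for key, mat in state.spearman.items():
        w(pio.write_table(mat, out / f"spearman_{_safe(key)}.csv", index=True))

    for ccdm in state.ccdm:
        d = ccdm["date_tag"].iloc[0]
        w(pio.write_table(ccdm, out / f"ccdm_{d}.csv"))
    w(pio.write_table(state.level_transfer_matrix, out / "level_transfer.csv",
                      index=True))
    w(pio.write_table(state.mean_d_by_transition, out / "mean_d_by_transition.csv",
                      index=True))

    ell = {
        d: dataclasses.asdict(e) for d, e in state.ellipses.items()
    }
    p = out / "ellipses.json"
    p.write_text(json.dumps(ell, indent=2, sort_keys=True))
    w(p)

    part = state.bundle_partition
    db = pd.DataFrame(sorted(part.db_scores.items()), columns=["k", "davies_bouldin"])
    w(pio.write_table(db, out / "bundle_db_scores.csv"))
    w(pio.write_table(part.cluster_profiles, out / "bundle_profiles.csv", index=True))
    w(pio.write_table(state.bundle_labels, out / "bundle_labels.csv", index=True))
    w(pio.write_table(state.village_bundle_table, out / "bundle_assignments.csv"))
    for key, mat in state.bundle_transfer_matrices.items():
        w(pio.write_table(mat, out / f"bundle_transfer_{_safe(key)}.csv", index=True))
    return written


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


@dataclass
class RunManifest:
    seed: int
    config: dict
    stages: list[str]
    file_hashes: dict[str, str]
    warnings: int
    started: float
    finished: float

    def write(self, path: str | Path) -> Path:
        path = Path(path)
        path.write_text(json.dumps(asdict(self), indent=2, sort_keys=True))
        return path

    @classmethod
    def read(cls, path: str | Path) -> "RunManifest":
        return cls(**json.loads(Path(path).read_text()))


STAGES = ("synth", "features", "train", "classify", "transitions", "es",
          "aggregate", "interact", "ccdm", "ellipse", "bundles")


def run_pipeline(config: PipelineConfig, out_dir: str | Path) -> RunManifest:
    """Execute every stage, write outputs and a manifest into ``out_dir``."""
    counter = _WarningCounter()
    logging.getLogger().addHandler(counter)
    started = time.time()
    try:
        state = PipelineState(config)
        files = write_outputs(state, out_dir)
    finally:
        logging.getLogger().removeHandler(counter)
    manifest = RunManifest(
        seed=config.seed,
        config=config.to_dict(),
        stages=list(STAGES),
        file_hashes={f.name: _sha256(f) for f in sorted(files)},
        warnings=counter.count,
        started=started,
        finished=time.time(),
    )
    manifest.write(Path(out_dir) / "manifest.json")
    return manifest


def run_from_manifest(manifest_path: str | Path, out_dir: str | Path) -> RunManifest:
    """Re-execute a run from its manifest's config snapshot."""
    prev = RunManifest.read(manifest_path)
    config = PipelineConfig.from_dict(prev.config)
    return run_pipeline(config, out_dir)
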