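"""End-to-end orchestration: simulate -> preprocess -> segment -> spectra
-> features -> rank -> classify -> evaluate -> map.

A :class:`PipelineConfig` holds every stage's parameters plus one master
seed, which is expanded deterministically into independent per-stage
streams.  Each stage writes its artifacts into the run directory and
records them in ``manifest.json`` together with the config hash; on a
rerun with an unchanged hash, stages whose outputs are all present are
skipped and their artifacts reloaded.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as cfio
from .classification import (
    classify_and_map,
    plot_accuracy_curves,
    plot_thematic_map,
    run_incremental_svm,
    select_optimal_k,
)
from .containers import PointCloud, TreeRecord
from .feature_selection import prune_correlated, rank_importance
from .hsi_features import assemble_hsi_features
from .lidar_features import assemble_lidar_features
from .metrics import confusion_from_predictions, evaluate, write_confusion_csv
from .preprocess import denoise, filter_ground, normalize_heights, smooth_spectra
from .segmentation import (
    crown_metrics,
    crown_outline,
    match_to_reference,
    segment_trees,
)
from .spectra import extract_crown_spectra
from .synthetic import SceneConfig, generate_scene, scene_preset

STAGES = (
    "simulate", "preprocess", "segment", "spectra", "features",
    "rank", "classify", "evaluate", "map",
)
SOURCES = ("HSI", "LiDAR", "HSI+LiDAR")


@dataclass
class PipelineConfig:
    out_dir: str = "run"
    seed: int = 0
    scene_preset: str = "sparse"
    scene: dict = field(default_factory=dict)          # SceneConfig overrides
    denoise: dict = field(default_factory=lambda: dict(
        k_neighbors=10, sd_multiplier=3.0))
    ground: dict = field(default_factory=lambda: dict(
        iter_angle=10.0, iter_distance=1.5, cell=20.0))
    smoothing: dict = field(default_factory=lambda: dict(window=7, polyorder=2))
    segmentation: dict = field(default_factory=lambda: dict(
        spacing_threshold=2.0, min_points=50, min_height=2.0))
    matching: dict = field(default_factory=lambda: dict(
        max_dist=2.0, height_tolerance=0.20))
    spectra: dict = field(default_factory=lambda: dict(n_sunlit=100))
    features: dict = field(default_factory=lambda: dict(
        n_pca=10, n_mnf=15, n_ica=20, mresri_literature=False))
    selection: dict = field(default_factory=lambda: dict(
        n_trees_rf=500, r_threshold=0.90))
    classification: dict = field(default_factory=lambda: dict(
        k_max=40, n_repetitions=120, train_fraction=0.60, C=10.0,
        stability_margin=0.0))
    sources: list = field(default_factory=lambda: list(SOURCES))
    save_cloud_csv: bool = True

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "PipelineConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        merged = cls()
        for key, val in raw.items():
            default = getattr(merged, key)
            if isinstance(default, dict) and isinstance(val, dict):
                sub_unknown = set(val) - set(default) if default else set()
                if key != "scene" and sub_unknown:
                    raise ValueError(
                        f"unknown config keys under {key!r}: {sorted(sub_unknown)}"
                    )
                default.update(val)
            else:
                setattr(merged, key, val)
        return merged

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def config_hash(self) -> str:
        canon = json.dumps(self.to_dict(), sort_keys=True)
        return hashlib.sha256(canon.encode()).hexdigest()[:16]

    def stage_seed(self, stage: str, extra: str = "") -> int:
        """Deterministic per-stage seed from the master seed."""
        h = hashlib.sha256(f"{self.seed}:{stage}:{extra}".encode()).digest()
        return int.from_bytes(h[:4], "little") % (2**31 - 1)


class PipelineRun:
    """Executes the stages against one run directory."""

    def __init__(self, config: PipelineConfig):
        self.cfg = config
        self.out = Path(config.out_dir)
        self.out.mkdir(parents=True, exist_ok=True)
        self.manifest_path = self.out / "manifest.json"
        self.manifest = self._load_manifest()
        self.state: dict = {}

    # -- manifest bookkeeping ------------------------------------------------
    def _load_manifest(self) -> dict:
        if self.manifest_path.exists():
            with open(self.manifest_path) as fh:
                m = json.load(fh)
            if m.get("config_hash") == self.cfg.config_hash():
                return m
        return {"config_hash": self.cfg.config_hash(), "stages": {}}

    def _save_manifest(self) -> None:
        with open(self.manifest_path, "w") as fh:
            json.dump(self.manifest, fh, indent=2)

    def _stage_done(self, stage: str) -> bool:
        entry = self.manifest["stages"].get(stage)
        if not entry or not entry.get("completed"):
            return False
        return all((self.out / p).exists() for p in entry["outputs"])

    def _mark_done(self, stage: str, outputs, started: float) -> None:
        self.manifest["stages"][stage] = {
            "completed": True,
            "outputs": [str(p) for p in outputs],
            "seconds": round(time.time() - started, 2),
        }
        self._save_manifest()

    # -- stages --------------------------------------------------------------
    def run(self) -> dict:
        for stage in STAGES:
            started = time.time()
            runner = getattr(self, f"_stage_{stage}")
            try:
                if self._stage_done(stage):
                    runner(resume=True)
                    self.manifest["stages"][stage]["skipped"] = True
                    self._save_manifest()
                else:
                    outputs = runner(resume=False)
                    self._mark_done(stage, outputs, started)
            except Exception as exc:
                raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc
        return self.state

    def _stage_simulate(self, resume: bool):
        scene_cfg = scene_preset(
            self.cfg.scene_preset,
            seed=self.cfg.stage_seed("scene"),
            **self.cfg.scene,
        )
        if resume:
            cloud = PointCloud.load_csv(self.out / "cloud_raw.csv")
            cube = cfio.read_envi(self.out / "cube")
            stems = pd.read_csv(self.out / "stems.csv")
            from shapely.geometry import Point

            polys = {
                int(r.tree_id): Point(r.x, r.y).buffer(r.crown_radius,
                                                       quad_segs=32)
                for r in stems.itertuples()
            }
            from .containers import GroundTruth

            truth = GroundTruth(stems=stems, crown_polygons=polys)
        else:
            cloud, cube, truth = generate_scene(scene_cfg)
        self.state.update(cloud=cloud, cube=cube, truth=truth,
                          scene_cfg=scene_cfg)
        if resume:
            return None
        outputs = ["stems.csv", "cube.hdr", "cube.bsq"]
        truth.stems.to_csv(self.out / "stems.csv", index=False)
        cfio.write_envi(cube, self.out / "cube")
        if self.cfg.save_cloud_csv:
            cloud.save_csv(self.out / "cloud_raw.csv")
            outputs.append("cloud_raw.csv")
        with open(self.out / "scene_config.yaml", "w") as fh:
            yaml.safe_dump(
                {**dataclasses.asdict(scene_cfg),
                 "config_hash": self.cfg.config_hash()}, fh)
        outputs.append("scene_config.yaml")
        return outputs

    def _stage_preprocess(self, resume: bool):
        if resume:
            cloud = PointCloud.load_csv(self.out / "cloud_normalized.csv")
            cube = cfio.read_envi(self.out / "cube_smooth")
            self.state.update(cloud_norm=cloud, cube_smooth=cube)
            return None
        cloud = denoise(self.state["cloud"], **self.cfg.denoise)
        cloud = filter_ground(cloud, **self.cfg.ground)
        cloud = normalize_heights(cloud)
        cube = smooth_spectra(self.state["cube"], **self.cfg.smoothing)
        self.state.update(cloud_norm=cloud, cube_smooth=cube)
        outputs = ["cube_smooth.hdr", "cube_smooth.bsq"]
        cfio.write_envi(cube, self.out / "cube_smooth")
        if self.cfg.save_cloud_csv:
            cloud.save_csv(self.out / "cloud_normalized.csv")
            outputs.append("cloud_normalized.csv")
        return outputs

    def _stage_segment(self, resume: bool):
        if resume:
            from shapely.geometry import shape as shp_shape

            trees = []
            crowns = cfio.read_crowns_geojson(self.out / "crowns.geojson")
            seg_cloud = PointCloud.load_csv(self.out / "cloud_segmented.csv")
            labels = pd.read_csv(self.out / "cloud_segment_labels.csv")[
                "tree_label"].to_numpy()
            for props, geom in crowns:
                members = np.nonzero(labels == props["tree_id"])[0]
                rec = TreeRecord(
                    tree_id=props["tree_id"],
                    points=seg_cloud.subset(members),
                    apex_xy=(props["apex_x"], props["apex_y"]),
                    crown_polygon=geom,
                    height=props["H_T"],
                    crown_width=props["W_C"],
                    crown_area=props["A_C"],
                    crown_volume=props["V_C"],
                    species=props["species"],
                )
                trees.append(rec)
            with open(self.out / "segmentation_report.json") as fh:
                seg_report = json.load(fh)
            self.state.update(trees=trees, seg_report=seg_report)
            return None

        cloud = self.state["cloud_norm"]
        trees = segment_trees(cloud, **self.cfg.segmentation)
        kept = []
        for t in trees:
            try:
                crown_outline(t)
                crown_metrics(t)
                kept.append(t)
            except ValueError:
                continue
        trees = kept
        truth = self.state["truth"]
        match = match_to_reference(trees, truth, **self.cfg.matching)
        # species labels for matched trees, from the reference stem map
        stems = truth.stems.reset_index(drop=True)
        for t in trees:
            si = match.assignments.get(t.tree_id)
            if si is not None:
                t.species = str(stems.loc[si, "species"])
        self.state.update(trees=trees, seg_report=match.to_dict())

        cfio.write_crowns_geojson(trees, self.out / "crowns.geojson")
        with open(self.out / "segmentation_report.json", "w") as fh:
            json.dump(match.to_dict(), fh, indent=2)
        outputs = ["crowns.geojson", "segmentation_report.json"]
        if self.cfg.save_cloud_csv:
            labels = np.full(len(cloud), -1, dtype=int)
            # rebuild per-point labels from the tree subsets via coordinates
            cloud.save_csv(self.out / "cloud_segmented.csv")
            key = {}
            for i, (x, y, z) in enumerate(zip(cloud.x, cloud.y, cloud.z)):
                key[(round(x, 6), round(y, 6), round(z, 6))] = i
            for t in trees:
                for x, y, z in zip(t.points.x, t.points.y, t.points.z):
                    idx = key.get((round(x, 6), round(y, 6), round(z, 6)))
                    if idx is not None:
                        labels[idx] = t.tree_id
            pd.DataFrame({"tree_label": labels}).to_csv(
                self.out / "cloud_segment_labels.csv", index=False)
            outputs += ["cloud_segmented.csv", "cloud_segment_labels.csv"]
        return outputs

    def _stage_spectra(self, resume: bool):
        trees = self.state["trees"]
        path = self.out / "crown_spectra.csv"
        if resume:
            df = pd.read_csv(path, index_col=0)
            by_id = {t.tree_id: t for t in trees}
            for tid, row in df.iterrows():
                if tid in by_id:
                    by_id[tid].crown_spectrum = row.to_numpy(float)
            return None
        extract_crown_spectra(trees, self.state["cube_smooth"],
                              n_sunlit=self.cfg.spectra["n_sunlit"])
        wl = self.state["cube_smooth"].wavelengths
        rows = {t.tree_id: t.crown_spectrum for t in trees
                if t.crown_spectrum is not None}
        df = pd.DataFrame.from_dict(
            rows, orient="index", columns=[f"{w:.2f}" for w in wl]
        )
        df.index.name = "tree_id"
        df.to_csv(path, float_format="%.6f")
        return ["crown_spectra.csv"]

    def _stage_features(self, resume: bool):
        trees = self.state["trees"]
        labeled = [t for t in trees if t.species != "unknown"
                   and t.crown_spectrum is not None]
        wl = self.state["cube_smooth"].wavelengths
        hsi, models = assemble_hsi_features(
            labeled, wl, seed=self.cfg.stage_seed("ica"),
            **self.cfg.features,
        )
        lidar, flags = assemble_lidar_features(labeled)
        lidar = lidar.loc[hsi.index]
        from .containers import merge_feature_tables

        fused = merge_feature_tables(hsi, lidar)
        labels = pd.Series({t.tree_id: t.species for t in labeled}).loc[hsi.index]
        self.state.update(
            hsi_table=hsi, lidar_table=lidar, fused_table=fused,
            labels=labels, transform_models=models,
        )
        if resume:
            return None
        outputs = []
        for name, table in (("hsi", hsi), ("lidar", lidar), ("fused", fused)):
            table.to_csv(self.out / f"features_{name}.csv",
                         float_format="%.6g")
            with open(self.out / f"features_{name}.schema.json", "w") as fh:
                json.dump(table.attrs.get("provenance", {}), fh)
            outputs += [f"features_{name}.csv", f"features_{name}.schema.json"]
        labels.rename("species").to_csv(self.out / "labels.csv")
        outputs.append("labels.csv")
        flags.to_csv(self.out / "lidar_flags.csv")
        outputs.append("lidar_flags.csv")
        return outputs

    def _tables_by_source(self):
        return {
            "HSI": self.state["hsi_table"],
            "LiDAR": self.state["lidar_table"],
            "HSI+LiDAR": self.state["fused_table"],
        }

    def _stage_rank(self, resume: bool):
        labels = self.state["labels"]
        rankings = {}
        for source, table in self._tables_by_source().items():
            if source not in self.cfg.sources:
                continue
            ranking = rank_importance(
                table, labels,
                n_trees_rf=self.cfg.selection["n_trees_rf"],
                seed=self.cfg.stage_seed("rf", source),
            )
            rankings[source] = prune_correlated(
                ranking, table, self.cfg.selection["r_threshold"]
            )
        self.state["rankings"] = rankings
        if resume:
            return None
        outputs = []
        for source, ranking in rankings.items():
            tag = source.replace("+", "_")
            ranking.to_frame().to_csv(
                self.out / f"ranking_{tag}.csv", index=False)
            outputs.append(f"ranking_{tag}.csv")
        return outputs

    def _stage_classify(self, resume: bool):
        labels = self.state["labels"]
        ccfg = self.cfg.classification
        runs = {}
        for source, table in self._tables_by_source().items():
            if source not in self.cfg.sources:
                continue
            run = run_incremental_svm(
                table, self.state["rankings"][source], labels,
                source=source,
                k_max=ccfg["k_max"],
                n_repetitions=ccfg["n_repetitions"],
                train_fraction=ccfg["train_fraction"],
                C=ccfg["C"],
                seed=self.cfg.stage_seed("svm", source),
            )
            select_optimal_k(run, ccfg["stability_margin"])
            runs[source] = run
        self.state["runs"] = runs
        if resume:
            return None
        frames = [run.to_frame() for run in runs.values()]
        pd.concat(frames).to_csv(self.out / "accuracy_curves.csv", index=False)
        plot_accuracy_curves(list(runs.values()),
                             self.out / "accuracy_curves.png")
        with open(self.out / "optimal_k.json", "w") as fh:
            json.dump(
                {s: {"optimal_k": r.optimal_k,
                     "mean_oa": float(r.mean_oa[r.optimal_k - 1])}
                 for s, r in runs.items()}, fh, indent=2)
        return ["accuracy_curves.csv", "accuracy_curves.png", "optimal_k.json"]

    def _stage_evaluate(self, resume: bool):
        labels = self.state["labels"]
        reports = {}
        for source, run in self.state["runs"].items():
            table = self._tables_by_source()[source]
            fc, model = classify_and_map(
                [], table, labels, run,
                seed=self.cfg.stage_seed("final", source),
                C=self.cfg.classification["C"],
            )
            # confusion over the held-out split of the final model
            from sklearn.model_selection import StratifiedShuffleSplit

            splitter = StratifiedShuffleSplit(
                n_splits=1, train_size=run.train_fraction,
                random_state=self.cfg.stage_seed("final", source),
            )
            X = table[run.feature_order[: run.optimal_k]]
            (tr, te), = splitter.split(X, labels)
            pred = model.predict(X.iloc[te])
            cm = confusion_from_predictions(
                labels.iloc[te].to_numpy(), pred,
                labels=sorted(labels.unique()),
            )
            reports[source] = {
                "confusion": cm,
                "report": evaluate(cm),
                "model": model,
            }
        self.state["reports"] = reports
        if resume:
            return None
        outputs = []
        summary = {}
        for source, r in reports.items():
            tag = source.replace("+", "_")
            write_confusion_csv(r["confusion"], self.out / f"confusion_{tag}.csv")
            with open(self.out / f"evaluation_{tag}.json", "w") as fh:
                json.dump(r["report"].to_dict(), fh, indent=2)
            outputs += [f"confusion_{tag}.csv", f"evaluation_{tag}.json"]
            summary[source] = {"OA": r["report"].oa, "Kappa": r["report"].kappa}
        summary["segmentation"] = self.state["seg_report"]
        with open(self.out / "evaluation_summary.json", "w") as fh:
            json.dump(summary, fh, indent=2)
        outputs.append("evaluation_summary.json")
        return outputs

    def _stage_map(self, resume: bool):
        if resume:
            return None
        trees = self.state["trees"]
        labels = self.state["labels"]
        source = ("HSI+LiDAR" if "HSI+LiDAR" in self.state["runs"]
                  else list(self.state["runs"])[0])
        run = self.state["runs"][source]
        table = self._tables_by_source()[source]
        fc, _ = classify_and_map(
            trees, table, labels, run,
            seed=self.cfg.stage_seed("map"),
            path=self.out / "thematic_map.geojson",
        )
        preds = {f["properties"]["tree_id"]: f["properties"]["species_pred"]
                 for f in fc["features"]}
        plot_thematic_map(trees, preds, self.out / "thematic_map.png")
        return ["thematic_map.geojson", "thematic_map.png"]


def run_pipeline(config: PipelineConfig) -> dict:
    """Run every stage; returns the in-memory state dict."""
    return PipelineRun(config).run()
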