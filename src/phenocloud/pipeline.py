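"""Declarative orchestration of the full trait pipeline.

A YAML config lists input clouds, optional crop regions and per-organ
parameters; each declared organ is cropped and routed to its trait stage
(stem -> skeleton, leaf -> surface reconstruction, fruit -> ellipsoid
fit).  Per-organ failures are recorded in the report and the run
continues — partial results beat none in a survey context.  The report
carries provenance (input files, config hash, seed) so a run can be
reproduced exactly.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import leaf as leaf_mod
from . import skeleton as skel_mod
from .calibration import ScaleCalibration, apply_scale
from .cloud import PointCloud
from .fruit import fruit_volume_pipeline
from .io import read_point_cloud, write_mesh, write_point_cloud
from .segment import BoxRegion, PolygonRegion, crop

logger = logging.getLogger("phenocloud")

__all__ = ["TraitReport", "run_pipeline", "config_hash", "load_config"]

_TRAIT_UNITS = {
    "inter_node_length_m": "m",
    "leaf_area_m2": "m^2",
    "fruit_volume_m3": "m^3",
}


@dataclass
class TraitReport:
    """Per-measurement trait rows plus run provenance."""

    rows: pd.DataFrame
    provenance: dict = field(default_factory=dict)

    def to_csv(self, path) -> None:
        self.rows.to_csv(path, index=False)

    def to_json(self, path) -> None:
        payload = {
            "provenance": self.provenance,
            "rows": self.rows.to_dict(orient="records"),
        }
        Path(path).write_text(json.dumps(payload, indent=2, default=float))


def config_hash(config: dict) -> str:
    """SHA-256 of the canonical JSON form of a config mapping."""
    canonical = json.dumps(config, sort_keys=True, separators=(",", ":"), default=str)
    return hashlib.sha256(canonical.encode()).hexdigest()


def load_config(path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict) or "organs" not in cfg:
        raise ValueError(f"config {path} must be a mapping with an 'organs' list")
    return cfg


def _region_from_config(spec: dict):
    kind = spec.get("kind", "box")
    if kind == "box":
        return BoxRegion(tuple(spec["min"]), tuple(spec["max"]))
    if kind == "polygon":
        return PolygonRegion(tuple(map(tuple, spec["vertices"])),
                             tuple(spec["view_direction"]))
    raise ValueError(f"unknown region kind {kind!r}")


def _load_organ_cloud(organ: dict, base: Path, cal: ScaleCalibration | None) -> PointCloud:
    cloud = read_point_cloud(base / organ["input"])
    if not cloud.is_metric:
        if cal is None:
            raise ValueError(
                f"organ {organ.get('id')}: cloud is not metric and no "
                "calibration was supplied")
        cloud = apply_scale(cloud, cal)
    if "region" in organ:
        cloud = crop(cloud, _region_from_config(organ["region"]))
    return cloud


def _measure_stem(cloud: PointCloud, params: dict, artifacts: Path | None, organ_id):
    cloud.require_metric("stem trait extraction")
    cparams = skel_mod.ContractionParams(**params.get("contraction", {}))
    spacing = params.get("sample_spacing", 0.005)
    contracted = skel_mod.contract_point_cloud(cloud, cparams)
    graph = skel_mod.build_skeleton_graph(contracted, spacing)
    spacings = skel_mod.measure_internode_spacings(graph)
    nodes = skel_mod.extract_node_positions(graph)
    if artifacts is not None:
        write_point_cloud(contracted, artifacts / f"{organ_id}_skeleton.ply")
        node_rows = pd.DataFrame(
            [{"id": n.id, "x": n.position[0], "y": n.position[1],
              "z": n.position[2], "degree": n.degree, "kind": n.kind}
             for n in nodes])
        node_rows.to_csv(artifacts / f"{organ_id}_nodes.csv", index=False)
    rows = []
    for i, value in enumerate(spacings):
        rows.append({
            "trait": "inter_node_length_m",
            "value": float(value),
            "value_common": float(value) * 100.0,  # cm
            "diagnostics": json.dumps({
                "segment": i, "n_points": len(cloud),
                "n_skeleton_vertices": int(graph.nodes.shape[0]),
                "n_branch_nodes": int(graph.branch_nodes.size)}),
        })
    return rows


def _measure_leaf(cloud: PointCloud, params: dict, artifacts: Path | None, organ_id):
    mls = (leaf_mod.MLSParams(**params["mls"]) if "mls" in params else None)
    bpa = (leaf_mod.BPAParams(**params["bpa"]) if "bpa" in params else None)
    result = leaf_mod.leaf_area_pipeline(cloud, mls, bpa)
    if artifacts is not None:
        write_mesh(result.mesh, artifacts / f"{organ_id}_mesh.ply")
    return [{
        "trait": "leaf_area_m2",
        "value": result.area,
        "value_common": result.area_cm2,
        "diagnostics": json.dumps(result.diagnostics),
    }]


def _measure_fruit(cloud: PointCloud, params: dict, artifacts: Path | None, organ_id):
    fit, volume_cm3 = fruit_volume_pipeline(cloud)
    if artifacts is not None:
        from .fruit import ellipsoid_mesh

        write_mesh(ellipsoid_mesh(fit), artifacts / f"{organ_id}_ellipsoid.ply")
    a, b, c = fit.semi_axes
    return [{
        "trait": "fruit_volume_m3",
        "value": fit.volume,
        "value_common": volume_cm3,
        "diagnostics": json.dumps({
            "semi_axes_mm": [a * 1e3, b * 1e3, c * 1e3],
            "residual": fit.residual, "n_points": fit.n_points,
            "coverage": fit.coverage}),
    }]


_MEASURE = {"stem": _measure_stem, "leaf": _measure_leaf, "fruit": _measure_fruit}


def run_pipeline(config, base_dir=None, artifacts_dir=None) -> TraitReport:
    """Run every declared organ through its trait stage.

    ``config`` is a mapping or a YAML path.  Missing input files abort
    before any processing; failures inside a single organ's stage are
    recorded as error rows and the run continues."""
    if not isinstance(config, dict):
        base_dir = Path(base_dir) if base_dir else Path(config).parent
        config = load_config(config)
    base = Path(base_dir) if base_dir else Path(".")
    artifacts = None
    if artifacts_dir is not None:
        artifacts = Path(artifacts_dir)
        artifacts.mkdir(parents=True, exist_ok=True)

    cal = None
    cal_spec = config.get("calibration")
    if isinstance(cal_spec, str):
        cal = ScaleCalibration.from_json(base / cal_spec)
    elif isinstance(cal_spec, dict):
        cal = ScaleCalibration(**cal_spec)

    organs = config["organs"]
    missing = [o["input"] for o in organs if not (base / o["input"]).exists()]
    if missing:
        raise FileNotFoundError(f"missing input file(s): {missing}")

    rows = []
    for organ in organs:
        organ_id = organ.get("id", organ["input"])
        kind = organ["kind"]
        if kind not in _MEASURE:
            raise ValueError(f"organ {organ_id}: unknown kind {kind!r}")
        t0 = time.perf_counter()
        try:
            cloud = _load_organ_cloud(organ, base, cal)
            produced = _MEASURE[kind](cloud, organ.get("params", {}),
                                      artifacts, organ_id)
            for row in produced:
                row.update({"plant_id": organ.get("plant_id", ""),
                            "organ_id": organ_id, "status": "ok", "error": ""})
            rows.extend(produced)
            logger.info("organ %s (%s): %d row(s) in %.2fs",
                        organ_id, kind, len(produced), time.perf_counter() - t0)
        except Exception as exc:  # per-organ failures must not kill the survey
            logger.warning("organ %s (%s) failed: %s", organ_id, kind, exc)
            rows.append({
                "plant_id": organ.get("plant_id", ""), "organ_id": organ_id,
                "trait": {"stem": "inter_node_length_m",
                          "leaf": "leaf_area_m2",
                          "fruit": "fruit_volume_m3"}[kind],
                "value": np.nan, "value_common": np.nan,
                "diagnostics": "{}", "status": "error", "error": str(exc),
            })

    frame = pd.DataFrame(
        rows, columns=["plant_id", "organ_id", "trait", "value",
                       "value_common", "diagnostics", "status", "error"])
    provenance = {
        "inputs": [str(o["input"]) for o in organs],
        "config_hash": config_hash(config),
        "seed": config.get("seed"),
    }
    return TraitReport(frame, provenance)
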