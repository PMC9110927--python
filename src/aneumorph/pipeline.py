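"""Reproducible orchestration: config, manifests, batch feature extraction.

A run is described by a :class:`RunConfig` (deserializable from YAML).  The
pipeline executes the requested stages (cohort generation, feature
extraction, benchmarking) with per-case error isolation — one bad mesh is
recorded in the error ledger instead of killing the batch — and writes a
JSON manifest listing every output file with a content hash, the seeds and
the config hash, so equal manifests imply equal outputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import benchmark as bm
from .features import ALL_FEATURES, compute_descriptor
from .mesh import load_mesh
from .synthetic import AneurysmRecord, CohortSpec, make_cohort

log = logging.getLogger(__name__)

EXIT_OK = 0
EXIT_CONFIG_ERROR = 2
EXIT_DATA_ERROR = 3
EXIT_PARTIAL_FAILURE = 4
EXIT_INTERNAL_ERROR = 5


class ConfigError(ValueError):
    pass


@dataclass
class RunConfig:
    """Declarative description of one pipeline run."""

    output_dir: str = "aneumorph_run"
    stages: tuple[str, ...] = ("features",)
    mesh_paths: tuple[str, ...] = ()
    metadata_csv: str | None = None          # case_id, location, ruptured
    cut_type: str = "dome"
    families: tuple[str, ...] = ("geometry", "curvature", "writhe", "zernike")
    zernike_grid: int = 64
    cohort: dict = field(default_factory=dict)   # CohortSpec fields
    model: str = "NSI+LOC"
    folds: int = 5
    repeats: int = 20
    seed: int = 0

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        for key in ("stages", "mesh_paths", "families"):
            if key in raw and isinstance(raw[key], list):
                raw[key] = tuple(raw[key])
        return cls(**raw)

    def config_hash(self) -> str:
        blob = json.dumps(dataclasses.asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def run_pipeline(config: RunConfig) -> dict:
    """Execute the configured stages; return the run manifest.

    The manifest records config hash, seed, per-stage timing, output hashes
    and a per-case error ledger.  Exit-status semantics for CLI use:
    partial per-case failures set ``manifest['status']`` to 'partial'.
    """
    out_dir = Path(config.output_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "config_hash": config.config_hash(),
        "config": dataclasses.asdict(config),
        "seed": config.seed,
        "stages": {},
        "outputs": {},
        "errors": [],
        "status": "ok",
    }

    records: list[AneurysmRecord] = []
    meshes = {}

    for stage in config.stages:
        t0 = time.time()
        if stage == "cohort":
            spec = CohortSpec(seed=config.seed, **config.cohort)
            cohort = make_cohort(spec)
            mesh_dir = out_dir / "meshes"
            mesh_dir.mkdir(exist_ok=True)
            rows = []
            for mesh, rec in cohort:
                path = mesh_dir / f"{rec.case_id}.stl"
                mesh.save(path)
                meshes[rec.case_id] = mesh
                records.append(rec)
                rows.append({"case_id": rec.case_id, "location": rec.location,
                             "ruptured": rec.ruptured, "cut_type": rec.cut_type,
                             **rec.params})
            manifest_path = out_dir / "cohort_manifest.csv"
            pd.DataFrame(rows).to_csv(manifest_path, index=False)
            manifest["outputs"][str(manifest_path)] = _sha256(manifest_path)
        elif stage == "features":
            if not records:
                records, meshes = _load_cases(config, manifest)
            rows, index = [], []
            for rec in records:
                try:
                    desc = compute_descriptor(
                        meshes[rec.case_id], cut_type=rec.cut_type,
                        families=config.families,
                        zernike_grid=config.zernike_grid, seed=config.seed,
                    )
                except Exception as exc:  # noqa: BLE001 - per-case isolation
                    manifest["errors"].append({"case": rec.case_id, "error": str(exc)})
                    manifest["status"] = "partial"
                    continue
                rec.descriptor = desc
                rows.append(desc)
                index.append(rec.case_id)
            fdf = pd.DataFrame(rows, index=index)
            fdf = fdf[[c for c in ALL_FEATURES if c in fdf.columns]]
            fpath = out_dir / "features.csv"
            fdf.to_csv(fpath, index_label="case_id")
            manifest["outputs"][str(fpath)] = _sha256(fpath)
        elif stage == "benchmark":
            ok = [r for r in records if r.descriptor is not None]
            if not ok:
                raise ConfigError("benchmark stage needs extracted features")
            fm = bm.FeatureMatrix.from_records(ok)
            cv = bm.cross_validate(
                fm, bm.named_config(config.model),
                folds=config.folds, repeats=config.repeats, seed=config.seed,
            )
            epath = out_dir / "cv_evaluations.csv"
            spath = out_dir / "cv_summary.csv"
            cv.evaluations.to_csv(epath, index=False)
            cv.summary.to_csv(spath)
            manifest["outputs"][str(epath)] = _sha256(epath)
            manifest["outputs"][str(spath)] = _sha256(spath)
        else:
            raise ConfigError(f"unknown stage {stage!r}")
        manifest["stages"][stage] = {"seconds": round(time.time() - t0, 3)}
        log.info("stage %s finished in %.1fs", stage, time.time() - t0)

    mpath = out_dir / "manifest.json"
    with open(mpath, "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)
    return manifest


def _load_cases(config: RunConfig, manifest: dict):
    """Load meshes (and optional metadata) named in the config."""
    if not config.mesh_paths:
        raise ConfigError("features stage needs mesh_paths or a cohort stage")
    meta = None
    if config.metadata_csv:
        meta = pd.read_csv(config.metadata_csv).set_index("case_id")
    records, meshes = [], {}
    for p in config.mesh_paths:
        case_id = Path(p).stem
        try:
            mesh = load_mesh(p)
        except Exception as exc:  # noqa: BLE001
            manifest["errors"].append({"case": case_id, "error": str(exc)})
            manifest["status"] = "partial"
            continue
        loc, rupt = "MCA bif", False
        if meta is not None and case_id in meta.index:
            loc = str(meta.loc[case_id, "location"])
            rupt = bool(meta.loc[case_id, "ruptured"])
        records.append(AneurysmRecord(
            case_id=case_id, dataset="input", cut_type=config.cut_type,
            location=loc, ruptured=rupt,
        ))
        meshes[case_id] = mesh
    if not records:
        raise ConfigError("no loadable meshes")
    return records, meshes
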