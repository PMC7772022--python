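"""End-to-end orchestration: cohort -> morphometry -> fall -> FE ->
attributes -> selection -> classification, with file I/O and manifests.

Every stage is driven by a single :class:`PipelineConfig`; one global
seed deterministically derives all per-stage randomness, so a fixed
config reproduces byte-identical attribute tables and reports.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import attributes as attrs
from . import classify, fall, fe, morphometry, selection
from .cohort import (CohortSpec, ScanRaster, SubjectRecord, default_spec,
                     generate_cohort)

__all__ = [
    "PipelineConfig",
    "RunManifest",
    "PipelineError",
    "compute_subject_attributes",
    "compute_attribute_table",
    "run_all",
    "save_cohort",
    "ingest_external",
]

log = logging.getLogger(__name__)

CLINICAL_COLUMNS = ("subject_id", "group", "age", "height", "weight",
                    "bmi", "bmd_total", "gender")


class PipelineError(ValueError):
    """Raised for invalid configurations or inconsistent inputs."""


@dataclass
class PipelineConfig:
    """All tunables of the pipeline in one serialisable object."""

    seed: int = 0
    n_fractured: int = 89
    n_control: int = 48
    target_elements: int = 6000
    material_law_a: float = 6850.0
    material_law_p: float = 1.49
    material_t_ref_cm: float = 1.0
    material_e_floor: float = 10.0
    yield_strain: float = 7300e-6
    neck_band_mm: float = 15.0
    pad_b_fraction: float = 0.8
    pad_t_fraction: float = 0.3837
    pad_thickness_mm: float = 6.0
    impact_stiffness: float = 71000.0
    impact_mass_fraction: float = 0.5
    impact_hip_height_fraction: float = 0.40294
    pca_components: int = 3
    pca_weight_floor: float = 0.1
    correlation_threshold: float = 0.9
    min_links: int = 4
    train_fraction: float = 0.70
    n_runs: int = 1000
    smote_target: int = 200
    smote_k: int = 5
    models: list[str] = field(default_factory=lambda: list(classify.MODEL_NAMES))
    output_dir: str = "femfall_out"

    @classmethod
    def from_dict(cls, data: dict) -> "PipelineConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise PipelineError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls.from_dict(data)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def config_hash(self) -> str:
        """Hash of the scientific parameters (the output location is not
        part of the experiment identity)."""
        payload = self.to_dict()
        payload.pop("output_dir")
        return hashlib.sha256(json.dumps(payload, sort_keys=True)
                              .encode()).hexdigest()[:16]

    def cohort_spec(self) -> CohortSpec:
        spec = default_spec(seed=self.seed)
        spec.n_fractured = self.n_fractured
        spec.n_control = self.n_control
        return spec

    def impact_params(self) -> fall.ImpactModelParams:
        return fall.ImpactModelParams(
            stiffness=self.impact_stiffness,
            mass_fraction=self.impact_mass_fraction,
            hip_height_fraction=self.impact_hip_height_fraction)


@dataclass
class RunManifest:
    config_hash: str
    version: str
    timings: dict[str, float]
    outputs: dict[str, str]
    warnings: list[str]
    failed_stage: str | None = None
    diagnostic: str | None = None

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=2, sort_keys=True)


# --------------------------------------------------------------------------
# per-subject computation
# --------------------------------------------------------------------------

def compute_subject_attributes(record: SubjectRecord, scan: ScanRaster,
                               config: PipelineConfig | None = None
                               ) -> dict[str, float]:
    """Full morphometry + fall + FE + attribute chain for one subject."""
    cfg = config if config is not None else PipelineConfig()
    scan = morphometry.standardise_pose(scan)
    lm = morphometry.analyze(scan)
    morph = lm.morph
    rois = morphometry.partition_rois(scan, morph, cfg.neck_band_mm, landmarks=lm)
    pads = morphometry.place_pads(scan, morph,
                                  pad_thickness=cfg.pad_thickness_mm,
                                  b_fraction=cfg.pad_b_fraction,
                                  t_fraction=cfg.pad_t_fraction, landmarks=lm)
    fall_attrs = fall.fall_chain(record.weight, record.height, record.bmi,
                                 pads, record.gender, cfg.impact_params())
    mesh = fe.mesh_domain(scan, pads, cfg.target_elements)
    materials = fe.assign_materials(mesh, scan, cfg.material_law_a,
                                    cfg.material_law_p, cfg.material_t_ref_cm,
                                    cfg.material_e_floor)
    bcs = fe.apply_constraints(mesh, pads)
    load = fe.apply_load(mesh, fall_attrs.hp, pads)
    solution = fe.solve(mesh, materials, bcs, load)
    tissue = attrs.tissue_attributes(materials, mesh.areas(),
                                     mesh.tags == fe.TAG_FEMUR)
    mech = attrs.mechanical_attributes(solution, materials, rois,
                                       fall_attrs.fp,
                                       attrs.YieldModel(cfg.yield_strain))
    return attrs.assemble(record, morph, fall_attrs, tissue, mech)


def compute_attribute_table(cohort: list[tuple[SubjectRecord, ScanRaster]],
                            config: PipelineConfig | None = None
                            ) -> pd.DataFrame:
    """Attribute table (subject_id, group, 39 attributes) for a cohort."""
    rows = []
    for record, scan in cohort:
        values = compute_subject_attributes(record, scan, config)
        rows.append({"subject_id": record.subject_id, "group": record.group,
                     **values})
    return pd.DataFrame(rows)


# --------------------------------------------------------------------------
# I/O
# --------------------------------------------------------------------------

def save_cohort(cohort: list[tuple[SubjectRecord, ScanRaster]],
                out_dir: str | Path) -> tuple[Path, Path]:
    """Write the clinical CSV and one NPZ raster container per subject."""
    out = Path(out_dir)
    scans_dir = out / "scans"
    scans_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    for record, scan in cohort:
        rows.append({c: getattr(record, c) for c in CLINICAL_COLUMNS})
        np.savez_compressed(scans_dir / f"{record.subject_id}.npz",
                            bmd_map=scan.bmd_map, mask=scan.mask,
                            pixel_dx=scan.pixel_dx, pixel_dy=scan.pixel_dy)
    csv_path = out / "clinical.csv"
    pd.DataFrame(rows).to_csv(csv_path, index=False)
    return csv_path, scans_dir


def ingest_external(clinical_csv: str | Path, scans_dir: str | Path
                    ) -> list[tuple[SubjectRecord, ScanRaster]]:
    """Load a cohort from a clinical CSV plus per-subject raster files."""
    table = pd.read_csv(clinical_csv)
    missing = [c for c in CLINICAL_COLUMNS if c not in table.columns]
    if missing:
        raise PipelineError(f"clinical table lacks columns: {missing}")
    extra = [c for c in table.columns if c not in CLINICAL_COLUMNS]
    if extra:
        log.warning("ignoring unknown clinical columns: %s", extra)
    cohort = []
    for _, row in table.iterrows():
        sid = str(row["subject_id"])
        path = Path(scans_dir) / f"{sid}.npz"
        if not path.exists():
            raise PipelineError(f"no scan file for subject {sid!r}")
        with np.load(path) as data:
            if data["bmd_map"].shape != data["mask"].shape:
                raise PipelineError(f"scan shape mismatch for subject {sid!r}")
            scan = ScanRaster(bmd_map=data["bmd_map"],
                              mask=data["mask"].astype(bool),
                              pixel_dx=float(data["pixel_dx"]),
                              pixel_dy=float(data["pixel_dy"]))
        record = SubjectRecord(
            subject_id=sid, group=str(row["group"]), age=float(row["age"]),
            height=float(row["height"]), weight=float(row["weight"]),
            bmi=float(row["bmi"]), bmd_total=float(row["bmd_total"]),
            gender=str(row["gender"]))
        cohort.append((record, scan))
    return cohort


# --------------------------------------------------------------------------
# full run
# --------------------------------------------------------------------------

def run_all(config: PipelineConfig,
            cohort: list[tuple[SubjectRecord, ScanRaster]] | None = None
            ) -> RunManifest:
    """Execute every stage and write all outputs under the output directory."""
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    timings: dict[str, float] = {}
    outputs: dict[str, str] = {}
    warnings: list[str] = []
    version = "0.1.0"
    log.info("run %s: calibration constants: impact k=%.0f N/m, "
             "mass fraction=%.3f, hip-height fraction=%.5f; "
             "material law a=%.0f p=%.2f t_ref=%.1f cm; "
             "yield strain=%.0f microstrain; pad t=%.4f*NW",
             config.config_hash(), config.impact_stiffness,
             config.impact_mass_fraction, config.impact_hip_height_fraction,
             config.material_law_a, config.material_law_p,
             config.material_t_ref_cm, config.yield_strain * 1e6,
             config.pad_t_fraction)
    stage = "generate"
    try:
        t0 = time.perf_counter()
        if cohort is None:
            cohort = generate_cohort(config.cohort_spec())
        csv_path, scans_dir = save_cohort(cohort, out)
        outputs["clinical_csv"] = str(csv_path)
        outputs["scans_dir"] = str(scans_dir)
        timings[stage] = time.perf_counter() - t0

        stage = "attributes"
        t0 = time.perf_counter()
        table = compute_attribute_table(cohort, config)
        attr_path = out / "attributes.csv"
        table.to_csv(attr_path, index=False)
        (out / "attributes_units.json").write_text(
            json.dumps(attrs.ATTRIBUTE_UNITS, indent=2))
        outputs["attributes_csv"] = str(attr_path)
        outputs["attributes_units_json"] = str(out / "attributes_units.json")
        timings[stage] = time.perf_counter() - t0

        stage = "select"
        t0 = time.perf_counter()
        attr_cols = list(attrs.ATTRIBUTE_NAMES)
        normed, _ = selection.normalise(table[attr_cols].astype(float))
        pca = selection.run_pca(normed)
        pd.DataFrame({"component": [f"PC{i+1}" for i in
                                    range(len(pca.explained_pct))],
                      "explained_pct": pca.explained_pct}) \
            .to_csv(out / "explained_variance.csv", index=False)
        cm = selection.correlation_mask(table[attr_cols].astype(float),
                                        config.correlation_threshold)
        cm.pearson.to_csv(out / "correlation_pearson.csv")
        cm.spearman.to_csv(out / "correlation_spearman.csv")
        cm.mask.astype(int).to_csv(out / "correlation_mask.csv")
        outputs["explained_variance_csv"] = str(out / "explained_variance.csv")
        outputs["correlation_mask_csv"] = str(out / "correlation_mask.csv")
        sel = selection.select(table, config.pca_components,
                               config.pca_weight_floor,
                               config.correlation_threshold, config.min_links)
        audit = {
            "pca_selected": selection._canonical_sorted(sel.pca_selected),
            "augmented": selection._canonical_sorted(sel.augmented),
            "removed": selection._canonical_sorted(sel.removed),
            "final": sel.final,
            "features_12": sel.features_12,
        }
        audit_path = out / "selection.json"
        audit_path.write_text(json.dumps(audit, indent=2))
        outputs["selection_json"] = str(audit_path)
        timings[stage] = time.perf_counter() - t0

        stage = "benchmark"
        t0 = time.perf_counter()
        feature_sets = {"selected": sel.final, "extended": sel.features_12}
        report = classify.benchmark(
            table, feature_sets, config.models,
            classify.SplitSpec(train_fraction=config.train_fraction,
                               n_runs=config.n_runs, base_seed=config.seed),
            classify.SmoteSpec(target_per_class=config.smote_target,
                               k_neighbours=config.smote_k))
        report_path = out / "evaluation.csv"
        report.table.to_csv(report_path, index=False)
        outputs["evaluation_csv"] = str(report_path)
        timings[stage] = time.perf_counter() - t0
    except Exception as exc:   # partial outputs retained
        manifest = RunManifest(config_hash=config.config_hash(),
                               version=version, timings=timings,
                               outputs=outputs, warnings=warnings,
                               failed_stage=stage, diagnostic=str(exc))
        (out / "manifest.json").write_text(manifest.to_json())
        raise
    manifest = RunManifest(config_hash=config.config_hash(), version=version,
                           timings=timings, outputs=outputs, warnings=warnings)
    (out / "manifest.json").write_text(manifest.to_json())
    return manifest
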