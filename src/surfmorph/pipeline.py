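"""Configuration-driven end-to-end pipeline.

A single YAML config names a cohort (a synthetic spec or files on disk),
the detection parameters, and an optional threshold/smoothing sweep. All
randomness funnels through one seed, and a run writes a manifest recording
every parameter, so identical config + seed gives identical outputs.
"""
from __future__ import annotations

import json
import logging
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from . import __version__, surface_io
from .detection import (DEFAULT_MIN_AREA, extract_clusters, fit_normative,
                        loo_zscores, zscore_subject)
from .errors import ConfigError
from .evaluation import (DetectionOutcome, categorical_detection,
                         extra_lesional_area, lesion_coverage_metrics,
                         parameter_sweep, sens_spec, union_detection)
from .mesh import LesionLabel, TriangleMesh, VertexOverlay
from .smoothing import smooth_overlay
from .synthetic import (CohortConfig, LesionSpec, MeasureSpec,
                        SyntheticCohort, simulate_cohort)

log = logging.getLogger("surfmorph")

__all__ = ["run_pipeline", "load_config", "parse_thresholds",
           "load_cohort_from_files", "load_cohort_from_manifest"]


def load_config(path) -> dict:
    path = Path(path)
    if not path.exists():
        raise ConfigError(f"config file not found: {path}")
    with open(path) as f:
        cfg = yaml.safe_load(f)
    if not isinstance(cfg, dict):
        raise ConfigError(f"config {path} is not a mapping")
    return cfg


def parse_thresholds(spec) -> list[float]:
    """Accept a list of z values or a 'start:stop:step' string (inclusive)."""
    if isinstance(spec, str):
        try:
            start, stop, step = (float(t) for t in spec.split(":"))
        except ValueError:
            raise ConfigError(f"bad threshold spec {spec!r}; use start:stop:step")
        n = int(round((stop - start) / step)) + 1
        return [start + i * step for i in range(n)]
    return [float(t) for t in spec]


def _build_synthetic(spec: dict, seed: int) -> SyntheticCohort:
    measures = {
        name: MeasureSpec(**vals)
        for name, vals in spec.get(
            "measures", {"thickness": {}}
        ).items()
    }
    lesion = LesionSpec(**spec.get("lesion", {}))
    config = CohortConfig(
        subdivisions=spec.get("subdivisions", 4),
        radius=spec.get("radius", 50.0),
        n_controls=spec.get("n_controls", 41),
        n_patients=spec.get("n_patients", 1),
        measures=measures,
        lesion=lesion,
        seed=seed,
    )
    return simulate_cohort(config)


def _require(path: Path) -> Path:
    if not path.exists():
        raise ConfigError(f"input file not found: {path}")
    return path


def load_cohort_from_files(spec: dict, base: Path) -> tuple[
        TriangleMesh, dict, dict, list[LesionLabel]]:
    """Load a cohort laid out as explicit file paths (relative to ``base``)."""
    mesh = surface_io.read_surface(_require(base / spec["surface"]))
    n = mesh.n_vertices

    def read_group(group: dict) -> dict:
        out = {}
        for measure, paths in group.items():
            out[measure] = [
                surface_io.read_overlay(_require(base / p), n, measure)
                for p in paths
            ]
        return out

    controls = read_group(spec.get("controls", {}))
    patients = read_group(spec.get("patients", {}))
    labels = [surface_io.read_label(_require(base / p), n)
              for p in spec.get("labels", [])]
    return mesh, controls, patients, labels


def load_cohort_from_manifest(manifest_path) -> tuple[
        TriangleMesh, dict, dict, list[LesionLabel]]:
    manifest_path = Path(manifest_path)
    with open(_require(manifest_path)) as f:
        manifest = json.load(f)
    return load_cohort_from_files(manifest["inventory"], manifest_path.parent)


def run_pipeline(config_path, output_dir=None) -> dict:
    """Run the full study a config describes; returns a summary report."""
    cfg = load_config(config_path)
    seed = int(cfg.get("seed", 0))
    outdir = Path(output_dir or cfg.get("output_dir", "surfmorph_out"))
    outdir.mkdir(parents=True, exist_ok=True)

    cohort_spec = cfg.get("cohort")
    if not cohort_spec:
        raise ConfigError("config key 'cohort' is required")
    if "synthetic" in cohort_spec:
        cohort = _build_synthetic(cohort_spec["synthetic"], seed)
        mesh, controls, patients, labels = (cohort.mesh, cohort.controls,
                                            cohort.patients, cohort.labels)
    elif "files" in cohort_spec:
        base = Path(config_path).parent
        mesh, controls, patients, labels = load_cohort_from_files(
            cohort_spec["files"], base)
    else:
        raise ConfigError("cohort must contain a 'synthetic' or 'files' key")

    det = cfg.get("detection", {})
    fwhm = float(det.get("fwhm", 5.0))
    threshold = float(det.get("threshold", 4.0))
    tail = det.get("tail", "two_sided")
    min_area = float(det.get("min_area", DEFAULT_MIN_AREA))
    union_of = list(cfg.get("union", ["thickness", "gwc"]))
    log.info("detection: fwhm=%s threshold=%s tail=%s min_area=%s measures=%s",
             fwhm, threshold, tail, min_area, sorted(patients))

    measures = sorted(patients.keys())
    if not measures:
        raise ConfigError("cohort has no patient overlays")

    zmap_dir = outdir / "zmaps"
    zmap_dir.mkdir(exist_ok=True)
    cluster_report: dict = {}
    table_rows = []
    per_measure_outcomes: dict = {m: [] for m in measures}
    control_flags: dict = {}
    for m in measures:
        sm_controls = [smooth_overlay(mesh, o, fwhm) for o in controls[m]]
        model = fit_normative(sm_controls, fwhm)
        loo = loo_zscores(sm_controls, fwhm)
        control_flags[m] = [
            len(extract_clusters(mesh, zm, threshold, tail, min_area)) > 0
            for zm in loo
        ]
        for i, raw in enumerate(patients[m]):
            sid = f"patient_{i:03d}"
            zm = zscore_subject(model, smooth_overlay(mesh, raw, fwhm), sid)
            surface_io.write_overlay(
                zmap_dir / f"{sid}.{m}.z.curv",
                VertexOverlay(m, np.nan_to_num(zm.values), "z"))
            cs = extract_clusters(mesh, zm, threshold, tail, min_area)
            cluster_report.setdefault(sid, {})[m] = cs.to_records()
            lesion = labels[i] if i < len(labels) else None
            detected = (categorical_detection(cs, lesion)
                        if lesion is not None and len(lesion) else
                        len(cs) > 0)
            per_measure_outcomes[m].append(DetectionOutcome(
                sid, m, detected, cs.vertex_union(), cs, lesion))

    n_patients = len(next(iter(per_measure_outcomes.values())))
    union_members = [m for m in union_of if m in measures]
    for i in range(n_patients):
        row: dict = {"subject": f"patient_{i:03d}"}
        outcomes = []
        for m in measures:
            o = per_measure_outcomes[m][i]
            row[f"{m}_detected"] = o.detected
            if o.lesion is not None and len(o.lesion):
                row[f"{m}_extra_lesional_mm2"] = round(
                    extra_lesional_area(mesh, o.cluster_vertices, o.lesion), 2)
            if m in union_members:
                outcomes.append(o)
        if outcomes:
            u = union_detection(outcomes)
            row["union_detected"] = u.detected
            if u.lesion is not None and len(u.lesion):
                row["union_extra_lesional_mm2"] = round(
                    extra_lesional_area(mesh, u.cluster_vertices, u.lesion), 2)
                cov, a_sens, a_spec = lesion_coverage_metrics(
                    mesh, u.cluster_vertices, u.lesion)
                row["union_coverage_ratio"] = round(cov, 4)
        table_rows.append(row)
    detection_table = pd.DataFrame(table_rows)
    detection_table.to_csv(outdir / "detection_table.csv", index=False)
    with open(outdir / "clusters.json", "w") as f:
        json.dump(cluster_report, f, indent=2, sort_keys=True)

    summary: dict = {"seed": seed, "n_patients": n_patients,
                     "n_controls": {m: len(controls[m]) for m in measures}}
    if labels and len(labels) >= n_patients:
        for m in measures:
            flags = [o.detected for o in per_measure_outcomes[m]]
            sens, spec = sens_spec(flags, control_flags[m])
            summary[m] = {"sensitivity_pct": sens, "specificity_pct": spec}
        if union_members:
            u_flags = [any(per_measure_outcomes[m][i].detected
                           for m in union_members)
                       for i in range(n_patients)]
            cu_flags = [any(col) for col in
                        zip(*(control_flags[m] for m in union_members))]
            sens, spec = sens_spec(u_flags, cu_flags)
            summary["union"] = {"sensitivity_pct": sens,
                                "specificity_pct": spec}

    sweep_cfg = cfg.get("sweep")
    if sweep_cfg and sweep_cfg.get("enabled", True) and labels:
        thresholds = parse_thresholds(sweep_cfg.get("thresholds", "1:7:0.5"))
        fwhms = [float(f) for f in sweep_cfg.get("fwhms", [5, 9, 12])]
        grid = parameter_sweep(mesh, patients, controls, labels,
                               thresholds=thresholds, fwhms=fwhms,
                               union_of=union_of, tail=tail,
                               min_area=min_area)
        grid.table.to_csv(outdir / "sweep.csv", index=False,
                          float_format="%.6g")
        grid.auc_table().to_csv(outdir / "roc_auc.csv", index=False,
                                float_format="%.6g")
        summary["sweep_rows"] = int(len(grid.table))

    manifest = {
        "version": __version__,
        "seed": seed,
        "parameters": {"fwhm": fwhm, "threshold": threshold, "tail": tail,
                       "min_area": min_area, "union": union_members},
        "outputs": sorted(p.name for p in outdir.iterdir() if p.is_file()),
        "summary": summary,
    }
    with open(outdir / "manifest.json", "w") as f:
        json.dump(manifest, f, indent=2, sort_keys=True)
    return manifest
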