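"""Detection performance: sensitivity/specificity, ROC, sweeps, electrodes.

Categorical detection calls a patient a true positive when any
supra-threshold cluster shares at least one vertex with the traced lesion
(an optional geodesic adjacency tolerance relaxes this), and a control a
false positive when it shows any cluster at all under leave-one-out
scoring. Area-based metrics weight every vertex by its barycentric surface
area, so coverage and specificity are expressed in mm² terms rather than
vertex counts.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .detection import (DEFAULT_MIN_AREA, ClusterSet, extract_clusters,
                        fit_normative, loo_zscores, zscore_subject)
from .errors import ConsistencyError, LocalizationError
from .mesh import LesionLabel, TriangleMesh, VertexOverlay, geodesic_distance
from .smoothing import smooth_overlay

__all__ = [
    "DetectionOutcome",
    "RocCurve",
    "SweepGrid",
    "Electrode",
    "categorical_detection",
    "union_detection",
    "sensitivity",
    "specificity",
    "sens_spec",
    "roc_auc",
    "lesion_coverage_metrics",
    "extra_lesional_area",
    "parameter_sweep",
    "classify_electrode",
]

SWEEP_THRESHOLDS = tuple(np.arange(1.0, 7.0 + 0.25, 0.5))  # 13 values, z = 1..7
SWEEP_FWHMS = (5.0, 9.0, 12.0)


def _round1(x: float) -> float:
    """Round to one decimal, halves away from zero."""
    return float(np.floor(abs(x) * 10 + 0.5) / 10 * np.sign(x))


@dataclass
class DetectionOutcome:
    subject_id: str
    measure_name: str
    detected: bool
    cluster_vertices: np.ndarray
    clusters: ClusterSet | None = None
    lesion: LesionLabel | None = None


@dataclass
class RocCurve:
    points: np.ndarray            # (k, 2) of (1 - specificity, sensitivity)
    thresholds: list
    auc: float


@dataclass
class SweepGrid:
    table: pd.DataFrame           # columns: measure, fwhm, threshold, sens, spec

    def auc_table(self) -> pd.DataFrame:
        rows = []
        for (measure, fwhm), grp in self.table.groupby(["measure", "fwhm"]):
            pts = list(zip(grp["sensitivity"] / 100.0,
                           grp["specificity"] / 100.0,
                           grp["threshold"]))
            rows.append({"measure": measure, "fwhm": fwhm,
                         "auc": roc_auc(pts).auc})
        return pd.DataFrame(rows)


@dataclass
class Electrode:
    name: str
    position: np.ndarray          # (3,) mm, surface space
    diameter: float = 4.0

    def __post_init__(self):
        self.position = np.asarray(self.position, float).reshape(3)
        if not self.diameter > 0:
            raise ValueError("electrode diameter must be positive")


def categorical_detection(clusters: ClusterSet, lesion: LesionLabel,
                          mesh: TriangleMesh | None = None,
                          adjacency_mm: float = 0.0) -> bool:
    """True iff any cluster touches the lesion label.

    With ``adjacency_mm > 0`` a cluster within that geodesic distance of
    the label also counts (requires ``mesh``).
    """
    if len(lesion) == 0:
        raise ValueError("a patient's lesion label may not be empty")
    hits = np.intersect1d(clusters.vertex_union(), lesion.vertex_indices)
    if hits.size > 0:
        return True
    if adjacency_mm > 0:
        if mesh is None:
            raise ValueError("adjacency tolerance requires the mesh")
        cl = clusters.vertex_union()
        if cl.size == 0:
            return False
        d = geodesic_distance(mesh, set(lesion.vertex_indices.tolist()))
        return bool(np.nanmin(d.values[cl]) <= adjacency_mm)
    return False


def union_detection(outcomes: Sequence[DetectionOutcome]) -> DetectionOutcome:
    """Logical-OR combination of per-measure outcomes for one subject."""
    outcomes = list(outcomes)
    if not outcomes:
        raise ValueError("need at least one outcome")
    subjects = {o.subject_id for o in outcomes}
    if len(subjects) > 1:
        raise ConsistencyError(f"mixed subjects in union: {sorted(subjects)}")
    verts = [o.cluster_vertices for o in outcomes if o.cluster_vertices.size]
    union = (np.unique(np.concatenate(verts)) if verts
             else np.empty(0, dtype=np.int64))
    return DetectionOutcome(
        subject_id=outcomes[0].subject_id,
        measure_name="union",
        detected=any(o.detected for o in outcomes),
        cluster_vertices=union,
        lesion=outcomes[0].lesion,
    )


def sensitivity(patient_flags: Sequence[bool]) -> float:
    """TP / (TP + FN) as a percentage, one decimal."""
    flags = list(patient_flags)
    if not flags:
        raise ValueError("patient flags must be nonempty")
    return _round1(100.0 * sum(bool(f) for f in flags) / len(flags))


def specificity(control_flags: Sequence[bool]) -> float:
    """TN / (TN + FP) as a percentage, one decimal."""
    flags = list(control_flags)
    if not flags:
        raise ValueError("control flags must be nonempty")
    return _round1(100.0 * sum(not bool(f) for f in flags) / len(flags))


def sens_spec(patient_flags: Sequence[bool],
              control_flags: Sequence[bool]) -> tuple[float, float]:
    return sensitivity(patient_flags), specificity(control_flags)


def roc_auc(points: Sequence) -> RocCurve:
    """ROC curve and trapezoidal AUC from (sensitivity, specificity[, thr]).

    Sensitivity and specificity are fractions in [0, 1]. The anchors (0,0)
    and (1,1) are added; ties in false-positive rate keep the best
    sensitivity.
    """
    pts = []
    thresholds: list = []
    for p in points:
        sens, spec = float(p[0]), float(p[1])
        if not (0 <= sens <= 1 and 0 <= spec <= 1):
            raise ValueError("sensitivity/specificity must lie in [0, 1]")
        pts.append((1.0 - spec, sens))
        thresholds.append(p[2] if len(p) > 2 else None)
    if not pts:
        raise ValueError("need at least one ROC point")
    pts.extend([(0.0, 0.0), (1.0, 1.0)])
    pts.sort()
    # collapse ties in x to the max y
    xs, ys = [], []
    for x, y in pts:
        if xs and x == xs[-1]:
            ys[-1] = max(ys[-1], y)
        else:
            xs.append(x)
            ys.append(y)
    auc = float(np.trapezoid(ys, xs))
    return RocCurve(np.column_stack([xs, ys]), thresholds, auc)


def _cluster_areas(mesh: TriangleMesh, cluster_vertices: np.ndarray,
                   lesion: LesionLabel) -> tuple[float, float, float, float]:
    areas = mesh.vertex_areas
    lmask = lesion.mask(mesh.n_vertices)
    cmask = np.zeros(mesh.n_vertices, dtype=bool)
    cmask[np.asarray(cluster_vertices, dtype=np.int64)] = True
    tp = float(areas[cmask & lmask].sum())
    fp = float(areas[cmask & ~lmask].sum())
    fn = float(areas[~cmask & lmask].sum())
    tn = float(areas[~cmask & ~lmask].sum())
    return tp, fp, fn, tn


def lesion_coverage_metrics(mesh: TriangleMesh, clusters,
                            lesion: LesionLabel) -> tuple[float, float, float]:
    """(coverage ratio, area sensitivity %, area specificity %).

    Coverage ratio is the supra-threshold area inside the lesion over the
    total lesion area; all quantities use vertex areas, not counts.
    """
    if len(lesion) == 0:
        raise ValueError("lesion label may not be empty")
    verts = (clusters.vertex_union() if isinstance(clusters, ClusterSet)
             else np.asarray(clusters, dtype=np.int64))
    tp, fp, fn, tn = _cluster_areas(mesh, verts, lesion)
    coverage = tp / (tp + fn)
    area_sens = _round1(100.0 * coverage)
    area_spec = _round1(100.0 * tn / (tn + fp)) if (tn + fp) > 0 else 100.0
    return coverage, area_sens, area_spec


def extra_lesional_area(mesh: TriangleMesh, clusters,
                        lesion: LesionLabel) -> float:
    """Summed area (mm²) of cluster vertices outside the lesion label."""
    verts = (clusters.vertex_union() if isinstance(clusters, ClusterSet)
             else np.asarray(clusters, dtype=np.int64))
    if verts.size == 0:
        return 0.0
    outside = np.setdiff1d(verts, lesion.vertex_indices)
    return float(mesh.vertex_areas[outside].sum())


def parameter_sweep(mesh: TriangleMesh,
                    patients: Mapping[str, Sequence[VertexOverlay]],
                    controls: Mapping[str, Sequence[VertexOverlay]],
                    lesions: Sequence[LesionLabel],
                    thresholds: Sequence[float] = SWEEP_THRESHOLDS,
                    fwhms: Sequence[float] = SWEEP_FWHMS,
                    union_of: Sequence[str] = ("thickness", "gwc"),
                    tail: str = "two_sided",
                    min_area: float = DEFAULT_MIN_AREA) -> SweepGrid:
    """Sensitivity/specificity over the full threshold × smoothing grid.

    ``patients`` and ``controls`` map measure name to per-subject raw
    (unsmoothed) overlays; smoothing at each grid FWHM happens here.
    Control flags come from leave-one-out z-maps. A ``union`` row combines
    the measures in ``union_of`` (those present) by logical OR.
    """
    measures = sorted(patients.keys())
    if not measures or not lesions:
        raise ValueError("patients, controls and lesions must be nonempty")
    for m in measures:
        if m not in controls:
            raise ConsistencyError(f"no control overlays for measure {m!r}")
        if len(patients[m]) != len(lesions):
            raise ConsistencyError("one lesion label per patient is required")
    rows = []
    union_members = [m for m in union_of if m in measures]
    for fwhm in fwhms:
        # flags[measure][threshold] -> (patient_flags, control_flags)
        flags: dict = {}
        for m in measures:
            sm_controls = [smooth_overlay(mesh, o, fwhm) for o in controls[m]]
            sm_patients = [smooth_overlay(mesh, o, fwhm) for o in patients[m]]
            model = fit_normative(sm_controls, fwhm)
            loo = loo_zscores(sm_controls, fwhm)
            pat_z = [zscore_subject(model, o, f"patient_{i:03d}")
                     for i, o in enumerate(sm_patients)]
            flags[m] = {}
            for thr in thresholds:
                p_flags = []
                for zm, lesion in zip(pat_z, lesions):
                    cs = extract_clusters(mesh, zm, thr, tail, min_area)
                    p_flags.append(categorical_detection(cs, lesion))
                c_flags = [
                    len(extract_clusters(mesh, zm, thr, tail, min_area)) > 0
                    for zm in loo
                ]
                flags[m][thr] = (p_flags, c_flags)
                sens, spec = sens_spec(p_flags, c_flags)
                rows.append({"measure": m, "fwhm": fwhm, "threshold": thr,
                             "sensitivity": sens, "specificity": spec})
        if union_members:
            for thr in thresholds:
                p_sets = [flags[m][thr][0] for m in union_members]
                c_sets = [flags[m][thr][1] for m in union_members]
                p_union = [any(col) for col in zip(*p_sets)]
                c_union = [any(col) for col in zip(*c_sets)]
                sens, spec = sens_spec(p_union, c_union)
                rows.append({"measure": "union", "fwhm": fwhm,
                             "threshold": thr, "sensitivity": sens,
                             "specificity": spec})
    return SweepGrid(pd.DataFrame(rows))


def classify_electrode(mesh: TriangleMesh, lesion: LesionLabel,
                       electrode: Electrode,
                       max_snap_mm: float = 10.0) -> str:
    """Classify an electrode as ``in_on``, ``adjacent`` or ``outside``.

    The electrode snaps to its nearest surface vertex; its footprint is
    every vertex within diameter/2 geodesic mm. ``in_on`` when at least
    half the footprint area lies inside the lesion; otherwise ``adjacent``
    when the geodesic distance to the lesion is at most 10 mm; otherwise
    ``outside``.
    """
    if len(lesion) == 0:
        raise ValueError("lesion label may not be empty")
    d_euclid = np.linalg.norm(mesh.vertices - electrode.position, axis=1)
    snap = int(np.argmin(d_euclid))
    if d_euclid[snap] > max_snap_mm:
        raise LocalizationError(
            f"electrode {electrode.name!r} is {d_euclid[snap]:.1f} mm from "
            f"the surface (snap limit {max_snap_mm} mm)"
        )
    d = geodesic_distance(mesh, {snap}).values
    footprint = np.flatnonzero(d <= electrode.diameter / 2.0)
    areas = mesh.vertex_areas
    foot_area = areas[footprint].sum()
    inside = np.intersect1d(footprint, lesion.vertex_indices)
    if foot_area > 0 and areas[inside].sum() / foot_area >= 0.5:
        return "in_on"
    d_lesion = geodesic_distance(mesh, set(lesion.vertex_indices.tolist()))
    if d_lesion.values[snap] <= 10.0:
        return "adjacent"
    return "outside"
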