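"""Single-subject normative z-maps and cluster extraction.

A normative model stores the per-vertex mean and unbiased SD of one
measure across a healthy control cohort; a subject's z-map is
``(subject - mean) / SD`` vertex by vertex. Control specificity uses a
leave-one-out scheme: each control is z-scored against the remaining
controls. Supra-threshold vertices are grouped into edge-connected
clusters, and clusters smaller than a minimum surface area are discarded
to control false positives (cluster-extent correction).
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.sparse.csgraph import connected_components

from .errors import ConsistencyError
from .mesh import TriangleMesh, VertexOverlay
from .smoothing import smooth_overlay, smoothing_operator

__all__ = [
    "NormativeModel",
    "ZMap",
    "Cluster",
    "ClusterSet",
    "fit_normative",
    "zscore_subject",
    "loo_zscores",
    "extract_clusters",
    "false_positive_counts",
    "cluster_extent_null",
]

DEFAULT_MIN_AREA = 30.0  # mm^2


@dataclass
class NormativeModel:
    measure_name: str
    mean: np.ndarray
    sd: np.ndarray
    n_subjects: int
    fwhm_used: float
    sd_floor: float

    def __post_init__(self):
        if self.n_subjects < 2:
            raise ValueError("a normative model needs at least 2 subjects")
        if not (self.sd_floor > 0):
            raise ValueError("sd_floor must be positive")


@dataclass
class ZMap:
    values: np.ndarray
    measure_name: str
    subject_id: str = ""

    @property
    def missing(self) -> np.ndarray:
        return ~np.isfinite(self.values)


@dataclass
class Cluster:
    vertices: np.ndarray          # sorted vertex indices
    peak_z: float                 # signed z at the peak (max |z|)
    peak_vertex: int
    area_mm2: float
    sign: int                     # +1 or -1

    def __len__(self) -> int:
        return len(self.vertices)


@dataclass
class ClusterSet:
    clusters: list[Cluster] = field(default_factory=list)
    threshold: float = 0.0
    tail: str = "two_sided"
    min_area: float = 0.0
    measure_name: str = ""

    def __len__(self) -> int:
        return len(self.clusters)

    def __iter__(self):
        return iter(self.clusters)

    def vertex_union(self) -> np.ndarray:
        if not self.clusters:
            return np.empty(0, dtype=np.int64)
        return np.unique(np.concatenate([c.vertices for c in self.clusters]))

    def total_area(self) -> float:
        return float(sum(c.area_mm2 for c in self.clusters))

    def to_records(self) -> list[dict]:
        return [
            {
                "cluster_id": i + 1,
                "peak_z": c.peak_z,
                "peak_vertex": int(c.peak_vertex),
                "area_mm2": c.area_mm2,
                "sign": c.sign,
                "n_vertices": len(c),
            }
            for i, c in enumerate(self.clusters)
        ]

    def to_overlay(self, n_vertices: int) -> VertexOverlay:
        """Per-vertex cluster ids (1-based; 0 = background)."""
        vals = np.zeros(n_vertices)
        for i, c in enumerate(self.clusters):
            vals[c.vertices] = i + 1
        return VertexOverlay("cluster_id", vals, units="")


def _check_cohort(cohort: Sequence[VertexOverlay]) -> None:
    names = {o.measure_name for o in cohort}
    if len(names) > 1:
        raise ConsistencyError(f"mixed measures in cohort: {sorted(names)}")
    lengths = {o.n_vertices for o in cohort}
    if len(lengths) > 1:
        raise ConsistencyError("cohort overlays differ in vertex count")


def fit_normative(cohort: Sequence[VertexOverlay], fwhm: float,
                  sd_floor: float | None = None) -> NormativeModel:
    """Per-vertex sample mean and unbiased (n-1) SD of a control cohort.

    ``sd_floor`` defaults to 1e-6 times the cohort-wide median SD, so
    degenerate (zero-variance) vertices cannot produce infinite z.
    Overlays are expected already smoothed at ``fwhm``.
    """
    cohort = list(cohort)
    if len(cohort) < 2:
        raise ValueError("need at least 2 control subjects")
    _check_cohort(cohort)
    data = np.stack([o.values for o in cohort])
    with np.errstate(invalid="ignore"):
        mean = np.nanmean(data, axis=0)
        counts = np.isfinite(data).sum(axis=0)
        sd = np.full(data.shape[1], np.nan)
        ok = counts >= 2
        sd[ok] = np.nanstd(data[:, ok], axis=0, ddof=1)
    if sd_floor is None:
        med = np.nanmedian(sd[np.isfinite(sd) & (sd > 0)]) if np.any(
            np.isfinite(sd) & (sd > 0)) else np.nan
        sd_floor = 1e-6 * med if np.isfinite(med) else 1e-6
        sd_floor = max(sd_floor, 1e-12)
    sd = np.where(np.isfinite(sd), np.maximum(sd, sd_floor), np.nan)
    mean[counts < 2] = np.nan
    return NormativeModel(cohort[0].measure_name, mean, sd,
                          n_subjects=len(cohort), fwhm_used=float(fwhm),
                          sd_floor=float(sd_floor))


def zscore_subject(model: NormativeModel, subject: VertexOverlay,
                   subject_id: str = "") -> ZMap:
    """Vertex-wise z-scores of one subject against the normative model."""
    if subject.measure_name != model.measure_name:
        raise ConsistencyError(
            f"measure mismatch: model is {model.measure_name!r}, subject "
            f"is {subject.measure_name!r}"
        )
    if subject.n_vertices != len(model.mean):
        raise ConsistencyError("subject overlay does not match model size")
    with np.errstate(invalid="ignore"):
        z = (subject.values - model.mean) / model.sd
    return ZMap(z, model.measure_name, subject_id)


def loo_zscores(cohort: Sequence[VertexOverlay], fwhm: float,
                sd_floor: float | None = None,
                subject_ids: Sequence[str] | None = None) -> list[ZMap]:
    """Leave-one-out z-maps: subject i against a model fit without i."""
    cohort = list(cohort)
    if len(cohort) < 3:
        raise ValueError("leave-one-out needs at least 3 subjects")
    _check_cohort(cohort)
    if subject_ids is None:
        subject_ids = [f"control_{i:03d}" for i in range(len(cohort))]
    maps = []
    for i, subject in enumerate(cohort):
        rest = cohort[:i] + cohort[i + 1:]
        model = fit_normative(rest, fwhm, sd_floor=sd_floor)
        maps.append(zscore_subject(model, subject, subject_ids[i]))
    return maps


def _components(mesh: TriangleMesh, mask: np.ndarray) -> list[np.ndarray]:
    idx = np.flatnonzero(mask)
    if idx.size == 0:
        return []
    sub = mesh.adjacency[idx][:, idx]
    n_comp, labels = connected_components(sub, directed=False)
    return [idx[labels == c] for c in range(n_comp)]


def extract_clusters(mesh: TriangleMesh, zmap: ZMap, threshold: float,
                     tail: str = "two_sided",
                     min_area: float = DEFAULT_MIN_AREA) -> ClusterSet:
    """Edge-connected supra-threshold clusters of a z-map.

    ``tail`` selects z > threshold (positive), z < -threshold (negative) or
    both tails separately (two_sided; opposite signs never share a
    cluster). Clusters below ``min_area`` mm² are discarded; the result is
    sorted by peak |z| descending, ties by lowest member vertex index.
    """
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    if min_area < 0:
        raise ValueError("min_area must be nonnegative")
    if tail not in ("positive", "negative", "two_sided"):
        raise ValueError(f"unknown tail {tail!r}")
    z = zmap.values
    areas = mesh.vertex_areas
    clusters: list[Cluster] = []
    signs = []
    if tail in ("positive", "two_sided"):
        signs.append(1)
    if tail in ("negative", "two_sided"):
        signs.append(-1)
    with np.errstate(invalid="ignore"):
        for sign in signs:
            mask = (sign * z) > threshold
            mask &= np.isfinite(z)
            for verts in _components(mesh, mask):
                area = float(areas[verts].sum())
                if area < min_area:
                    continue
                zv = z[verts]
                peak_local = np.flatnonzero(np.abs(zv) == np.abs(zv).max())
                peak_vertex = int(verts[peak_local].min())
                clusters.append(Cluster(
                    vertices=np.sort(verts),
                    peak_z=float(z[peak_vertex]),
                    peak_vertex=peak_vertex,
                    area_mm2=area,
                    sign=sign,
                ))
    clusters.sort(key=lambda c: (-abs(c.peak_z), int(c.vertices.min())))
    return ClusterSet(clusters, threshold=float(threshold), tail=tail,
                      min_area=float(min_area),
                      measure_name=zmap.measure_name)


def false_positive_counts(mesh: TriangleMesh,
                          control_cohort: Sequence[VertexOverlay],
                          thresholds: Sequence[float], fwhm: float,
                          tail: str = "two_sided",
                          min_area: float = DEFAULT_MIN_AREA) -> pd.DataFrame:
    """Leave-one-out false positives in controls per threshold.

    Returns a table with, per threshold, the number of control hemispheres
    showing at least one cluster and the total cluster count; both are
    non-increasing in threshold.
    """
    thresholds = list(thresholds)
    if not thresholds:
        raise ValueError("thresholds must be nonempty")
    zmaps = loo_zscores(control_cohort, fwhm)
    rows = []
    for thr in thresholds:
        flagged = 0
        total = 0
        for zm in zmaps:
            cs = extract_clusters(mesh, zm, thr, tail=tail, min_area=min_area)
            flagged += int(len(cs) > 0)
            total += len(cs)
        rows.append({"threshold": thr, "n_flagged_hemispheres": flagged,
                     "total_clusters": total})
    return pd.DataFrame(rows)


def cluster_extent_null(mesh: TriangleMesh, fwhm: float, threshold: float,
                        n_iterations: int = 100, seed: int = 0,
                        tail: str = "two_sided",
                        quantile: float = 0.95) -> float:
    """Monte-Carlo cluster-extent criterion (mm²).

    Smooths standardized Gaussian noise on the mesh, records the largest
    supra-threshold cluster area per iteration, and returns the requested
    quantile of that null distribution (0 when no null iteration produces a
    cluster). Offered as an alternative to the fixed minimum-area rule.
    """
    rng = np.random.default_rng(seed)
    n_iter_smooth = None
    maxima = []
    P = smoothing_operator(mesh)
    from .smoothing import calibrate_iterations

    n_iter_smooth = calibrate_iterations(mesh, fwhm) if fwhm > 0 else 0
    for _ in range(n_iterations):
        x = rng.standard_normal(mesh.n_vertices)
        for _ in range(n_iter_smooth):
            x = P @ x
        sd = x.std()
        if sd > 0:
            x = (x - x.mean()) / sd
        zm = ZMap(x, "null")
        cs = extract_clusters(mesh, zm, threshold, tail=tail, min_area=0.0)
        maxima.append(max((c.area_mm2 for c in cs), default=0.0))
    return float(np.quantile(maxima, quantile))
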