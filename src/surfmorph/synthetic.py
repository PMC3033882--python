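"""Synthetic cohorts for end-to-end testing of the detection pipeline.

The generator emulates the statistical structure the method assumes: every
subject's overlay is a per-vertex mean profile plus SD times a unit-variance
spatially correlated Gaussian field (white noise smoothed on the mesh to a
stated correlation FWHM, then re-standardized per vertex). Patients carry a
focal lesion: a geodesic disc in which the measure is shifted by a chosen
number of cohort SDs, with a cosine taper over the outer 20% of the radius
so cluster boundaries are not artificially crisp.

Defaults mirror a typical normative study: 41 controls, thickness-like
fields (mean 2.5 mm, SD 0.25 mm, correlation FWHM 15 mm) on a 50 mm
icosphere, lesions of 10 mm radius and 6 SD effect size.
"""
from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import trimesh.creation

from .detection import NormativeModel, fit_normative
from .errors import ConfigError
from .mesh import LesionLabel, TriangleMesh, VertexOverlay, geodesic_distance
from .smoothing import calibrate_iterations, smoothing_operator

__all__ = [
    "MeasureSpec",
    "LesionSpec",
    "CohortConfig",
    "SyntheticCohort",
    "make_icosphere",
    "simulate_cohort",
    "implant_lesion",
    "correlated_field",
    "write_cohort",
]

_PROBE_SEED = 2026041  # fixed: the per-vertex noise normalizer is a mesh
_N_PROBES = 256        # property, independent of the study seed


@dataclass
class MeasureSpec:
    """Statistical recipe for one measure's control distribution."""

    mean: float = 2.5
    sd: float = 0.25
    correlation_fwhm: float = 15.0
    units: str = "mm"

    def __post_init__(self):
        if self.sd <= 0 or self.correlation_fwhm < 0:
            raise ConfigError("measure SD must be > 0 and FWHM >= 0")


@dataclass
class LesionSpec:
    radius_mm: float = 10.0
    delta: float = 6.0            # effect size in cohort-SD units (signed)
    center: int | None = None     # None: seeded draw per patient

    def __post_init__(self):
        if self.radius_mm <= 0:
            raise ConfigError("lesion radius must be positive")
        if not np.isfinite(self.delta):
            raise ConfigError("lesion effect size must be finite")


@dataclass
class CohortConfig:
    subdivisions: int = 4
    radius: float = 50.0
    n_controls: int = 41
    n_patients: int = 1
    measures: Mapping[str, MeasureSpec] = field(
        default_factory=lambda: {"thickness": MeasureSpec()}
    )
    lesion: LesionSpec = field(default_factory=LesionSpec)
    seed: int = 0

    def __post_init__(self):
        if self.n_controls < 2:
            raise ConfigError("need at least 2 controls")
        if self.radius <= 0:
            raise ConfigError("mesh radius must be positive")
        if not self.measures:
            raise ConfigError("at least one measure is required")


@dataclass
class SyntheticCohort:
    mesh: TriangleMesh
    controls: dict                # measure -> list of VertexOverlay
    patients: dict                # measure -> list of VertexOverlay
    labels: list                  # one LesionLabel per patient
    config: CohortConfig


def make_icosphere(subdivisions: int, radius: float) -> TriangleMesh:
    """Closed icosphere with 10·4^s + 2 vertices."""
    if subdivisions < 0:
        raise ValueError("subdivisions must be >= 0")
    if subdivisions > 7:
        raise ValueError("subdivisions > 7 would create an enormous mesh")
    m = trimesh.creation.icosphere(subdivisions=subdivisions, radius=radius)
    return TriangleMesh(np.asarray(m.vertices), np.asarray(m.faces))


_EXACT_NORMALIZER_LIMIT = 5000


def _noise_normalizer(mesh: TriangleMesh, fwhm: float) -> np.ndarray:
    """Per-vertex output SD of the smoothing operator on white noise.

    Exact (row norms of the dense operator power) up to
    ``_EXACT_NORMALIZER_LIMIT`` vertices; Monte-Carlo with a fixed probe
    seed beyond that. Cached per (mesh, fwhm).
    """
    key = ("noise_norm", round(float(fwhm), 9))
    if key in mesh._cache:
        return mesh._cache[key]
    n_iter = calibrate_iterations(mesh, fwhm) if fwhm > 0 else 0
    if n_iter == 0:
        norm = np.ones(mesh.n_vertices)
    else:
        P = smoothing_operator(mesh)
        if mesh.n_vertices <= _EXACT_NORMALIZER_LIMIT:
            Q = np.eye(mesh.n_vertices)
            for _ in range(n_iter):
                Q = P @ Q
            norm = np.sqrt((Q * Q).sum(axis=1))
        else:
            rng = np.random.default_rng(_PROBE_SEED)
            probes = rng.standard_normal((mesh.n_vertices, _N_PROBES))
            for _ in range(n_iter):
                probes = P @ probes
            norm = probes.std(axis=1, ddof=1)
        norm = np.maximum(norm, 1e-12)
    mesh._cache[key] = norm
    return norm


def correlated_field(mesh: TriangleMesh, correlation_fwhm: float,
                     rng: np.random.Generator) -> np.ndarray:
    """Unit-variance spatially correlated Gaussian field on the mesh."""
    x = rng.standard_normal(mesh.n_vertices)
    if correlation_fwhm > 0:
        n_iter = calibrate_iterations(mesh, correlation_fwhm)
        P = smoothing_operator(mesh)
        for _ in range(n_iter):
            x = P @ x
        x = x / _noise_normalizer(mesh, correlation_fwhm)
    return x


def implant_lesion(mesh: TriangleMesh, overlay: VertexOverlay, center: int,
                   radius: float, delta: float,
                   model: NormativeModel) -> tuple[VertexOverlay, LesionLabel]:
    """Shift a geodesic disc of the overlay by ``delta`` model SDs.

    The shift is a plateau of ``delta * SD`` tapered to zero by a cosine
    ramp over the outer 20% of the radius; the returned label is the full
    disc regardless of ``delta``.
    """
    if radius <= 0:
        raise ValueError("lesion radius must be positive")
    if not (0 <= center < mesh.n_vertices):
        raise ValueError("lesion center vertex out of range")
    d = geodesic_distance(mesh, {center}).values
    inside = d <= radius
    label = LesionLabel(np.flatnonzero(inside), source="synthetic")
    taper = np.zeros(mesh.n_vertices)
    plateau_r = 0.8 * radius
    taper[d <= plateau_r] = 1.0
    rim = inside & (d > plateau_r)
    taper[rim] = 0.5 * (1.0 + np.cos(np.pi * (d[rim] - plateau_r)
                                     / (radius - plateau_r)))
    values = overlay.values + delta * model.sd * taper
    return overlay.with_values(values), label


def _draw_center(mesh: TriangleMesh, radius: float, previous: list[int],
                 rng: np.random.Generator) -> int:
    """Seeded center draw avoiding vertices within 2·radius of prior lesions."""
    allowed = np.ones(mesh.n_vertices, dtype=bool)
    if previous:
        d = geodesic_distance(mesh, set(previous)).values
        allowed &= d > 2.0 * radius
    if not allowed.any():
        allowed[:] = True
    return int(rng.choice(np.flatnonzero(allowed)))


def simulate_cohort(config: CohortConfig,
                    mesh: TriangleMesh | None = None) -> SyntheticCohort:
    """Generate a full synthetic study (deterministic given the seed).

    Passing a prebuilt ``mesh`` (matching the config geometry) lets
    replicate studies share per-mesh smoothing caches.
    """
    if mesh is None:
        mesh = make_icosphere(config.subdivisions, config.radius)
    rng = np.random.default_rng(config.seed)
    controls: dict = {m: [] for m in config.measures}
    patients: dict = {m: [] for m in config.measures}

    for name, spec in config.measures.items():
        for _ in range(config.n_controls):
            f = correlated_field(mesh, spec.correlation_fwhm, rng)
            controls[name].append(
                VertexOverlay(name, spec.mean + spec.sd * f, spec.units)
            )
        for _ in range(config.n_patients):
            f = correlated_field(mesh, spec.correlation_fwhm, rng)
            patients[name].append(
                VertexOverlay(name, spec.mean + spec.sd * f, spec.units)
            )

    labels: list[LesionLabel] = []
    centers: list[int] = []
    models = {m: fit_normative(controls[m], fwhm=0.0)
              for m in config.measures}
    for p in range(config.n_patients):
        center = (config.lesion.center if config.lesion.center is not None
                  else _draw_center(mesh, config.lesion.radius_mm, centers,
                                    rng))
        centers.append(center)
        label = None
        for name in config.measures:
            patients[name][p], label = implant_lesion(
                mesh, patients[name][p], center, config.lesion.radius_mm,
                config.lesion.delta, models[name]
            )
        labels.append(label)
    return SyntheticCohort(mesh, controls, patients, labels, config)


def write_cohort(cohort: SyntheticCohort, outdir) -> Path:
    """Write a cohort to disk (surface, overlays, labels, JSON manifest)."""
    from . import surface_io

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    surface_path = outdir / "template.surf"
    surface_io.write_surface(surface_path, cohort.mesh)
    inventory: dict = {"surface": surface_path.name, "controls": {},
                       "patients": {}, "labels": []}
    for name, overlays in cohort.controls.items():
        paths = []
        for i, o in enumerate(overlays):
            p = outdir / f"control_{i:03d}.{name}.curv"
            surface_io.write_overlay(p, o)
            paths.append(p.name)
        inventory["controls"][name] = paths
    for name, overlays in cohort.patients.items():
        paths = []
        for i, o in enumerate(overlays):
            p = outdir / f"patient_{i:03d}.{name}.curv"
            surface_io.write_overlay(p, o)
            paths.append(p.name)
        inventory["patients"][name] = paths
    for i, label in enumerate(cohort.labels):
        p = outdir / f"patient_{i:03d}.lesion.label"
        surface_io.write_label(p, label, cohort.mesh)
        inventory["labels"].append(p.name)
    cfg = cohort.config
    manifest = {
        "seed": cfg.seed,
        "config": {
            "subdivisions": cfg.subdivisions,
            "radius": cfg.radius,
            "n_controls": cfg.n_controls,
            "n_patients": cfg.n_patients,
            "measures": {
                m: {"mean": s.mean, "sd": s.sd,
                    "correlation_fwhm": s.correlation_fwhm, "units": s.units}
                for m, s in cfg.measures.items()
            },
            "lesion": {"radius_mm": cfg.lesion.radius_mm,
                       "delta": cfg.lesion.delta,
                       "center": cfg.lesion.center},
        },
        "inventory": inventory,
    }
    with open(outdir / "manifest.json", "w") as f:
        json.dump(manifest, f, indent=2, sort_keys=True)
    return outdir / "manifest.json"
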