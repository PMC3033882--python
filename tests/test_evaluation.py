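"""Sensitivity/specificity, ROC, coverage, sweep and electrode metrics."""
import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import surfmorph as sm
from surfmorph.detection import Cluster, ClusterSet, ZMap
from surfmorph.errors import ConsistencyError, LocalizationError
from surfmorph.evaluation import SWEEP_THRESHOLDS


def cluster_set(mesh, vertex_lists, measure="thickness"):
    clusters = []
    for verts in vertex_lists:
        verts = np.asarray(sorted(verts), dtype=np.int64)
        clusters.append(Cluster(verts, 5.0, int(verts[0]),
                                float(mesh.vertex_areas[verts].sum()), 1))
    return ClusterSet(clusters, threshold=4.0, measure_name=measure)


def outcome(mesh, subject, verts, lesion=None, measure="thickness"):
    verts = np.asarray(sorted(verts), dtype=np.int64)
    detected = (lesion is not None
                and bool(np.intersect1d(verts, lesion.vertex_indices).size))
    return sm.DetectionOutcome(subject, measure, detected, verts,
                               lesion=lesion)


class TestCategoricalDetection:
    def test_disjoint_false(self, ico3):
        cs = cluster_set(ico3, [[1, 2, 3]])
        assert not sm.categorical_detection(cs, sm.LesionLabel([10, 11]))

    def test_equal_true(self, ico3):
        cs = cluster_set(ico3, [[10, 11]])
        assert sm.categorical_detection(cs, sm.LesionLabel([10, 11]))

    def test_single_shared_vertex_true(self, ico3):
        cs = cluster_set(ico3, [[9, 10]])
        assert sm.categorical_detection(cs, sm.LesionLabel([10, 11]))

    def test_empty_lesion_rejected(self, ico3):
        cs = cluster_set(ico3, [[1]])
        with pytest.raises(ValueError):
            sm.categorical_detection(cs, sm.LesionLabel(np.array([], int)))

    def test_adjacency_tolerance(self, ico3):
        lesion = sm.LesionLabel([0])
        nbr = int(ico3.neighbors(0)[0])
        cs = cluster_set(ico3, [[nbr]])
        assert not sm.categorical_detection(cs, lesion)
        assert sm.categorical_detection(cs, lesion, mesh=ico3,
                                        adjacency_mm=10.0)


class TestUnionDetection:
    def test_or_semantics(self, ico3):
        lesion = sm.LesionLabel([5])
        thick = outcome(ico3, "p1", [5, 6], lesion, "thickness")
        gwc = outcome(ico3, "p1", [100], lesion, "gwc")
        u = sm.union_detection([thick, gwc])
        assert u.detected and u.measure_name == "union"
        assert set(u.cluster_vertices) == {5, 6, 100}

    def test_both_negative(self, ico3):
        lesion = sm.LesionLabel([5])
        u = sm.union_detection([outcome(ico3, "p1", [50], lesion),
                                outcome(ico3, "p1", [60], lesion, "gwc")])
        assert not u.detected

    def test_mixed_subjects_rejected(self, ico3):
        with pytest.raises(ConsistencyError):
            sm.union_detection([outcome(ico3, "p1", [1]),
                                outcome(ico3, "p2", [2])])


class TestSensSpec:
    def test_half_sensitivity_full_specificity(self):
        assert sm.sens_spec([True, True, False, False],
                            [False] * 10) == (50.0, 100.0)

    def test_all_detected_all_flagged(self):
        assert sm.sens_spec([True] * 5, [True] * 5) == (100.0, 0.0)

    def test_twelve_of_thirteen(self):
        sens, _ = sm.sens_spec([True] * 12 + [False], [False])
        assert sens == 92.3

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            sm.sensitivity([])
        with pytest.raises(ValueError):
            sm.specificity([])

    @settings(deadline=None, max_examples=30, derandomize=True)
    @given(st.lists(st.booleans(), min_size=1, max_size=30),
           st.lists(st.booleans(), min_size=1, max_size=30))
    def test_bounds(self, p, c):
        sens, spec = sm.sens_spec(p, c)
        assert 0.0 <= sens <= 100.0 and 0.0 <= spec <= 100.0


class TestRocAuc:
    def test_perfect_point(self):
        assert sm.roc_auc([(1.0, 1.0)]).auc == pytest.approx(1.0)

    def test_chance_point(self):
        assert sm.roc_auc([(0.5, 0.5)]).auc == pytest.approx(0.5)

    def test_trapezoid_single_point(self):
        # (0,0) -> (0.2, 0.8) -> (1,1): 0.5*0.2*0.8 + 0.5*0.8*(0.8+1)
        assert sm.roc_auc([(0.8, 0.8)]).auc == pytest.approx(0.80)

    def test_anchors_present(self):
        curve = sm.roc_auc([(0.7, 0.9, 4.0)])
        assert (curve.points[0] == [0.0, 0.0]).all()
        assert (curve.points[-1] == [1.0, 1.0]).all()

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            sm.roc_auc([(1.2, 0.5)])

    def test_random_detector_near_half(self):
        # flags independent of case/control status: AUC converges to 0.5
        rng = np.random.default_rng(12)
        scores_p = rng.random(200)
        scores_c = rng.random(200)
        pts = []
        for thr in np.linspace(0.05, 0.95, 19):
            sens = float(np.mean(scores_p > thr))
            spec = float(np.mean(scores_c <= thr))
            pts.append((sens, spec, thr))
        assert sm.roc_auc(pts).auc == pytest.approx(0.5, abs=0.07)

    def test_perfect_separation_gives_one(self):
        scores_p = np.array([5.0, 6.0, 7.0])
        scores_c = np.array([1.0, 2.0, 3.0])
        pts = []
        for thr in np.arange(0.0, 8.0, 0.5):
            pts.append((float(np.mean(scores_p > thr)),
                        float(np.mean(scores_c <= thr)), thr))
        assert sm.roc_auc(pts).auc == pytest.approx(1.0)


class TestAreaMetrics:
    def test_cluster_equals_lesion(self, ico3):
        lesion = sm.LesionLabel(np.arange(30))
        cs = cluster_set(ico3, [np.arange(30)])
        cov, a_sens, a_spec = sm.lesion_coverage_metrics(ico3, cs, lesion)
        assert (cov, a_sens, a_spec) == (1.0, 100.0, 100.0)

    def test_disjoint_zero_coverage(self, ico3):
        lesion = sm.LesionLabel(np.arange(30))
        cs = cluster_set(ico3, [np.arange(100, 130)])
        cov, a_sens, _ = sm.lesion_coverage_metrics(ico3, cs, lesion)
        assert cov == 0.0 and a_sens == 0.0

    def test_half_area_coverage(self, ico3):
        lesion_idx = np.arange(40)
        areas = ico3.vertex_areas[lesion_idx]
        csum = np.cumsum(areas)
        k = int(np.searchsorted(csum, csum[-1] / 2.0)) + 1
        cs = cluster_set(ico3, [lesion_idx[:k]])
        cov, _, _ = sm.lesion_coverage_metrics(
            ico3, cs, sm.LesionLabel(lesion_idx))
        assert cov == pytest.approx(0.5, abs=0.05)

    def test_extra_lesional_inside_zero(self, ico3):
        lesion = sm.LesionLabel(np.arange(30))
        cs = cluster_set(ico3, [np.arange(10)])
        assert sm.extra_lesional_area(ico3, cs, lesion) == 0.0

    def test_extra_lesional_fully_outside(self, ico3):
        lesion = sm.LesionLabel(np.arange(30))
        outside = np.arange(100, 140)
        cs = cluster_set(ico3, [outside])
        assert sm.extra_lesional_area(ico3, cs, lesion) == pytest.approx(
            ico3.vertex_areas[outside].sum())

    def test_straddling_cluster_counts_outside_part(self, ico3):
        lesion = sm.LesionLabel(np.arange(30))
        verts = np.arange(20, 50)  # 10 inside, 20 outside
        cs = cluster_set(ico3, [verts])
        expected = ico3.vertex_areas[np.arange(30, 50)].sum()
        assert sm.extra_lesional_area(ico3, cs, lesion) == pytest.approx(expected)

    @pytest.mark.parametrize("seed", range(3))
    def test_area_conservation(self, ico3, seed):
        rng = np.random.default_rng(seed)
        verts = rng.choice(ico3.n_vertices, size=80, replace=False)
        lesion = sm.LesionLabel(
            rng.choice(ico3.n_vertices, size=50, replace=False))
        cs = cluster_set(ico3, [verts])
        total = ico3.vertex_areas[verts].sum()
        outside = sm.extra_lesional_area(ico3, cs, lesion)
        inside = ico3.vertex_areas[
            np.intersect1d(verts, lesion.vertex_indices)].sum()
        assert inside + outside == pytest.approx(total, rel=1e-12)


@pytest.fixture(scope="module")
def sweep(ico3):
    cfg = sm.CohortConfig(
        subdivisions=3, radius=50.0, n_controls=8, n_patients=2,
        measures={"thickness": sm.MeasureSpec(),
                  "gwc": sm.MeasureSpec(mean=-0.2, sd=0.03, units="")},
        lesion=sm.LesionSpec(radius_mm=10.0, delta=5.0), seed=21)
    coh = sm.simulate_cohort(cfg, mesh=ico3)
    return sm.parameter_sweep(
        ico3, coh.patients, coh.controls, coh.labels,
        thresholds=[1.0, 2.0, 3.0, 4.0, 6.0], fwhms=[5.0])


class TestParameterSweep:
    def test_grid_complete(self, sweep):
        t = sweep.table
        assert set(t["measure"]) == {"thickness", "gwc", "union"}
        assert all(len(g) == 5 for _, g in t.groupby(["measure", "fwhm"]))

    def test_sensitivity_monotone_in_threshold(self, sweep):
        for _, g in sweep.table.groupby(["measure", "fwhm"]):
            s = g.sort_values("threshold")["sensitivity"].to_numpy()
            assert np.all(np.diff(s) <= 0)

    def test_union_dominates_components(self, sweep):
        t = sweep.table.set_index(["measure", "threshold"])
        for thr in [1.0, 2.0, 3.0, 4.0, 6.0]:
            u_sens = t.loc[("union", thr), "sensitivity"]
            u_spec = t.loc[("union", thr), "specificity"]
            for m in ("thickness", "gwc"):
                assert u_sens >= t.loc[(m, thr), "sensitivity"]
                assert u_spec <= t.loc[(m, thr), "specificity"]

    def test_auc_table(self, sweep):
        auc = sweep.auc_table()
        assert ((auc["auc"] >= 0) & (auc["auc"] <= 1)).all()

    def test_default_threshold_grid_has_13_values(self):
        assert len(SWEEP_THRESHOLDS) == 13
        assert SWEEP_THRESHOLDS[0] == 1.0 and SWEEP_THRESHOLDS[-1] == 7.0


@pytest.fixture(scope="module")
def lesion(ico4):
    d = sm.geodesic_distance(ico4, {0}).values
    return sm.LesionLabel(np.flatnonzero(d <= 20.0)), d


class TestElectrodes:
    def test_center_of_large_lesion_in_on(self, ico4, lesion):
        label, _ = lesion
        e = sm.Electrode("G1", ico4.vertices[0])
        assert sm.classify_electrode(ico4, label, e) == "in_on"

    def test_far_electrode_outside(self, ico4, lesion):
        label, d = lesion
        v = int(np.argmin(np.abs(d - 45.0)))  # 25 mm beyond the boundary
        e = sm.Electrode("G2", ico4.vertices[v])
        assert sm.classify_electrode(ico4, label, e) == "outside"

    def test_five_mm_outside_adjacent(self, ico4, lesion):
        label, d = lesion
        v = int(np.argmin(np.abs(d - 25.0)))  # ~5 mm beyond the boundary
        # geodesic oracle: distance from this vertex to the label
        d_to_label = sm.geodesic_distance(
            ico4, set(label.vertex_indices.tolist())).values[v]
        assert 0 < d_to_label <= 10.0
        e = sm.Electrode("G3", ico4.vertices[v])
        assert sm.classify_electrode(ico4, label, e) == "adjacent"

    def test_snap_distance_guard(self, ico4, lesion):
        label, _ = lesion
        e = sm.Electrode("Deep", [0.0, 0.0, 0.0])  # sphere center, 50 mm away
        with pytest.raises(LocalizationError):
            sm.classify_electrode(ico4, label, e)
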