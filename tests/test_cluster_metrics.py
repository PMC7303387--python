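"""Cluster extraction, ROI filtering, matching and the PDAV/DCM/DSC metrics."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import boldrepro as br
from boldrepro.cluster_metrics import RoiMask
from boldrepro.thresholding import ActivationMap


def make_act(active, tmap=None):
    active = np.asarray(active, dtype=bool)
    if tmap is None:
        tmap = active.astype(float)
    return ActivationMap(active=active, tmap=np.asarray(tmap, float),
                         method="Bon")


AFF4 = br.centered_affine((16, 16, 12), 4.0)


class TestFindClusters:
    def test_twelve_voxel_blob_retained_768ul(self):
        active = np.zeros((16, 16, 12), dtype=bool)
        active[2:5, 2:4, 2:4] = True  # 3*2*2 = 12 voxels
        clusters = br.find_clusters(make_act(active), AFF4)
        assert len(clusters) == 1
        assert clusters[0].n_voxels == 12
        assert clusters[0].volume_ul == pytest.approx(768.0)

    def test_eleven_voxel_blob_discarded(self):
        active = np.zeros((16, 16, 12), dtype=bool)
        active[2:5, 2:4, 2:4] = True
        active[2, 2, 2] = False  # 11 voxels
        assert br.find_clusters(make_act(active), AFF4) == []

    def test_corner_touch_is_two_clusters(self):
        active = np.zeros((16, 16, 12), dtype=bool)
        active[2:5, 2:4, 2:4] = True           # blob A
        active[5:8, 4:6, 4:6] = True           # blob B touches only at corner
        clusters = br.find_clusters(make_act(active), AFF4)
        assert len(clusters) == 2

    def test_face_touch_is_one_cluster(self):
        active = np.zeros((16, 16, 12), dtype=bool)
        active[2:5, 2:4, 2:4] = True
        active[5:8, 2:4, 2:4] = True           # shares faces at x=4/5
        clusters = br.find_clusters(make_act(active), AFF4)
        assert len(clusters) == 1


class TestWeightedCom:
    def test_uniform_weights_geometric_center(self):
        voxels = np.argwhere(np.ones((3, 3, 3), dtype=bool))
        aff = br.centered_affine((3, 3, 3), 4.0)
        com = br.weighted_com(voxels, np.ones(27), aff)
        assert np.allclose(com, [0.0, 0.0, 0.0])

    def test_t_weighting(self):
        # voxels at x = 0 mm and x = 4 mm, weights 1 and 3 -> x = 3 mm
        aff = np.eye(4) * 1.0
        aff[0, 0] = 4.0
        voxels = np.array([[0, 0, 0], [1, 0, 0]])
        com = br.weighted_com(voxels, np.array([1.0, 3.0]), aff)
        assert com[0] == pytest.approx(3.0)

    def test_nonpositive_weights_rejected(self):
        with pytest.raises(ValueError):
            br.weighted_com(np.array([[0, 0, 0]]), np.array([-1.0]), AFF4)


class TestRoiMask:
    def test_inclusive_ten_percent_boundary(self):
        maps = [np.zeros((4, 4, 4), dtype=bool) for _ in range(10)]
        maps[0][1, 1, 1] = True          # active in 1 of 10 = exactly 10%
        roi = br.build_roi_mask(maps, prevalence=0.10)
        assert roi.mask[1, 1, 1]
        assert roi.mask.sum() == 1       # never-active voxels excluded

    def test_always_active_included_any_prevalence(self):
        maps = [np.ones((2, 2, 2), dtype=bool) for _ in range(5)]
        assert br.build_roi_mask(maps, prevalence=1.0).mask.all()

    def test_empty_list_rejected(self):
        with pytest.raises(ValueError):
            br.build_roi_mask([])


class TestFilterByRoi:
    def _cluster_at(self, ijk, aff=AFF4):
        voxels = np.array([ijk])
        return br.Cluster(voxels=voxels, t_values=np.array([1.0]),
                          volume_ul=64.0,
                          com_mm=br.weighted_com(voxels, np.array([1.0]), aff))

    def test_com_in_roi_kept_out_dropped(self):
        roi_mask = np.zeros((16, 16, 12), dtype=bool)
        roi_mask[8, 8, 6] = True
        roi = RoiMask(mask=roi_mask, prevalence=0.1, n_maps=1)
        inside = self._cluster_at((8, 8, 6))
        outside = self._cluster_at((2, 2, 2))
        kept = br.filter_by_roi([inside, outside], roi, AFF4)
        assert kept == [inside]

    def test_overlap_without_com_in_roi_dropped(self):
        # a big cluster overlapping the ROI but centered outside is dropped
        roi_mask = np.zeros((16, 16, 12), dtype=bool)
        roi_mask[2, 2, 2] = True
        roi = RoiMask(mask=roi_mask, prevalence=0.1, n_maps=1)
        voxels = np.argwhere(np.ones((5, 5, 5), dtype=bool)) + 2
        c = br.Cluster(voxels=voxels, t_values=np.ones(125), volume_ul=8000.0,
                       com_mm=br.weighted_com(voxels, np.ones(125), AFF4))
        assert br.filter_by_roi([c], roi, AFF4) == []

    def test_empty_roi_empty_result(self):
        roi = RoiMask(mask=np.zeros((16, 16, 12), bool), prevalence=0.1,
                      n_maps=1)
        assert br.filter_by_roi([self._cluster_at((8, 8, 6))], roi, AFF4) == []


def _cluster_with_com(com_mm, volume_ul=640.0):
    return br.Cluster(voxels=np.array([[0, 0, 0]]), t_values=np.array([1.0]),
                      volume_ul=volume_ul, com_mm=np.asarray(com_mm, float))


class TestMatchClusters:
    def test_boundary_10mm_inclusive(self):
        t = [_cluster_with_com((0, 0, 0))]
        assert len(br.match_clusters(t, [_cluster_with_com((10.0, 0, 0))])) == 1
        assert len(br.match_clusters(t, [_cluster_with_com((10.1, 0, 0))])) == 0

    def test_closest_candidate_chosen(self):
        t = [_cluster_with_com((0, 0, 0))]
        near = _cluster_with_com((4.0, 0, 0))
        far = _cluster_with_com((7.0, 0, 0))
        pairs = br.match_clusters(t, [far, near])
        assert len(pairs) == 1
        assert pairs[0].retest is near
        assert pairs[0].dcm_mm == pytest.approx(4.0)

    def test_many_to_one_allowed(self):
        tests = [_cluster_with_com((0, 0, 0)), _cluster_with_com((4, 0, 0))]
        retest = [_cluster_with_com((2, 0, 0))]
        pairs = br.match_clusters(tests, retest)
        assert len(pairs) == 2
        assert pairs[0].retest is pairs[1].retest

    def test_all_pairs_within_bound(self):
        rng = np.random.default_rng(0)
        tests = [_cluster_with_com(rng.uniform(-20, 20, 3)) for _ in range(10)]
        retests = [_cluster_with_com(rng.uniform(-20, 20, 3)) for _ in range(10)]
        for p in br.match_clusters(tests, retests):
            assert p.dcm_mm <= 10.0


class TestMetrics:
    def test_ideal_values(self):
        assert br.pdav(500.0, 500.0) == 0.0
        assert br.dcm((1, 2, 3), (1, 2, 3)) == 0.0
        s = {(0, 0, 0), (1, 0, 0)}
        assert br.dsc(s, set(s)) == 1.0

    def test_pdav_examples(self):
        assert br.pdav(100.0, 50.0) == pytest.approx(200.0 / 3.0)
        assert br.pdav(100.0, 0.0) == pytest.approx(200.0)
        with pytest.raises(ValueError):
            br.pdav(0.0, 0.0)

    def test_dcm_345(self):
        assert br.dcm((0, 0, 0), (3, 4, 0)) == pytest.approx(5.0)

    def test_dsc_examples(self):
        assert br.dsc({(0, 0, 0)}, {(1, 1, 1)}) == 0.0
        assert br.dsc({(0, 0, 0), (1, 0, 0)}, {(1, 0, 0), (2, 0, 0)}) == 0.5
        with pytest.raises(ValueError):
            br.dsc(set(), set())

    @given(v1=st.floats(0.1, 1e5), v2=st.floats(0.1, 1e5))
    @settings(deadline=None, max_examples=50)
    def test_pdav_symmetric_and_bounded(self, v1, v2):
        a, b = br.pdav(v1, v2), br.pdav(v2, v1)
        assert a == pytest.approx(b)
        assert 0.0 <= a <= 200.0

    @given(st.lists(st.tuples(st.floats(-50, 50), st.floats(-50, 50),
                              st.floats(-50, 50)), min_size=3, max_size=3))
    @settings(deadline=None, max_examples=50)
    def test_dcm_triangle_inequality(self, pts):
        a, b, c = pts
        assert br.dcm(a, c) <= br.dcm(a, b) + br.dcm(b, c) + 1e-9

    def test_dsc_symmetric(self):
        s1 = {(0, 0, 0), (1, 0, 0), (2, 0, 0)}
        s2 = {(1, 0, 0), (5, 5, 5)}
        assert br.dsc(s1, s2) == br.dsc(s2, s1)

    def test_metric_record_identical_pair_is_ideal(self):
        vox = np.argwhere(np.ones((3, 2, 2), dtype=bool))
        c = br.Cluster(voxels=vox, t_values=np.ones(12), volume_ul=768.0,
                       com_mm=br.weighted_com(vox, np.ones(12), AFF4))
        pair = br.ClusterPair(test=c, retest=c, dcm_mm=0.0)
        rec = br.metric_record(pair)
        assert rec["pdav_percent"] == 0.0
        assert rec["dcm_mm"] == 0.0
        assert rec["dsc"] == 1.0
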