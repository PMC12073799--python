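"""Connectome construction: retention, FA weighting, consensus."""

import numpy as np
import pytest

from ccdnet import (
    Cohort,
    CohortConfig,
    Connectome,
    SeedConnectivityMap,
    build_connectome,
    build_consensus,
    classify_edge,
    generate_cohort,
    virtual_callosotomy,
)
from ccdnet.build import cortical_homotopic_edges, edge_weight_fa, retain_connection
from ccdnet.synthetic import _cc_edges, build_parcellation


def _map(values, labels, seed=0, fa=None):
    return SeedConnectivityMap(seed, np.asarray(values, float), np.asarray(labels), fa)


class TestRetention:
    # label volumes: region k occupies voxels labeled k + 1
    def test_single_voxel_overlap_retained(self):
        m = _map([[0.2, 0.0]], [[2, 1]])
        assert retain_connection(m, 1) is True

    def test_zero_overlap_dropped(self):
        m = _map([[0.0, 0.5]], [[2, 1]])
        assert retain_connection(m, 1) is False

    def test_small_ratio_still_retained(self):
        # 4-voxel region with values (0, 0, 0.1, 0): ratio 0.025 > 0
        m = _map([[0, 0, 0.1, 0]], [[2, 2, 2, 2]])
        assert retain_connection(m, 1) is True

    def test_zero_volume_region_errors(self):
        m = _map([[0.2]], [[1]])
        with pytest.raises(ValueError):
            retain_connection(m, 5)


class TestFAWeight:
    def test_subthreshold_voxels_excluded(self):
        m = _map([[0.002, 0.0005]], [[1, 1]])
        fa = np.array([[0.5, 0.7]])
        assert edge_weight_fa(m, fa) == pytest.approx(0.5)

    def test_all_subthreshold_is_absent(self):
        m = _map([[0.001, 0.0002]], [[1, 1]])
        fa = np.array([[0.5, 0.7]])
        assert edge_weight_fa(m, fa) == 0.0

    def test_uniform_fa(self):
        m = _map([[0.9, 0.2, 0.0]], [[1, 1, 1]])
        fa = np.full((1, 3), 0.4)
        assert edge_weight_fa(m, fa) == pytest.approx(0.4)

    def test_shape_mismatch(self):
        m = _map([[0.9]], [[1]])
        with pytest.raises(ValueError):
            edge_weight_fa(m, np.zeros((2, 2)))


class TestBuildConnectome:
    @pytest.fixture()
    def tiny_parcellation(self):
        # 4-node toy parcellation (2 per hemisphere)
        from ccdnet.synthetic import Node, Parcellation

        return Parcellation(
            nodes=(
                Node(0, "alpha", "Al", "L", "frontal", True),
                Node(1, "beta", "Be", "L", "occipital", True),
                Node(2, "alpha", "Al", "R", "frontal", True),
                Node(3, "beta", "Be", "R", "occipital", True),
            )
        )

    def _toy_maps(self, connect=True):
        # 1x4 volume: regions 0..3 occupy one voxel each (labels 1..4)
        labels = np.array([[1, 2, 3, 4]])
        fa = np.array([[0.4, 0.5, 0.6, 0.7]])
        maps = {}
        for r in range(4):
            values = np.zeros((1, 4))
            values[0, r] = 1.0
            if connect and r in (0, 1):
                other = 1 - r
                values[0, other] = 0.3  # regions 0 and 1 mutually connected
            maps[r] = SeedConnectivityMap(r, values, labels, fa)
        return maps

    def test_single_connected_pair(self, tiny_parcellation):
        c = build_connectome(self._toy_maps(), tiny_parcellation)
        expected_weight = np.mean([0.4, 0.5])  # FA of the two pair voxels
        assert c.weights[0, 1] == pytest.approx(expected_weight)
        assert c.weights[1, 0] == pytest.approx(expected_weight)
        off = c.weights.copy()
        off[0, 1] = off[1, 0] = 0
        assert not off.any()

    def test_no_overlap_gives_zero_matrix(self, tiny_parcellation):
        c = build_connectome(self._toy_maps(connect=False), tiny_parcellation)
        assert not c.weights.any()

    def test_step2_rejection_removes_edge(self, tiny_parcellation):
        # region 0's map touches region 1, but seeding from 1 never reaches
        # 0 within the pair mask -> conjunction fails
        maps = self._toy_maps(connect=False)
        v = maps[0].values.copy()
        v[0, 1] = 0.3
        maps[0] = SeedConnectivityMap(0, v, maps[0].labels, maps[0].fa)
        c = build_connectome(maps, tiny_parcellation)
        assert c.weights[0, 1] == 0.0

    def test_missing_map_errors(self, tiny_parcellation):
        maps = self._toy_maps()
        del maps[2]
        with pytest.raises(ValueError):
            build_connectome(maps, tiny_parcellation)


class TestVirtualCallosotomy:
    def test_empty_list_is_identity(self, cohorts):
        c = cohorts["normal_cc"].connectomes[0]
        np.testing.assert_array_equal(virtual_callosotomy(c, []).weights, c.weights)

    def test_listed_edges_zeroed_others_untouched(self, cohorts, parcellation):
        c = cohorts["normal_cc"].connectomes[0]
        edges = cortical_homotopic_edges(parcellation)
        cut = virtual_callosotomy(c, edges)
        for i, j in edges:
            assert cut.weights[i, j] == 0
        mask = np.ones_like(c.weights, dtype=bool)
        for i, j in edges:
            mask[i, j] = mask[j, i] = False
        np.testing.assert_array_equal(cut.weights[mask], c.weights[mask])

    def test_matches_generator_paired_cohort(self, cohorts, parcellation):
        # cross-module consistency: manual callosotomy of each normal subject
        # reproduces the generator's paired virtual-callosotomy subject
        cc = [(e.i, e.j) for e in _cc_edges(parcellation)]
        for cn, cv in zip(
            cohorts["normal_cc"].connectomes,
            cohorts["virtual_callosotomy"].connectomes,
        ):
            np.testing.assert_array_equal(
                virtual_callosotomy(cn, cc).weights, cv.weights
            )


class TestConsensus:
    def _cohort_with_support(self, count, n=10, weight=0.5):
        parc = build_parcellation()
        mats = []
        for k in range(n):
            W = np.zeros((76, 76))
            if k < count:
                W[0, 1] = W[1, 0] = weight
            mats.append(Connectome(parc, W, f"s{k}"))
        return Cohort("normal_cc", parc, mats)

    def test_half_presence_kept(self):
        cons = build_consensus(self._cohort_with_support(5))
        assert cons.weights[0, 1] > 0
        assert cons.support[0, 1] == 5

    def test_below_half_dropped(self):
        cons = build_consensus(self._cohort_with_support(4))
        assert cons.weights[0, 1] == 0

    def test_weight_is_carrier_mean(self):
        parc = build_parcellation()
        mats = []
        for k in range(10):
            W = np.zeros((76, 76))
            if k < 8:
                w = 0.4 if k % 2 == 0 else 0.6
                W[0, 1] = W[1, 0] = w
            mats.append(Connectome(parc, W, f"s{k}"))
        cons = build_consensus(Cohort("normal_cc", parc, mats))
        assert cons.weights[0, 1] == pytest.approx(0.5)

    def test_support_invariant(self, cohorts):
        cons = build_consensus(cohorts["normal_cc"])
        present = cons.weights > 0
        assert np.all(cons.support[present] >= 5)

    def test_monotone_in_min_fraction(self, cohorts):
        cohort = cohorts["partial_ccd"]
        previous = None
        for frac in (0.3, 0.5, 0.7, 0.9):
            edges = set(zip(*np.nonzero(build_consensus(cohort, frac).weights)))
            if previous is not None:
                assert edges <= previous
            previous = edges


class TestClassifyEdge:
    def test_examples(self, parcellation):
        fra_l = parcellation.index("Fra,L")
        hp_r = parcellation.index("Hp,R")
        v1_l = parcellation.index("V1,L")
        assert classify_edge(parcellation, fra_l, hp_r) == "interhemispheric"
        assert classify_edge(parcellation, fra_l, v1_l) == "intrahemispheric"
        assert classify_edge(parcellation, hp_r, fra_l) == "interhemispheric"

    def test_self_edge_rejected(self, parcellation):
        with pytest.raises(ValueError):
            classify_edge(parcellation, 3, 3)
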