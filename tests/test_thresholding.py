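"""FDR, cluster extent/growth rules, small-volume correction, conjunction."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cuemed import thresholding
from cuemed.errors import ConfigurationError, GridMismatchError


def _pmap(shape, fill=1.0):
    return np.full(shape, fill, dtype=float)


class TestFDR:
    def test_all_small_p_all_significant(self):
        p = _pmap((10, 10, 1), 0.001)
        mask = np.ones(p.shape, dtype=bool)
        sig, thr = thresholding.fdr_bh(p, mask, q=0.05)
        assert sig.all()
        assert thr == pytest.approx(0.001)

    def test_step_up_definition_on_sorted_example(self):
        p = np.array([0.01, 0.02, 0.03, 0.04]).reshape(4, 1, 1)
        mask = np.ones(p.shape, dtype=bool)
        sig, _ = thresholding.fdr_bh(p, mask, q=0.05)
        assert sig.all()   # largest k with p(k) <= 0.05*k/4 is 4

    def test_all_unit_p_none_significant(self):
        p = _pmap((5, 5, 1))
        sig, thr = thresholding.fdr_bh(p, np.ones(p.shape, bool), q=0.05)
        assert not sig.any()
        assert thr == 0.0

    def test_matches_direct_step_up_oracle(self, rng):
        p = rng.uniform(size=(8, 8, 2)) ** 2
        mask = rng.uniform(size=p.shape) < 0.8
        sig, _ = thresholding.fdr_bh(p, mask, q=0.05)
        vals = np.sort(p[mask])
        m = vals.size
        ks = np.flatnonzero(vals <= 0.05 * np.arange(1, m + 1) / m)
        thr_oracle = vals[ks.max()] if ks.size else 0.0
        oracle = np.zeros(p.shape, dtype=bool)
        oracle[mask] = p[mask] <= thr_oracle
        assert np.array_equal(sig, oracle)

    def test_monotone_in_q(self, rng):
        p = rng.uniform(size=(6, 6, 6)) ** 3
        mask = np.ones(p.shape, dtype=bool)
        s1, _ = thresholding.fdr_bh(p, mask, q=0.01)
        s2, _ = thresholding.fdr_bh(p, mask, q=0.10)
        assert (s1 <= s2).all()

    def test_empty_mask_rejected(self):
        with pytest.raises(ConfigurationError):
            thresholding.fdr_bh(_pmap((3, 3, 3)),
                                np.zeros((3, 3, 3), bool))


def _flood_fill_oracle(passing, connectivity=6):
    """Independent BFS connected components over a boolean 3D array."""
    offsets = []
    for dx in (-1, 0, 1):
        for dy in (-1, 0, 1):
            for dz in (-1, 0, 1):
                if (dx, dy, dz) == (0, 0, 0):
                    continue
                order = sum(v != 0 for v in (dx, dy, dz))
                if (connectivity == 6 and order == 1) or \
                   (connectivity == 18 and order <= 2) or connectivity == 26:
                    offsets.append((dx, dy, dz))
    seen = np.zeros(passing.shape, dtype=bool)
    comps = []
    for start in map(tuple, np.argwhere(passing)):
        if seen[start]:
            continue
        queue, comp = [start], []
        seen[start] = True
        while queue:
            v = queue.pop()
            comp.append(v)
            for off in offsets:
                w = tuple(np.add(v, off))
                if all(0 <= w[i] < passing.shape[i] for i in range(3)) \
                        and passing[w] and not seen[w]:
                    seen[w] = True
                    queue.append(w)
        comps.append(set(comp))
    return comps


class TestClusterFilter:
    def test_three_voxel_run_passes_extent(self):
        p = _pmap((5, 5, 5))
        p[1, 1, 1] = p[2, 1, 1] = p[3, 1, 1] = 0.0005
        cs = thresholding.cluster_filter(p, np.ones(p.shape, bool), k_min=3)
        assert len(cs) == 1
        assert cs.clusters[0].size == 3

    def test_two_voxels_fail_extent(self):
        p = _pmap((5, 5, 5))
        p[1, 1, 1] = p[2, 1, 1] = 0.0005
        cs = thresholding.cluster_filter(p, np.ones(p.shape, bool), k_min=3)
        assert len(cs) == 0

    def test_growth_annexes_adjacent_only(self):
        p = _pmap((5, 5, 5))
        p[1, 1, 1] = p[2, 1, 1] = p[3, 1, 1] = 0.0005   # seed
        p[4, 1, 1] = 0.004                                # face-adjacent
        p[0, 4, 4] = 0.004                                # distant
        cs = thresholding.cluster_filter(p, np.ones(p.shape, bool), k_min=3,
                                         grow_ps=(0.005, 0.01))
        assert len(cs) == 1
        members = {tuple(v) for v in cs.clusters[0].coords}
        assert (4, 1, 1) in members
        assert (0, 4, 4) not in members
        assert cs.clusters[0].size == 4

    def test_growth_is_monotone_and_idempotent(self, rng):
        p = rng.uniform(size=(6, 6, 6)) ** 4
        mask = np.ones(p.shape, dtype=bool)
        seeds = thresholding.cluster_filter(p, mask, k_min=2, grow_ps=())
        grown = thresholding.cluster_filter(p, mask, k_min=2,
                                            grow_ps=(0.005, 0.01))
        seed_vox = {tuple(v) for c in seeds.clusters for v in c.coords}
        grown_vox = {tuple(v) for c in grown.clusters for v in c.coords}
        assert seed_vox <= grown_vox
        again = thresholding.cluster_filter(p, mask, k_min=2,
                                            grow_ps=(0.01, 0.01))
        grown2 = thresholding.cluster_filter(p, mask, k_min=2,
                                             grow_ps=(0.01,))
        assert ({tuple(v) for c in again.clusters for v in c.coords}
                == {tuple(v) for c in grown2.clusters for v in c.coords})

    @pytest.mark.parametrize("connectivity", [6, 18, 26])
    def test_matches_flood_fill_oracle(self, rng, connectivity):
        for _ in range(5):
            p = rng.uniform(size=(5, 5, 5))
            p[p < 0.4] /= 1000.0   # sprinkle sub-threshold voxels
            mask = np.ones(p.shape, dtype=bool)
            cs = thresholding.cluster_filter(p, mask, primary_p=0.001,
                                             k_min=1, grow_ps=(),
                                             connectivity=connectivity)
            ours = sorted(frozenset(map(tuple, c.coords)) for c in cs.clusters)
            oracle = sorted(map(frozenset,
                                _flood_fill_oracle(p < 0.001, connectivity)))
            assert ours == oracle

    def test_growth_never_creates_new_clusters(self):
        p = _pmap((5, 5, 5))
        p[0, 0, 0] = 0.004   # passes growth threshold but touches no seed
        cs = thresholding.cluster_filter(p, np.ones(p.shape, bool), k_min=3,
                                         grow_ps=(0.005,))
        assert len(cs) == 0

    def test_unsorted_grow_thresholds_rejected(self):
        with pytest.raises(ConfigurationError):
            thresholding.cluster_filter(_pmap((3, 3, 3)),
                                        np.ones((3, 3, 3), bool),
                                        grow_ps=(0.01, 0.005))


class TestSVC:
    def test_bonferroni_arithmetic(self):
        p = _pmap((10, 10, 1))
        p[0, 0, 0] = 0.0004
        roi = np.ones(p.shape, dtype=bool)   # 100 voxels
        sig, info = thresholding.small_volume_correction(
            roi, method="bonferroni", p_map=p)
        assert sig[0, 0, 0]
        assert sig.sum() == 1
        assert info["threshold"] == pytest.approx(0.0005)

    def test_single_voxel_roi_reduces_to_uncorrected(self):
        p = _pmap((3, 3, 3))
        p[1, 1, 1] = 0.03
        roi = np.zeros(p.shape, dtype=bool)
        roi[1, 1, 1] = True
        sig, info = thresholding.small_volume_correction(
            roi, method="bonferroni", p_map=p, alpha=0.05)
        assert sig[1, 1, 1]
        assert info["threshold"] == pytest.approx(0.05)

    def test_permutation_detects_strong_signal(self, rng):
        roi = np.zeros((4, 4, 4), dtype=bool)
        roi[:2] = True
        maps = rng.standard_normal((16, 4, 4, 4)) * 0.5
        maps[:, 0, 0, 0] += 2.0
        sig, info = thresholding.small_volume_correction(
            roi, method="permutation", subject_maps=maps, n_perm=500, seed=0)
        assert sig[0, 0, 0]

    def test_permutation_null_familywise_calibration(self):
        # null subject maps: familywise rejection rate near alpha
        rejections = 0
        n_sims = 200
        for sim in range(n_sims):
            rng = np.random.default_rng(10_000 + sim)
            maps = rng.standard_normal((12, 5, 5, 4))
            roi = np.zeros((5, 5, 4), dtype=bool)
            roi[:, :, :2] = True   # 50-voxel ROI
            sig, _ = thresholding.small_volume_correction(
                roi, method="permutation", subject_maps=maps,
                n_perm=300, seed=sim)
            rejections += int(sig.any())
        assert rejections / n_sims <= 0.095   # alpha=.05 plus binomial slack

    def test_empty_roi_rejected(self):
        with pytest.raises(ConfigurationError):
            thresholding.small_volume_correction(
                np.zeros((3, 3, 3), bool), method="bonferroni",
                p_map=_pmap((3, 3, 3)))


class TestConjunction:
    def test_idempotence(self, rng):
        m = rng.uniform(size=(4, 4, 4)) < 0.3
        assert np.array_equal(thresholding.conjunction([m, m]), m)

    def test_disjoint_masks_empty(self):
        a = np.zeros((3, 3, 3), dtype=bool)
        b = np.zeros((3, 3, 3), dtype=bool)
        a[0, 0, 0] = True
        b[1, 1, 1] = True
        assert not thresholding.conjunction([a, b]).any()

    def test_three_masks_match_set_intersection_oracle(self, rng):
        masks = [rng.uniform(size=(4, 4, 4)) < 0.6 for _ in range(3)]
        shared = {(0, 0, 0), (2, 3, 1)}
        for m in masks:
            for v in shared:
                m[v] = True
        conj = thresholding.conjunction(masks)
        oracle = set.intersection(*[
            {tuple(v) for v in np.argwhere(m)} for m in masks])
        assert {tuple(v) for v in np.argwhere(conj)} == oracle
        assert shared <= oracle

    def test_result_subset_of_every_input(self, rng):
        masks = [rng.uniform(size=(5, 5, 5)) < 0.5 for _ in range(4)]
        conj = thresholding.conjunction(masks)
        for m in masks:
            assert (conj <= m).all()

    def test_grid_mismatch_rejected(self):
        with pytest.raises(GridMismatchError):
            thresholding.conjunction([np.ones((3, 3, 3), bool),
                                      np.ones((4, 4, 4), bool)])


@settings(max_examples=25, deadline=None, derandomize=True)
@given(seed=st.integers(0, 5000), q1=st.floats(0.01, 0.05),
       q2=st.floats(0.05, 0.2))
def test_property_fdr_rejections_nested_in_q(seed, q1, q2):
    rng = np.random.default_rng(seed)
    p = rng.uniform(size=(5, 5, 5)) ** 2
    mask = np.ones(p.shape, dtype=bool)
    s1, _ = thresholding.fdr_bh(p, mask, q=q1)
    s2, _ = thresholding.fdr_bh(p, mask, q=q2)
    assert (s1 <= s2).all()
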