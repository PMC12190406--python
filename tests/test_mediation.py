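"""Path algebra, bootstrap behavior, moderation, and the voxelwise wrapper."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cuemed import mediation
from cuemed.errors import ConfigurationError, SingularFitError
from cuemed.mediation import SubjectPaths


def _random_paths(rng, n, a=0.0, b=0.0, sd=1.0):
    return [SubjectPaths(a=a + sd * rng.standard_normal(),
                         b=b + sd * rng.standard_normal(),
                         c=rng.standard_normal(), c_prime=rng.standard_normal())
            for _ in range(n)]


class TestCueCoding:
    @pytest.mark.parametrize("group,kind,sign", [
        ("Heat", "valence", -1.0),
        ("Salt", "valence", -1.0),
        ("Sugar", "valence", 1.0),
        ("Heat", "intensity", 1.0),
        ("Salt", "intensity", 1.0),
        ("Sugar", "intensity", 1.0),
    ])
    def test_contrast_signs(self, group, kind, sign):
        assert mediation.code_cue_contrast(group, kind) == sign

    def test_unknown_group_rejected(self):
        with pytest.raises(ConfigurationError):
            mediation.code_cue_contrast("Vinegar", "intensity")

    def test_cue_to_x_applies_sign(self):
        x = mediation.cue_to_x(["High", "Low"], "Heat", "valence")
        assert x.tolist() == [-0.5, 0.5]


class TestSubjectPaths:
    def test_hand_computed_example(self):
        p = mediation.fit_subject_paths([-0.5, -0.5, 0.5, 0.5],
                                        [0, 1, 1, 2], [0, 1, 2, 3])
        assert (p.a, p.b, p.c, p.c_prime) == pytest.approx((1, 1, 2, 1))
        assert p.c - p.c_prime == pytest.approx(p.a * p.b, abs=1e-12)

    def test_null_b_path_limit(self):
        # Y depends on X only; M varies independently of X
        x = np.array([-0.5, -0.5, 0.5, 0.5])
        m = np.array([0.0, 1.0, 0.0, 1.0])
        y = 2.0 * x
        p = mediation.fit_subject_paths(x, m, y)
        assert p.b == pytest.approx(0.0, abs=1e-12)
        assert p.c == pytest.approx(p.c_prime, abs=1e-12)

    def test_identity_on_random_instances(self):
        rng = np.random.default_rng(42)
        worst = 0.0
        for _ in range(200):
            n = rng.integers(5, 40)
            x = rng.standard_normal(n)
            m = rng.standard_normal(n) + 0.5 * x
            y = rng.standard_normal(n) + 0.3 * x + 0.7 * m
            p = mediation.fit_subject_paths(x, m, y)
            worst = max(worst, abs(p.c - p.c_prime - p.a * p.b))
        assert worst <= 1e-10

    def test_constant_inputs_rejected(self):
        with pytest.raises(SingularFitError):
            mediation.fit_subject_paths([1, 1, 1, 1], [0, 1, 2, 3],
                                        [0, 1, 2, 3])
        with pytest.raises(SingularFitError):
            mediation.fit_subject_paths([0, 1, 0, 1], [2, 2, 2, 2],
                                        [0, 1, 2, 3])


class TestPopulation:
    def test_constant_paths(self):
        res = mediation.population_mediation(
            [SubjectPaths(1, 1, 2, 1), SubjectPaths(1, 1, 2, 1)])
        assert res.ab == pytest.approx(1.0)
        assert res.cov_ab == pytest.approx(0.0)

    def test_two_point_covariance_algebra(self):
        res = mediation.population_mediation(
            [SubjectPaths(0, 0, 0, 0), SubjectPaths(2, 2, 0, 0)])
        assert res.a == pytest.approx(1.0)
        assert res.b == pytest.approx(1.0)
        assert res.cov_ab == pytest.approx(1.0)
        assert res.ab == pytest.approx(2.0)   # mean(a)mean(b) + cov_n

    def test_decomposition_identity_random_draws(self):
        rng = np.random.default_rng(7)
        paths = _random_paths(rng, 30)
        res = mediation.population_mediation(paths)
        direct = np.mean([p.a * p.b for p in paths])
        assert abs(res.ab - direct) <= 1e-12
        assert abs(res.ab - (res.a * res.b + res.cov_ab)) <= 1e-12

    def test_single_subject_rejected(self):
        with pytest.raises(SingularFitError):
            mediation.population_mediation([SubjectPaths(1, 1, 1, 1)])


class TestBootstrap:
    def test_degenerate_resampling_hits_floor(self):
        paths = [SubjectPaths(1, 1, 2, 1) for _ in range(6)]
        res = mediation.bootstrap_test(paths, n_boot=1000, seed=0)
        assert res.p["ab"] == pytest.approx(1.0 / 1000)

    def test_seed_determinism(self):
        rng = np.random.default_rng(3)
        paths = _random_paths(rng, 12, a=0.5, b=0.5)
        r1 = mediation.bootstrap_test(paths, n_boot=500, seed=99)
        r2 = mediation.bootstrap_test(paths, n_boot=500, seed=99)
        assert r1.p == r2.p

    def test_small_n_boot_warns(self):
        rng = np.random.default_rng(4)
        with pytest.warns(UserWarning):
            mediation.bootstrap_test(_random_paths(rng, 5), n_boot=50, seed=0)

    def test_strong_effect_detected(self):
        rng = np.random.default_rng(5)
        paths = _random_paths(rng, 25, a=1.0, b=1.0, sd=0.2)
        res = mediation.bootstrap_test(paths, n_boot=2000, seed=1)
        assert res.p["ab"] < 0.01


class TestModeration:
    def test_two_group_contrast(self):
        paths = [SubjectPaths(1, 0, 0, 0)] * 4 + [SubjectPaths(-1, 0, 0, 0)] * 4
        import pandas as pd
        design = pd.DataFrame({"intercept": np.ones(8),
                               "dummy_a": [1.0] * 4 + [0.0] * 4})
        res = mediation.moderated_mediation(paths, design, n_boot=200, seed=0)
        assert res["a"]["estimate"]["dummy_a"] == pytest.approx(2.0, abs=1e-10)
        assert res["a"]["estimate"]["intercept"] == pytest.approx(-1.0, abs=1e-10)

    def test_centered_dummy_intercept_equals_mean_path(self):
        rng = np.random.default_rng(6)
        paths = _random_paths(rng, 10, a=0.4)
        import pandas as pd
        dummy = np.array([0.5] * 5 + [-0.5] * 5)
        design = pd.DataFrame({"intercept": np.ones(10), "mod": dummy})
        res = mediation.moderated_mediation(paths, design, n_boot=200, seed=0)
        mean_a = np.mean([p.a for p in paths])
        assert res["a"]["estimate"]["intercept"] == pytest.approx(mean_a,
                                                                  abs=1e-10)

    def test_orthogonal_moderator_null(self):
        rng = np.random.default_rng(8)
        rejections = 0
        import pandas as pd
        for seed in range(20):
            paths = _random_paths(np.random.default_rng(seed), 16, a=0.5, b=0.5)
            dummy = np.array([1.0] * 8 + [0.0] * 8)
            design = pd.DataFrame({"intercept": np.ones(16), "mod": dummy})
            res = mediation.moderated_mediation(paths, design, n_boot=400,
                                                seed=seed)
            rejections += res["ab"]["p"]["mod"] < 0.05
        assert rejections <= 4   # near-nominal false-positive count

    def test_collinear_design_rejected(self):
        import pandas as pd
        paths = [SubjectPaths(1, 1, 1, 1)] * 4
        design = pd.DataFrame({"intercept": np.ones(4),
                               "d1": [1.0, 1, 0, 0], "d2": [1.0, 1, 0, 0]})
        with pytest.raises(ConfigurationError):
            mediation.moderated_mediation(paths, design, n_boot=100, seed=0)

    def test_group_design_codes(self):
        design = mediation.level2_design(
            ["Heat", "Salt", "Sugar"], factors=("group", "modality",
                                                "aversiveness"))
        assert design.loc[0, "heat_gt_salt"] == 1.0
        assert design.loc[1, "salt_gt_sugar"] == 1.0
        assert design.loc[0, "modality_heat"] == 1.0
        assert design.loc[2, "appetitive"] == 1.0


class TestVoxelwise:
    def _inputs(self, rng, n_subj=6, n_trials=20, n_vox=5):
        betas, xs, ys = {}, {}, {}
        for s in range(n_subj):
            x = np.repeat([0.5, -0.5], n_trials // 2)
            m = rng.standard_normal((n_trials, n_vox)) + 0.8 * x[:, None]
            y = rng.standard_normal(n_trials) + m[:, 0]
            betas[f"s{s}"], xs[f"s{s}"], ys[f"s{s}"] = m, x, y
        return betas, xs, ys

    def test_single_voxel_matches_scalar_bitwise(self, rng):
        betas, xs, ys = self._inputs(rng, n_vox=1)
        vox = mediation.voxelwise_mediation(betas, xs, ys, n_boot=300, seed=5)
        paths = [mediation.fit_subject_paths(xs[s], betas[s][:, 0], ys[s])
                 for s in betas]
        scal = mediation.bootstrap_test(paths, n_boot=300, seed=5)
        for stat in ("a", "b", "c", "c_prime", "ab"):
            assert getattr(vox, stat) == getattr(scal, stat)
            assert vox.p[stat] == scal.p[stat]

    def test_voxelwise_equals_scalar_per_voxel(self, rng):
        betas, xs, ys = self._inputs(rng, n_vox=8)
        vox = mediation.voxelwise_mediation(betas, xs, ys, n_boot=200, seed=2)
        for j in rng.choice(8, size=5, replace=False):
            paths = [mediation.fit_subject_paths(xs[s], betas[s][:, j], ys[s])
                     for s in betas]
            scal = mediation.population_mediation(paths)
            for stat in ("a", "b", "c", "c_prime", "ab"):
                assert getattr(vox, stat)[j] == pytest.approx(
                    getattr(scal, stat), abs=1e-12)

    def test_planted_region_small_p_null_voxels_uniform(self, planted_brain):
        ds, bspec = planted_brain
        betas, xs, ys = mediation.dataset_mediation_inputs(ds, "intensity")
        res = mediation.voxelwise_mediation(betas, xs, ys, n_boot=500, seed=3)
        region = np.zeros(bspec.shape, dtype=bool)
        region[tuple(bspec.regions[0].coords.T)] = True
        ridx = region[ds.mask]
        assert np.median(res.p["ab"][ridx]) < 0.05
        null_p = res.p["ab"][~ridx]
        assert 0.3 < np.mean(null_p) < 0.7    # roughly uniform under the null

    def test_permuted_x_destroys_signal(self, planted_brain):
        ds, bspec = planted_brain
        betas, xs, ys = mediation.dataset_mediation_inputs(ds, "intensity")
        rng = np.random.default_rng(17)
        xs = {s: rng.permutation(v) for s, v in xs.items()}
        res = mediation.voxelwise_mediation(betas, xs, ys, n_boot=500, seed=3)
        region = np.zeros(bspec.shape, dtype=bool)
        region[tuple(bspec.regions[0].coords.T)] = True
        rate = np.mean(res.p["a"][region[ds.mask]] < 0.05)
        assert rate < 0.3    # no systematic path-a signal after permutation


@settings(max_examples=40, deadline=None, derandomize=True)
@given(seed=st.integers(0, 10_000), n=st.integers(4, 25))
def test_property_identity_and_decomposition(seed, n):
    """c - c' = a*b per subject; ab = mean(a_i b_i) at the population level."""
    rng = np.random.default_rng(seed)
    paths = []
    for _ in range(n):
        x = rng.standard_normal(12)
        m = rng.standard_normal(12) + 0.4 * x
        y = rng.standard_normal(12) + 0.4 * m
        p = mediation.fit_subject_paths(x, m, y)
        assert abs(p.c - p.c_prime - p.a * p.b) <= 1e-10
        paths.append(p)
    res = mediation.population_mediation(paths)
    assert abs(res.ab - np.mean([p.a * p.b for p in paths])) <= 1e-12
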