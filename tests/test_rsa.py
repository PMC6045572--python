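"""RDMs, second-order comparison, permutation inference, searchlight."""

import numpy as np
import pytest
from scipy import stats

from visemnet import (
    RDM,
    RegionSpec,
    compare_rdms,
    composite_best_stage_map,
    compute_rdm,
    compute_rdm_from_patterns,
    gen_synthetic_brain,
    gen_visual_stage_trajectory,
    group_inference,
    noise_ceiling_lower,
    roi_permutation_test,
    searchlight_map,
)
from visemnet.syndata import StageRepresentation, SyntheticBrain


def random_rdm(n, rng):
    return compute_rdm_from_patterns(rng.normal(size=(n, 30)))


class TestComputeRdm:
    def test_identical_patterns_zero_dissimilarity(self):
        X = np.vstack([np.arange(8.0), np.arange(8.0), np.random.default_rng(0).normal(size=8)])
        rdm = compute_rdm_from_patterns(X)
        assert rdm.matrix[0, 1] == pytest.approx(0.0, abs=1e-12)

    def test_negated_pattern_maximal_dissimilarity(self):
        base = np.array([1.0, -2.0, 3.0, -2.0])  # mean-free
        X = np.vstack([base, -base, np.array([0.5, 1.0, -1.0, -0.5])])
        rdm = compute_rdm_from_patterns(X)
        assert rdm.matrix[0, 1] == pytest.approx(2.0)

    def test_orthogonal_patterns_dissimilarity_one(self):
        """Mean-centred orthogonal patterns sit at 1 - r = 1."""
        X = np.array([
            [1.0, -1.0, 0.0, 0.0],
            [0.0, 0.0, 1.0, -1.0],
            [1.0, 1.0, -1.0, -1.0],
        ])
        rdm = compute_rdm_from_patterns(X)
        assert rdm.matrix[0, 1] == pytest.approx(1.0)

    def test_matches_pairwise_brute_force(self):
        rng = np.random.default_rng(1)
        X = rng.normal(size=(7, 12))
        rdm = compute_rdm_from_patterns(X)
        for i in range(7):
            for j in range(7):
                expected = 0.0 if i == j else 1 - stats.pearsonr(X[i], X[j]).statistic
                assert rdm.matrix[i, j] == pytest.approx(expected, abs=1e-12)

    def test_constant_pattern_names_item(self):
        X = np.vstack([np.ones(5), np.arange(5.0), np.arange(5.0) ** 2])
        with pytest.raises(ValueError, match="item 0"):
            compute_rdm_from_patterns(X)

    def test_stage_representation_entrypoint(self):
        rep = StageRepresentation(
            "s", ["a", "b", "c"], np.random.default_rng(0).normal(size=(3, 9))
        )
        assert compute_rdm(rep).items == ["a", "b", "c"]


class TestCompareRdms:
    def test_self_correlation_is_one(self):
        rdm = random_rdm(6, np.random.default_rng(0))
        assert compare_rdms(rdm, rdm) == pytest.approx(1.0)

    def test_rank_reversal_gives_minus_one(self):
        rdm = random_rdm(6, np.random.default_rng(1))
        reversed_ = RDM(items=rdm.items, matrix=2.0 - rdm.matrix)
        np.fill_diagonal(reversed_.matrix, 0.0)
        assert compare_rdms(rdm, reversed_) == pytest.approx(-1.0)

    def test_matches_rank_then_pearson_oracle(self):
        """4-item triangles, rho recomputed by ranking by hand."""
        rng = np.random.default_rng(2)
        a, b = random_rdm(4, rng), random_rdm(4, rng)
        ta = [a.matrix[i, j] for i in range(4) for j in range(i)]
        tb = [b.matrix[i, j] for i in range(4) for j in range(i)]
        ra, rb = stats.rankdata(ta), stats.rankdata(tb)
        oracle = stats.pearsonr(ra, rb).statistic
        assert compare_rdms(a, b) == pytest.approx(oracle, abs=1e-12)

    def test_invariant_to_monotone_transform(self):
        rng = np.random.default_rng(3)
        a, b = random_rdm(8, rng), random_rdm(8, rng)
        warped = RDM(items=b.items, matrix=np.sqrt(b.matrix) * 1.7)
        assert compare_rdms(a, warped) == pytest.approx(compare_rdms(a, b))
        assert compare_rdms(a, b) == pytest.approx(compare_rdms(b, a))

    def test_mismatched_items_rejected(self):
        rng = np.random.default_rng(4)
        a, b = random_rdm(5, rng), random_rdm(5, rng)
        b.items = list(reversed(b.items))
        with pytest.raises(ValueError):
            compare_rdms(a, b)


class TestRoiPermutationTest:
    def test_identical_rdm_minimal_p(self):
        rng = np.random.default_rng(0)
        neural = random_rdm(10, rng)
        res = roi_permutation_test(neural, {"m": neural}, n_perm=1000, seed=0)
        assert res.rho["m"] == pytest.approx(1.0)
        assert res.p["m"] <= 2 / 1001

    def test_bonferroni_caps_at_one(self):
        rng = np.random.default_rng(1)
        res = roi_permutation_test(
            random_rdm(8, rng), {"m": random_rdm(8, rng)},
            n_perm=200, n_comparisons=50, seed=0,
        )
        assert 0 < res.p_corrected["m"] <= 1.0

    def test_small_n_perm_rejected(self):
        rng = np.random.default_rng(2)
        with pytest.raises(ValueError):
            roi_permutation_test(random_rdm(5, rng), {"m": random_rdm(5, rng)},
                                 n_perm=10)


class TestNoiseCeiling:
    def test_identical_subjects_ceiling_one(self):
        rdm = random_rdm(6, np.random.default_rng(0))
        assert noise_ceiling_lower([rdm, rdm, rdm]) == pytest.approx(1.0)

    def test_two_subjects_symmetric_pairwise(self):
        rng = np.random.default_rng(1)
        a, b = random_rdm(7, rng), random_rdm(7, rng)
        b.items = a.items
        assert noise_ceiling_lower([a, b]) == pytest.approx(
            (compare_rdms(a, b) + compare_rdms(b, a)) / 2
        )

    def test_decreases_with_noise(self):
        """LOSO bound falls as inter-subject noise rises."""
        rng = np.random.default_rng(2)
        signal = rng.normal(size=(10, 20))
        bounds = []
        for scale in (0.2, 1.0, 4.0):
            vals = []
            for rep in range(10):
                rdms = [
                    compute_rdm_from_patterns(signal + scale * rng.normal(size=signal.shape))
                    for _ in range(4)
                ]
                vals.append(noise_ceiling_lower(rdms))
            bounds.append(np.mean(vals))
        assert bounds[0] > bounds[1] > bounds[2]

    def test_requires_two_subjects(self):
        with pytest.raises(ValueError):
            noise_ceiling_lower([random_rdm(5, np.random.default_rng(0))])


@pytest.fixture(scope="module")
def small_brain():
    rng = np.random.default_rng(0)
    emb = rng.normal(size=(12, 10))
    stages = gen_visual_stage_trajectory(emb, n_layers=2, seed=0)
    return gen_synthetic_brain(
        stages,
        [RegionSpec("A", "visual_layer2", n_voxels=40)],
        n_subjects=5,
        snr=1e9,
        grid_shape=(8, 6, 6),
        seed=0,
    ), stages


class TestSearchlight:
    def test_matches_per_voxel_brute_force(self, small_brain):
        brain, stages = small_brain
        from visemnet.rsa import compute_rdm

        model = compute_rdm(stages[1])
        got = searchlight_map(brain, model, radius=2.0, subject=1)
        # naive reimplementation over every voxel
        coords = np.array(np.unravel_index(np.arange(brain.n_voxels), brain.grid_shape)).T
        P = brain.patterns[1]
        for v in range(0, brain.n_voxels, 17):
            d = np.sqrt(((coords - coords[v]) ** 2).sum(axis=1))
            sphere = np.flatnonzero(d <= 2.0)
            X = P[:, sphere]
            if X.std(axis=1).min() == 0 or len(sphere) < 2:
                assert np.isnan(got[v])
                continue
            local = compute_rdm_from_patterns(X)
            assert got[v] == pytest.approx(compare_rdms(local, model), abs=1e-10)

    def test_sphere_covering_noiseless_region_gives_rho_one(self):
        """A sphere that contains exactly the region recovers its stage."""
        rng = np.random.default_rng(3)
        emb = rng.normal(size=(12, 10))
        stages = gen_visual_stage_trajectory(emb, n_layers=2, seed=3)
        brain = gen_synthetic_brain(
            stages,
            [RegionSpec("A", "visual_layer2", n_voxels=27)],
            n_subjects=1, snr=1e12, grid_shape=(3, 3, 3), seed=3,
        )
        assert len(brain.region_voxels("A")) == brain.n_voxels
        model = compute_rdm(stages[1])
        got = searchlight_map(brain, model, radius=2.0, subject=0)
        center = np.ravel_multi_index((1, 1, 1), (3, 3, 3))
        assert got[center] == pytest.approx(1.0, abs=1e-6)

    def test_single_voxel_grid_yields_missing(self):
        brain = SyntheticBrain(
            n_subjects=1, grid_shape=(1, 1, 1),
            region_map=np.array(["background"], dtype=object),
            patterns=[np.random.default_rng(0).normal(size=(6, 1))],
            truth={}, snr={}, items=[f"i{k}" for k in range(6)],
        )
        model = random_rdm(6, np.random.default_rng(1))
        got = searchlight_map(brain, model, radius=1.0, subject=0)
        assert np.isnan(got[0])

    def test_small_radius_rejected(self, small_brain):
        brain, stages = small_brain
        with pytest.raises(ValueError):
            searchlight_map(brain, random_rdm(12, np.random.default_rng(0)),
                            radius=0.5, subject=0)


class TestGroupInference:
    def test_all_zero_maps_empty_mask(self):
        maps = np.zeros((6, 50))
        with pytest.warns(UserWarning, match="sign patterns"):
            res = group_inference(maps, alpha_fdr=0.05, n_perm=5000, seed=0)
        assert not res.mask.any()

    def test_planted_effect_recovered(self):
        """Signal block fully detected; background rejections at FDR level."""
        rng = np.random.default_rng(0)
        n_subj, n_vox = 12, 200
        power, background = [], []
        for rep in range(10):
            maps = 0.05 * rng.normal(size=(n_subj, n_vox))
            maps[:, :40] += 0.6  # strong consistent effect in one block
            res = group_inference(maps, alpha_fdr=0.01, n_perm=2000, seed=rep)
            power.append(res.mask[:40].mean())
            background.append(res.mask[40:].mean())
        assert np.mean(power) == 1.0
        assert np.mean(background) < 0.01

    def test_exhaustive_flips_for_few_subjects(self):
        rng = np.random.default_rng(1)
        maps = rng.normal(size=(5, 30))
        with pytest.warns(UserWarning, match="exhaustive"):
            res = group_inference(maps, alpha_fdr=0.05, n_perm=1000, seed=0)
        assert np.nanmin(res.p) >= 2 / (2**5 + 1)

    def test_too_few_subjects_rejected(self):
        with pytest.raises(ValueError):
            group_inference(np.zeros((3, 10)))


class TestCompositeMap:
    def test_single_significant_stage(self):
        maps = {"s1": np.array([0.1, 0.5, 0.2]), "s2": np.array([0.3, 0.4, 0.1])}
        masks = {"s1": np.array([True, True, False]), "s2": np.array([False] * 3)}
        out = composite_best_stage_map(maps, masks)
        # voxel 0: s2 has higher rho even though only s1 is significant
        assert out.tolist() == [2, 1, 0]

    def test_exact_tie_goes_to_earlier_stage(self):
        maps = {"s1": np.array([0.4]), "s2": np.array([0.4])}
        masks = {"s1": np.array([True]), "s2": np.array([True])}
        assert composite_best_stage_map(maps, masks).tolist() == [1]

    def test_mismatched_stages_rejected(self):
        with pytest.raises(ValueError):
            composite_best_stage_map({"a": np.zeros(2)}, {"b": np.zeros(2, dtype=bool)})
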