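"""Generators: norms, embeddings, visual trajectory, SVD, synthetic brain."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from visemnet import (
    RegionSpec,
    gen_feature_norms,
    gen_synthetic_brain,
    gen_visual_embeddings,
    gen_visual_stage_trajectory,
    svd_reduce,
)
from visemnet.rsa import compare_rdms, compute_rdm, compute_rdm_from_patterns
from visemnet.syndata import FEATURE_TYPES


def jaccard(a, b):
    a, b = set(np.flatnonzero(a)), set(np.flatnonzero(b))
    return len(a & b) / len(a | b)


class TestFeatureNorms:
    def test_seeded_determinism(self):
        a = gen_feature_norms(n_concepts=6, n_categories=2, features_per_concept=4, seed=5)
        b = gen_feature_norms(n_concepts=6, n_categories=2, features_per_concept=4, seed=5)
        assert np.array_equal(a.matrix, b.matrix)
        assert a.feature_type == b.feature_type

    def test_category_structure_in_jaccard(self, tiny_norms):
        """Concepts within a category share more features than across."""
        cats = np.array(tiny_norms.category)
        within, between = [], []
        for i, j in itertools.combinations(range(len(cats)), 2):
            sim = jaccard(tiny_norms.matrix[i], tiny_norms.matrix[j])
            (within if cats[i] == cats[j] else between).append(sim)
        assert np.mean(within) > np.mean(between)

    def test_every_concept_has_distinguishing_feature(self, tiny_norms):
        N = tiny_norms.concept_count
        has_dist = (tiny_norms.matrix[:, N <= 2].sum(axis=1) >= 1).all()
        assert has_dist

    def test_rejects_impossible_budget(self):
        with pytest.raises(ValueError):
            gen_feature_norms(
                n_concepts=6, n_categories=2, features_per_concept=2,
                sharedness_profile={"category": 0.5, "cross_category": 0.5,
                                    "distinguishing": 0.0},
            )

    @settings(max_examples=15, deadline=None, derandomize=True)
    @given(
        n_concepts=st.integers(8, 40),
        n_categories=st.integers(2, 6),
        fpc=st.integers(6, 16),
        seed=st.integers(0, 10_000),
    )
    def test_invariants_hold_across_parameters(self, n_concepts, n_categories, fpc, seed):
        norms = gen_feature_norms(
            n_concepts=n_concepts, n_categories=n_categories,
            features_per_concept=fpc, seed=seed,
        )
        norms.validate()  # binary, no empty concepts or features
        assert np.array_equal(norms.concept_count, norms.matrix.sum(axis=0))
        assert set(norms.feature_type) <= set(FEATURE_TYPES)

    def test_tsv_roundtrip(self, tiny_norms, tmp_path):
        tiny_norms.to_tsv(tmp_path / "norms.tsv", tmp_path / "meta.tsv")
        back = type(tiny_norms).from_tsv(tmp_path / "norms.tsv", tmp_path / "meta.tsv")
        assert np.array_equal(back.matrix, tiny_norms.matrix)
        assert back.feature_type == tiny_norms.feature_type


class TestVisualEmbeddings:
    def test_decoupled_limit_has_no_visual_signal(self, tiny_norms):
        emb = gen_visual_embeddings(tiny_norms, n_dims=10, visual_coupling=0.0,
                                    noise_sd=1.0, seed=0)
        V = tiny_norms.visual_submatrix()
        overlap = V @ V.T
        sim = np.corrcoef(emb)
        iu = np.triu_indices(len(sim), k=1)
        r = np.corrcoef(overlap[iu], sim[iu])[0, 1]
        assert abs(r) < 0.15

    def test_identical_visual_features_identical_embeddings(self, tiny_norms):
        emb = gen_visual_embeddings(tiny_norms, n_dims=10, visual_coupling=1.0,
                                    noise_sd=0.0, seed=0)
        V = tiny_norms.visual_submatrix()
        same = [
            (i, j)
            for i, j in itertools.combinations(range(V.shape[0]), 2)
            if np.array_equal(V[i], V[j])
        ]
        assert same, "fixture should contain concepts with identical visual features"
        for i, j in same:
            assert np.allclose(emb[i], emb[j])

    def test_coupling_detectable_by_permutation(self, tiny_norms):
        """Embedding similarity tracks visual-feature overlap (p < 0.01)."""
        from scipy import stats

        emb = gen_visual_embeddings(tiny_norms, n_dims=10, visual_coupling=0.8,
                                    noise_sd=0.5, seed=1)
        V = tiny_norms.visual_submatrix()
        overlap = V @ V.T
        sim = np.corrcoef(emb)
        iu = np.triu_indices(len(sim), k=1)
        obs = stats.spearmanr(overlap[iu], sim[iu]).statistic
        rng = np.random.default_rng(0)
        n = len(sim)
        null = []
        for _ in range(1000):
            p = rng.permutation(n)
            null.append(stats.spearmanr(overlap[p][:, p][iu], sim[iu]).statistic)
        pval = (1 + np.sum(np.array(null) >= obs)) / 1001
        assert pval < 0.01


class TestVisualTrajectory:
    def test_single_layer_equals_embeddings(self, tiny_norms):
        emb = gen_visual_embeddings(tiny_norms, seed=0)
        stages = gen_visual_stage_trajectory(emb, n_layers=1, seed=0)
        assert len(stages) == 1
        assert np.array_equal(stages[0].matrix, emb)

    def test_rdm_similarity_monotone_in_depth(self, tiny_norms):
        emb = gen_visual_embeddings(tiny_norms, seed=0)
        stages = gen_visual_stage_trajectory(emb, n_layers=7, seed=0)
        target = compute_rdm_from_patterns(emb)
        rhos = [compare_rdms(compute_rdm(s), target) for s in stages]
        assert all(b >= a - 1e-12 for a, b in zip(rhos, rhos[1:]))
        assert rhos[0] < rhos[-1]
        assert rhos[-1] == pytest.approx(1.0)


class TestSvdReduce:
    def test_low_rank_full_recovery(self):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(30, 2)) @ rng.normal(size=(2, 15))
        _, ve = svd_reduce(X, 2)
        assert ve == pytest.approx(1.0)

    def test_full_rank_preserves_euclidean_geometry(self):
        """At full rank the projection is a rotation: distances survive."""
        from scipy.spatial.distance import pdist

        rng = np.random.default_rng(1)
        X = rng.normal(size=(12, 8))
        R, ve = svd_reduce(X, 8)
        assert ve == pytest.approx(1.0)
        assert np.allclose(pdist(R), pdist(X))

    def test_variance_matches_gram_eigendecomposition(self):
        """Independent oracle: eigenvalues of X X^T."""
        rng = np.random.default_rng(2)
        X = rng.normal(size=(100, 40))
        _, ve = svd_reduce(X, 10)
        evals = np.sort(np.linalg.eigvalsh(X @ X.T))[::-1]
        assert ve == pytest.approx(evals[:10].sum() / evals.sum(), rel=1e-10)

    def test_variance_nondecreasing_in_k(self):
        rng = np.random.default_rng(3)
        X = rng.normal(size=(20, 10))
        ves = [svd_reduce(X, k)[1] for k in range(1, 11)]
        assert all(b >= a for a, b in zip(ves, ves[1:]))
        assert ves[-1] == pytest.approx(1.0)

    def test_rejects_bad_input(self):
        with pytest.raises(ValueError):
            svd_reduce(np.array([[np.nan, 1.0]]), 1)
        with pytest.raises(ValueError):
            svd_reduce(np.ones((3, 3)), 4)


class TestSyntheticBrain:
    @pytest.fixture(scope="class")
    def stages(self, tiny_norms):
        emb = gen_visual_embeddings(tiny_norms, seed=0)
        return gen_visual_stage_trajectory(emb, n_layers=3, seed=0,
                                           items=tiny_norms.concept_ids)

    def test_noiseless_region_rdm_equals_stage_rdm(self, stages):
        brain = gen_synthetic_brain(
            stages, [RegionSpec("A", "visual_layer2")], n_subjects=2, snr=1e12, seed=0
        )
        vox = brain.region_voxels("A")
        region_rdm = compute_rdm_from_patterns(brain.patterns[0][:, vox])
        stage_rdm = compute_rdm(stages[1])
        assert np.allclose(region_rdm.matrix, stage_rdm.matrix, atol=1e-6)

    def test_zero_snr_rejected(self, stages):
        with pytest.raises(ValueError):
            gen_synthetic_brain(
                stages, [RegionSpec("A", "visual_layer1", snr=0.0)],
                n_subjects=1, seed=0,
            )

    def test_unknown_stage_rejected(self, stages):
        with pytest.raises(ValueError):
            gen_synthetic_brain(
                stages, [RegionSpec("A", "no_such_stage")], n_subjects=1, seed=0
            )

    def test_determinism(self, stages):
        specs = [RegionSpec("A", "visual_layer1")]
        b1 = gen_synthetic_brain(stages, specs, n_subjects=2, snr=2.0, seed=9)
        b2 = gen_synthetic_brain(stages, specs, n_subjects=2, snr=2.0, seed=9)
        assert np.array_equal(b1.patterns[1], b2.patterns[1])

    def test_region_rdm_prefers_generative_stage(self, stages):
        """At snr 2 the region tracks its own stage, not distant ones."""
        rhos_own, rhos_far = [], []
        stage_rdms = [compute_rdm(s) for s in stages]
        for seed in range(6):
            brain = gen_synthetic_brain(
                stages, [RegionSpec("A", "visual_layer1")],
                n_subjects=4, snr=2.0, seed=seed,
            )
            vox = brain.region_voxels("A")
            for s in range(4):
                neural = compute_rdm_from_patterns(
                    brain.patterns[s][:, vox], items=stages[0].items
                )
                rhos_own.append(compare_rdms(neural, stage_rdms[0]))
                rhos_far.append(compare_rdms(neural, stage_rdms[2]))
        assert np.mean(rhos_own) > np.mean(rhos_far)

    def test_recovery_improves_with_snr(self, stages):
        """Mean region-stage RDM agreement is monotone over an snr grid."""
        stage_rdm = compute_rdm(stages[1])
        means = []
        for snr in (0.25, 1.0, 4.0):
            vals = []
            for seed in range(20):
                brain = gen_synthetic_brain(
                    stages, [RegionSpec("A", "visual_layer2")],
                    n_subjects=1, snr=snr, seed=seed,
                )
                vox = brain.region_voxels("A")
                neural = compute_rdm_from_patterns(
                    brain.patterns[0][:, vox], items=stages[0].items
                )
                vals.append(compare_rdms(neural, stage_rdm))
            means.append(np.mean(vals))
        assert means[0] < means[1] < means[2]
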