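"""Generate the synthetic inputs: feature norms, embeddings, visual stages.

Builds a category-structured binary concept x feature table, visual
embeddings coupled to the visual-type features, and a layered visual
trajectory running from a pixel-like representation to the embeddings.
"""

import numpy as np

from visemnet import (
    gen_feature_norms,
    gen_visual_embeddings,
    gen_visual_stage_trajectory,
    svd_reduce,
)
from visemnet.rsa import compare_rdms, compute_rdm, compute_rdm_from_patterns

norms = gen_feature_norms(n_concepts=60, n_categories=6, features_per_concept=14, seed=1)
N = norms.concept_count
print(f"norms: {len(norms.concept_ids)} concepts x {len(norms.feature_ids)} features")
print(f"  distinguishing (N<=2): {np.sum(N <= 2)}, shared (N>=3): {np.sum(N >= 3)}")
print(f"  feature types: { {t: norms.feature_type.count(t) for t in set(norms.feature_type)} }")

emb = gen_visual_embeddings(norms, n_dims=20, visual_coupling=0.8, noise_sd=0.5, seed=1)
inputs, var = svd_reduce(emb, 20)
print(f"embeddings: {emb.shape}, SVD retains {100 * var:.1f}% of variance")

stages = gen_visual_stage_trajectory(inputs, n_layers=7, seed=1, items=norms.concept_ids)
target = compute_rdm_from_patterns(inputs, items=norms.concept_ids)
rhos = [compare_rdms(compute_rdm(s), target) for s in stages]
print("visual trajectory: RDM agreement with the embedding geometry by layer:")
print("  " + "  ".join(f"L{i + 1}:{r:+.2f}" for i, r in enumerate(rhos)))
print("(deeper layers look progressively more like the high-level embedding space)")
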