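"""Feature-dynamics analysis: which features activate fastest?

Classifies semantic features by sharedness (distinctiveness = 1/N) and
type, then tracks mean activation of each group across the network's
time-ticks.  Highly shared and visual-type features should rise first;
distinguishing features rely on recurrent settling and rise later.
"""

import numpy as np

from visemnet import (
    activation_curves,
    classify_features,
    gen_feature_norms,
    gen_visual_embeddings,
    init_network,
    run_ticks,
    svd_reduce,
    top_feature_weights,
    train_bptt,
)

norms = gen_feature_norms(seed=1)
emb = gen_visual_embeddings(norms, seed=1)
inputs, _ = svd_reduce(emb, 20)
net = init_network(20, norms.matrix.shape[1], seed=1)
trained, *_ = train_bptt(net, inputs, norms.matrix)
traj = run_ticks(trained, inputs)

classes = classify_features(norms)
sh = activation_curves(traj, norms, classes, "sharedness3")
ty = activation_curves(traj, norms, classes, "feature_type")

print("mean activation at ticks 2, 4, 8, 20 (sharedness groups):")
for g in ("high_shared", "low_shared", "distinguishing", "non_target"):
    c = sh.curves[g]
    print(f"  {g:15s} {c[0]:.2f}  {c[2]:.2f}  {c[6]:.2f}  {c[-1]:.2f}")
print("mean activation at ticks 2, 4, 8, 20 (feature types):")
for g in ("visual", "nonvisual_perceptual", "functional", "encyclopaedic"):
    c = ty.curves[g]
    print(f"  {g:20s} {c[0]:.2f}  {c[2]:.2f}  {c[6]:.2f}  {c[-1]:.2f}")

top = top_feature_weights(trained, 5, feature_ids=norms.feature_ids)
print("strongest visual-to-semantic connection weights:")
for f, node, w in top:
    print(f"  {f} <- input node {node}: {w:+.2f}")
print("(shared, visual features take the strongest input from the visual layer)")
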