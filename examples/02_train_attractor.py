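"""Train the semantic attractor network on the synthetic norms.

The network maps 20 visual input units onto the semantic feature layer
through feed-forward and fully recurrent connections, unrolled over 20
time-ticks; training stops when 95% of target features reach activation
0.70 at the final tick.
"""

from visemnet import (
    gen_feature_norms,
    gen_visual_embeddings,
    init_network,
    run_ticks,
    svd_reduce,
    train_bptt,
)
from visemnet.attractor import criterion_fraction

norms = gen_feature_norms(seed=1)
emb = gen_visual_embeddings(norms, seed=1)
inputs, _ = svd_reduce(emb, 20)

net = init_network(input_dim=20, semantic_dim=norms.matrix.shape[1],
                   c=0.25, n_ticks=20, seed=1)
trained, epochs, hist = train_bptt(net, inputs, norms.matrix,
                                   lr=0.01, momentum=0.9, max_epochs=2000)

final = run_ticks(trained, inputs).at_tick(20)
frac = criterion_fraction(final, norms.matrix, level=0.70)
print(f"converged: {hist.converged} after {epochs} epochs")
print(f"target features at >= 0.70 on the final tick: {100 * frac:.1f}%")
print(f"loss: {hist.loss[0]:.1f} (epoch 1) -> {hist.loss[-1]:.1f} (epoch {epochs})")
print("(the network settles each concept's feature pattern from its visual input)")
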