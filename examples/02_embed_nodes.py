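"""Learn node features: biased walks, skip-gram, topology fusion.

Embeds a synthetic heterogeneous network with the default
hyperparameters (64 dimensions, 10 walks of length 50 per node,
window 10, p=0.5, q=2) and shows that nodes sharing a latent module
end up closer in embedding space than nodes from different modules.
"""

import numpy as np

from repowalk import (
    SyntheticConfig,
    WalkConfig,
    fuse_features,
    generate,
    generate_walks,
    topology_features,
    train_skipgram,
)

net, _, truth = generate(SyntheticConfig(seed=0))
cfg = WalkConfig(seed=0)
walks = generate_walks(net, cfg)
print(f"walk corpus: {len(walks)} walks, "
      f"{sum(len(w) for w in walks)} node visits")

emb = train_skipgram(walks, cfg)
topo = topology_features(net)
features = fuse_features(emb, topo)
print(f"fused feature matrix: {features.shape[0]} nodes x "
      f"{features.shape[1]} dims (64 embedding + 4 topology)")

# cosine similarity between ingredient and disease nodes
m = emb.to_numpy()
m = m / np.linalg.norm(m, axis=1, keepdims=True)
pos = {n: i for i, n in enumerate(emb.index)}
same, cross = [], []
for i in net.nodes_of_type("ingredient"):
    for d in net.nodes_of_type("disease"):
        sim = float(m[pos[i]] @ m[pos[d]])
        (same if truth.modules[i] == truth.modules[d] else cross).append(sim)
print(f"mean ingredient-disease cosine, same module:  {np.mean(same):.3f}")
print(f"mean ingredient-disease cosine, cross module: {np.mean(cross):.3f}")
print(
    "\nThe gap between the two means is the signal the link predictor "
    "feeds on: associated ingredient-disease pairs live in the same "
    "network neighbourhood, and the biased walks place them nearby in "
    "the embedding."
)
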