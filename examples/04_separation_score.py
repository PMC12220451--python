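"""Quantify compound-disease proximity on a PPI with S_AB.

Takes the target neighbourhood of an ingredient as gene set A and of
a disease as gene set B, and computes the network separation
S_AB = d_AB - (d_AA + d_BB)/2 on the protein-protein interaction
layer, for one associated (same-module) and one unrelated pair.
"""

import networkx as nx

from repowalk import GeneSet, SyntheticConfig, generate, overlap, separation_score

net, ppi, truth = generate(SyntheticConfig(seed=0))
g = nx.Graph((a, b) for a, b, _ in ppi)


def targets_of(node):
    return GeneSet.from_iterable(
        node, (n for n in net.graph[node]
               if net.node_type(n) == "target" and n in g),
    )


def first_pair(want_same):
    for i in net.nodes_of_type("ingredient"):
        for d in net.nodes_of_type("disease"):
            same = truth.modules[i] == truth.modules[d]
            planted = net.graph.has_edge(i, d)
            if want_same != (same and planted):
                continue
            a, b = targets_of(i), targets_of(d)
            if len(a.members) >= 3 and len(b.members) >= 3:
                return i, d, a, b
    raise SystemExit("no suitable pair in this draw")


for label, want in [("associated pair", True), ("unrelated pair", False)]:
    i, d, a, b = first_pair(want)
    res = separation_score(g, a, b)
    n_shared, _ = overlap(a, b)
    s = res.summary
    print(f"{label}: {i} vs {d}")
    print(f"  |A|={s.n_a_used} |B|={s.n_b_used} shared targets={n_shared}")
    print(f"  d_AA={s.d_aa:.3f} d_BB={s.d_bb:.3f} d_AB={s.d_ab:.3f}"
          f"  ->  S_AB = {res.s_ab:+.4f}")

print(
    "\nNegative S_AB: the two gene sets overlap topologically — the "
    "compound's targets sit inside the disease module, the network "
    "signature of a plausible therapeutic link. Positive S_AB: the "
    "modules occupy separate regions of the interactome."
)
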