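"""Node feature learning: biased second-order random walks, skip-gram
embeddings, and classical topology attributes.

The walk sampler implements the node2vec transition rule.  Having
arrived at node v through edge (t, v), the unnormalised probability of
stepping to a neighbour x of v is

    pi_vx = alpha_pq(t, x) * w_vx,

where alpha is 1/p when x = t (a return, d_tx = 0), 1 when x is also a
neighbour of t (d_tx = 1), and 1/q otherwise (d_tx = 2).  Low p keeps
the walk local; q > 1 biases it towards breadth-first exploration of
the start node's surroundings.  The first step of a walk has no
predecessor and is sampled uniformly over neighbours.

Walks run over the full heterogeneous graph: node types do not
constrain transitions, so an embedding reflects proximity across herb,
ingredient, target and disease layers alike.

Embeddings are trained with skip-gram negative sampling
(:mod:`repowalk.skipgram`) and then fused, by plain concatenation,
with four per-node topology attributes — degree, local clustering
coefficient, closeness centrality and PageRank — giving feature
vectors of length ``dimensions + 4`` (68 at the defaults).
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import networkx as nx
import numpy as np
import pandas as pd

from .hetnet import HeterogeneousNetwork, ValidationError

__all__ = [
    "WalkConfig",
    "step_distribution",
    "generate_walks",
    "train_skipgram",
    "topology_features",
    "fuse_features",
    "NoContextError",
    "MissingNodeError",
]

TOPOLOGY_COLUMNS = ("degree", "clustering", "closeness", "pagerank")


class NoContextError(ValueError):
    """Every walk has length 1, so skip-gram has no training pairs."""


class MissingNodeError(KeyError):
    """Embedding and topology inputs cover different node sets."""


@dataclass(frozen=True)
class WalkConfig:
    """Hyperparameters of the walk/embedding stage.

    Defaults are the published operating point for this model family:
    64-dimensional embeddings from 10 walks of length 50 per node with
    a window of 10, and return/in-out biases p = 0.5, q = 2 — i.e. the
    walk prefers to stay near its start, which suits densely clustered
    herb–disease neighbourhoods.  Skip-gram settings (epochs, negative
    samples, learning rate) are standard word2vec defaults.
    """

    dimensions: int = 64
    walk_length: int = 50
    num_walks: int = 10
    window: int = 10
    p: float = 0.5
    q: float = 2.0
    seed: int = 0
    epochs: int = 5
    negative: int = 5
    alpha: float = 0.025

    def __post_init__(self) -> None:
        if self.p <= 0 or self.q <= 0:
            raise ValidationError(f"p and q must be positive, got p={self.p}, q={self.q}")
        for name in ("dimensions", "walk_length", "num_walks", "window", "epochs"):
            if getattr(self, name) < 1:
                raise ValidationError(f"{name} must be a positive integer")

    def with_seed(self, seed: int) -> "WalkConfig":
        return replace(self, seed=seed)


def _as_graph(net: HeterogeneousNetwork | nx.Graph) -> nx.Graph:
    return net.graph if isinstance(net, HeterogeneousNetwork) else net


def step_distribution(
    net: HeterogeneousNetwork | nx.Graph,
    prev: str | None,
    curr: str,
    p: float,
    q: float,
) -> dict[str, float]:
    """Normalised next-step probabilities over the neighbours of ``curr``.

    With ``prev`` absent (first step) the distribution is proportional
    to edge weights alone.  An isolated ``curr`` yields an empty map.
    """
    if p <= 0 or q <= 0:
        raise ValidationError(f"p and q must be positive, got p={p}, q={q}")
    g = _as_graph(net)
    nbrs = sorted(g[curr])
    if not nbrs:
        return {}
    prev_nbrs = set(g[prev]) if prev is not None else set()
    weights = []
    for x in nbrs:
        w = g.edges[curr, x].get("weight", 1.0)
        if prev is None:
            alpha = 1.0
        elif x == prev:
            alpha = 1.0 / p
        elif x in prev_nbrs:
            alpha = 1.0
        else:
            alpha = 1.0 / q
        weights.append(alpha * w)
    z = sum(weights)
    return {x: w / z for x, w in zip(nbrs, weights)}


def generate_walks(
    net: HeterogeneousNetwork | nx.Graph, config: WalkConfig
) -> list[list[str]]:
    """Sample ``num_walks`` biased walks from every node.

    Node order is shuffled each pass; a walk ends early at a node with
    no neighbours.  Bit-for-bit reproducible under a fixed seed.
    """
    g = _as_graph(net)
    if g.number_of_nodes() == 0:
        raise ValidationError("network is empty")
    rng = np.random.default_rng(config.seed)
    nodes = sorted(g.nodes)
    nbrs = {u: sorted(g[u]) for u in nodes}
    nbr_sets = {u: set(ns) for u, ns in nbrs.items()}
    base_w = {
        u: np.array([g.edges[u, x].get("weight", 1.0) for x in ns], dtype=float)
        for u, ns in nbrs.items()
    }
    inv_p, inv_q = 1.0 / config.p, 1.0 / config.q

    # transition tables are memoised per directed edge (prev, curr):
    # on realistic graphs each state recurs many times per corpus
    cdf_cache: dict[tuple[str, str], np.ndarray] = {}

    def state_cdf(prev: str, curr: str) -> np.ndarray:
        key = (prev, curr)
        cached = cdf_cache.get(key)
        if cached is not None:
            return cached
        xs = nbrs[curr]
        w = base_w[curr].copy()
        pset = nbr_sets[prev]
        for i, x in enumerate(xs):
            if x == prev:
                w[i] *= inv_p
            elif x not in pset:
                w[i] *= inv_q
        cdf = np.cumsum(w)
        cdf /= cdf[-1]
        cdf_cache[key] = cdf
        return cdf

    walks: list[list[str]] = []
    for _ in range(config.num_walks):
        for idx in rng.permutation(len(nodes)):
            start = nodes[idx]
            walk = [start]
            ns = nbrs[start]
            if ns:
                # no predecessor yet: uniform over neighbours
                walk.append(ns[int(rng.integers(len(ns)))])
            while len(walk) < config.walk_length:
                curr = walk[-1]
                if not nbrs[curr]:
                    break
                cdf = state_cdf(walk[-2], curr)
                walk.append(nbrs[curr][int(np.searchsorted(cdf, rng.random(), side="right"))])
            walks.append(walk)
    return walks


def train_skipgram(walks: list[list[str]], config: WalkConfig) -> pd.DataFrame:
    """Train skip-gram on the walk corpus.

    Returns a DataFrame with one ``dimensions``-length row per node
    that occurs in at least one walk, indexed by node id (sorted).
    Deterministic under a fixed seed (training is single-threaded).
    """
    vocab = sorted({n for walk in walks for n in walk})
    if not vocab:
        raise NoContextError("no walks supplied")
    if all(len(w) < 2 for w in walks):
        raise NoContextError("all walks have length 1; no skip-gram contexts exist")
    index = {n: i for i, n in enumerate(vocab)}
    corpus = [np.array([index[n] for n in walk], dtype=np.int64) for walk in walks]
    from .skipgram import train_sgns

    mat = train_sgns(
        corpus,
        vocab_size=len(vocab),
        dimensions=config.dimensions,
        window=config.window,
        epochs=config.epochs,
        negative=config.negative,
        alpha=config.alpha,
        seed=config.seed,
    )
    return pd.DataFrame(
        mat, index=pd.Index(vocab, name="node"),
        columns=[f"e{i}" for i in range(config.dimensions)],
    )


def topology_features(net: HeterogeneousNetwork | nx.Graph) -> pd.DataFrame:
    """Degree, clustering coefficient, closeness centrality and
    PageRank for every node, indexed by sorted node id.

    Closeness uses the Wasserman–Faust correction on disconnected
    graphs (each node's value is computed over its reachable set and
    scaled by its relative size), so isolated nodes get 0.  PageRank
    uses damping 0.85.
    """
    g = _as_graph(net)
    if g.number_of_nodes() == 0:
        raise ValidationError("network is empty")
    degree = dict(g.degree())
    clustering = nx.clustering(g)
    closeness = nx.closeness_centrality(g, wf_improved=True)
    pagerank = nx.pagerank(g, alpha=0.85, tol=1e-12, max_iter=1000)
    nodes = sorted(g.nodes)
    return pd.DataFrame(
        {
            "degree": [float(degree[n]) for n in nodes],
            "clustering": [clustering[n] for n in nodes],
            "closeness": [closeness[n] for n in nodes],
            "pagerank": [pagerank[n] for n in nodes],
        },
        index=pd.Index(nodes, name="node"),
    )


def fuse_features(
    emb: pd.DataFrame, topo: pd.DataFrame, scale_topology: bool = False
) -> pd.DataFrame:
    """Concatenate embedding rows with the four topology attributes.

    Both inputs must cover the same node set; rows come out sorted by
    node id, each of length ``dimensions + 4``.  ``scale_topology``
    min-max scales the four attributes to [0, 1] (off by default: the
    downstream tree ensemble is scale-invariant).
    """
    emb_ids, topo_ids = set(emb.index), set(topo.index)
    if emb_ids != topo_ids:
        only_emb = sorted(emb_ids - topo_ids)
        only_topo = sorted(topo_ids - emb_ids)
        raise MissingNodeError(
            f"node universes differ: embedding-only {only_emb[:10]}, "
            f"topology-only {only_topo[:10]}"
        )
    topo = topo[list(TOPOLOGY_COLUMNS)]
    if scale_topology:
        span = topo.max() - topo.min()
        span = span.replace(0.0, 1.0)
        topo = (topo - topo.min()) / span
    fused = pd.concat([emb, topo], axis=1).sort_index()
    if not np.isfinite(fused.to_numpy()).all():
        raise ValidationError("fused feature matrix contains non-finite entries")
    return fused
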