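"""Network proximity between gene sets on a PPI graph.

The separation score of a compound target set A and a disease gene
set B on a protein–protein interaction network is

    S_AB = <d_AB> - (<d_AA> + <d_BB>) / 2,

where <d_AA> (resp. <d_BB>) is the mean, over members of A (resp. B),
of the shortest-path distance to the closest *other* member of the
same set, and <d_AB> is the mean, over members of both sets, of the
shortest-path distance to the closest member of the opposite set
(shared members contribute distance 0).  Negative S_AB means the two
modules overlap topologically — the compound's targets sit inside the
disease neighbourhood; positive S_AB means they occupy separate
regions of the interactome.

Genes absent from the PPI, or with no finite distance to the relevant
set, are dropped from the means and reported rather than poisoning
them with infinities.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx

from .hetnet import HeterogeneousNetwork

__all__ = [
    "GeneSet",
    "DistanceSummary",
    "SabResult",
    "read_gene_set",
    "set_distances",
    "cross_set_distance",
    "sab_score",
    "separation_score",
    "overlap",
    "EmptySetError",
    "UndefinedDistanceError",
]


class EmptySetError(ValueError):
    """A gene set has no members on the PPI network."""


class UndefinedDistanceError(ValueError):
    """Within-set distance requested for a set of size 1."""


@dataclass(frozen=True)
class GeneSet:
    """A named, deduplicated set of gene/protein identifiers."""

    name: str
    members: frozenset[str]

    @classmethod
    def from_iterable(cls, name: str, members) -> "GeneSet":
        return cls(name=name, members=frozenset(members))


@dataclass
class DistanceSummary:
    """Mean shortest-path distances within and between two gene sets,
    plus the genes excluded from each mean (absent or unreachable)."""

    d_aa: float
    d_bb: float
    d_ab: float
    n_a_used: int
    n_b_used: int
    dropped: list[str] = field(default_factory=list)


@dataclass(frozen=True)
class SabResult:
    s_ab: float
    summary: DistanceSummary


def read_gene_set(
    path: str | Path, name: str | None = None, uppercase: bool = False
) -> GeneSet:
    """Plain-text gene set: one identifier per line, ``#`` comments and
    blank lines ignored; matching is by exact string (optionally
    upper-cased)."""
    members = set()
    with open(path) as fh:
        for line in fh:
            token = line.split("#", 1)[0].strip()
            if token:
                members.add(token.upper() if uppercase else token)
    return GeneSet(name=name or Path(path).stem, members=frozenset(members))


def _as_graph(ppi: HeterogeneousNetwork | nx.Graph) -> nx.Graph:
    return ppi.graph if isinstance(ppi, HeterogeneousNetwork) else ppi


def _min_distances(g: nx.Graph, sources: set[str], targets: set[str],
                   exclude_self: bool) -> tuple[dict[str, int], list[str]]:
    """For each source, the BFS distance to the nearest target
    (excluding the source itself when ``exclude_self``)."""
    out: dict[str, int] = {}
    dropped: list[str] = []
    for s in sorted(sources):
        goal = targets - {s} if exclude_self else targets
        if not exclude_self and s in targets:
            out[s] = 0
            continue
        dist = nx.single_source_shortest_path_length(g, s)
        best = min((dist[t] for t in goal if t in dist), default=None)
        if best is None:
            dropped.append(s)
        else:
            out[s] = best
    return out, dropped


def cross_set_distance(
    ppi: HeterogeneousNetwork | nx.Graph, a: GeneSet, b: GeneSet
) -> float:
    """Mean cross-set distance d_AB alone.

    Averages, over the members of A and of B present on the PPI, each
    node's shortest-path distance to the closest member of the other
    set (0 for shared members).  Unlike the within-set means this is
    well defined for singleton sets.
    """
    g = _as_graph(ppi)
    nodes = set(g.nodes)
    a_in = a.members & nodes
    b_in = b.members & nodes
    if not a_in:
        raise EmptySetError(f"gene set {a.name!r} has no members on the PPI")
    if not b_in:
        raise EmptySetError(f"gene set {b.name!r} has no members on the PPI")
    dab_a, _ = _min_distances(g, a_in, b_in, exclude_self=False)
    dab_b, _ = _min_distances(g, b_in, a_in, exclude_self=False)
    cross = list(dab_a.values()) + list(dab_b.values())
    if not cross:
        raise UndefinedDistanceError("no finite cross-set distances")
    return sum(cross) / len(cross)


def set_distances(
    ppi: HeterogeneousNetwork | nx.Graph, a: GeneSet, b: GeneSet
) -> DistanceSummary:
    """Mean within-set (d_AA, d_BB) and cross-set (d_AB) distances.

    d_AB averages, over the members of A and of B present on the PPI,
    each node's distance to the closest member of the other set (0 for
    shared members).  d_AA / d_BB average each member's distance to
    the closest *different* member of its own set, hence are >= 1 for
    disjointly-placed members.  Unreachable nodes are dropped and
    listed in the summary.
    """
    g = _as_graph(ppi)
    nodes = set(g.nodes)
    a_in = a.members & nodes
    b_in = b.members & nodes
    dropped_absent = sorted((a.members | b.members) - nodes)
    if not a_in:
        raise EmptySetError(f"gene set {a.name!r} has no members on the PPI")
    if not b_in:
        raise EmptySetError(f"gene set {b.name!r} has no members on the PPI")
    if len(a_in) < 2:
        raise UndefinedDistanceError(
            f"gene set {a.name!r} has {len(a_in)} PPI member; d_AA undefined"
        )
    if len(b_in) < 2:
        raise UndefinedDistanceError(
            f"gene set {b.name!r} has {len(b_in)} PPI member; d_BB undefined"
        )

    daa, drop_aa = _min_distances(g, a_in, a_in, exclude_self=True)
    dbb, drop_bb = _min_distances(g, b_in, b_in, exclude_self=True)
    dab_a, drop_ab_a = _min_distances(g, a_in, b_in, exclude_self=False)
    dab_b, drop_ab_b = _min_distances(g, b_in, a_in, exclude_self=False)

    if not daa or not dbb or not (dab_a or dab_b):
        raise UndefinedDistanceError("no finite distances available for a mean")

    cross = list(dab_a.values()) + list(dab_b.values())
    dropped = sorted(set(dropped_absent + drop_aa + drop_bb + drop_ab_a + drop_ab_b))
    return DistanceSummary(
        d_aa=sum(daa.values()) / len(daa),
        d_bb=sum(dbb.values()) / len(dbb),
        d_ab=sum(cross) / len(cross),
        n_a_used=len(a_in),
        n_b_used=len(b_in),
        dropped=dropped,
    )


def sab_score(summary: DistanceSummary) -> SabResult:
    """S_AB = d_AB - (d_AA + d_BB) / 2 from a distance summary."""
    s = summary.d_ab - (summary.d_aa + summary.d_bb) / 2.0
    return SabResult(s_ab=s, summary=summary)


def separation_score(
    ppi: HeterogeneousNetwork | nx.Graph, a: GeneSet, b: GeneSet
) -> SabResult:
    """Convenience wrapper: distances then S_AB in one call."""
    return sab_score(set_distances(ppi, a, b))


def overlap(a: GeneSet, b: GeneSet) -> tuple[int, list[str]]:
    """Exact intersection of two gene sets: size and sorted members."""
    shared = sorted(a.members & b.members)
    return len(shared), shared
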