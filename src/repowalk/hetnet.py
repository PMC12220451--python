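"""Typed heterogeneous network assembly.

The networks handled here have four semantic node classes — herbs,
ingredients, targets (genes/proteins) and diseases — joined by typed
relations such as ingredient–disease or herb–target, plus a
protein–protein interaction (PPI) layer read from STRING-style edge
lists with integer confidence scores on a 0–1000 scale.

The graph is undirected and simple: duplicate edges (in either
orientation) are collapsed keeping the first relation tag and the
maximum weight, and self-loops are dropped with a warning since they
are meaningless for random walks and shortest-path distances.  A node
id carries exactly one node type; the same string appearing with two
types is a hard error, because downstream feature matrices are indexed
by id alone.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import networkx as nx
import pandas as pd

__all__ = [
    "NODE_TYPES",
    "RELATIONS",
    "TypedEdge",
    "HeterogeneousNetwork",
    "ParseError",
    "ValidationError",
    "TypeConflictError",
    "read_string_links",
    "read_edge_table",
    "assemble_network",
    "summarize_network",
    "remove_edges",
]

NODE_TYPES = ("herb", "ingredient", "target", "disease")

#: relation name -> (source node type, target node type)
RELATIONS = {
    "ingredient-disease": ("ingredient", "disease"),
    "herb-ingredient": ("herb", "ingredient"),
    "herb-target": ("herb", "target"),
    "disease-herb": ("disease", "herb"),
    "ingredient-target": ("ingredient", "target"),
    "disease-target": ("disease", "target"),
    "target-target": ("target", "target"),
}


class ParseError(ValueError):
    """A malformed row in an input file."""


class ValidationError(ValueError):
    """A value outside its admissible range."""


class TypeConflictError(ValueError):
    """The same node id was assigned two different node types."""


@dataclass(frozen=True)
class TypedEdge:
    """An undirected edge with a relation tag; endpoint node types are
    implied by the relation (source gets the first type, target the
    second)."""

    source: str
    target: str
    relation: str
    weight: float = 1.0

    def __post_init__(self) -> None:
        if not self.source or not self.target:
            raise ValidationError("edge endpoints must be non-empty ids")
        if self.relation not in RELATIONS:
            raise ValidationError(
                f"unknown relation {self.relation!r}; expected one of {sorted(RELATIONS)}"
            )
        if not self.weight > 0:
            raise ValidationError(f"edge weight must be positive, got {self.weight}")

    @property
    def endpoint_types(self) -> tuple[str, str]:
        return RELATIONS[self.relation]


class HeterogeneousNetwork:
    """Undirected simple graph with typed nodes and relation-tagged edges.

    Thin wrapper over :class:`networkx.Graph`; node type lives in the
    ``node_type`` node attribute, relation and weight in edge attributes.
    """

    def __init__(self) -> None:
        self.graph = nx.Graph()

    # -- construction -------------------------------------------------

    def add_node(self, node_id: str, node_type: str) -> None:
        if node_type not in NODE_TYPES:
            raise ValidationError(f"unknown node type {node_type!r}")
        existing = self.graph.nodes.get(node_id, {}).get("node_type")
        if existing is not None and existing != node_type:
            raise TypeConflictError(
                f"node {node_id!r} already registered as {existing!r}, "
                f"cannot also be {node_type!r}"
            )
        self.graph.add_node(node_id, node_type=node_type)

    def add_edge(self, edge: TypedEdge) -> None:
        if edge.source == edge.target:
            warnings.warn(
                f"dropping self-loop on {edge.source!r} ({edge.relation})",
                stacklevel=2,
            )
            return
        s_type, t_type = edge.endpoint_types
        self.add_node(edge.source, s_type)
        self.add_node(edge.target, t_type)
        if self.graph.has_edge(edge.source, edge.target):
            # simple graph: keep first relation tag, max weight
            data = self.graph.edges[edge.source, edge.target]
            data["weight"] = max(data["weight"], edge.weight)
        else:
            self.graph.add_edge(
                edge.source, edge.target, relation=edge.relation, weight=edge.weight
            )

    # -- queries ------------------------------------------------------

    @property
    def n_nodes(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    def node_type(self, node_id: str) -> str:
        return self.graph.nodes[node_id]["node_type"]

    def nodes_of_type(self, node_type: str) -> list[str]:
        return sorted(
            n for n, d in self.graph.nodes(data=True) if d["node_type"] == node_type
        )

    def edges_of_relation(self, relation: str) -> list[tuple[str, str]]:
        """Edges tagged with ``relation``, oriented source-type first."""
        s_type, t_type = RELATIONS[relation]
        out = []
        for u, v, d in self.graph.edges(data=True):
            if d["relation"] != relation:
                continue
            if self.node_type(u) == s_type:
                out.append((u, v))
            else:
                out.append((v, u))
        return sorted(out)

    def has_pair(self, ingredient: str, disease: str) -> bool:
        return self.graph.has_edge(ingredient, disease)

    def copy(self) -> "HeterogeneousNetwork":
        new = HeterogeneousNetwork()
        new.graph = self.graph.copy()
        return new

    # -- I/O ----------------------------------------------------------

    def write_edge_tables(self, out_dir: str | Path) -> dict[str, Path]:
        """One TSV per relation present (PPI relation included), two
        id columns plus a weight column when any weight differs from 1."""
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        written: dict[str, Path] = {}
        for relation in sorted(RELATIONS):
            rows = self.edges_of_relation(relation)
            if not rows:
                continue
            path = out_dir / f"{relation}.tsv"
            with open(path, "w") as fh:
                for u, v in rows:
                    w = self.graph.edges[u, v]["weight"]
                    if w == 1.0:
                        fh.write(f"{u}\t{v}\n")
                    else:
                        fh.write(f"{u}\t{v}\t{w!r}\n")
            written[relation] = path
        return written


def read_string_links(path: str | Path, min_score: int = 700) -> list[TypedEdge]:
    """Read a STRING-style protein links file and keep confident pairs.

    The file has whitespace-delimited rows ``protein1 protein2
    combined_score`` with an optional header (auto-detected by a
    non-integer third field on the first line).  A record is retained
    when ``combined_score >= min_score`` — the threshold is inclusive.
    Duplicate and reversed-duplicate pairs are collapsed; retained
    records become target–target edges with unit weight.
    """
    if not 0 <= min_score <= 1000:
        raise ValidationError(f"min_score must lie in [0, 1000], got {min_score}")
    kept: dict[tuple[str, str], TypedEdge] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            parts = line.split()
            if not parts:
                continue
            if len(parts) != 3:
                raise ParseError(
                    f"{path}, line {lineno}: expected 3 columns, found {len(parts)}"
                )
            if lineno == 1:
                try:
                    int(parts[2])
                except ValueError:
                    continue  # header line
            try:
                score = int(parts[2])
            except ValueError as exc:
                raise ParseError(
                    f"{path}, line {lineno}: combined_score {parts[2]!r} is not an integer"
                ) from exc
            if not 0 <= score <= 1000:
                raise ValidationError(
                    f"{path}, line {lineno}: combined_score {score} outside [0, 1000]"
                )
            if score < min_score:
                continue
            a, b = parts[0], parts[1]
            if a == b:
                warnings.warn(f"{path}, line {lineno}: dropping self-interaction {a!r}")
                continue
            key = (a, b) if a <= b else (b, a)
            if key not in kept:
                kept[key] = TypedEdge(key[0], key[1], "target-target", 1.0)
    return [kept[k] for k in sorted(kept)]


def read_edge_table(path: str | Path, relation: str) -> list[TypedEdge]:
    """Read a two-column (optionally three with weight) TSV of id pairs.

    Blank lines are skipped; endpoint node types are implied by the
    relation.
    """
    if relation not in RELATIONS:
        raise ValidationError(f"unknown relation {relation!r}")
    edges: list[TypedEdge] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            parts = line.split("\t")
            if len(parts) < 2 or not parts[0].strip() or not parts[1].strip():
                raise ParseError(
                    f"{path}, line {lineno}: expected 2 tab-separated columns"
                )
            weight = 1.0
            if len(parts) >= 3 and parts[2].strip():
                try:
                    weight = float(parts[2])
                except ValueError as exc:
                    raise ParseError(
                        f"{path}, line {lineno}: weight {parts[2]!r} is not numeric"
                    ) from exc
            edges.append(TypedEdge(parts[0].strip(), parts[1].strip(), relation, weight))
    return edges


def assemble_network(edge_lists: list[list[TypedEdge]]) -> HeterogeneousNetwork:
    """Union the edge lists into one network, collapsing duplicates.

    Raises :class:`TypeConflictError` if the union assigns two node
    types to one id.
    """
    net = HeterogeneousNetwork()
    for edges in edge_lists:
        for edge in edges:
            net.add_edge(edge)
    return net


def summarize_network(net: HeterogeneousNetwork) -> pd.DataFrame:
    """Per-relation counts: distinct source-type nodes, distinct
    target-type nodes, and edges — one row per relation present."""
    rows = []
    for relation in sorted(RELATIONS):
        pairs = net.edges_of_relation(relation)
        if not pairs:
            continue
        s_type, t_type = RELATIONS[relation]
        if s_type == t_type:
            involved = {n for pair in pairs for n in pair}
            n1 = n2 = len(involved)
        else:
            n1 = len({u for u, _ in pairs})
            n2 = len({v for _, v in pairs})
        rows.append(
            {"relation": relation, "node1": s_type, "node2": t_type,
             "n_node1": n1, "n_node2": n2, "n_edges": len(pairs)}
        )
    return pd.DataFrame(
        rows, columns=["relation", "node1", "node2", "n_node1", "n_node2", "n_edges"]
    )


def remove_edges(
    net: HeterogeneousNetwork, pairs: set[tuple[str, str]] | list[tuple[str, str]]
) -> HeterogeneousNetwork:
    """Return a copy of ``net`` lacking the given ingredient–disease
    edges; all nodes are retained.  Absent pairs are skipped with a
    warning."""
    new = net.copy()
    for ing, dis in pairs:
        if new.graph.has_edge(ing, dis):
            new.graph.remove_edge(ing, dis)
        else:
            warnings.warn(f"pair ({ing!r}, {dis!r}) not present; skipped")
    return new
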