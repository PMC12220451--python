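"""Synthetic heterogeneous networks with planted associations.

The generator emulates a herb/ingredient/target/disease network plus a
STRING-like PPI layer at desk scale, with a known ground truth so every
pipeline stage can be validated end to end.  It is a latent-module
(stochastic block) model: every node is assigned to one of
``k_modules`` uniformly, pairs inside a module connect with probability
``p_in`` and pairs across modules with ``p_out``.  That choice mirrors
the repositioning premise itself — ingredients and diseases that share
a neighbourhood of targets are the ones that should be linked — so the
planted ingredient–disease edges (same-module pairs, rate ``p_in``)
are recoverable exactly to the extent the walk embeddings capture
module structure.

PPI confidence scores are drawn from a high range for within-module
pairs and a low range for cross-module pairs, so the standard
confidence filter separates signal from noise by construction.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .hetnet import (
    HeterogeneousNetwork,
    TypedEdge,
    ValidationError,
    assemble_network,
)

__all__ = ["SyntheticConfig", "GroundTruth", "GenerationError", "generate", "write_fixture"]

#: relations generated from module structure (besides ingredient-disease and PPI)
_BACKGROUND_RELATIONS = (
    ("herb-ingredient", "herb", "ingredient"),
    ("herb-target", "herb", "target"),
    ("disease-herb", "disease", "herb"),
    ("ingredient-target", "ingredient", "target"),
    ("disease-target", "disease", "target"),
)


class GenerationError(ValueError):
    """A parameter combination produced an empty relation."""


@dataclass(frozen=True)
class SyntheticConfig:
    """Desk-scale defaults: 10 herbs / 40 ingredients / 120 targets /
    30 diseases in 4 modules, p_in = 0.4, p_out = 0.01 — large enough
    for stable link-prediction performance, small enough for
    seconds-scale tests.  PPI score ranges default to [800, 1000]
    within modules and [0, 400] across, so a 700 filter keeps exactly
    the within-module interactions."""

    n_herbs: int = 10
    n_ingredients: int = 40
    n_targets: int = 120
    n_diseases: int = 30
    k_modules: int = 4
    p_in: float = 0.4
    p_out: float = 0.01
    ppi_in_score_range: tuple[int, int] = (800, 1000)
    ppi_out_score_range: tuple[int, int] = (0, 400)
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_herbs", "n_ingredients", "n_targets", "n_diseases", "k_modules"):
            if getattr(self, name) < 1:
                raise ValidationError(f"{name} must be a positive integer")
        if not 0 < self.p_in <= 1:
            raise ValidationError(f"p_in must be in (0, 1], got {self.p_in}")
        if not 0 <= self.p_out < 1:
            raise ValidationError(f"p_out must be in [0, 1), got {self.p_out}")
        if not self.p_in > self.p_out:
            raise ValidationError("p_in must exceed p_out")
        for rng_name in ("ppi_in_score_range", "ppi_out_score_range"):
            lo, hi = getattr(self, rng_name)
            if not (0 <= lo <= hi <= 1000):
                raise ValidationError(f"{rng_name} must be within [0, 1000], got {(lo, hi)}")


@dataclass
class GroundTruth:
    """What the generator planted: the module of every node, the
    ingredient–disease positives, and (when a holdout fraction is
    used) the positives withheld from the emitted edges."""

    modules: dict[str, int]
    planted_pairs: list[tuple[str, str]]
    holdout_pairs: list[tuple[str, str]] = field(default_factory=list)


def _node_ids(prefix: str, n: int) -> list[str]:
    return [f"{prefix}{i:04d}" for i in range(n)]


def generate(
    config: SyntheticConfig, holdout: float = 0.0
) -> tuple[HeterogeneousNetwork, list[tuple[str, str, int]], GroundTruth]:
    """Generate (network, PPI records, ground truth).

    The network holds the six typed relations; the PPI layer is
    returned as raw ``(protein1, protein2, combined_score)`` records so
    it flows through the same confidence filter as real STRING data.
    With ``holdout`` > 0, that fraction of planted ingredient–disease
    pairs is withheld from the network (listed in
    ``GroundTruth.holdout_pairs``) to support leakage-free evaluation.
    Fully reproducible under the config seed.
    """
    if not 0 <= holdout < 1:
        raise ValidationError(f"holdout must be in [0, 1), got {holdout}")
    rng = np.random.default_rng(config.seed)
    ids = {
        "herb": _node_ids("H", config.n_herbs),
        "ingredient": _node_ids("I", config.n_ingredients),
        "target": _node_ids("T", config.n_targets),
        "disease": _node_ids("D", config.n_diseases),
    }
    modules = {
        node: int(m)
        for ntype in ("herb", "ingredient", "target", "disease")
        for node, m in zip(ids[ntype], rng.integers(0, config.k_modules, len(ids[ntype])))
    }

    def draw_pairs(left: list[str], right: list[str], same_type: bool):
        pairs = []
        for i, u in enumerate(left):
            vs = right[i + 1 :] if same_type else right
            for v in vs:
                p = config.p_in if modules[u] == modules[v] else config.p_out
                if rng.random() < p:
                    pairs.append((u, v))
        return pairs

    edge_lists = []
    for relation, lt, rt in _BACKGROUND_RELATIONS:
        pairs = draw_pairs(ids[lt], ids[rt], same_type=False)
        if not pairs:
            raise GenerationError(f"relation {relation!r} came out empty; "
                                  "raise p_in or the node counts")
        edge_lists.append([TypedEdge(u, v, relation) for u, v in pairs])

    # planted positives: same-module ingredient-disease pairs at rate p_in
    planted = [
        (i, d)
        for i in ids["ingredient"]
        for d in ids["disease"]
        if modules[i] == modules[d] and rng.random() < config.p_in
    ]
    if not planted:
        raise GenerationError("relation 'ingredient-disease' came out empty; "
                              "raise p_in or the node counts")
    n_hold = int(round(holdout * len(planted)))
    hold_idx = set(rng.choice(len(planted), size=n_hold, replace=False)) if n_hold else set()
    emitted = [p for k, p in enumerate(planted) if k not in hold_idx]
    withheld = [p for k, p in enumerate(planted) if k in hold_idx]
    if not emitted:
        raise GenerationError("holdout withheld every ingredient-disease edge")
    edge_lists.append([TypedEdge(i, d, "ingredient-disease") for i, d in emitted])

    lo_in, hi_in = config.ppi_in_score_range
    lo_out, hi_out = config.ppi_out_score_range
    ppi: list[tuple[str, str, int]] = []
    targets = ids["target"]
    for i, u in enumerate(targets):
        for v in targets[i + 1 :]:
            if modules[u] == modules[v]:
                if rng.random() < config.p_in:
                    ppi.append((u, v, int(rng.integers(lo_in, hi_in + 1))))
            elif rng.random() < config.p_out:
                ppi.append((u, v, int(rng.integers(lo_out, hi_out + 1))))
    if not ppi:
        raise GenerationError("relation 'target-target' came out empty; "
                              "raise p_in or n_targets")

    net = assemble_network(edge_lists)
    # every configured node exists even if it drew no edges
    for ntype, nodes in ids.items():
        for node in nodes:
            net.add_node(node, ntype)
    truth = GroundTruth(modules=modules, planted_pairs=sorted(planted),
                        holdout_pairs=sorted(withheld))
    return net, ppi, truth


def write_fixture(
    net: HeterogeneousNetwork,
    ppi: list[tuple[str, str, int]],
    truth: GroundTruth,
    out_dir: str | Path,
) -> dict[str, Path]:
    """Serialise a generated dataset: one TSV per typed relation, a
    STRING-format PPI file, a ground-truth JSON and, when holdout
    pairs exist, a TSV listing them.  Re-reading the files through
    :mod:`repowalk.hetnet` reproduces the network exactly; output is
    byte-identical across runs with the same seed."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written = net.write_edge_tables(out_dir)
    # node roster keeps isolated nodes alive across a round-trip
    nodes_path = out_dir / "nodes.tsv"
    with open(nodes_path, "w") as fh:
        for node in sorted(net.graph.nodes):
            fh.write(f"{node}\t{net.node_type(node)}\n")
    written["nodes"] = nodes_path
    ppi_path = out_dir / "ppi_links.txt"
    with open(ppi_path, "w") as fh:
        fh.write("protein1 protein2 combined_score\n")
        for u, v, s in sorted(ppi):
            fh.write(f"{u} {v} {s}\n")
    written["ppi"] = ppi_path
    truth_path = out_dir / "ground_truth.json"
    with open(truth_path, "w") as fh:
        json.dump(
            {
                "modules": {k: truth.modules[k] for k in sorted(truth.modules)},
                "planted_pairs": [list(p) for p in sorted(truth.planted_pairs)],
                "holdout_pairs": [list(p) for p in sorted(truth.holdout_pairs)],
            },
            fh,
            indent=1,
            sort_keys=True,
        )
        fh.write("\n")
    written["ground_truth"] = truth_path
    if truth.holdout_pairs:
        hold_path = out_dir / "holdout_pairs.tsv"
        with open(hold_path, "w") as fh:
            for i, d in sorted(truth.holdout_pairs):
                fh.write(f"{i}\t{d}\n")
        written["holdout"] = hold_path
    return written
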