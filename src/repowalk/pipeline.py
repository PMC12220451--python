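"""End-to-end orchestration: build network → embed → predict → rank
(→ separation score), from a single config, with deterministic
artifact serialization.

Seeding: one global seed fans out to per-stage seeds by a fixed
derivation (``stage_seed = seed + stage index``; negatives=1, split=2,
walks/skip-gram=3, classifier=4), so any stage can be re-run in
isolation with a known seed.

Leakage control: by default the embedding is trained on the network
with the test-split positives removed, so no test edge can inform the
features it is judged on.  ``full_graph_embedding=True`` instead
embeds the complete network once — the convention of pipelines that
treat embedding as unsupervised preprocessing — and is logged
prominently because it changes results.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import hetnet, reposition
from .embedding import WalkConfig, fuse_features, generate_walks, topology_features, train_skipgram
from .hetnet import HeterogeneousNetwork, ValidationError
from .proximity import read_gene_set, separation_score
from .reposition import MetricsReport

__all__ = ["RunConfig", "RunResult", "run", "load_network"]

#: standard fixture filenames, as written by synthetic.write_fixture
RELATION_FILES = {
    rel: f"{rel}.tsv"
    for rel in (
        "ingredient-disease",
        "herb-ingredient",
        "herb-target",
        "disease-herb",
        "ingredient-target",
        "disease-target",
    )
}
PPI_FILE = "ppi_links.txt"


@dataclass(frozen=True)
class RunConfig:
    """Everything a run needs.  ``data_dir`` holds one TSV per typed
    relation (standard names) plus a STRING-format PPI file filtered
    at ``min_score``.  ``holdout_pairs_path`` switches evaluation from
    an internal 8:2 split to an externally supplied positive test set
    (e.g. pairs a generator withheld)."""

    data_dir: str
    out_dir: str
    seed: int = 0
    walk: WalkConfig = field(default_factory=WalkConfig)
    train_fraction: float = 0.8
    negative_ratio: float | str = 10
    threshold: float = 0.5
    min_score: int = 700
    full_graph_embedding: bool = False
    holdout_pairs_path: str | None = None
    rank_ingredient: str | None = None
    gene_set_a: str | None = None
    gene_set_b: str | None = None


@dataclass
class RunResult:
    metrics: MetricsReport
    predictions: pd.DataFrame
    ranking: pd.DataFrame
    out_dir: Path
    sab: dict | None = None


def load_network(data_dir: str | Path, min_score: int = 700) -> HeterogeneousNetwork:
    """Assemble the heterogeneous network from a fixture directory:
    the typed relation TSVs present plus the confidence-filtered PPI."""
    data_dir = Path(data_dir)
    edge_lists = []
    for relation, fname in RELATION_FILES.items():
        path = data_dir / fname
        if path.exists():
            edge_lists.append(hetnet.read_edge_table(path, relation))
    ppi_path = data_dir / PPI_FILE
    if ppi_path.exists():
        edge_lists.append(hetnet.read_string_links(ppi_path, min_score=min_score))
    if not edge_lists:
        raise ValidationError(f"no recognised edge files under {data_dir}")
    net = hetnet.assemble_network(edge_lists)
    roster = data_dir / "nodes.tsv"
    if roster.exists():
        with open(roster) as fh:
            for line in fh:
                if line.strip():
                    node, ntype = line.rstrip("\n").split("\t")[:2]
                    net.add_node(node, ntype)
    return net


def _config_hash(config: RunConfig) -> str:
    payload = json.dumps(
        {
            **{k: getattr(config, k) for k in (
                "seed", "train_fraction", "negative_ratio", "threshold",
                "min_score", "full_graph_embedding", "rank_ingredient",
            )},
            "walk": config.walk.__dict__,
        },
        sort_keys=True,
        default=str,
    )
    return hashlib.sha256(payload.encode()).hexdigest()[:16]


def _read_pairs(path: str | Path) -> list[tuple[str, str]]:
    pairs = []
    with open(path) as fh:
        for line in fh:
            if line.strip():
                i, d = line.rstrip("\n").split("\t")[:2]
                pairs.append((i, d))
    return pairs


def run(config: RunConfig) -> RunResult:
    """Execute the full pipeline and write its artifacts.

    Writes ``metrics.json``, ``predictions.csv``, ``ranking.csv``,
    optionally ``sab.json``, and ``run.log`` under ``out_dir``.
    Identical config + seed reproduces byte-identical outputs
    (training is single-threaded throughout).
    """
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    log_lines: list[str] = []

    def log(msg: str) -> None:
        log_lines.append(msg)

    net = load_network(config.data_dir, min_score=config.min_score)
    log(f"network: {net.n_nodes} nodes, {net.n_edges} edges")

    # ---- labelled pairs and split ----------------------------------
    if config.holdout_pairs_path:
        holdout = _read_pairs(config.holdout_pairs_path)
        pairs = reposition.build_pair_dataset(
            net, config.negative_ratio, seed=config.seed + 1, exclude=set(holdout)
        )
        train = pairs  # all emitted edges train; withheld pairs test
        neg_pool = reposition.build_pair_dataset(
            net, "all", seed=config.seed + 1, exclude=set(holdout)
        )
        neg_pool = neg_pool[neg_pool["label"] == 0]
        train_negs = set(map(tuple, train[train["label"] == 0][["ingredient", "disease"]].to_numpy()))
        avail = neg_pool[~neg_pool.apply(
            lambda r: (r["ingredient"], r["disease"]) in train_negs, axis=1)]
        ratio = len(avail) / len(holdout) if config.negative_ratio == "all" \
            else float(config.negative_ratio)
        n_neg = min(len(avail), int(round(ratio * len(holdout))))
        test_negs = avail.sample(n=n_neg, random_state=config.seed + 2)
        test = pd.concat(
            [pd.DataFrame({"ingredient": [i for i, _ in holdout],
                           "disease": [d for _, d in holdout],
                           "label": 1}),
             test_negs],
            ignore_index=True,
        )
        log(f"holdout evaluation: {len(holdout)} external positives, {n_neg} negatives")
    else:
        pairs = reposition.build_pair_dataset(
            net, config.negative_ratio, seed=config.seed + 1
        )
        train, test = reposition.split_dataset(
            pairs, config.train_fraction, seed=config.seed + 2
        )
        log(f"split: {len(train)} train / {len(test)} test pairs "
            f"(fraction {config.train_fraction})")

    # ---- embedding --------------------------------------------------
    if config.full_graph_embedding or config.holdout_pairs_path:
        emb_net = net
        log("embedding mode: FULL GRAPH (test edges visible to the embedding)"
            if config.full_graph_embedding else
            "embedding mode: holdout positives absent from the input network")
    else:
        test_pos = [
            (r.ingredient, r.disease)
            for r in test.itertuples()
            if r.label == 1
        ]
        emb_net = hetnet.remove_edges(net, test_pos)
        log(f"embedding mode: leakage-free ({len(test_pos)} test positives removed)")
    walk_cfg = config.walk.with_seed(config.seed + 3)
    walks = generate_walks(emb_net, walk_cfg)
    emb = train_skipgram(walks, walk_cfg)
    topo = topology_features(emb_net)
    features = fuse_features(emb, topo)
    log(f"features: {features.shape[0]} nodes x {features.shape[1]} dims")

    # ---- classifier -------------------------------------------------
    x_train = reposition.pair_features(train, features)
    clf = reposition.train_classifier(
        x_train, train["label"].to_numpy(), seed=config.seed + 4
    )
    x_test = reposition.pair_features(test, features)
    scores = reposition.score_pairs(clf, x_test)
    predictions = test.rename(columns={"label": "true_label"}).copy()
    predictions["score"] = scores
    predictions["predicted_label"] = (scores >= config.threshold).astype(int)
    predictions = predictions[
        ["ingredient", "disease", "score", "predicted_label", "true_label"]
    ].sort_values(["ingredient", "disease"], kind="mergesort").reset_index(drop=True)
    metrics = reposition.evaluate(predictions, threshold=config.threshold)
    log("metrics: " + json.dumps(metrics.to_dict(), sort_keys=True))

    # ---- ranking ----------------------------------------------------
    test_pos_pairs = predictions[predictions["true_label"] == 1]
    if config.rank_ingredient is not None:
        focus = config.rank_ingredient
    else:
        counts = test_pos_pairs["ingredient"].value_counts()
        focus = sorted(counts[counts == counts.max()].index)[0] if len(counts) \
            else net.nodes_of_type("ingredient")[0]
    known = set(map(tuple, net.edges_of_relation("ingredient-disease"))) | set(
        map(tuple, test_pos_pairs[["ingredient", "disease"]].to_numpy())
    )
    ranking = reposition.rank_diseases(
        focus, clf, features, net.nodes_of_type("disease"),
        known_positives=known, threshold=config.threshold,
    )
    log(f"ranked {len(ranking)} diseases for ingredient {focus!r}")

    # ---- separation score -------------------------------------------
    sab_payload = None
    if config.gene_set_a and config.gene_set_b:
        ppi_edges = hetnet.read_string_links(
            Path(config.data_dir) / PPI_FILE, min_score=config.min_score
        )
        ppi = hetnet.assemble_network([ppi_edges])
        res = separation_score(
            ppi, read_gene_set(config.gene_set_a), read_gene_set(config.gene_set_b)
        )
        sab_payload = {
            "s_ab": res.s_ab,
            "d_AA": res.summary.d_aa,
            "d_BB": res.summary.d_bb,
            "d_AB": res.summary.d_ab,
            "n_A_used": res.summary.n_a_used,
            "n_B_used": res.summary.n_b_used,
            "dropped": res.summary.dropped,
        }
        log(f"S_AB = {res.s_ab:.4f}")

    # ---- artifacts --------------------------------------------------
    meta = {
        "config_hash": _config_hash(config),
        "seed": config.seed,
        "embedding_mode": "full_graph" if config.full_graph_embedding else "leakage_free",
        "threshold": config.threshold,
        "ranked_ingredient": focus,
    }
    with open(out_dir / "metrics.json", "w") as fh:
        json.dump({**metrics.to_dict(), **meta}, fh, indent=1, sort_keys=True)
        fh.write("\n")
    predictions.to_csv(out_dir / "predictions.csv", index=False)
    ranking.to_csv(out_dir / "ranking.csv", index=False)
    if sab_payload is not None:
        with open(out_dir / "sab.json", "w") as fh:
            json.dump(sab_payload, fh, indent=1, sort_keys=True)
            fh.write("\n")
    with open(out_dir / "run.log", "w") as fh:
        fh.write("\n".join(log_lines) + "\n")
    return RunResult(
        metrics=metrics, predictions=predictions, ranking=ranking,
        out_dir=out_dir, sab=sab_payload,
    )
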