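"""Pair construction, Hadamard fusion, classifier, metric oracles, ranking."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from repowalk import (
    TypedEdge,
    assemble_network,
    build_pair_dataset,
    evaluate,
    hadamard_fuse,
    rank_diseases,
    score_pairs,
    split_dataset,
    train_classifier,
)
from repowalk.hetnet import ValidationError
from repowalk.reposition import UndefinedMetricError


# ---------------------------------------------------------------- oracles

def oracle_auc(y, s):
    """Exhaustive pairwise concordance with ties counted 1/2."""
    pos = [si for si, yi in zip(s, y) if yi == 1]
    neg = [si for si, yi in zip(s, y) if yi == 0]
    wins = sum(1.0 if p > n else 0.5 if p == n else 0.0 for p in pos for n in neg)
    return wins / (len(pos) * len(neg))


def oracle_aupr(y, s):
    """Average precision from first principles: step-wise summation of
    (recall gain) x (precision) over the unique score thresholds, with
    tied scores entering as one block."""
    y = np.asarray(y)
    s = np.asarray(s)
    total_pos = y.sum()
    ap, prev_recall = 0.0, 0.0
    for t in sorted(set(s), reverse=True):
        sel = s >= t
        tp = y[sel].sum()
        precision = tp / sel.sum()
        recall = tp / total_pos
        ap += (recall - prev_recall) * precision
        prev_recall = recall
    return ap


def oracle_threshold_metrics(y, s, threshold):
    """Confusion-matrix counting."""
    pred = [1 if si >= threshold else 0 for si in s]
    tp = sum(1 for p, t in zip(pred, y) if p == 1 and t == 1)
    fp = sum(1 for p, t in zip(pred, y) if p == 1 and t == 0)
    fn = sum(1 for p, t in zip(pred, y) if p == 0 and t == 1)
    tn = sum(1 for p, t in zip(pred, y) if p == 0 and t == 0)
    acc = (tp + tn) / len(y)
    prec = tp / (tp + fp) if tp + fp else 0.0
    rec = tp / (tp + fn) if tp + fn else 0.0
    f1 = 2 * prec * rec / (prec + rec) if prec + rec else 0.0
    return acc, prec, rec, f1


def records(y, s):
    return pd.DataFrame({"true_label": y, "score": s})


def bipartite_net(n_ing, n_dis, edges):
    net = assemble_network([[TypedEdge(i, d, "ingredient-disease") for i, d in edges]])
    for k in range(n_ing):
        net.add_node(f"I{k}", "ingredient")
    for k in range(n_dis):
        net.add_node(f"D{k}", "disease")
    return net


# ----------------------------------------------------------- pair dataset

class TestBuildPairDataset:
    def test_ratio_one_doubles_the_positives(self):
        edges = [(f"I{k}", f"D{k}") for k in range(10)]
        net = bipartite_net(10, 10, edges)
        pairs = build_pair_dataset(net, negative_ratio=1, seed=0)
        assert len(pairs) == 20
        assert pairs["label"].sum() == 10

    def test_complete_block_has_no_negatives(self):
        edges = [(f"I{i}", f"D{j}") for i in range(3) for j in range(3)]
        net = bipartite_net(3, 3, edges)
        with pytest.warns(UserWarning, match="capping"):
            pairs = build_pair_dataset(net, negative_ratio=2, seed=0)
        assert (pairs["label"] == 1).all()

    def test_negatives_disjoint_from_edges(self, synthetic_default):
        net, _, _ = synthetic_default
        pairs = build_pair_dataset(net, negative_ratio=5, seed=3)
        edge_set = set(net.edges_of_relation("ingredient-disease"))
        for row in pairs.itertuples():
            in_net = (row.ingredient, row.disease) in edge_set
            assert in_net == (row.label == 1)  # exhaustive membership check

    def test_no_duplicate_pairs_and_seeded(self, synthetic_default):
        net, _, _ = synthetic_default
        a = build_pair_dataset(net, negative_ratio=3, seed=7)
        b = build_pair_dataset(net, negative_ratio=3, seed=7)
        assert a.equals(b)
        assert not a.duplicated(["ingredient", "disease"]).any()

    def test_exclusions_never_sampled(self, synthetic_default):
        net, _, _ = synthetic_default
        diseases = net.nodes_of_type("disease")
        ing = net.nodes_of_type("ingredient")[0]
        banned = {(ing, d) for d in diseases}
        pairs = build_pair_dataset(net, negative_ratio=10, seed=1, exclude=banned)
        negs = pairs[pairs["label"] == 0]
        assert not (negs["ingredient"] == ing).any()

    def test_all_sentinel_exhausts_nonedges(self):
        edges = [("I0", "D0")]
        net = bipartite_net(3, 3, edges)
        pairs = build_pair_dataset(net, negative_ratio="all", seed=0)
        assert len(pairs) == 9  # 1 positive + 8 non-edges


# --------------------------------------------------------------- hadamard

class TestHadamard:
    def test_ones_is_identity_element(self, rng):
        fd = rng.normal(size=68)
        assert hadamard_fuse(np.ones(68), fd) == pytest.approx(fd)

    def test_definition(self):
        assert hadamard_fuse([1, 2], [3, 4]) == pytest.approx([3, 8])

    def test_matches_elementwise_loop(self, rng):
        fc, fd = rng.normal(size=68), rng.normal(size=68)
        h = hadamard_fuse(fc, fd)
        for k in range(68):
            assert h[k] == fc[k] * fd[k]

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValidationError):
            hadamard_fuse(np.ones(5), np.ones(6))


# ------------------------------------------------------------------ split

class TestSplit:
    def make_pairs(self, n, pos_frac, seed=0):
        rng = np.random.default_rng(seed)
        return pd.DataFrame({
            "ingredient": [f"I{k}" for k in range(n)],
            "disease": [f"D{k}" for k in range(n)],
            "label": (rng.random(n) < pos_frac).astype(int),
        })

    def test_eighty_twenty(self):
        train, test = split_dataset(self.make_pairs(100, 0.3), 0.8, seed=0)
        assert (len(train), len(test)) == (80, 20)

    def test_seed_reproducible_and_partition(self):
        pairs = self.make_pairs(60, 0.4)
        t1 = split_dataset(pairs, 0.8, seed=5)
        t2 = split_dataset(pairs, 0.8, seed=5)
        assert t1[0].equals(t2[0]) and t1[1].equals(t2[1])
        both = pd.concat([t1[0], t1[1]])
        assert len(both) == 60
        assert not both.duplicated(["ingredient", "disease"]).any()

    def test_stratification_preserves_minority_fraction(self):
        pairs = self.make_pairs(1000, 0.1, seed=1)
        _, test = split_dataset(pairs, 0.8, seed=2)
        expected = pairs["label"].sum() * 0.2
        assert abs(test["label"].sum() - expected) <= 1

    def test_tiny_class_falls_back_with_warning(self):
        pairs = self.make_pairs(10, 0.0)
        pairs.loc[0, "label"] = 1
        with pytest.warns(UserWarning, match="stratification"):
            split_dataset(pairs, 0.8, seed=0)


# ------------------------------------------------------------- classifier

class TestClassifier:
    def test_separable_data_perfect_training_auc(self, rng):
        x = np.vstack([rng.uniform(0.5, 1, (40, 10)), rng.uniform(-1, -0.5, (40, 10))])
        y = np.array([1] * 40 + [0] * 40)
        clf = train_classifier(x, y, seed=0)
        rec = records(y, score_pairs(clf, x))
        assert evaluate(rec).auc == 1.0

    def test_scores_are_probabilities(self, rng):
        x = rng.normal(size=(60, 8))
        y = rng.integers(0, 2, 60)
        y[:2] = [0, 1]
        clf = train_classifier(x, y, seed=1)
        s = score_pairs(clf, rng.normal(size=(30, 8)))
        assert ((s >= 0) & (s <= 1)).all()

    def test_single_class_rejected(self, rng):
        with pytest.raises(ValidationError):
            train_classifier(rng.normal(size=(10, 4)), np.ones(10), seed=0)

    def test_label_permutation_gives_chance_auc(self, rng):
        """Permutation null: with labels shuffled independently of the
        features, held-out AUC must hover around 0.5."""
        x = rng.normal(size=(300, 12))
        y = (x[:, 0] > 0).astype(int)
        aucs = []
        for seed in range(20):
            perm = np.random.default_rng(seed).permutation(len(y))
            y_perm = y[perm]
            x_tr, x_te = x[:200], x[200:]
            clf = train_classifier(x_tr, y_perm[:200], seed=seed, n_trees=50)
            aucs.append(evaluate(records(y_perm[200:], score_pairs(clf, x_te))).auc)
        assert 0.4 <= np.mean(aucs) <= 0.6


# ---------------------------------------------------------------- metrics

class TestEvaluate:
    def test_perfect_separation_all_ones(self):
        rec = records([1, 1, 0, 0], [0.9, 0.8, 0.2, 0.1])
        m = evaluate(rec, threshold=0.5)
        assert m.to_dict() == pytest.approx(
            {k: 1.0 for k in ("auc", "aupr", "accuracy", "precision", "recall", "f1")}
        )

    def test_concordance_example(self):
        rec = records([1, 0, 1, 0], [0.9, 0.8, 0.7, 0.4])
        assert evaluate(rec).auc == pytest.approx(0.75)
        assert oracle_auc([1, 0, 1, 0], [0.9, 0.8, 0.7, 0.4]) == pytest.approx(0.75)

    def test_all_ties_give_half(self):
        rec = records([1, 0, 1, 0], [0.5] * 4)
        assert evaluate(rec).auc == pytest.approx(0.5)

    @pytest.mark.parametrize("n,pos_frac,seed", [(50, 0.5, 0), (400, 0.1, 1), (1000, 0.3, 2)])
    def test_matches_from_scratch_oracles(self, n, pos_frac, seed):
        rng = np.random.default_rng(seed)
        y = (rng.random(n) < pos_frac).astype(int)
        y[:2] = [0, 1]
        s = np.round(rng.random(n), 2)  # coarse scores force ties
        m = evaluate(records(y, s), threshold=0.5)
        assert m.auc == pytest.approx(oracle_auc(y, s))
        assert m.aupr == pytest.approx(oracle_aupr(y, s))
        acc, prec, rec, f1 = oracle_threshold_metrics(y, s, 0.5)
        assert (m.accuracy, m.precision, m.recall, m.f1) == pytest.approx((acc, prec, rec, f1))

    def test_f1_is_harmonic_mean(self, rng):
        y = rng.integers(0, 2, 200)
        y[:2] = [0, 1]
        s = rng.random(200)
        m = evaluate(records(y, s))
        if m.precision + m.recall > 0:
            hm = 2 * m.precision * m.recall / (m.precision + m.recall)
            assert abs(m.f1 - hm) < 1e-12

    def test_score_reversal_flips_auc(self, rng):
        y = rng.integers(0, 2, 300)
        y[:2] = [0, 1]
        s = rng.random(300)
        assert evaluate(records(y, 1 - s)).auc == pytest.approx(1 - evaluate(records(y, s)).auc)

    def test_order_and_duplication_invariance(self, rng):
        y = rng.integers(0, 2, 100)
        y[:2] = [0, 1]
        s = rng.random(100)
        base = evaluate(records(y, s)).to_dict()
        perm = np.random.default_rng(1).permutation(100)
        assert evaluate(records(y[perm], s[perm])).to_dict() == pytest.approx(base)
        doubled = records(np.concatenate([y, y]), np.concatenate([s, s]))
        assert evaluate(doubled).to_dict() == pytest.approx(base)

    def test_single_class_undefined(self):
        with pytest.raises(UndefinedMetricError):
            evaluate(records([1, 1], [0.4, 0.9]))


# ---------------------------------------------------------------- ranking

class FirstCoordinateClassifier:
    """Oracle stand-in scoring each pair by its first feature value."""

    classes_ = np.array([0, 1])

    def predict_proba(self, x):
        s = np.clip(np.asarray(x)[:, 0], 0, 1)
        return np.column_stack([1 - s, s])


class TestRankDiseases:
    def features(self, values):
        return pd.DataFrame(
            {"f0": values, "f1": np.zeros(len(values))},
            index=[f"D{k}" for k in range(len(values) - 1)] + ["I0"],
        )

    def test_oracle_classifier_ranking_is_sorted(self):
        feats = self.features([0.3, 0.9, 0.1, 0.5, 1.0])  # I0 has f0 = 1
        out = rank_diseases("I0", FirstCoordinateClassifier(), feats,
                            ["D0", "D1", "D2", "D3"])
        assert list(out["disease"]) == ["D1", "D3", "D0", "D2"]
        assert (out["score"].diff().dropna() <= 0).all()

    def test_ties_break_lexicographically(self):
        feats = self.features([0.5, 0.5, 0.5, 0.5, 1.0])
        out = rank_diseases("I0", FirstCoordinateClassifier(), feats,
                            ["D2", "D0", "D3", "D1"])
        assert list(out["disease"]) == ["D0", "D1", "D2", "D3"]

    def test_predicted_and_true_labels(self):
        feats = self.features([0.9, 0.2, 0.6, 0.4, 1.0])
        out = rank_diseases(
            "I0", FirstCoordinateClassifier(), feats, ["D0", "D1", "D2", "D3"],
            known_positives={("I0", "D0")}, threshold=0.5,
        ).set_index("disease")
        assert out.loc["D0", "predicted_label"] == 1
        assert out.loc["D1", "predicted_label"] == 0
        assert out.loc["D0", "true_label"] == 1
        assert out.loc["D2", "true_label"] == 0

    def test_unknown_ingredient_rejected(self):
        feats = self.features([0.5, 1.0])
        with pytest.raises(KeyError):
            rank_diseases("I9", FirstCoordinateClassifier(), feats, ["D0"])

    def test_planted_diseases_rank_higher(self):
        """Planted-truth recovery: diseases sharing the ingredient's
        latent signature must out-rank background diseases (rank-sum
        test pooled over seeds)."""
        planted_ranks, background_ranks = [], []
        for seed in range(10):
            rng = np.random.default_rng(seed)
            n_dis, dim = 50, 16
            signature = rng.normal(size=dim)
            dis_feats = rng.normal(size=(n_dis, dim))
            planted = [f"D{k:02d}" for k in range(5)]
            dis_feats[:5] = signature + rng.normal(scale=0.4, size=(5, dim))
            feats = pd.DataFrame(
                np.vstack([dis_feats, signature]),
                index=[f"D{k:02d}" for k in range(n_dis)] + ["I0"],
            )
            # train on labelled pairs from the same generative story
            x, y = [], []
            for _ in range(120):
                sig2 = rng.normal(size=dim)
                if rng.random() < 0.5:
                    x.append(sig2 * (sig2 + rng.normal(scale=0.4, size=dim)))
                    y.append(1)
                else:
                    x.append(sig2 * rng.normal(size=dim))
                    y.append(0)
            clf = train_classifier(np.array(x), np.array(y), seed=seed, n_trees=50)
            out = rank_diseases("I0", clf, feats, [f"D{k:02d}" for k in range(n_dis)])
            rank_of = {d: r for r, d in enumerate(out["disease"])}
            planted_ranks += [rank_of[d] for d in planted]
            background_ranks += [rank_of[d] for d in out["disease"] if d not in planted]
        test = stats.mannwhitneyu(planted_ranks, background_ranks, alternative="less")
        assert test.pvalue < 0.05
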