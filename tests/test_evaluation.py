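"""Split schemes, metric correctness against brute force, homology baseline."""

import numpy as np
import pandas as pd
import pytest

import genesem as gs
from genesem.corpus import Sentence, from_sentences
from genesem.evaluation import NO_HIT, SplitError


def grid_corpus(n_contigs, groups=None):
    sentences = []
    for i in range(n_contigs):
        toks = [f"K{i:05d}.01", f"K{i:05d}.02"]
        g = groups[i % len(groups)] if groups else None
        sentences.append(Sentence(f"c{i}", toks, group=g))
    return from_sentences(sentences)


class TestKFold:
    def test_partition(self):
        corpus = grid_corpus(10)
        plan = gs.kfold_split(corpus, k=5, seed=0)
        test_sets = [set(f.test_sentences) for f in plan.folds]
        assert all(len(ts) == 2 for ts in test_sets)
        assert set.union(*test_sets) == {s.contig_id for s in corpus.sentences}
        for i in range(5):
            for j in range(i + 1, 5):
                assert not (test_sets[i] & test_sets[j])

    def test_uneven_sizes(self):
        plan = gs.kfold_split(grid_corpus(3), k=2, seed=0)
        assert sorted(len(f.test_sentences) for f in plan.folds) == [1, 2]

    def test_deterministic(self):
        corpus = grid_corpus(20)
        p1 = gs.kfold_split(corpus, k=4, seed=9)
        p2 = gs.kfold_split(corpus, k=4, seed=9)
        assert [f.test_sentences for f in p1.folds] == [f.test_sentences for f in p2.folds]

    def test_k_too_large(self):
        with pytest.raises(SplitError):
            gs.kfold_split(grid_corpus(3), k=5)


class TestLeaveOneGroupOut:
    def test_one_fold_per_group(self):
        corpus = grid_corpus(9, groups=["x", "y", "z"])
        plan = gs.leave_one_group_out_split(corpus)
        assert len(plan.folds) == 3
        for fold in plan.folds:
            groups = {s.group for s in corpus.sentences if s.contig_id in set(fold.test_sentences)}
            assert len(groups) == 1

    def test_single_group_rejected(self):
        with pytest.raises(SplitError):
            gs.leave_one_group_out_split(grid_corpus(4, groups=["only"]))

    def test_missing_labels_listed(self):
        corpus = grid_corpus(4, groups=["x", "y"])
        corpus.sentences[0].group = None
        with pytest.raises(SplitError, match="c0"):
            gs.leave_one_group_out_split(corpus)


class TestLeaveOneKOOut:
    def test_subclusters_stay_together(self):
        mapping = {f"K00001.{i:02d}": "catA" for i in range(1, 4)}
        mapping.update({f"K00002.{i:02d}": "catB" for i in range(1, 3)})
        scheme = gs.CategoryScheme(categories=["catA", "catB"], token_to_category=mapping)
        plan = gs.leave_one_ko_out_split(scheme, {})
        assert len(plan.folds) == 2
        by_name = {f.name: f for f in plan.folds}
        assert by_name["ko_K00001"].test_tokens == {f"K00001.{i:02d}" for i in range(1, 4)}

    def test_partition_property(self):
        rng = np.random.default_rng(0)
        mapping = {f"K{rng.integers(1, 20):05d}.{i:02d}": "c" for i in range(1, 60)}
        mapping["K90000.01"] = "d"
        scheme = gs.CategoryScheme(categories=["c", "d"], token_to_category=mapping)
        plan = gs.leave_one_ko_out_split(scheme, {})
        test_sets = [f.test_tokens for f in plan.folds]
        assert set.union(*test_sets) == set(mapping)
        assert sum(len(ts) for ts in test_sets) == len(mapping)
        kos = {t.split(".")[0] for t in mapping}
        assert len(plan.folds) == len(kos)


def brute_force_average_precision(y_true, scores):
    """Step integration AP: sum over descending thresholds of dP x precision."""
    order = np.argsort(-scores, kind="stable")
    y = np.asarray(y_true)[order]
    tp = 0
    ap = 0.0
    n_pos = y.sum()
    prev_recall = 0.0
    for i in range(len(y)):
        tp += y[i]
        # threshold boundaries fall between distinct scores
        if i + 1 < len(y) and scores[order[i]] == scores[order[i + 1]]:
            continue
        precision = tp / (i + 1)
        recall = tp / n_pos
        ap += (recall - prev_recall) * precision
        prev_recall = recall
    return ap


class TestEvaluate:
    def fixture_predictions(self, seed=0, n=30, cats=("a", "b", "c")):
        rng = np.random.default_rng(seed)
        truth = {f"K{i:05d}.01": cats[rng.integers(len(cats))] for i in range(n)}
        scores = rng.random((n, len(cats)))
        scores /= scores.sum(axis=1, keepdims=True)
        df = pd.DataFrame({"token": list(truth)})
        for j, c in enumerate(cats):
            df[f"score_{c}"] = scores[:, j]
        df["predicted_category"] = [cats[j] for j in scores.argmax(axis=1)]
        df["raw_score"] = scores.max(axis=1)
        return df, truth

    def test_perfect_predictions(self):
        df, truth = self.fixture_predictions()
        for c in ("a", "b", "c"):
            df[f"score_{c}"] = [1.0 if truth[t] == c else 0.0 for t in df["token"]]
        df["predicted_category"] = [truth[t] for t in df["token"]]
        report = gs.evaluate(df, truth)
        assert (report.per_category["f1"] == 1.0).all()
        assert (report.per_category["aupr"] == 1.0).all()
        assert report.weighted_f1 == 1.0

    def test_no_skill_aupr_equals_prevalence(self):
        df, truth = self.fixture_predictions(seed=1)
        for c in ("a", "b", "c"):
            df[f"score_{c}"] = 0.5
        report = gs.evaluate(df, truth)
        y = np.array(list(truth.values()))
        for _, row in report.per_category.iterrows():
            prevalence = (y == row["category"]).mean()
            assert row["aupr"] == pytest.approx(prevalence, abs=1e-9)

    def test_matches_brute_force(self):
        df, truth = self.fixture_predictions(seed=2)
        report = gs.evaluate(df, truth)
        y_true = np.array([truth[t] for t in df["token"]])
        y_pred = df["predicted_category"].to_numpy()
        for _, row in report.per_category.iterrows():
            c = row["category"]
            tp = np.sum((y_pred == c) & (y_true == c))
            fp = np.sum((y_pred == c) & (y_true != c))
            fn = np.sum((y_pred != c) & (y_true == c))
            precision = tp / (tp + fp) if tp + fp else 0.0
            recall = tp / (tp + fn) if tp + fn else 0.0
            f1 = 2 * precision * recall / (precision + recall) if precision + recall else 0.0
            assert row["precision"] == pytest.approx(precision, abs=1e-9)
            assert row["recall"] == pytest.approx(recall, abs=1e-9)
            assert row["f1"] == pytest.approx(f1, abs=1e-9)
            ap = brute_force_average_precision(
                (y_true == c).astype(int), df[f"score_{c}"].to_numpy()
            )
            assert row["aupr"] == pytest.approx(ap, abs=1e-9)
        supports = report.per_category.set_index("category")["support"]
        f1s = report.per_category.set_index("category")["f1"]
        weighted = (supports * f1s).sum() / supports.sum()
        assert report.weighted_f1 == pytest.approx(weighted, abs=1e-9)
        # confusion rows sum to per-category truth counts
        for c in ("a", "b", "c"):
            assert report.confusion.loc[c].sum() == (y_true == c).sum()

    def test_permutation_invariant(self):
        df, truth = self.fixture_predictions(seed=3)
        shuffled = df.sample(frac=1.0, random_state=1).reset_index(drop=True)
        r1 = gs.evaluate(df, truth)
        r2 = gs.evaluate(shuffled, truth)
        pd.testing.assert_frame_equal(r1.per_category, r2.per_category)

    def test_truth_mismatch_rejected(self):
        df, truth = self.fixture_predictions(seed=4)
        del truth[df.loc[0, "token"]]
        with pytest.raises(SplitError):
            gs.evaluate(df, truth)


class TestBestHitBaseline:
    def scheme(self, n_kos=20, cats=("a", "b")):
        rng = np.random.default_rng(6)
        mapping = {f"K{i:05d}.01": cats[rng.integers(len(cats))] for i in range(n_kos)}
        return gs.CategoryScheme(categories=list(cats), token_to_category=mapping)

    def test_self_hit_only_gives_no_hit(self):
        scheme = gs.CategoryScheme(
            categories=["a"], token_to_category={"K00001.01": "a", "K00001.02": "a"}
        )
        hits = pd.DataFrame([{"query": "K00001.01", "subject": "K00001.02", "evalue": 1e-20}])
        out = gs.best_hit_baseline(hits, scheme, queries=["K00001.01"])
        assert out.loc[0, "predicted_category"] == NO_HIT

    def test_evalue_threshold_strict(self):
        scheme = self.scheme()
        q = "K00000.01"
        hits = pd.DataFrame([
            {"query": q, "subject": "K00005.01", "evalue": 1e-5},
            {"query": q, "subject": "K00006.01", "evalue": 1e-2},
        ])
        out = gs.best_hit_baseline(hits, scheme, queries=[q])
        assert out.loc[0, "best_subject"] == "K00005.01"
        hits_bad = pd.DataFrame([{"query": q, "subject": "K00006.01", "evalue": 1e-3}])
        out = gs.best_hit_baseline(hits_bad, scheme, queries=[q])
        assert out.loc[0, "predicted_category"] == NO_HIT  # E < 1e-3 is strict

    def test_matches_per_query_brute_force(self):
        rng = np.random.default_rng(7)
        scheme = self.scheme(n_kos=30, cats=("a", "b", "c"))
        tokens = list(scheme.token_to_category)
        rows = []
        for _ in range(400):
            q, s = rng.choice(tokens, size=2)
            rows.append({"query": q, "subject": s,
                         "evalue": 10.0 ** rng.uniform(-30, 1)})
        hits = pd.DataFrame(rows)
        queries = sorted(set(rng.choice(tokens, size=100)))
        out = gs.best_hit_baseline(hits, scheme, queries=queries).set_index("token")
        for q in queries:
            best_e, best_s = None, None
            for r in hits.itertuples(index=False):
                if r.query != q or r.evalue >= 1e-3:
                    continue
                if r.subject.split(".")[0] == q.split(".")[0]:
                    continue
                if best_e is None or r.evalue < best_e or (r.evalue == best_e and r.subject < best_s):
                    best_e, best_s = r.evalue, r.subject
            expected = scheme.token_to_category[best_s] if best_s else NO_HIT
            assert out.loc[q, "predicted_category"] == expected

    def test_embedding_more_sensitive_than_partial_recall_baseline(self):
        """When homology search misses queries, context-based prediction keeps
        assigning categories, so its recall exceeds the baseline's."""
        cfg = gs.SyntheticConfig(
            n_contigs=600, systems=gs.make_systems(6, 5, 3, insertion_rate=0.3), seed=61
        )
        corpus, truth = gs.generate_corpus(cfg)
        scheme = gs.scheme_from_truth(truth.tokens)
        hits = gs.generate_hit_table(truth, recall=0.5, seed=62)
        baseline = gs.best_hit_baseline(hits, scheme, queries=scheme.labeled_tokens())
        cat = truth.category_of()
        base_recall = (baseline["predicted_category"] == baseline["token"].map(cat)).mean()
        emb = gs.train_embeddings(corpus, dim=32, epochs=5, seed=63)
        model = gs.train_classifier(emb, scheme, batch_size=8, seed=64)
        preds = gs.predict(model, {t: emb.embed(t) for t in scheme.labeled_tokens() if t in emb})
        emb_recall = (preds["predicted_category"] == preds["token"].map(cat)).mean()
        assert emb_recall > base_recall
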