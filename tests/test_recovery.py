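from itertools import chain, combinations

import numpy as np
import pandas as pd
import pytest

import protrep as P
from protrep.recovery import RecoveryReport


def powerset(universe):
    return [frozenset(c) for c in
            chain.from_iterable(combinations(universe, r) for r in range(len(universe) + 1))]


class TestSetMetrics:
    def test_worked_example(self):
        pred, truth = {"A", "B"}, {"B", "C"}
        assert P.set_iou(pred, truth) == pytest.approx(1 / 3)
        assert P.set_precision(pred, truth) == pytest.approx(1 / 2)
        assert P.set_recall(pred, truth) == pytest.approx(1 / 2)
        assert P.set_f1(pred, truth) == pytest.approx(1 / 2)

    def test_identity_and_empty_prediction(self):
        assert P.set_iou({"A"}, {"A"}) == 1.0
        assert P.set_iou(set(), {"A"}) == 0.0
        assert P.set_precision(set(), {"A"}) == 0.0
        assert P.set_f1(set(), {"A"}) == 0.0

    def test_superset_prediction(self):
        assert P.set_recall({"A", "B", "C"}, {"A"}) == 1.0
        assert P.set_precision({"A", "B", "C"}, {"A"}) == pytest.approx(1 / 3)

    @pytest.mark.parametrize("metric", [P.set_iou, P.set_precision, P.set_recall, P.set_f1])
    def test_empty_truth_rejected(self, metric):
        with pytest.raises(ValueError):
            metric({"A"}, set())

    def test_exhaustive_algebra_on_four_element_universe(self):
        """All (prediction, truth) subset pairs of a 4-label universe:
        metric values match first-principles set arithmetic; IoU is a
        lower bound of precision, recall, and F1."""
        universe = ("a", "b", "c", "d")
        for pred in powerset(universe):
            for truth in powerset(universe):
                if not truth:
                    continue
                inter, union = len(pred & truth), len(pred | truth)
                iou = P.set_iou(pred, truth)
                prec = P.set_precision(pred, truth)
                rec = P.set_recall(pred, truth)
                f1 = P.set_f1(pred, truth)
                assert iou == pytest.approx(inter / union)
                assert prec == pytest.approx(inter / len(pred) if pred else 0.0)
                assert rec == pytest.approx(inter / len(truth))
                expected_f1 = 0.0 if prec + rec == 0 else 2 * prec * rec / (prec + rec)
                assert f1 == pytest.approx(expected_f1)
                assert iou <= prec + 1e-12 and iou <= rec + 1e-12 and iou <= f1 + 1e-12
                for v in (iou, prec, rec, f1):
                    assert 0.0 <= v <= 1.0

    def test_single_label_collapse_to_accuracy(self):
        for pred in ("a", "b"):
            for truth in ("a", "b"):
                vals = {m({pred}, {truth}) for m in
                        (P.set_iou, P.set_precision, P.set_recall, P.set_f1)}
                assert vals == ({1.0} if pred == truth else {0.0})


class TestKnnIndex:
    def _matrix(self, vectors, ids=None):
        ids = ids or [f"p{i:03d}" for i in range(len(vectors))]
        return P.RepresentationMatrix(ids, vectors, "pca-reduced")

    def test_self_query_returns_zero_distance(self, rng):
        m = self._matrix(rng.normal(size=(10, 4)))
        index = P.build_knn_index(m)
        (pid, d), = P.query(index, m.row("p003"), 1)
        assert pid == "p003" and d == 0.0

    def test_matches_brute_force_oracle(self, rng):
        vectors = rng.normal(size=(200, 8))
        m = self._matrix(vectors)
        index = P.build_knn_index(m)
        for qi in range(5):
            got = P.query(index, vectors[qi], 10)
            # independent oracle: explicit loop + stable sort on (dist, id)
            pairs = sorted(
                ((float(np.sqrt(((vectors[j] - vectors[qi]) ** 2).sum())), f"p{j:03d}")
                 for j in range(200)),
            )[:10]
            assert [(pid, pytest.approx(d)) for d, pid in pairs] == got

    def test_ties_broken_by_ascending_id(self):
        vectors = np.zeros((4, 3))
        m = self._matrix(vectors, ids=["z", "b", "m", "a"])
        got = P.query(P.build_knn_index(m), np.zeros(3), 4)
        assert [pid for pid, _ in got] == ["a", "b", "m", "z"]

    def test_oversized_query_rejected(self, rng):
        m = self._matrix(rng.normal(size=(5, 2)))
        with pytest.raises(ValueError, match="n=6"):
            P.query(P.build_knn_index(m), np.zeros(2), 6)


class TestPredictLabels:
    @pytest.fixture
    def table(self):
        t = P.AnnotationTable()
        t.add("n1", "Pfam", "X")
        t.add("n2", "Pfam", "X")
        t.add("n3", "Pfam", "Y")
        return t

    @pytest.mark.parametrize("agg", ["majority", "union", "plurality"])
    def test_k1_equals_nearest_neighbor_labels(self, table, agg):
        assert P.predict_labels(["n1", "n3"], 1, table, "Pfam", agg) == {"X"}

    def test_majority_vote(self, table):
        assert P.predict_labels(["n1", "n2", "n3"], 3, table, "Pfam") == {"X"}

    def test_majority_fallback_to_nearest(self, table):
        assert P.predict_labels(["n1", "n3"], 2, table, "Pfam") == {"X"}

    def test_union_and_plurality(self, table):
        assert P.predict_labels(["n1", "n2", "n3"], 3, table, "Pfam", "union") == {"X", "Y"}
        assert P.predict_labels(["n1", "n3"], 2, table, "Pfam", "plurality") == {"X", "Y"}


@pytest.fixture(scope="module")
def kmer_pca(default_corpus):
    m = P.kmer_tfidf_matrix(default_corpus.proteins, k=3)
    red, _ = P.pca_reduce(m, P.ProjectionConfig(pca_components=50))
    return red


class TestEvaluateRecovery:

    def test_separable_representation_perfect_iou(self):
        # one-hot of the true label as coordinates: neighbors always share it
        ids = [f"p{i:02d}" for i in range(30)]
        labels = [i % 3 for i in range(30)]
        vectors = np.eye(3)[labels]
        table = P.AnnotationTable()
        for pid, lab in zip(ids, labels):
            table.add(pid, "function", f"L{lab}")
        m = P.RepresentationMatrix(ids, vectors, "pca-reduced")
        cfg = P.RecoveryConfig(k_values=(1, 3, 7), max_neighbors=7, n_repeats=1)
        report = P.evaluate_recovery(m, table, ["function"], cfg)
        assert (report.per_protein["iou"] == 1.0).all()

    def test_function_beats_taxonomy_at_every_k(self, default_corpus, kmer_pca):
        cfg = P.RecoveryConfig(k_values=(1, 3, 11), max_neighbors=11, n_repeats=2)
        report = P.evaluate_recovery(kmer_pca, default_corpus.annotations,
                                     ["function", "taxonomy"], cfg)
        for k in (1, 3, 11):
            assert report.mean_iou("function", k) > report.mean_iou("taxonomy", k)

    def test_fold_assignment_is_partition(self, default_corpus, kmer_pca):
        cfg = P.RecoveryConfig(k_values=(1,), max_neighbors=1, n_repeats=2)
        report = P.evaluate_recovery(kmer_pca, default_corpus.annotations,
                                     ["function"], cfg)
        counts = report.per_protein.groupby(["protein_id", "repeat"]).size()
        assert (counts == 1).all()
        assert counts.index.get_level_values(0).nunique() == len(default_corpus.proteins)

    def test_deterministic_given_seed(self, default_corpus, kmer_pca):
        cfg = P.RecoveryConfig(k_values=(1, 3), max_neighbors=3, n_repeats=1, seed=5)
        a = P.evaluate_recovery(kmer_pca, default_corpus.annotations, ["function"], cfg)
        b = P.evaluate_recovery(kmer_pca, default_corpus.annotations, ["function"], cfg)
        pd.testing.assert_frame_equal(a.per_protein, b.per_protein)

    def test_union_iou_degrades_with_k(self, default_corpus, kmer_pca):
        # with union aggregation a larger neighborhood can only add labels,
        # so recovery of the motif-derived labels gets harder as k grows
        cfg = P.RecoveryConfig(k_values=(1, 11), max_neighbors=11, n_repeats=2,
                               aggregation="union")
        report = P.evaluate_recovery(kmer_pca, default_corpus.annotations,
                                     ["function"], cfg)
        assert report.mean_iou("function", 11) < report.mean_iou("function", 1)

    def test_unknown_ontology_lists_available(self, default_corpus, kmer_pca):
        with pytest.raises(ValueError, match="function"):
            P.evaluate_recovery(kmer_pca, default_corpus.annotations, ["Pfam"],
                                P.RecoveryConfig(k_values=(1,), max_neighbors=1,
                                                 n_repeats=1))


class TestRecoveryErrorRate:
    def _report(self, iou_values):
        rows = [("p1", "function", 1, r, v, v, v, v) for r, v in enumerate(iou_values)]
        frame = pd.DataFrame(rows, columns=["protein_id", "ontology", "k", "repeat",
                                            "iou", "precision", "recall", "f1"])
        return RecoveryReport(frame)

    @pytest.mark.parametrize("ious,expected", [
        ([1.0, 1.0], 0.0),
        ([0.0, 0.0], 1.0),
        ([1.0, 0.5, 0.0], 0.5),
    ])
    def test_rer_is_one_minus_mean_iou(self, ious, expected):
        rer = P.recovery_error_rate(self._report(ious))
        assert rer["p1"] == pytest.approx(expected)

    def test_rer_pools_over_ontologies_and_k(self, small_corpus):
        m = P.kmer_tfidf_matrix(small_corpus.proteins, k=2)
        cfg = P.RecoveryConfig(k_values=(1, 3), max_neighbors=3, n_repeats=1)
        report = P.evaluate_recovery(m, small_corpus.annotations,
                                     ["function", "taxonomy"], cfg)
        pid = small_corpus.proteins[0].id
        sub = report.per_protein[report.per_protein.protein_id == pid]
        assert report.rer[pid] == pytest.approx(1.0 - sub["iou"].mean())
        assert ((report.rer >= 0) & (report.rer <= 1)).all()
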