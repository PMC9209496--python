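"""Multi-label kNN label-recovery benchmark.

For each ontology, proteins carrying at least one label are split into
folds (default fivefold). For every held-out protein the labels of its
nearest neighbors (Euclidean distance in representation space, default up
to N = 51) are aggregated into a predicted label set, which is scored
against the ground truth with four set metrics:

    IoU       = |pred ∩ truth| / |pred ∪ truth|
    Precision = |pred ∩ truth| / |pred|
    Recall    = |pred ∩ truth| / |truth|
    F1        = 2 P R / (P + R)

For single-label ontologies all four reduce to 0/1 accuracy per example.
The per-protein Recovery Error Rate is 1 minus the protein's mean IoU
pooled over ontologies, neighborhood sizes and repeats; high RER marks
proteins whose function neighbors cannot explain.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from .io import AnnotationTable, RepresentationMatrix

logger = logging.getLogger(__name__)

AGGREGATIONS = ("majority", "union", "plurality")


# ---------------------------------------------------------------------------
# Set metrics


def set_iou(prediction: Iterable[str], truth: Iterable[str]) -> float:
    """Intersection over union of two label sets; truth must be non-empty."""
    pred, truth = frozenset(prediction), frozenset(truth)
    if not truth:
        raise ValueError("IoU undefined for empty ground truth")
    if not pred:
        return 0.0
    return len(pred & truth) / len(pred | truth)


def set_precision(prediction: Iterable[str], truth: Iterable[str]) -> float:
    pred, truth = frozenset(prediction), frozenset(truth)
    if not truth:
        raise ValueError("precision undefined for empty ground truth")
    if not pred:
        return 0.0  # empty prediction: no correct labels among zero predicted
    return len(pred & truth) / len(pred)


def set_recall(prediction: Iterable[str], truth: Iterable[str]) -> float:
    pred, truth = frozenset(prediction), frozenset(truth)
    if not truth:
        raise ValueError("recall undefined for empty ground truth")
    return len(pred & truth) / len(truth)


def set_f1(prediction: Iterable[str], truth: Iterable[str]) -> float:
    p = set_precision(prediction, truth)
    r = set_recall(prediction, truth)
    return 0.0 if p + r == 0 else 2 * p * r / (p + r)


# ---------------------------------------------------------------------------
# Exact kNN with deterministic tie-breaking


class KnnIndex:
    """Exact Euclidean nearest-neighbor index over a RepresentationMatrix.

    Queries return neighbors in ascending distance order; exact distance
    ties are broken by ascending protein id.
    """

    def __init__(self, m: RepresentationMatrix):
        if len(m.ids) == 0:
            raise ValueError("cannot index an empty matrix")
        self.ids = np.asarray(m.ids, dtype=object)
        self.vectors = m.vectors

    def __len__(self) -> int:
        return len(self.ids)

    def query(self, vector: np.ndarray, n: int,
              exclude: str | None = None) -> list[tuple[str, float]]:
        """n nearest (id, distance) pairs; ``exclude`` drops one id
        (defensive self-exclusion for vectors present in the index)."""
        mask = np.ones(len(self.ids), dtype=bool)
        if exclude is not None:
            mask &= self.ids != exclude
        avail = int(mask.sum())
        if n > avail:
            raise ValueError(f"requested n={n} neighbors but index holds {avail}")
        dists = np.linalg.norm(self.vectors[mask] - np.asarray(vector), axis=1)
        ids = self.ids[mask]
        order = np.lexsort((ids, dists))[:n]
        return [(str(ids[i]), float(dists[i])) for i in order]


def build_knn_index(m: RepresentationMatrix) -> KnnIndex:
    return KnnIndex(m)


def query(index: KnnIndex, vector: np.ndarray, n: int) -> list[tuple[str, float]]:
    return index.query(vector, n)


# ---------------------------------------------------------------------------
# Label aggregation


def predict_labels(neighbor_ids: Sequence[str], k: int, annotations: AnnotationTable,
                   ontology: str, aggregation: str = "majority") -> frozenset[str]:
    """Aggregate the label sets of the k nearest neighbors into a prediction.

    majority (default)
        a label is predicted iff it occurs in more than k/2 of the k
        neighbors; if no label clears the bar, fall back to the single
        nearest neighbor's labels (the prediction is never empty);
    union
        union of all k neighbors' labels;
    plurality
        the label(s) with the highest occurrence count.
    """
    if aggregation not in AGGREGATIONS:
        raise ValueError(f"unknown aggregation {aggregation!r}; choose from {AGGREGATIONS}")
    if k < 1 or k > len(neighbor_ids):
        raise ValueError(f"k={k} outside [1, {len(neighbor_ids)}]")
    sets = [annotations.labels(pid, ontology) for pid in neighbor_ids[:k]]
    counts: dict[str, int] = {}
    for s in sets:
        for lab in s:
            counts[lab] = counts.get(lab, 0) + 1
    if aggregation == "union":
        return frozenset(counts)
    if aggregation == "plurality":
        if not counts:
            return frozenset()
        top = max(counts.values())
        return frozenset(lab for lab, c in counts.items() if c == top)
    majority = frozenset(lab for lab, c in counts.items() if c > k / 2)
    return majority if majority else sets[0]


# ---------------------------------------------------------------------------
# Cross-validated recovery


@dataclass(frozen=True)
class RecoveryConfig:
    """Benchmark protocol: fivefold CV, neighborhoods up to N = 51,
    five repeats with derived seeds."""

    n_folds: int = 5
    max_neighbors: int = 51
    k_values: tuple[int, ...] = (1, 3, 11, 51)
    aggregation: str = "majority"
    n_repeats: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_folds < 2:
            raise ValueError("n_folds must be >= 2")
        if not self.k_values or list(self.k_values) != sorted(set(self.k_values)):
            raise ValueError("k_values must be non-empty and strictly ascending")
        if self.k_values[-1] > self.max_neighbors:
            raise ValueError("k_values may not exceed max_neighbors")
        if self.aggregation not in AGGREGATIONS:
            raise ValueError(f"aggregation must be one of {AGGREGATIONS}")
        if self.n_repeats < 1:
            raise ValueError("n_repeats must be positive")


@dataclass
class RecoveryReport:
    """Benchmark output.

    ``per_protein`` has one row per (protein, ontology, k, repeat) with the
    four metric values; ``aggregates`` holds mean and sd per (ontology, k);
    ``rer`` maps protein id -> Recovery Error Rate.
    """

    per_protein: pd.DataFrame
    aggregates: pd.DataFrame = field(init=False)
    rer: pd.Series = field(init=False)

    def __post_init__(self) -> None:
        metrics = ["iou", "precision", "recall", "f1"]
        agg = self.per_protein.groupby(["ontology", "k"])[metrics].agg(["mean", "std"])
        agg.columns = [f"{m}_{s}" for m, s in agg.columns]
        self.aggregates = agg.reset_index()
        self.rer = (1.0 - self.per_protein.groupby("protein_id")["iou"].mean()).rename("rer")

    def mean_iou(self, ontology: str, k: int | None = None) -> float:
        sub = self.per_protein[self.per_protein["ontology"] == ontology]
        if k is not None:
            sub = sub[sub["k"] == k]
        return float(sub["iou"].mean())


def evaluate_recovery(m: RepresentationMatrix, annotations: AnnotationTable,
                      ontologies: Sequence[str],
                      c: RecoveryConfig = RecoveryConfig()) -> RecoveryReport:
    """Run the fivefold-CV kNN label-recovery benchmark.

    For each ontology the analysis is restricted to proteins labeled in
    that ontology. Folds are a seeded partition; for each fold a kNN
    index is built on the remaining folds and every held-out protein is
    scored at each neighborhood size in ``c.k_values``. The whole
    procedure is repeated ``c.n_repeats`` times with seeds derived as
    ``seed + repeat``.
    """
    available = annotations.ontologies()
    missing = [o for o in ontologies if o not in available]
    if missing:
        raise ValueError(
            f"ontologies not present in annotations: {missing}; available: {available}"
        )
    rows: list[tuple] = []
    for ontology in ontologies:
        labeled = [pid for pid in annotations.proteins(ontology) if pid in m._index]
        if len(labeled) < c.n_folds:
            raise ValueError(
                f"ontology {ontology!r}: {len(labeled)} labeled proteins "
                f"< n_folds={c.n_folds}"
            )
        labeled = np.asarray(sorted(labeled), dtype=object)
        for repeat in range(c.n_repeats):
            rng = np.random.default_rng(c.seed + repeat)
            folds = np.array_split(rng.permutation(len(labeled)), c.n_folds)
            for fold in folds:
                test_ids = labeled[fold]
                train_mask = np.ones(len(labeled), dtype=bool)
                train_mask[fold] = False
                train_ids = labeled[train_mask]
                index = KnnIndex(m.subset(train_ids))
                n_query = min(c.max_neighbors, len(train_ids))
                usable_k = [k for k in c.k_values if k <= n_query]
                for pid in test_ids:
                    truth = annotations.labels(pid, ontology)
                    neighbors = index.query(m.row(pid), n_query, exclude=pid)
                    neighbor_ids = [nid for nid, _ in neighbors]
                    for k in usable_k:
                        pred = predict_labels(neighbor_ids, k, annotations,
                                              ontology, c.aggregation)
                        rows.append((pid, ontology, k, repeat,
                                     set_iou(pred, truth), set_precision(pred, truth),
                                     set_recall(pred, truth), set_f1(pred, truth)))
    per_protein = pd.DataFrame(
        rows, columns=["protein_id", "ontology", "k", "repeat",
                       "iou", "precision", "recall", "f1"])
    return RecoveryReport(per_protein)


def recovery_error_rate(report: RecoveryReport) -> pd.Series:
    """Per-protein RER = 1 − mean IoU pooled over ontologies, k and repeats."""
    return report.rer
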